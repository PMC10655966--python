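"""On-disk artifact formats.

Encoded tensors go to a compressed ``.npz`` archive keyed by example id with
a JSON sidecar manifest; genotype matrices export as ms-style text or VCF;
tree sequences use the native tskit format; configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "save_encoded_archive",
    "load_encoded_archive",
    "write_ms",
    "write_vcf",
    "load_config",
    "save_config",
    "save_report",
]


def save_encoded_archive(path, encodings: dict, manifest: dict) -> None:
    """Write encoded tensors (id -> (m, m, 3) array) plus a JSON manifest."""
    path = Path(path)
    np.savez_compressed(path, **{str(k): np.asarray(v) for k, v in encodings.items()})
    sidecar = path.with_suffix(".manifest.json")
    sidecar.write_text(json.dumps(manifest, indent=2, default=float))


def load_encoded_archive(path):
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    manifest = json.loads(path.with_suffix(".manifest.json").read_text())
    return {k: data[k] for k in data.files}, manifest


def write_ms(path, ts) -> None:
    """Export a tree sequence's genotypes in ms-style text."""
    geno = ts.genotype_matrix()
    positions = [s.position / ts.sequence_length for s in ts.sites()]
    with open(path, "w") as fh:
        fh.write(f"ms {ts.num_samples} 1\n\n//\n")
        fh.write(f"segsites: {len(positions)}\n")
        fh.write("positions: " + " ".join(f"{p:.6f}" for p in positions) + "\n")
        for hap in np.clip(geno, 0, 1).T:
            fh.write("".join(str(int(v)) for v in hap) + "\n")


def write_vcf(path, ts) -> None:
    with open(path, "w") as fh:
        ts.write_vcf(fh)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def save_report(path, report) -> None:
    Path(path).write_text(report.to_json())
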