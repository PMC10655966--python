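"""Matched source/target scenario pairs and dataset assembly.

A :class:`ScenarioPair` fixes everything the benchmarking protocol needs:
the source-domain simulation configuration (always well-specified, with true
genealogies), the target-domain configuration carrying the chosen
mis-specification (bottleneck, background-selection surrogate, rho override,
genealogy-inference-error surrogate), and the task. ``assemble_dataset``
turns a pair into a :class:`DatasetBundle` with the split fractions, target
class mixture and source:target size ratio of the benchmarking protocol;
target labels are retained only in the held-out test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .demography import DemographyModel, equilibrium, bottleneck, european_demography
from .genealogy import encode_genealogy, extract_focal_genealogy, nearest_segregating_site
from .perturb import apply_inference_error
from .simulate import (
    BackgroundSelectionConfig,
    RelernnExample,
    SweepParams,
    apply_bgs_surrogate,
    equilibrium_ne,
    harmonic_number,
    simulate_region,
    simulate_relernn_example,
    watterson_theta,
)

__all__ = [
    "DomainConfig",
    "ScenarioPair",
    "DatasetBundle",
    "assemble_dataset",
    "equilibrium_source",
    "tree_inference_only_pair",
    "bottleneck_pair",
    "extreme_pair",
    "relernn_bgs_pair",
    "relernn_demography_pair",
    "relernn_no_misspec_pair",
    "MISSPEC_PRESETS",
]

TASKS = ("sweep_classification", "s_regression", "rho_regression")


@dataclass(frozen=True)
class DomainConfig:
    """Simulation configuration of one domain (source or target)."""

    demography: Any  # DemographyModel or "european"
    L: float
    mu: Any  # float or (lo, hi)
    rho: Any  # float or (lo, hi)
    n_samples: int
    sweep_s_range: tuple[float, float] = (0.002, 0.01)
    sweep_f_init: float = 0.0
    sweep_sampling: str = "fixation"
    sweep_f_range: tuple[float, float] = (0.05, 0.95)
    bgs: BackgroundSelectionConfig | None = None
    inference_error: tuple[float, float] | None = None  # (sigma_bl, p_nni)
    label: str = ""

    def resolve_demography(self):
        if self.demography == "european":
            return european_demography()
        return self.demography

    def draw_rate(self, value, rng) -> float:
        if isinstance(value, (tuple, list)):
            return float(rng.uniform(*value))
        return float(value)

    @property
    def present_ne(self) -> float:
        if self.demography == "european":
            return 512_000.0  # present-day European size (normalization only)
        return self.demography.epochs[0][1]


@dataclass(frozen=True)
class ScenarioPair:
    """A (source, target) simulation configuration pair for one task."""

    source: DomainConfig
    target: DomainConfig
    task: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if (
            self.source.L != self.target.L
            or self.source.n_samples != self.target.n_samples
        ):
            raise ValueError("source and target must share L and sample size")


# ---------------------------------------------------------------------------
# example generation
# ---------------------------------------------------------------------------

_DOMAIN_CODE = {"source": 0, "target": 1}


def _example_seed(seed: int, domain: str, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _DOMAIN_CODE[domain], int(index)])
    )


def simulate_genealogy_example(
    cfg: DomainConfig, task: str, sweep: bool, seed: int, domain: str, index: int
) -> tuple[np.ndarray, float, dict]:
    """One encoded-genealogy example: (stacked (n-1,n-1,3) tensor, label, meta).

    The focal site is the segregating site nearest the region centre; target
    domains with an inference-error surrogate perturb the genealogy before
    encoding (emulating inferred trees).
    """
    rng = _example_seed(seed, domain, index)
    mu = cfg.draw_rate(cfg.mu, rng)
    rho = cfg.draw_rate(cfg.rho, rng)
    demog = cfg.resolve_demography()
    meta: dict[str, Any] = {"mu": mu, "rho": rho, "sweep": sweep}
    if cfg.bgs is not None and isinstance(demog, DemographyModel):
        demog, b = apply_bgs_surrogate(cfg.bgs, demog, rng=rng)
        meta["B"] = b
    sweep_params = None
    s = np.nan
    if sweep:
        s = float(rng.uniform(*cfg.sweep_s_range))
        f = None
        if cfg.sweep_sampling == "frequency":
            f = float(rng.uniform(*cfg.sweep_f_range))
        sweep_params = SweepParams(
            s=s,
            sweep_position=float(np.floor(cfg.L / 2)),
            f_init=cfg.sweep_f_init,
            sampling=cfg.sweep_sampling,
            f=f,
        )
        meta["s"] = s
    ts = simulate_region(
        demog,
        cfg.L,
        mu,
        rho,
        cfg.n_samples,
        sweep=sweep_params,
        seed=int(rng.integers(1, 2**31)),
    )
    centre = float(np.floor(cfg.L / 2))
    site = nearest_segregating_site(ts, centre)
    if site is None:
        # a monomorphic region carries no focal site; encode without R
        g = extract_focal_genealogy(ts, centre, focal_site_required=False)
    else:
        g = extract_focal_genealogy(ts, site.position, focal_site_required=True)
    if cfg.inference_error is not None:
        sigma_bl, p_nni = cfg.inference_error
        g = apply_inference_error(
            g, sigma_bl, p_nni, seed=int(rng.integers(1, 2**31))
        )
    enc = encode_genealogy(g, require_derived=False)
    x = enc.stacked().astype(np.float32)
    if task == "sweep_classification":
        y = 1.0 if sweep else 0.0
    else:  # s_regression trains on log10(s)
        y = float(np.log10(s))
    return x, y, meta


def _thin_sites(example: RelernnExample, max_sites: int) -> RelernnExample:
    S = example.num_sites
    if S <= max_sites:
        return example
    idx = np.unique(np.round(np.linspace(0, S - 1, max_sites)).astype(int))
    return replace(
        example, genotypes=example.genotypes[idx], positions=example.positions[idx]
    )


def simulate_rho_example(
    cfg: DomainConfig, seed: int, domain: str, index: int
) -> tuple[RelernnExample, dict]:
    rng = _example_seed(seed, domain, index)
    demog = cfg.resolve_demography()
    meta: dict[str, Any] = {}
    if cfg.bgs is not None and isinstance(demog, DemographyModel):
        demog, b = apply_bgs_surrogate(cfg.bgs, demog, rng=rng)
        meta["B"] = b
    mu_range = cfg.mu if isinstance(cfg.mu, (tuple, list)) else (cfg.mu, cfg.mu)
    rho_range = cfg.rho if isinstance(cfg.rho, (tuple, list)) else (cfg.rho, cfg.rho)
    ex = simulate_relernn_example(
        demog,
        seed=int(rng.integers(1, 2**31)),
        L=cfg.L,
        n_samples=cfg.n_samples,
        mu_range=tuple(mu_range),
        rho_range=tuple(rho_range),
    )
    meta.update({"mu": ex.mu, "rho": ex.rho})
    return ex, meta


# ---------------------------------------------------------------------------
# dataset bundles
# ---------------------------------------------------------------------------


@dataclass
class DatasetBundle:
    """Assembled train/val/test arrays for one scenario pair.

    For genealogy tasks ``X`` arrays are (N, n-1, n-1, 3) float32 stacked
    F/W/R channels (raw, unnormalized). For the rho task ``X`` is a dict
    with ``geno`` (N, max_sites, n_samples) int8 0/1 padded with -128 and
    ``pos`` (N, max_sites) float32 positions normalized to [0, 1] (padding
    0). Target labels exist only in ``target_test``.
    """

    task: str
    source_train: tuple
    source_val: tuple
    source_test: tuple
    target_train: Any
    target_val: Any
    target_test: tuple
    manifest: dict = field(default_factory=dict)

    def counts(self) -> dict:
        def _n(x):
            return len(x["pos"]) if isinstance(x, dict) else len(x)

        return {
            "source_train": _n(self.source_train[0]),
            "source_val": _n(self.source_val[0]),
            "source_test": _n(self.source_test[0]),
            "target_train": _n(self.target_train),
            "target_val": _n(self.target_val),
            "target_test": _n(self.target_test[0]),
        }


PAD_GENO = -128


def _pack_rho_examples(
    examples: list[RelernnExample], max_sites: int, L: float
) -> dict:
    N = len(examples)
    n = examples[0].n_samples if N else 0
    geno = np.full((N, max_sites, n), PAD_GENO, dtype=np.int8)
    pos = np.zeros((N, max_sites), dtype=np.float32)
    nsites = np.zeros(N, dtype=np.int32)
    for k, ex in enumerate(examples):
        ex = _thin_sites(ex, max_sites)  # uniform thinning preserves span
        S = ex.num_sites
        geno[k, :S] = ex.genotypes
        pos[k, :S] = ex.positions / L
        nsites[k] = S
    return {"geno": geno, "pos": pos, "nsites": nsites}


def _split_counts(n: int, splits: tuple[float, float, float]) -> tuple[int, int, int]:
    if abs(sum(splits) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {splits}")
    n_train = int(round(n * splits[0]))
    n_val = int(round(n * splits[1]))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split fractions inconsistent with dataset size")
    return n_train, n_val, n_test


def assemble_dataset(
    pair: ScenarioPair,
    n_source: int,
    n_target: int | None = None,
    target_sweep_fraction: float = 0.5,
    source_target_ratio: float = 1.0,
    splits: tuple[float, float, float] = (0.9, 0.02, 0.08),
    seed: int = 0,
    max_sites: int = 480,
    progress: bool = False,
) -> DatasetBundle:
    """Simulate and assemble a full dataset bundle for one scenario pair.

    ``n_target`` defaults to ``n_source / source_target_ratio``. For
    classification, the source domain and the target *test* split are always
    class-balanced; ``target_sweep_fraction`` shapes only the unlabeled
    target training/validation data (the imbalance experiments). Every
    example is reproducible from ``(seed, domain, index)``.
    """
    if n_target is None:
        n_target = int(round(n_source / source_target_ratio))
    if not (0.0 <= target_sweep_fraction <= 1.0):
        raise ValueError("target_sweep_fraction must be in [0, 1]")
    task = pair.task
    s_tr, s_va, s_te = _split_counts(n_source, splits)
    t_tr, t_va, t_te = _split_counts(n_target, splits)

    manifest: dict[str, Any] = {
        "task": task,
        "label": pair.label,
        "seed": int(seed),
        "n_source": n_source,
        "n_target": n_target,
        "splits": list(splits),
        "target_sweep_fraction": target_sweep_fraction,
        "source_target_ratio": source_target_ratio,
    }

    # index offsets keep every (domain, split) example stream disjoint/stable
    def gen_genealogy(
        cfg: DomainConfig,
        domain: str,
        count: int,
        sweep_fraction: float,
        offset: int = 0,
    ):
        xs, ys, metas = [], [], []
        n_sweep = int(round(count * sweep_fraction))
        for idx in range(count):
            sweep = idx < n_sweep if task == "sweep_classification" else True
            x, y, m = simulate_genealogy_example(
                cfg, task, sweep, seed, domain, idx + offset
            )
            xs.append(x)
            ys.append(y)
            metas.append(m)
        return np.stack(xs), np.array(ys, dtype=np.float32), metas

    if task == "rho_regression":
        def gen_rho(cfg, domain, start, count):
            exs, metas = [], []
            for idx in range(start, start + count):
                ex, m = simulate_rho_example(cfg, seed, domain, idx)
                exs.append(ex)
                metas.append(m)
            return exs, metas

        src, src_meta = gen_rho(pair.source, "source", 0, n_source)
        tgt, tgt_meta = gen_rho(pair.target, "target", 0, n_target)
        X_src = _pack_rho_examples(src, max_sites, pair.source.L)
        X_tgt = _pack_rho_examples(tgt, max_sites, pair.target.L)
        y_src = np.array([e.rho for e in src], dtype=np.float64)
        y_tgt = np.array([e.rho for e in tgt], dtype=np.float64)

        def take(X, idx):
            return {k: v[idx] for k, v in X.items()}

        i_src = np.arange(n_source)
        i_tgt = np.arange(n_target)
        bundle = DatasetBundle(
            task=task,
            source_train=(take(X_src, i_src[:s_tr]), y_src[:s_tr]),
            source_val=(take(X_src, i_src[s_tr : s_tr + s_va]), y_src[s_tr : s_tr + s_va]),
            source_test=(take(X_src, i_src[s_tr + s_va :]), y_src[s_tr + s_va :]),
            target_train=take(X_tgt, i_tgt[:t_tr]),
            target_val=take(X_tgt, i_tgt[t_tr : t_tr + t_va]),
            target_test=(take(X_tgt, i_tgt[t_tr + t_va :]), y_tgt[t_tr + t_va :]),
            manifest=manifest,
        )
        manifest["max_sites"] = max_sites
        manifest["mean_sites_source"] = float(np.mean([e.num_sites for e in src]))
        manifest["mean_sites_target"] = float(np.mean([e.num_sites for e in tgt]))
        manifest["B_factors_target"] = [
            m["B"] for m in tgt_meta if "B" in m
        ][:50]
        return bundle

    # genealogy tasks
    Xs, ys, _ = gen_genealogy(pair.source, "source", n_source, 0.5)
    # shuffle source so sweep/neutral interleave across splits
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    perm = rng.permutation(n_source)
    Xs, ys = Xs[perm], ys[perm]
    # target: train/val at the requested mixture, test balanced
    Xt_big, yt_big, _ = gen_genealogy(
        pair.target, "target", t_tr + t_va, target_sweep_fraction, offset=10**6
    )
    permt = rng.permutation(t_tr + t_va)
    Xt_big = Xt_big[permt]
    Xt_test, yt_test, _ = gen_genealogy(
        pair.target, "target", t_te, 0.5, offset=2 * 10**6
    )
    bundle = DatasetBundle(
        task=task,
        source_train=(Xs[:s_tr], ys[:s_tr]),
        source_val=(Xs[s_tr : s_tr + s_va], ys[s_tr : s_tr + s_va]),
        source_test=(Xs[s_tr + s_va :], ys[s_tr + s_va :]),
        target_train=Xt_big[:t_tr],
        target_val=Xt_big[t_tr:],
        target_test=(Xt_test, yt_test),
        manifest=manifest,
    )
    return bundle


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------


def equilibrium_source(
    n_samples: int = 32,
    L: float = 100_000.0,
    ne: float = 10_000.0,
) -> DomainConfig:
    """The canonical well-specified source: equilibrium Ne=10,000, mu=rho=1.25e-8."""
    return DomainConfig(
        demography=equilibrium(ne),
        L=L,
        mu=1.25e-8,
        rho=1.25e-8,
        n_samples=n_samples,
        label="equilibrium_source",
    )


_DEFAULT_INFERR = (0.3, 0.05)  # (sigma_bl, p_nni) inference-error surrogate


def tree_inference_only_pair(
    task: str = "sweep_classification", n_samples: int = 32, L: float = 100_000.0
) -> ScenarioPair:
    """Target differs from source only through genealogy-inference error."""
    src = equilibrium_source(n_samples, L)
    tgt = replace(src, inference_error=_DEFAULT_INFERR, label="tree_inference_only")
    return ScenarioPair(source=src, target=tgt, task=task, label="tree_inference_only")


def bottleneck_pair(
    ne_bottleneck: float,
    task: str = "sweep_classification",
    n_samples: int = 32,
    L: float = 100_000.0,
) -> ScenarioPair:
    """Unmodeled bottleneck (Ne drop between generations 1,000-2,000) + inferred trees."""
    src = equilibrium_source(n_samples, L)
    tgt = replace(
        src,
        demography=bottleneck(ne_bottleneck),
        inference_error=_DEFAULT_INFERR,
        label=f"bottleneck_{ne_bottleneck:g}",
    )
    return ScenarioPair(
        source=src, target=tgt, task=task, label=f"bottleneck_{ne_bottleneck:g}"
    )


def extreme_pair(
    task: str = "sweep_classification", n_samples: int = 32, L: float = 100_000.0
) -> ScenarioPair:
    """5% bottleneck + background selection + 8-fold mis-specified rho."""
    src = equilibrium_source(n_samples, L)
    genic = (L / 2 - 5_000, L / 2 + 5_000)
    tgt = replace(
        src,
        demography=bottleneck(500.0),
        rho=1e-7,
        bgs=BackgroundSelectionConfig(genic_span=genic),
        inference_error=_DEFAULT_INFERR,
        label="extreme",
    )
    return ScenarioPair(source=src, target=tgt, task=task, label="extreme")


def relernn_bgs_pair(n_samples: int = 32, L: float = 300_000.0) -> ScenarioPair:
    """Recombination task; target has the central 100 kb under purifying selection."""
    src = DomainConfig(
        demography=equilibrium(10_000.0),
        L=L,
        mu=(1.875e-8, 3.125e-8),
        rho=(0.0, 6.25e-8),
        n_samples=n_samples,
        label="relernn_bgs_source",
    )
    genic = (L / 2 - 50_000, L / 2 + 50_000)
    tgt = replace(
        src,
        bgs=BackgroundSelectionConfig(genic_span=genic),
        label="relernn_bgs_target",
    )
    return ScenarioPair(source=src, target=tgt, task="rho_regression", label="relernn_bgs")


def relernn_no_misspec_pair(n_samples: int = 32, L: float = 300_000.0) -> ScenarioPair:
    """Source and target drawn from the identical distribution (safety check)."""
    src = DomainConfig(
        demography=equilibrium(10_000.0),
        L=L,
        mu=(1.875e-8, 3.125e-8),
        rho=(0.0, 6.25e-8),
        n_samples=n_samples,
        label="relernn_no_misspec",
    )
    return ScenarioPair(
        source=src, target=src, task="rho_regression", label="relernn_no_misspec"
    )


def relernn_demography_pair(
    seed: int = 0,
    pilot_regions: int = 300,
    n_samples: int = 32,
    L: float = 300_000.0,
) -> tuple[ScenarioPair, dict]:
    """Recombination task with a mis-specified (equilibrium) source demography.

    The target is the packaged European out-of-Africa model. The source Ne
    is what a practitioner would use: the mean per-region Watterson theta of
    pilot "real" (target) data divided by four times the mean mutation rate.
    Returns the pair and a dict with the pilot estimate.
    """
    mu_range = (1.875e-8, 3.125e-8)
    rho_range = (0.0, 6.25e-8)
    tgt = DomainConfig(
        demography="european",
        L=L,
        mu=mu_range,
        rho=rho_range,
        n_samples=n_samples,
        label="relernn_demography_target",
    )
    thetas = []
    for idx in range(pilot_regions):
        ex, _ = simulate_rho_example(tgt, seed, "target", 10**7 + idx)
        thetas.append(watterson_theta(ex.num_sites, n_samples, L))
    mu_bar = 0.5 * (mu_range[0] + mu_range[1])
    ne_hat = equilibrium_ne(float(np.mean(thetas)), mu_bar)
    src = DomainConfig(
        demography=equilibrium(ne_hat),
        L=L,
        mu=mu_range,
        rho=rho_range,
        n_samples=n_samples,
        label=f"relernn_demography_source_Ne{ne_hat:.0f}",
    )
    pair = ScenarioPair(
        source=src, target=tgt, task="rho_regression", label="relernn_demography"
    )
    info = {
        "ne_hat": float(ne_hat),
        "mean_theta_w": float(np.mean(thetas)),
        "mu_bar": mu_bar,
        "pilot_regions": pilot_regions,
    }
    return pair, info


MISSPEC_PRESETS = {
    "tree_inference_only": lambda **kw: tree_inference_only_pair(**kw),
    "bottleneck_8000": lambda **kw: bottleneck_pair(8000.0, **kw),
    "bottleneck_5000": lambda **kw: bottleneck_pair(5000.0, **kw),
    "bottleneck_2000": lambda **kw: bottleneck_pair(2000.0, **kw),
    "bottleneck_500": lambda **kw: bottleneck_pair(500.0, **kw),
    "extreme": lambda **kw: extreme_pair(**kw),
}
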