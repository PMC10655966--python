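"""Gradient-reversal network assembly for the three inference tasks.

A :class:`DannNetwork` is three addressable components joined as in the
domain-adversarial architecture: a feature extractor shared by both heads,
a label predictor (sweep class probabilities, log10 selection coefficient,
or recombination rate), and a domain classifier attached through a
:class:`popdann.nn.GradientReversal` layer. The standard (non-adaptive)
variant is the same network with the domain branch detached; it shares the
feature-extractor and label-predictor parameters.

The exact layer dimensions of the original networks are unpublished;
the defaults here are small strided convolutional stacks sized for
single-CPU training and are configuration, not claims. Regression targets
are standardized internally (selection coefficients as log10(s),
recombination rates in units of 1e-8/bp); predictions are returned in
natural units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    Conv1D,
    Conv2D,
    Dense,
    GlobalAvgPool1D,
    GlobalAvgPool2D,
    GradientReversal,
    ReLU,
    Sequential,
    softmax,
)
from .scenarios import PAD_GENO

__all__ = [
    "NetworkSpec",
    "DannNetwork",
    "PredictionResult",
    "build_network",
    "predict",
    "batch_input",
]

TASKS = ("sweep_classification", "s_regression", "rho_regression")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture configuration for one task.

    ``input_shape`` is ``(n-1, n-1, 3)`` for genealogy input (stacked F/W/R)
    or ``(max_sites, n_samples)`` for genotype input. ``width`` scales the
    default channel counts; ``w_scale`` normalizes the W channel
    (generations) and defaults to 4*Ne_ref.
    """

    task: str
    input_shape: tuple
    width: int = 16
    feature_dim: int = 32
    grl_lambda: float = 1.0
    w_scale: float = 40_000.0
    rho_unit: float = 1e-8
    # genotype-branch encoding: "ld_profile" summarizes the genotype matrix
    # into a fixed-length linkage-disequilibrium/diversity profile before the
    # (dense) feature extractor; "raw" feeds -1/1 genotype + position + gap
    # channels to a strided 1-D conv stack
    input_encoding: str = "ld_profile"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.task in ("sweep_classification", "s_regression"):
            if len(self.input_shape) != 3 or self.input_shape[2] != 3:
                raise ValueError(
                    f"genealogy task expects (n-1, n-1, 3) input, got "
                    f"{self.input_shape}"
                )
            if self.input_shape[0] != self.input_shape[1]:
                raise ValueError("genealogy channels must be square")
        else:
            if len(self.input_shape) != 2:
                raise ValueError(
                    f"genotype task expects (max_sites, n_samples) input, got "
                    f"{self.input_shape}"
                )

    @property
    def is_genealogy(self) -> bool:
        return self.task in ("sweep_classification", "s_regression")

    @property
    def n_label_out(self) -> int:
        return 2 if self.task == "sweep_classification" else 1


@dataclass(frozen=True)
class PredictionResult:
    """Per-example prediction in natural units."""

    p_neutral: float | None = None
    p_sweep: float | None = None
    estimate: float | None = None


class DannNetwork:
    """Feature extractor + label predictor + domain classifier (via GRL)."""

    def __init__(self, spec: NetworkSpec, fe: Sequential, lh: Sequential, dh: Sequential):
        self.spec = spec
        self.feature_extractor = fe
        self.label_predictor = lh
        self.domain_classifier = dh  # first layer is the GRL
        self._domain_attached = True

    # -- component bookkeeping --------------------------------------------

    def parameter_counts(self) -> dict[str, int]:
        return {
            "feature_extractor": self.feature_extractor.n_params(),
            "label_predictor": self.label_predictor.n_params(),
            "domain_classifier": self.domain_classifier.n_params(),
            "total": (
                self.feature_extractor.n_params()
                + self.label_predictor.n_params()
                + self.domain_classifier.n_params()
            ),
        }

    @property
    def grl(self) -> GradientReversal:
        return self.domain_classifier.layers[0]

    def trainable_params(self, domain_adaptive: bool = True):
        ps = self.feature_extractor.params() + self.label_predictor.params()
        if domain_adaptive:
            ps = ps + self.domain_classifier.params()
        return ps

    def standard_variant(self) -> "DannNetwork":
        """The same network with the domain branch detached (shared weights)."""
        clone = DannNetwork(
            self.spec, self.feature_extractor, self.label_predictor,
            self.domain_classifier,
        )
        clone._domain_attached = False
        return clone

    # -- forward passes ----------------------------------------------------

    def features(self, x, train: bool = False):
        return self.feature_extractor.forward(x, train=train)

    def label_logits(self, x, train: bool = False):
        f, fc = self.features(x, train=train)
        out, lc = self.label_predictor.forward(f, train=train)
        return out, (fc, lc)

    def domain_logits(self, x, train: bool = False):
        if not self._domain_attached:
            raise RuntimeError("domain branch is detached on the standard variant")
        f, fc = self.features(x, train=train)
        out, dc = self.domain_classifier.forward(f, train=train)
        return out, (fc, dc)

    def domain_probabilities(self, x) -> np.ndarray:
        logits, _ = self.domain_logits(x)
        return softmax(logits)

    # -- serialization -------------------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.trainable_params(True)]

    def set_state(self, state) -> None:
        for p, v in zip(self.trainable_params(True), state):
            p.value[...] = v

    def architecture_manifest(self) -> dict:
        return {
            "task": self.spec.task,
            "input_shape": list(self.spec.input_shape),
            "grl_lambda": self.grl.lam,
            "parameter_counts": self.parameter_counts(),
        }


def _head(n_in, n_hidden, n_out, rng) -> list:
    return [Dense(n_in, n_hidden, rng), ReLU(), Dense(n_hidden, n_out, rng)]


def build_network(spec: NetworkSpec, seed: int = 0) -> DannNetwork:
    """Assemble the three-component GRL network for ``spec``.

    Component initializations draw from independent child seeds, so the
    feature extractor and label predictor of a standard and a
    domain-adaptive network built from the same seed start identical.
    """
    ss = np.random.SeedSequence(seed)
    rng_fe, rng_lh, rng_dh = (np.random.default_rng(c) for c in ss.spawn(3))
    w = spec.width
    fd = spec.feature_dim
    if spec.is_genealogy:
        m = spec.input_shape[0]
        if m < 7:
            fe = Sequential(
                [Conv2D(3, w, 2, 1, rng_fe), ReLU(), GlobalAvgPool2D(),
                 Dense(w, fd, rng_fe), ReLU()]
            )
        else:
            fe = Sequential(
                [
                    Conv2D(3, w, 3, 2, rng_fe),
                    ReLU(),
                    Conv2D(w, 2 * w, 3, 2, rng_fe),
                    ReLU(),
                    GlobalAvgPool2D(),
                    Dense(2 * w, fd, rng_fe),
                    ReLU(),
                ]
            )
    elif spec.input_encoding == "ld_profile":
        fe = Sequential(
            [
                Dense(LD_PROFILE_DIM, 4 * w, rng_fe),
                ReLU(),
                Dense(4 * w, fd, rng_fe),
                ReLU(),
            ]
        )
    else:
        c_in = spec.input_shape[1] + 2  # haplotypes + position + gap channels
        fe = Sequential(
            [
                Conv1D(c_in, w, 7, 3, rng_fe),
                ReLU(),
                Conv1D(w, 2 * w, 5, 3, rng_fe),
                ReLU(),
                Conv1D(2 * w, 2 * w, 3, 2, rng_fe),
                ReLU(),
                GlobalAvgPool1D(),
                Dense(2 * w, fd, rng_fe),
                ReLU(),
            ]
        )
    lh = Sequential(_head(fd, 2 * fd, spec.n_label_out, rng_lh))
    dh = Sequential([GradientReversal(spec.grl_lambda)] + _head(fd, fd, 2, rng_dh))
    return DannNetwork(spec, fe, lh, dh)


# ---------------------------------------------------------------------------
# input building and prediction
# ---------------------------------------------------------------------------

# LD/diversity profile of one genotype matrix: adjacent-pair r^2 in distance
# bins + folded SFS bins + segregating-site/spacing scalars
_LD_BINS = 12
_LD_MAX_DIST = 1.0 / 15.0  # fraction of the region (20 kb of a 300 kb region)
_SFS_BINS = 8
LD_PROFILE_DIM = _LD_BINS + _SFS_BINS + 4


def _ld_profile_single(geno: np.ndarray, pos: np.ndarray, nsites: int) -> np.ndarray:
    """Fixed-length LD/diversity summary of one (padded) genotype matrix.

    Mean r^2 between nearby site pairs (lags 1,2,3,5,8) binned by pairwise
    distance, the folded site-frequency spectrum, and scalar diversity
    summaries. A deterministic function of the (genotypes, positions)
    input; recombination leaves its footprint in the distance-resolved LD
    decay, demography in the SFS and overall diversity.
    """
    out = np.zeros(LD_PROFILE_DIM, dtype=np.float32)
    S = int(nsites)
    if S < 3:
        return out
    g = geno[:S].astype(np.float32)
    ps = pos[:S].astype(np.float64)
    n = g.shape[1]
    p = g.mean(axis=1)
    seg = (p > 0) & (p < 1)
    g, ps, p = g[seg], ps[seg], p[seg]
    S = len(ps)
    if S < 3:
        return out
    bins = np.linspace(0.0, _LD_MAX_DIST, _LD_BINS + 1)
    r2sum = np.zeros(_LD_BINS)
    cnt = np.zeros(_LD_BINS)
    for lag in (1, 2, 3, 5, 8):
        if S <= lag:
            break
        a, b = g[:-lag], g[lag:]
        pa, pb = p[:-lag], p[lag:]
        D = (a * b).mean(axis=1) - pa * pb
        r2 = D**2 / np.maximum(pa * (1 - pa) * pb * (1 - pb), 1e-12)
        d = ps[lag:] - ps[:-lag]
        k = np.digitize(d, bins) - 1
        ok = (k >= 0) & (k < _LD_BINS)
        np.add.at(r2sum, k[ok], r2[ok])
        np.add.at(cnt, k[ok], 1)
    out[:_LD_BINS] = r2sum / np.maximum(cnt, 1)
    folded = np.minimum(p, 1 - p)
    sfs, _ = np.histogram(folded, bins=np.linspace(0, 0.5, _SFS_BINS + 1))
    out[_LD_BINS : _LD_BINS + _SFS_BINS] = sfs / S
    gaps = ps[1:] - ps[:-1]
    out[-4:] = (
        S / 500.0,
        p.mean(),
        float(np.mean(gaps)) * 100.0,
        float(np.median(gaps)) * 100.0,
    )
    return out


def ld_profile(X: dict, idx=None) -> np.ndarray:
    """LD/diversity profiles for a packed genotype dataset (cached in X)."""
    if "_ld" not in X:
        N = len(X["pos"])
        feats = np.empty((N, LD_PROFILE_DIM), dtype=np.float32)
        for k in range(N):
            feats[k] = _ld_profile_single(
                X["geno"][k], X["pos"][k], X["nsites"][k]
            )
        X["_ld"] = feats
    return X["_ld"] if idx is None else X["_ld"][idx]


def batch_input(spec: NetworkSpec, X, idx=None) -> np.ndarray:
    """Build the float network input for a batch.

    Genealogy tasks: transpose the (B, m, m, 3) stack to channels-first and
    scale F and R by 1/n, W by 1/w_scale. Genotype task: either the cached
    LD/diversity profile (default) or, with ``input_encoding="raw"``,
    -1/1-coded genotypes (padding 0) plus the normalized positions channel
    and the inter-site gap channel.
    """
    if spec.is_genealogy:
        x = X if idx is None else X[idx]
        x = np.ascontiguousarray(x.transpose(0, 3, 1, 2)).astype(np.float32)
        n = spec.input_shape[0] + 1
        x[:, 0] /= n
        x[:, 1] /= spec.w_scale
        x[:, 2] /= n
        return x
    if spec.input_encoding == "ld_profile":
        return ld_profile(X, idx)
    geno = X["geno"] if idx is None else X["geno"][idx]
    pos = X["pos"] if idx is None else X["pos"][idx]
    B, S, n = geno.shape
    g = geno.astype(np.float32)
    pad = geno == PAD_GENO
    g = np.where(pad, 0.0, 2.0 * g - 1.0)  # 0/1 -> -1/+1; padding -> 0
    x = np.empty((B, n + 2, S), dtype=np.float32)
    x[:, :n] = g.transpose(0, 2, 1)
    x[:, n] = pos
    gaps = np.diff(pos, axis=1, prepend=0.0)
    gaps[pos == 0.0] = 0.0
    x[:, n + 1] = gaps * 50.0  # typical gaps are ~1/S; rescale toward O(1)
    return x


def label_transform(spec: NetworkSpec, y: np.ndarray) -> np.ndarray:
    """Natural-unit labels -> training scale."""
    if spec.task == "rho_regression":
        return (y / spec.rho_unit).astype(np.float32)
    return np.asarray(y, dtype=np.float32)


def label_inverse(spec: NetworkSpec, out: np.ndarray) -> np.ndarray:
    """Training-scale label-head output -> natural units."""
    if spec.task == "rho_regression":
        return out.reshape(-1).astype(float) * spec.rho_unit
    if spec.task == "s_regression":
        return 10.0 ** out.reshape(-1).astype(float)
    return out


def predict(model: DannNetwork, X, idx=None, batch_size: int = 256) -> list[PredictionResult]:
    """Deterministic inference-mode predictions for a batch.

    Classification returns (P_neu, P_sweep); regression the point estimate
    in natural units (per-bp rho, or the selection coefficient s).
    """
    spec = model.spec
    N = (len(X["pos"]) if isinstance(X, dict) else len(X)) if idx is None else len(idx)
    order = np.arange(N) if idx is None else np.asarray(idx)
    results: list[PredictionResult] = []
    for k in range(0, N, batch_size):
        sl = order[k : k + batch_size]
        x = batch_input(spec, X, sl)
        out, _ = model.label_logits(x, train=False)
        if spec.task == "sweep_classification":
            p = softmax(out)
            for row in p:
                results.append(
                    PredictionResult(p_neutral=float(row[0]), p_sweep=float(row[1]))
                )
        else:
            est = label_inverse(spec, out)
            results.extend(PredictionResult(estimate=float(v)) for v in est)
    return results


def predict_values(model: DannNetwork, X, idx=None, batch_size: int = 256) -> np.ndarray:
    """Vector of sweep probabilities (classification) or estimates (regression)."""
    res = predict(model, X, idx=idx, batch_size=batch_size)
    if model.spec.task == "sweep_classification":
        return np.array([r.p_sweep for r in res])
    return np.array([r.estimate for r in res])
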