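"""Coalescent simulation of source/target domains.

All simulation goes through msprime. Sweep simulations use the structured
genic-selection model (beneficial allele at a chosen position, conditioned on
reaching a sampling frequency), neutral simulations the standard coalescent.
Rates are per-bp per-generation; coordinates 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import msprime
import numpy as np

from .demography import DemographyModel, equilibrium

__all__ = [
    "SweepParams",
    "BackgroundSelectionConfig",
    "SimulationError",
    "simulate_region",
    "simulate_relernn_example",
    "RelernnExample",
    "apply_bgs_surrogate",
    "watterson_theta",
    "equilibrium_ne",
    "harmonic_number",
]


class SimulationError(RuntimeError):
    """Simulation backend failed (e.g. sweep did not establish)."""


@dataclass(frozen=True)
class SweepParams:
    """Parameters of a selective sweep at a focal position.

    ``f_init`` > 0 gives a soft sweep from standing variation; 0 a hard
    sweep from a new mutation. ``sampling`` is the condition at sampling
    time: ``"fixation"`` (allele has just fixed) or ``"frequency"`` (allele
    segregates at frequency ``f``).
    """

    s: float
    sweep_position: float
    f_init: float = 0.0
    h_sweep: float = 0.5
    sampling: str = "fixation"
    f: float | None = None

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("selection coefficient s must be positive")
        if not (0 <= self.f_init < 1):
            raise ValueError("f_init must be in [0, 1)")
        if self.sampling not in ("fixation", "frequency"):
            raise ValueError(f"unknown sampling condition {self.sampling!r}")
        if self.sampling == "frequency" and not (self.f and 0 < self.f < 1):
            raise ValueError("segregating sampling requires f in (0, 1)")


@dataclass(frozen=True)
class BackgroundSelectionConfig:
    """Purifying selection acting on a central genic region.

    The deleterious DFE is gamma with mean ``dfe_mean`` (negative), shape
    ``dfe_shape`` and dominance ``h``. In ``surrogate`` mode the linked
    diversity reduction is emulated by rescaling Ne with a factor
    ``B ~ U[b_range]`` per region; ``external`` mode expects forward-simulated
    tree sequences via the ingest adapter.
    """

    genic_span: tuple[float, float]
    dfe_mean: float = -0.03
    dfe_shape: float = 0.2
    h: float = 0.25
    mode: str = "surrogate"
    b_range: tuple[float, float] = (0.7, 0.95)

    def __post_init__(self) -> None:
        if self.dfe_mean >= 0:
            raise ValueError("dfe_mean must be negative")
        if self.dfe_shape <= 0:
            raise ValueError("dfe_shape must be positive")
        if not (0 <= self.h <= 1):
            raise ValueError("dominance h must be in [0, 1]")
        if self.mode not in ("surrogate", "external"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _resolve_demography(demography):
    if isinstance(demography, DemographyModel):
        return demography.to_msprime(), None
    if isinstance(demography, msprime.Demography):
        # sample from EUR when present (the packaged European model)
        names = [p.name for p in demography.populations]
        return demography, ("EUR" if "EUR" in names else None)
    raise TypeError(f"unsupported demography {type(demography)}")


def simulate_region(
    demography,
    L: float,
    mu: float,
    rho: float,
    n_samples: int,
    sweep: SweepParams | None = None,
    seed: int | None = None,
    max_retries: int = 10,
) -> "msprime.TreeSequence":
    """Simulate a region of ``n_samples`` haploid genomes over ``[0, L)``.

    With ``sweep``, a structured-coalescent sweep at ``sweep.sweep_position``
    is simulated, conditioned on the allele frequency implied by the sampling
    condition; the backend is retried up to ``max_retries`` times on failure.
    Fully reproducible from ``seed``.
    """
    if L <= 0 or mu < 0 or rho < 0 or n_samples < 2:
        raise ValueError("parameters must be positive (n_samples >= 2)")
    if n_samples % 2:
        raise ValueError("n_samples must be even (diploid individuals)")
    demog, pop = _resolve_demography(demography)
    samples = {pop: n_samples // 2} if pop else n_samples // 2
    rng = np.random.default_rng(seed)
    model = None
    if sweep is not None:
        if not (0 <= sweep.sweep_position < L):
            raise ValueError("sweep_position outside region")
        if isinstance(demography, DemographyModel):
            ne = demography.epochs[0][1]
        else:
            ne = demog.populations[0].initial_size
        lo = 1.0 / (2 * ne)
        start = sweep.f_init if sweep.f_init > 0 else lo
        end = 1 - lo if sweep.sampling == "fixation" else sweep.f
        model = [
            msprime.SweepGenicSelection(
                position=sweep.sweep_position,
                start_frequency=start,
                end_frequency=end,
                s=sweep.s,
                dt=1.0 / (40 * ne),
            ),
            msprime.StandardCoalescent(),
        ]
    multi_epoch_sweep = (
        sweep is not None
        and isinstance(demography, DemographyModel)
        and len(demography.epochs) > 1
    )
    last_err: Exception | None = None
    for _ in range(max_retries):
        anc_seed = int(rng.integers(1, 2**31))
        mut_seed = int(rng.integers(1, 2**31))
        try:
            if multi_epoch_sweep:
                ts = _two_stage_sweep(
                    demography, L, rho, samples, model[0], anc_seed
                )
            else:
                ts = msprime.sim_ancestry(
                    samples=samples,
                    ploidy=2,
                    sequence_length=L,
                    recombination_rate=rho,
                    demography=demog,
                    model=model,
                    random_seed=anc_seed,
                )
            return msprime.sim_mutations(
                ts,
                rate=mu,
                random_seed=mut_seed,
                model=msprime.BinaryMutationModel(),
            )
        except Exception as err:  # msprime LibraryError on failed sweep
            last_err = err
    raise SimulationError(
        f"simulation failed after {max_retries} attempts: {last_err}"
    )


def _two_stage_sweep(
    demography: DemographyModel, L, rho, samples, sweep_model, seed: int
):
    """Sweep under a non-constant demography, in two stages.

    The structured sweep coalescent cannot process demographic events
    mid-sweep, so the sweep phase runs under the present-epoch constant
    size; the remaining (more ancient) history then continues under the
    full demography, with any epoch change that would have fallen inside
    the sweep window deferred to just after it. Neutral examples of the
    same domain carry the exact demography.
    """
    ne0 = demography.epochs[0][1]
    rng = np.random.default_rng(seed)
    ts1 = msprime.sim_ancestry(
        samples=samples,
        ploidy=2,
        sequence_length=L,
        recombination_rate=rho,
        demography=equilibrium(ne0).to_msprime(),
        model=[sweep_model],
        random_seed=int(rng.integers(1, 2**31)),
    )
    if all(tree.num_roots == 1 for tree in ts1.trees()):
        return ts1
    t_end = ts1.max_root_time
    shifted = [(0.0, ne0)]
    last = t_end
    for start, ne in demography.epochs[1:]:
        last = max(start, last * (1 + 1e-9))
        shifted.append((last, ne))
    d2 = DemographyModel(epochs=tuple(shifted), label=demography.label + "_deferred")
    ts2 = msprime.sim_ancestry(
        initial_state=ts1,
        demography=d2.to_msprime(),
        recombination_rate=rho,
        random_seed=int(rng.integers(1, 2**31)),
    )
    # drop the unary stage-boundary nodes the continuation leaves behind
    return ts2.simplify()


@dataclass(frozen=True)
class RelernnExample:
    """One labeled recombination-rate example.

    ``genotypes`` is (num_sites, n_samples) 0/1 int8 (ancestral/derived);
    ``positions`` are bp coordinates; the label is the drawn per-bp ``rho``.
    An example with zero segregating sites is kept with empty arrays.
    """

    genotypes: np.ndarray
    positions: np.ndarray
    rho: float
    mu: float
    L: float
    n_samples: int

    @property
    def num_sites(self) -> int:
        return self.genotypes.shape[0]


def simulate_relernn_example(
    demography,
    seed: int,
    L: float = 300_000.0,
    n_samples: int = 32,
    mu_range: tuple[float, float] = (1.875e-8, 3.125e-8),
    rho_range: tuple[float, float] = (0.0, 6.25e-8),
) -> RelernnExample:
    """One recombination-rate training example.

    The per-example mutation and recombination rates are drawn uniformly
    from ``mu_range`` and ``rho_range``; the drawn rho is the label.
    """
    rng = np.random.default_rng(seed)
    mu = float(rng.uniform(*mu_range))
    rho = float(rng.uniform(*rho_range))
    ts = simulate_region(
        demography, L, mu, rho, n_samples, seed=int(rng.integers(1, 2**31))
    )
    geno = ts.genotype_matrix().astype(np.int8)
    positions = np.array([s.position for s in ts.sites()])
    # drop non-biallelic / non-segregating rows (rare with the binary model)
    keep = [
        k
        for k in range(geno.shape[0])
        if 0 < int((geno[k] > 0).sum()) < n_samples
    ]
    geno = np.clip(geno[keep], 0, 1)
    positions = positions[keep]
    return RelernnExample(
        genotypes=geno,
        positions=positions,
        rho=rho,
        mu=mu,
        L=L,
        n_samples=n_samples,
    )


def apply_bgs_surrogate(
    config: BackgroundSelectionConfig,
    base_demography: DemographyModel,
    rng: np.random.Generator | None = None,
    b_factor: float | None = None,
) -> tuple[DemographyModel, float]:
    """Region-wide rescaled-Ne surrogate for background selection.

    Returns the scaled demography and the diversity-reduction factor ``B``
    (drawn ``U[b_range]`` unless given). ``B = 1`` leaves the configuration
    unchanged. ``external`` mode is handled by the ingest adapter, not here.
    """
    if config.mode != "surrogate":
        raise ValueError(
            "apply_bgs_surrogate requires mode='surrogate'; external mode "
            "ingests forward-simulated tree sequences instead"
        )
    if b_factor is None:
        if rng is None:
            raise ValueError("need an rng to draw B (or pass b_factor)")
        b_factor = float(rng.uniform(*config.b_range))
    if not (0 < b_factor <= 1):
        raise ValueError("B must be in (0, 1]")
    if b_factor == 1.0:
        return base_demography, 1.0
    scaled = DemographyModel(
        epochs=tuple((s, ne * b_factor) for s, ne in base_demography.epochs),
        label=f"{base_demography.label}_B{b_factor:.3f}",
    )
    return scaled, b_factor


def harmonic_number(n: int) -> float:
    """a_n = sum_{k=1}^{n} 1/k."""
    return float(sum(1.0 / k for k in range(1, n + 1)))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's per-bp theta: S / (a_{n-1} * L) for n haploid samples."""
    if n < 2:
        raise ValueError("need at least 2 haploid samples")
    if L <= 0:
        raise ValueError("L must be positive")
    if S < 0:
        raise ValueError("segregating-site count cannot be negative")
    return S / (harmonic_number(n - 1) * L)


def equilibrium_ne(theta_w: float, mu: float) -> float:
    """Effective size implied by Watterson theta at equilibrium: theta/(4 mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return theta_w / (4.0 * mu)
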