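"""Demographic models for source/target simulation domains.

Two kinds of model are used throughout the package:

* :class:`DemographyModel` -- a single-population piecewise-constant size
  history (present-first epochs), sufficient for the equilibrium and
  bottleneck scenarios.
* the packaged European out-of-Africa model (two demes plus migration,
  parameters in ``data/european_demography.yaml``), used as the target
  domain of the recombination-rate demography experiment.

Both convert to :class:`msprime.Demography` for simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import msprime
import yaml

__all__ = [
    "DemographyModel",
    "equilibrium",
    "bottleneck",
    "european_demography",
    "load_european_model",
]


@dataclass(frozen=True)
class DemographyModel:
    """Piecewise-constant single-population size history.

    ``epochs`` is a list of ``(start_generation, Ne)`` pairs, present first;
    epoch starts must be strictly increasing from 0 and every Ne positive.
    Ne is the diploid effective size.
    """

    epochs: tuple[tuple[float, float], ...]
    label: str = "unnamed"

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch required")
        starts = [s for s, _ in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at generation 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch starts must be strictly increasing")
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("all Ne must be positive")
        object.__setattr__(
            self, "epochs", tuple((float(s), float(ne)) for s, ne in self.epochs)
        )

    def to_msprime(self) -> msprime.Demography:
        d = msprime.Demography()
        d.add_population(name="pop0", initial_size=self.epochs[0][1])
        for start, ne in self.epochs[1:]:
            d.add_population_parameters_change(
                time=start, population="pop0", initial_size=ne, growth_rate=0
            )
        return d

    @property
    def sample_population(self) -> str:
        return "pop0"


def equilibrium(ne: float = 10_000.0) -> DemographyModel:
    """Constant-size equilibrium demography (source-domain default)."""
    return DemographyModel(epochs=((0.0, ne),), label=f"equilibrium_Ne{ne:g}")


def bottleneck(
    ne_bottleneck: float,
    ne: float = 10_000.0,
    start: float = 1_000.0,
    end: float = 2_000.0,
) -> DemographyModel:
    """Instantaneous bottleneck between ``start`` and ``end`` generations ago.

    The population is at size ``ne`` at present, drops to ``ne_bottleneck``
    between 1,000 and 2,000 generations before present (defaults), and is at
    ``ne`` again further in the past.
    """
    return DemographyModel(
        epochs=((0.0, ne), (start, ne_bottleneck), (end, ne)),
        label=f"bottleneck_Ne{ne_bottleneck:g}",
    )


def load_european_model() -> dict:
    """The raw parameter dictionary of the packaged European model fixture."""
    with resources.files("popdann.data").joinpath(
        "european_demography.yaml"
    ).open() as fh:
        return yaml.safe_load(fh)


def european_demography() -> msprime.Demography:
    """The packaged European out-of-Africa demography (two demes + migration).

    European samples experience an ancestral size of ~7,310, an out-of-Africa
    bottleneck (Ne 1,861), a second epoch growing from Ne 1,032, and rapid
    recent exponential growth, with continuing gene flow from the African
    deme. Sample from population ``EUR``.
    """
    p = load_european_model()
    ev = p["events"]
    mig = p["migration"]
    pops = {q["name"]: q for q in p["populations"]}
    t_eg = float(ev["recent_growth_start_gen"])
    t_eu0 = float(ev["eur_second_epoch"]["end_gen"])
    t_ooa = float(ev["out_of_africa_split_gen"])
    t_af = float(ev["african_expansion"]["end_gen"])
    r_af = float(pops["AFR"]["growth_rate_recent"])
    r_eu = float(pops["EUR"]["growth_rate_recent"])
    r_eu0 = float(ev["eur_second_epoch"]["growth_rate"])
    n_af1 = float(pops["AFR"]["size_at_growth_onset"])
    n_eu1 = float(pops["EUR"]["size_at_growth_onset"])
    n_b = float(ev["eur_bottleneck"]["size"])
    n_anc = float(ev["ancestral_size"])

    d = msprime.Demography()
    d.add_population(
        name="AFR",
        initial_size=n_af1 * math.exp(r_af * t_eg),
        growth_rate=r_af,
        initially_active=True,
    )
    d.add_population(
        name="EUR", initial_size=n_eu1 * math.exp(r_eu * t_eg), growth_rate=r_eu
    )
    d.set_symmetric_migration_rate(["AFR", "EUR"], float(mig["recent_rate"]))
    d.add_population_parameters_change(
        time=t_eg, population="AFR", growth_rate=0, initial_size=n_af1
    )
    d.add_population_parameters_change(
        time=t_eg, population="EUR", growth_rate=r_eu0, initial_size=n_eu1
    )
    d.add_population_parameters_change(
        time=t_eu0, population="EUR", growth_rate=0, initial_size=n_b
    )
    d.add_symmetric_migration_rate_change(
        time=t_eu0, populations=["AFR", "EUR"], rate=float(mig["bottleneck_rate"])
    )
    d.add_symmetric_migration_rate_change(
        time=t_ooa, populations=["AFR", "EUR"], rate=0
    )
    d.add_population_split(time=t_ooa, derived=["EUR"], ancestral="AFR")
    d.add_population_parameters_change(
        time=t_af, population="AFR", initial_size=n_anc, growth_rate=0
    )
    d.sort_events()
    return d
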