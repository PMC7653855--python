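"""Serial-passage (ALE) population simulator.

Models replicate batch cultures evolving under selection with periodic
dilution bottlenecks.  Genotypes are sets of tracked mutations; a genotype's
fitness is its per-doubling growth advantage, additive over its mutations:

    w(g) = 1 + sum_m s_m            (s_m = selection coefficient)

During a growth phase of ``d`` doublings the abundance of genotype ``g`` is
multiplied by ``2^(d * w(g))``; a transfer either rescales abundances
(deterministic mode) or draws genotype counts from a multinomial with the
bottleneck size as trial count (stochastic mode).  New mutant lineages do
not arise spontaneously: they are introduced by configured events at an
initial proportion ``pi`` carved out of a named background genotype.
Cross-contamination between replicates is modelled as frequency mixing,
``recipient <- (1-c) * recipient + c * donor``, applied at the first
transfer after a configured sampling point.

Abundance units are relative throughout; only frequencies are interpreted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import yaml

__all__ = [
    "Genotype",
    "Population",
    "Introduction",
    "Contamination",
    "ScenarioConfig",
    "Trajectory",
    "SimulationError",
    "ANCESTOR",
    "grow",
    "transfer",
    "introduce_mutation",
    "contaminate",
    "sample_clone",
    "run_scenario",
]

LOG2_100 = math.log2(100.0)  # doublings per 1:100 dilution


class SimulationError(RuntimeError):
    """Raised for invalid simulator state or configuration."""


class Genotype(NamedTuple):
    """A tracked genotype: its mutation set plus an optional lineage tag.

    The lineage tag distinguishes donor-derived copies of a genotype after a
    cross-contamination event from copies that arose within the recipient;
    it never affects how genotypes are matched against observations.
    """

    mutations: frozenset
    lineage: str | None = None


ANCESTOR = Genotype(frozenset())


@dataclass
class Population:
    """Per-culture genotype->abundance state."""

    culture: str
    abundances: dict
    generation: float = 0.0

    def total(self) -> float:
        return sum(self.abundances.values())

    def frequencies(self) -> dict:
        total = self.total()
        if total <= 0:
            raise SimulationError(f"culture {self.culture}: empty population")
        return {g: a / total for g, a in self.abundances.items()}

    def frequency_of_set(self, mutations: frozenset) -> float:
        """Frequency of a mutation set, summed over lineage tags."""
        total = self.total()
        return (
            sum(a for g, a in self.abundances.items() if g.mutations == mutations)
            / total
        )


@dataclass(frozen=True)
class Introduction:
    """Timed appearance of a mutant lineage at initial proportion pi."""

    mutation: str
    culture: str
    generation: float
    background: frozenset = frozenset()
    pi: float | None = None  # None -> scenario-wide default
    label: str | None = None


@dataclass(frozen=True)
class Contamination:
    """Mixing of a donor culture into a recipient after a sampling point."""

    donor: str
    recipient: str
    after: str | float  # sampling-point label (e.g. "T5") or generation
    proportion: float


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a simulated serial-passage experiment."""

    mutations: tuple = ()
    selection: dict = field(default_factory=dict)
    cultures: tuple = ("A", "B", "C")
    pi: float = 0.01
    introductions: tuple = ()
    sampling: tuple = (32.0, 62.0, 108.0, 126.0, 149.0, 177.0, 226.0)
    timepoint_labels: tuple = ("T1", "T2", "T3", "T4", "T5", "T6", "T7")
    doublings_per_transfer: float = LOG2_100
    bottleneck: float = 1e6
    contamination: tuple = ()
    lineage_fitness: dict = field(default_factory=dict)  # culture -> {mutation: delta}
    fitness_overrides: dict = field(default_factory=dict)  # frozenset -> w
    kappa: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pi < 1:
            raise SimulationError("pi must lie in (0, 1)")
        for s in self.selection.values():
            if s <= -1:
                raise SimulationError("selection coefficients must be > -1")
        if any(b <= a for a, b in zip(self.sampling, self.sampling[1:])):
            raise SimulationError("sampling generations must be strictly increasing")
        for ev in self.contamination:
            if not 0 <= ev.proportion <= 1:
                raise SimulationError("contamination proportion must be in [0, 1]")
        horizon = self.sampling[-1] if self.sampling else 0.0
        for ev in self.introductions:
            if ev.generation > horizon:
                raise SimulationError(
                    f"introduction of {ev.mutation} at generation "
                    f"{ev.generation} lies beyond the final sampling point"
                )

    # -- fitness --------------------------------------------------------

    def fitness(self, genotype: Genotype, culture: str | None = None) -> float:
        """Additive fitness, with per-genotype overrides and lineage offsets."""
        if genotype.mutations in self.fitness_overrides:
            return self.fitness_overrides[genotype.mutations]
        # iterate in sorted order: float accumulation must not depend on
        # set iteration order, or results vary with hash randomisation
        members = sorted(genotype.mutations)
        w = 1.0 + sum(self.selection.get(m, 0.0) for m in members)
        if genotype.lineage is not None and culture in self.lineage_fitness:
            offsets = self.lineage_fitness[culture]
            w += sum(offsets.get(m, 0.0) for m in members)
        return w

    def generation_of(self, timepoint: str | float) -> float:
        if isinstance(timepoint, str):
            try:
                return self.sampling[self.timepoint_labels.index(timepoint)]
            except ValueError:
                raise SimulationError(f"unknown time-point {timepoint!r}") from None
        return float(timepoint)

    def pi_of(self, event: Introduction) -> float:
        return self.pi if event.pi is None else event.pi

    # -- (de)serialisation ---------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mutations": list(self.mutations),
            "selection": dict(self.selection),
            "cultures": list(self.cultures),
            "pi": self.pi,
            "introductions": [
                {
                    "mutation": ev.mutation,
                    "culture": ev.culture,
                    "generation": ev.generation,
                    "background": sorted(ev.background),
                    **({"pi": ev.pi} if ev.pi is not None else {}),
                    **({"label": ev.label} if ev.label is not None else {}),
                }
                for ev in self.introductions
            ],
            "sampling": list(self.sampling),
            "timepoint_labels": list(self.timepoint_labels),
            "doublings_per_transfer": self.doublings_per_transfer,
            "bottleneck": self.bottleneck,
            "contamination": [
                {
                    "donor": ev.donor,
                    "recipient": ev.recipient,
                    "after": ev.after,
                    "proportion": ev.proportion,
                }
                for ev in self.contamination
            ],
            "lineage_fitness": {
                c: dict(d) for c, d in self.lineage_fitness.items()
            },
            "kappa": self.kappa,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        data = dict(data)
        intros = tuple(
            Introduction(
                mutation=ev["mutation"],
                culture=ev["culture"],
                generation=float(ev["generation"]),
                background=frozenset(ev.get("background", ())),
                pi=ev.get("pi"),
                label=ev.get("label"),
            )
            for ev in data.pop("introductions", ())
        )
        contam = tuple(
            Contamination(
                donor=ev["donor"],
                recipient=ev["recipient"],
                after=ev["after"],
                proportion=float(ev["proportion"]),
            )
            for ev in data.pop("contamination", ())
        )
        return cls(
            mutations=tuple(data.get("mutations", ())),
            selection=dict(data.get("selection", {})),
            cultures=tuple(data.get("cultures", ("A", "B", "C"))),
            pi=float(data.get("pi", 0.01)),
            introductions=intros,
            sampling=tuple(float(g) for g in data.get("sampling", ())),
            timepoint_labels=tuple(
                data.get("timepoint_labels", ("T1", "T2", "T3", "T4", "T5", "T6", "T7"))
            ),
            doublings_per_transfer=float(
                data.get("doublings_per_transfer", LOG2_100)
            ),
            bottleneck=float(data.get("bottleneck", 1e6)),
            contamination=contam,
            lineage_fitness={
                c: dict(d) for c, d in data.get("lineage_fitness", {}).items()
            },
            kappa=float(data.get("kappa", 0.0)),
            seed=int(data.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


@dataclass
class Trajectory:
    """Genotype frequency vectors per culture at each sampling generation."""

    sampling: tuple
    frequencies: dict  # culture -> {generation -> {Genotype: freq}}
    clones: dict | None = None  # culture -> {generation -> Genotype}

    def frequency(self, culture: str, generation: float, mutations: frozenset) -> float:
        vec = self.frequencies[culture][generation]
        return sum(f for g, f in vec.items() if g.mutations == mutations)

    def to_records(self) -> list[dict]:
        rows = []
        for culture, per_gen in self.frequencies.items():
            for gen, vec in per_gen.items():
                for g, f in vec.items():
                    rows.append(
                        {
                            "culture": culture,
                            "generation": gen,
                            "genotype": ";".join(sorted(g.mutations)),
                            "lineage": g.lineage or "",
                            "frequency": f,
                        }
                    )
        return rows


# -- elementary operations ----------------------------------------------


def grow(pop: Population, doublings: float, config: ScenarioConfig) -> Population:
    """Exponential growth: abundance of g scales by 2^(doublings * w(g)).

    Abundances are renormalised against the fittest genotype to keep the
    relative state in floating-point range over long horizons.
    """
    if doublings < 0:
        raise SimulationError("doublings must be >= 0")
    if doublings == 0 or not pop.abundances:
        return pop
    w = {g: config.fitness(g, pop.culture) for g in pop.abundances}
    w_max = max(w.values())
    total_before = pop.total()
    scaled = {
        g: a * math.exp2(doublings * (w[g] - w_max))
        for g, a in pop.abundances.items()
    }
    norm = total_before / sum(scaled.values())
    pop.abundances = {g: a * norm for g, a in scaled.items()}
    pop.generation += doublings
    return pop


def transfer(
    pop: Population,
    bottleneck: float,
    mode: str = "deterministic",
    rng: np.random.Generator | None = None,
) -> Population:
    """Dilution into fresh medium founding the next batch with N_b cells."""
    if bottleneck < 1:
        raise SimulationError("bottleneck size must be >= 1")
    freqs = pop.frequencies()  # raises on empty population
    if mode == "deterministic":
        pop.abundances = {g: f * bottleneck for g, f in freqs.items()}
        return pop
    if mode != "stochastic":
        raise SimulationError(f"unknown transfer mode {mode!r}")
    if rng is None:
        raise SimulationError("stochastic transfer requires an rng")
    genotypes = list(freqs)
    counts = rng.multinomial(int(bottleneck), [freqs[g] for g in genotypes])
    pop.abundances = {
        g: float(c) for g, c in zip(genotypes, counts) if c > 0
    }
    if not pop.abundances:
        raise SimulationError("population extinct at transfer")
    return pop


def introduce_mutation(
    pop: Population, event: Introduction, pi: float | None = None
) -> Population:
    """Create background+mutation at overall proportion pi.

    The background is matched by mutation set (highest-abundance copy if
    several lineage tags share the set); the new genotype inherits the
    background's lineage tag.  Total abundance is conserved.
    """
    if pi is None:
        pi = event.pi if event.pi is not None else 0.01
    total = pop.total()
    candidates = [
        (a, g) for g, a in pop.abundances.items() if g.mutations == event.background
    ]
    if not candidates:
        raise SimulationError(
            f"culture {pop.culture}: background {sorted(event.background)} absent "
            f"for introduction of {event.mutation}"
        )
    bg_ab, bg = max(candidates, key=lambda t: t[0])
    if bg_ab / total <= pi:
        raise SimulationError(
            f"culture {pop.culture}: background frequency {bg_ab / total:.3g} "
            f"<= pi={pi:.3g} for introduction of {event.mutation}"
        )
    new = Genotype(bg.mutations | {event.mutation}, bg.lineage)
    amount = pi * total
    pop.abundances[bg] = bg_ab - amount
    pop.abundances[new] = pop.abundances.get(new, 0.0) + amount
    return pop


def contaminate(
    recipient: Population,
    donor: Population,
    proportion: float,
    tag: str | None = None,
) -> Population:
    """Frequency mixing: recipient <- (1-c)*recipient + c*donor.

    Donor genotypes are optionally re-tagged with ``tag`` so that the
    donor-derived lineage remains distinguishable in the recipient.  The
    recipient's total abundance is preserved.
    """
    if not 0 <= proportion <= 1:
        raise SimulationError("contamination proportion must be in [0, 1]")
    if proportion == 0:
        return recipient
    total = recipient.total()
    donor_freqs = donor.frequencies()
    mixed: dict = {
        g: a * (1.0 - proportion) for g, a in recipient.abundances.items()
    }
    for g, f in donor_freqs.items():
        key = Genotype(g.mutations, tag) if tag is not None else g
        mixed[key] = mixed.get(key, 0.0) + proportion * f * total
    recipient.abundances = mixed
    return recipient


def sample_clone(
    pop: Population,
    kappa: float = 0.0,
    rng: np.random.Generator | None = None,
    config: ScenarioConfig | None = None,
) -> Genotype:
    """Draw one clone with probability proportional to frequency * w^kappa.

    kappa = 0 is unbiased frequency sampling; larger kappa models picking
    the largest/fastest colonies on the isolation plate.
    """
    freqs = pop.frequencies()
    genotypes = list(freqs)
    if len(genotypes) == 1:
        return genotypes[0]
    if kappa != 0.0:
        if config is None:
            raise SimulationError("biased sampling requires a ScenarioConfig")
        weights = np.array(
            [freqs[g] * config.fitness(g, pop.culture) ** kappa for g in genotypes]
        )
    else:
        weights = np.array([freqs[g] for g in genotypes])
    weights = weights / weights.sum()
    if rng is None:
        rng = np.random.default_rng()
    return genotypes[int(rng.choice(len(genotypes), p=weights))]


# -- scenario driver ----------------------------------------------------

_PRIO_SAMPLE, _PRIO_TRANSFER, _PRIO_CONTAM, _PRIO_INTRO = 0, 1, 2, 3


def _first_transfer_after(generation: float, step: float, horizon: float) -> float:
    k = math.floor(generation / step) + 1
    g = k * step
    if g > horizon:
        raise SimulationError(
            f"no transfer after generation {generation} before the horizon"
        )
    return g


def run_scenario(
    config: ScenarioConfig,
    mode: str = "deterministic",
    collect_clones: bool = False,
) -> Trajectory:
    """Run all cultures of a scenario and record sampled frequency vectors.

    Deterministic mode is seed-independent: growth is exact and transfers
    leave frequencies unchanged (they are skipped except as anchors for
    contamination timing).  Stochastic mode resamples genotype counts at
    every transfer with one named rng stream per culture, so cultures are
    independently reproducible.
    """
    if mode not in ("deterministic", "stochastic"):
        raise SimulationError(f"unknown mode {mode!r}")
    if not config.sampling:
        raise SimulationError("scenario has no sampling generations")
    horizon = config.sampling[-1]
    step = config.doublings_per_transfer

    # (generation, priority, seq, kind, payload); seq keeps event order stable
    events: list[tuple] = []
    seq = 0
    for gen in config.sampling:
        events.append((gen, _PRIO_SAMPLE, seq, "sample", None))
        seq += 1
    if mode == "stochastic":
        n_transfers = math.floor(horizon / step)
        for k in range(1, n_transfers + 1):
            events.append((k * step, _PRIO_TRANSFER, seq, "transfer", None))
            seq += 1
    for ev in config.introductions:
        events.append((ev.generation, _PRIO_INTRO, seq, "introduce", ev))
        seq += 1
    for ev in config.contamination:
        g_after = config.generation_of(ev.after)
        g_c = _first_transfer_after(g_after, step, horizon + step)
        events.append((g_c, _PRIO_CONTAM, seq, "contaminate", ev))
        seq += 1
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    pops = {
        c: Population(culture=c, abundances={ANCESTOR: 1.0}) for c in config.cultures
    }
    rngs = {
        c: np.random.default_rng([config.seed, i])
        for i, c in enumerate(config.cultures)
    }
    clone_rngs = {
        c: np.random.default_rng([config.seed, 10_000 + i])
        for i, c in enumerate(config.cultures)
    }
    stochastic = mode == "stochastic"

    freq_out: dict = {c: {} for c in config.cultures}
    clone_out: dict = {c: {} for c in config.cultures} if collect_clones else None

    now = 0.0
    for gen, prio, _, kind, payload in events:
        if gen > horizon and kind != "contaminate":
            continue
        if gen > now:
            for pop in pops.values():
                grow(pop, gen - now, config)
            now = gen
        if kind == "sample":
            for c, pop in pops.items():
                freq_out[c][gen] = pop.frequencies()
                if collect_clones:
                    clone_out[c][gen] = sample_clone(
                        pop, config.kappa, clone_rngs[c], config
                    )
        elif kind == "transfer":
            for c, pop in pops.items():
                transfer(
                    pop,
                    config.bottleneck,
                    "stochastic" if stochastic else "deterministic",
                    rngs[c] if stochastic else None,
                )
        elif kind == "introduce":
            ev: Introduction = payload
            if ev.culture not in pops:
                raise SimulationError(f"unknown culture {ev.culture!r}")
            introduce_mutation(pops[ev.culture], ev, config.pi_of(ev))
        elif kind == "contaminate":
            ev: Contamination = payload
            tag = ev.donor
            contaminate(pops[ev.recipient], pops[ev.donor], ev.proportion, tag=tag)

    return Trajectory(sampling=config.sampling, frequencies=freq_out, clones=clone_out)
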