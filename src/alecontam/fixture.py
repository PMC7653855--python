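"""Packaged study fixture: catalog, genotype matrix, observations, configs.

The package ships a reconstruction of a three-replicate, seven-time-point
isoprenol-tolerance ALE resequencing panel: a 24-mutation catalog, the
21-isolate binary genotype matrix (with per-cell stated/inferred provenance
flags), the derived one-clone-per-point observation series, and the pair of
scenario configurations used to compare a no-contamination model against a
model with 5% cross-contamination from culture B into cultures A and C
after the T5 sampling point.
"""

from __future__ import annotations

import math
from dataclasses import replace
from importlib import resources

from .catalog import GenotypeMatrix, MutationRecord, parse_mutation_table, read_genotype_matrix
from .inference import ObservationSet
from .sim import Contamination, Introduction, ScenarioConfig

__all__ = [
    "TIMEPOINT_GENERATIONS",
    "load_mutation_catalog",
    "load_genotype_matrix",
    "load_observations",
    "study_reference_config",
    "study_contamination_config",
    "reference_free_params",
    "contamination_free_params",
    "contamination_scan_builder",
    "packaged_fixture",
]

TIMEPOINT_GENERATIONS = {
    "T1": 32.0,
    "T2": 62.0,
    "T3": 108.0,
    "T4": 126.0,
    "T5": 149.0,
    "T6": 177.0,
    "T7": 226.0,
}

_DATA = resources.files("alecontam.data")


def _path(name: str):
    return resources.as_file(_DATA / name)


def load_mutation_catalog() -> list[MutationRecord]:
    with _path("mutations.tsv") as p:
        return parse_mutation_table(p)


def load_genotype_matrix() -> GenotypeMatrix:
    with _path("genotype_matrix.csv") as p, _path("genotype_provenance.csv") as q:
        return read_genotype_matrix(p, q)


def load_observations() -> ObservationSet:
    with _path("observations.csv") as p:
        return ObservationSet.read_csv(p)


def study_reference_config() -> ScenarioConfig:
    with _path("scenario_reference.yaml") as p:
        return ScenarioConfig.from_yaml(p)


def study_contamination_config() -> ScenarioConfig:
    with _path("scenario_contamination.yaml") as p:
        return ScenarioConfig.from_yaml(p)


def reference_free_params() -> list[str]:
    """Free parameters of the no-contamination fit: nine selection
    coefficients plus the scenario-wide introduction proportion (k = 10)."""
    cfg = study_reference_config()
    return [f"s:{m}" for m in cfg.mutations] + ["pi"]


def contamination_free_params() -> list[str]:
    """Free parameters of the contamination fit: the reference ten plus ten
    contamination-specific ones — the nine per-recipient donor-lineage
    fitness offsets and the shared proportion of the post-contamination
    introductions (k = 20).  The mixing proportion itself stays pinned at
    the scenario's assumed value."""
    cfg = study_contamination_config()
    extras = [
        f"delta:{culture}:{mut}"
        for culture in sorted(cfg.lineage_fitness)
        for mut in sorted(cfg.lineage_fitness[culture])
    ]
    return reference_free_params() + extras + ["pi:post"]


def contamination_scan_builder(timepoint: str, proportion: float):
    """Scenario/free-parameter factory for the contamination-timing scan.

    Contamination is applied at the first transfer after *timepoint*.  When
    the donor lineage can actually deliver the fabF+marC+yghB genotype
    before the recipients' rob_3 introductions (contamination after T4 or
    T5), the tailored contamination structure is used; for earlier or later
    contamination the recipients keep their own reference-model event
    chains and the donor only admixes.
    """
    from .sim import SimulationError, run_scenario

    step = ScenarioConfig().doublings_per_transfer
    g_after = TIMEPOINT_GENERATIONS[timepoint]
    g_c = (math.floor(g_after / step) + 1) * step
    donor_has_lineage = g_c > 108.0  # B_yghB introduction generation
    rob3_after_mixing = g_c < 155.0  # recipients' rob_3 introduction

    def with_events(base: ScenarioConfig) -> ScenarioConfig:
        contam = tuple(
            Contamination(ev.donor, ev.recipient, timepoint, proportion)
            for ev in base.contamination
        )
        return replace(base, contamination=contam)

    contam_template = study_contamination_config()
    if donor_has_lineage and rob3_after_mixing:
        candidate = with_events(contam_template)
        try:
            run_scenario(candidate, mode="deterministic")
        except SimulationError:
            candidate = None  # donor cannot deliver enough of the lineage
        if candidate is not None:
            return candidate, contamination_free_params()
    ref = study_reference_config()
    base = replace(
        ref,
        contamination=contam_template.contamination,
        lineage_fitness=contam_template.lineage_fitness,
    )
    return with_events(base), contamination_free_params()


def packaged_fixture():
    """(catalog, genotype matrix, observations, (reference, contamination))."""
    return (
        load_mutation_catalog(),
        load_genotype_matrix(),
        load_observations(),
        (study_reference_config(), study_contamination_config()),
    )
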