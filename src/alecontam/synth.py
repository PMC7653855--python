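"""Seeded generators for every input the analysis pipeline consumes.

Growth curves carry multiplicative log-normal noise on OD (flask/plate
reader error scales with the signal); dose-response rates carry additive
Gaussian noise truncated at zero (replicate SD of rate estimates).  ALE
datasets are produced by the stochastic serial-passage simulator with one
sampled clone per culture and sampling generation, mirroring how isolates
are picked in a real evolution experiment.
"""

from __future__ import annotations

import numpy as np

from .fitness import DoseResponse, GrowthCurve
from .inference import Observation, ObservationSet
from .sim import Introduction, ScenarioConfig, Trajectory, run_scenario

__all__ = [
    "gen_growth_curve",
    "gen_dose_response",
    "gen_ale_dataset",
    "recovery_scenario",
    "planted_inverted_repeat",
]


def gen_growth_curve(
    mu: float,
    od0: float = 0.2,
    times=None,
    noise_cv: float = 0.0,
    seed: int = 0,
    **meta,
) -> GrowthCurve:
    """OD(t) = od0 * exp(mu t) * exp(eta_t), eta_t ~ N(0, noise_cv^2) iid."""
    if mu < 0:
        raise ValueError("growth rate must be >= 0")
    if od0 <= 0:
        raise ValueError("initial OD must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if times is None:
        times = np.arange(0.0, 9.0)  # hourly readings over a working day
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    eta = rng.normal(0.0, noise_cv, size=times.shape) if noise_cv > 0 else 0.0
    od = od0 * np.exp(mu * times) * np.exp(eta)
    return GrowthCurve(times=times, od=od, **meta)


def gen_dose_response(
    mu0: float,
    ic50: float,
    h: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    **meta,
) -> DoseResponse:
    """Hill inhibition curve mu0 / (1 + (c/ic50)^h) plus N(0, sd) noise, >= 0."""
    if mu0 <= 0 or ic50 <= 0 or h <= 0:
        raise ValueError("mu0, ic50 and h must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    rates = mu0 / (1.0 + (conc / ic50) ** h)
    if noise_sd > 0:
        rates = rates + rng.normal(0.0, noise_sd, size=conc.shape)
    rates = np.clip(rates, 0.0, None)
    sd = np.full_like(conc, noise_sd)
    return DoseResponse(concentrations=conc, rates=rates, sd=sd, **meta)


def recovery_scenario(
    s: float = 0.15,
    pi: float = 0.01,
    bottleneck: float = 1e6,
    seed: int = 0,
) -> ScenarioConfig:
    """Three-culture single-mutation scenario for parameter-recovery studies.

    The mutant lineage is introduced at staggered generations (0, 20, 40 in
    cultures A, B, C) so that replicate trajectories differ and
    cross-contamination between them would be detectable.
    """
    return ScenarioConfig(
        mutations=("mut1",),
        selection={"mut1": s},
        cultures=("A", "B", "C"),
        pi=pi,
        introductions=tuple(
            Introduction(
                mutation="mut1",
                culture=c,
                generation=g,
                background=frozenset(),
                label=f"{c}_mut1",
            )
            for c, g in (("A", 0.0), ("B", 20.0), ("C", 40.0))
        ),
        bottleneck=bottleneck,
        seed=seed,
    )


def gen_ale_dataset(
    config: ScenarioConfig,
    n_replicate_experiments: int = 1,
    seed: int = 0,
) -> list:
    """Stochastic replicate experiments with one sampled clone per point.

    Returns a list of ``(ObservationSet, Trajectory)`` pairs; the trajectory
    is the ground truth against which recovery can be judged, and every
    observed genotype has nonzero frequency at its sampling generation by
    construction.
    """
    out = []
    labels = dict(zip(config.sampling, config.timepoint_labels))
    for i in range(n_replicate_experiments):
        cfg_i = ScenarioConfig.from_dict({**config.to_dict(), "seed": _subseed(seed, i)})
        traj = run_scenario(cfg_i, mode="stochastic", collect_clones=True)
        observations = []
        for culture in cfg_i.cultures:
            for gen in cfg_i.sampling:
                clone = traj.clones[culture][gen]
                observations.append(
                    Observation(
                        culture=culture,
                        timepoint=labels.get(gen, f"g{gen:g}"),
                        generation=gen,
                        mutations=frozenset(clone.mutations),
                    )
                )
        out.append((ObservationSet(observations), traj))
    return out


def _subseed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def planted_inverted_repeat(
    length: int = 60, k: int = 9, seed: int = 0
) -> tuple[str, int, int, str]:
    """Random background sequence with one planted motif/inverted-copy pair.

    Returns (sequence, pos1, pos2, motif).  The background is resampled
    until the planted pair is the only inverted repeat of length k, so the
    construction is usable as a known-answer test for motif finders.
    """
    from .motifs import find_inverted_repeats, reverse_complement

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    while True:
        motif = "".join(rng.choice(list(bases), size=k))
        background = list(rng.choice(list(bases), size=length))
        pos1 = int(rng.integers(0, length // 2 - k))
        pos2 = int(rng.integers(length // 2, length - k))
        background[pos1 : pos1 + k] = motif
        background[pos2 : pos2 + k] = reverse_complement(motif)
        seq = "".join(background)
        hits = find_inverted_repeats(seq, k)
        if hits == [(pos1, pos2, motif)]:
            return seq, pos1, pos2, motif
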