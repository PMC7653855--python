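"""Maximum-likelihood inference on clone-genotype observation series.

Only a single clone is sequenced per culture and time-point, so the
observation model is clone sampling: the probability of observing genotype
``o`` at a sampling generation is the modelled frequency of ``o`` at that
generation.  The total log-likelihood of an observation series under a
scenario is

    l = sum_obs ln max(f_obs, eps)

with deterministic-expectation frequencies from :func:`alecontam.sim.run_scenario`
and a small floor ``eps`` that keeps impossible observations finite.
Competing scenario structures (with and without cross-contamination) are
fitted by bounded multi-start local optimisation and compared by
likelihood-ratio test against a chi-square null with df equal to the
difference in free-parameter count.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .sim import (
    Contamination,
    Introduction,
    ScenarioConfig,
    SimulationError,
    run_scenario,
)

__all__ = [
    "Observation",
    "ObservationSet",
    "FitResult",
    "LRTResult",
    "clone_log_likelihood",
    "total_log_likelihood",
    "apply_params",
    "param_bounds",
    "fit_model",
    "chi2_upper_tail",
    "likelihood_ratio_test",
    "scan_contamination",
    "sensitivity_profile",
]

DEFAULT_EPS = 1e-6
_PENALTY = 1e6  # objective value for infeasible parameter vectors


@dataclass(frozen=True)
class Observation:
    """One sequenced clone: where, when and which mutation set."""

    culture: str
    timepoint: str
    generation: float
    mutations: frozenset


@dataclass
class ObservationSet:
    observations: list

    def __post_init__(self) -> None:
        seen = set()
        for obs in self.observations:
            key = (obs.culture, obs.timepoint)
            if key in seen:
                raise ValueError(f"duplicate observation for {key}")
            seen.add(key)

    def __iter__(self):
        return iter(self.observations)

    def __len__(self) -> int:
        return len(self.observations)

    @classmethod
    def read_csv(cls, path) -> "ObservationSet":
        """Columns: culture, timepoint, generation, genotype.

        ``genotype`` is a semicolon-joined list of mutation ids; empty
        means the ancestral (mutation-free) genotype.
        """
        out = []
        with open(path, newline="") as handle:
            for row in csv.DictReader(handle):
                genotype = row.get("genotype", "") or ""
                out.append(
                    Observation(
                        culture=row["culture"].strip(),
                        timepoint=row["timepoint"].strip(),
                        generation=float(row["generation"]),
                        mutations=frozenset(
                            m.strip() for m in genotype.split(";") if m.strip()
                        ),
                    )
                )
        return cls(out)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["culture", "timepoint", "generation", "genotype"])
            for obs in self.observations:
                gen = obs.generation
                writer.writerow(
                    [
                        obs.culture,
                        obs.timepoint,
                        int(gen) if float(gen).is_integer() else gen,
                        ";".join(sorted(obs.mutations)),
                    ]
                )


def clone_log_likelihood(freqs: dict, observed: frozenset, eps: float = DEFAULT_EPS) -> float:
    """ln of the observed genotype's frequency, floored at eps.

    ``freqs`` maps :class:`~alecontam.sim.Genotype` to frequency; lineage
    tags are ignored when matching, so donor-derived and resident copies of
    the same mutation set count together.
    """
    if not 0 < eps <= 1e-3:
        raise ValueError("eps must lie in (0, 1e-3]")
    f = sum(v for g, v in freqs.items() if g.mutations == observed)
    return math.log(max(f, eps))


def total_log_likelihood(
    config: ScenarioConfig,
    obs: ObservationSet,
    eps: float = DEFAULT_EPS,
    trajectory=None,
) -> float:
    """Sum of clone log-likelihoods over all observations.

    Observed mutation sets are projected onto the scenario's tracked
    mutations, because catalogs usually contain more (transient) mutations
    than the model follows.
    """
    if trajectory is None:
        trajectory = run_scenario(config, mode="deterministic")
    tracked = set(config.mutations)
    total = 0.0
    for ob in obs:
        per_gen = trajectory.frequencies.get(ob.culture)
        if per_gen is None or ob.generation not in per_gen:
            raise SimulationError(
                f"observation at culture {ob.culture!r}, generation "
                f"{ob.generation} does not match a sampling generation"
            )
        projected = frozenset(ob.mutations & tracked)
        total += clone_log_likelihood(per_gen[ob.generation], projected, eps)
    return total


# -- free-parameter plumbing --------------------------------------------
#
# Free parameters are addressed by name:
#   "s:<mutation>"            selection coefficient
#   "pi"                      scenario-wide introduction proportion
#   "pi:<label>"              per-event proportion (all events with label)
#   "c" / "c:<recipient>"     contamination proportion
#   "delta:<culture>:<mut>"   donor-lineage fitness offset in a recipient

_BOUNDS = {
    "s": (-0.499, 1.999),
    "pi": (1e-6, 0.5),
    "c": (1e-6, 0.5),
    "delta": (-1.0, 1.0),
}


def param_bounds(name: str) -> tuple[float, float]:
    return _BOUNDS[name.split(":", 1)[0]]


def _is_log_scale(name: str) -> bool:
    return name.split(":", 1)[0] in ("pi", "c")


def get_param(config: ScenarioConfig, name: str) -> float:
    kind, _, rest = name.partition(":")
    if kind == "s":
        return config.selection.get(rest, 0.0)
    if kind == "pi" and not rest:
        return config.pi
    if kind == "pi":
        for ev in config.introductions:
            if ev.label == rest:
                return ev.pi if ev.pi is not None else config.pi
        raise KeyError(f"no introduction labelled {rest!r}")
    if kind == "c":
        for ev in config.contamination:
            if not rest or ev.recipient == rest:
                return ev.proportion
        raise KeyError(f"no contamination event for {name!r}")
    if kind == "delta":
        culture, _, mut = rest.partition(":")
        return config.lineage_fitness.get(culture, {}).get(mut, 0.0)
    raise KeyError(f"unknown parameter {name!r}")


def apply_params(config: ScenarioConfig, params: dict) -> ScenarioConfig:
    """Return a copy of *config* with the named parameters replaced."""
    selection = None
    lineage = None
    intros = None
    contam = None
    pi = config.pi
    for name, value in params.items():
        kind, _, rest = name.partition(":")
        if kind == "s":
            if selection is None:
                selection = dict(config.selection)
            selection[rest] = float(value)
        elif kind == "pi" and not rest:
            pi = float(value)
        elif kind == "pi":
            if intros is None:
                intros = list(config.introductions)
            hit = False
            for i, ev in enumerate(intros):
                if ev.label == rest:
                    intros[i] = replace(ev, pi=float(value))
                    hit = True
            if not hit:
                raise KeyError(f"no introduction labelled {rest!r}")
        elif kind == "c":
            if contam is None:
                contam = list(config.contamination)
            hit = False
            for i, ev in enumerate(contam):
                if not rest or ev.recipient == rest:
                    contam[i] = replace(ev, proportion=float(value))
                    hit = True
            if not hit:
                raise KeyError(f"no contamination event for {name!r}")
        elif kind == "delta":
            culture, _, mut = rest.partition(":")
            if lineage is None:
                lineage = {c: dict(d) for c, d in config.lineage_fitness.items()}
            lineage.setdefault(culture, {})[mut] = float(value)
        else:
            raise KeyError(f"unknown parameter {name!r}")
    kwargs: dict = {"pi": pi}
    if selection is not None:
        kwargs["selection"] = selection
    if lineage is not None:
        kwargs["lineage_fitness"] = lineage
    if intros is not None:
        kwargs["introductions"] = tuple(intros)
    if contam is not None:
        kwargs["contamination"] = tuple(contam)
    return replace(config, **kwargs)


@dataclass
class FitResult:
    """Outcome of a (multi-start) maximum-likelihood fit."""

    loglik: float
    params: dict
    k: int
    converged: bool
    n_starts: int
    best_start: int
    template: ScenarioConfig
    free: tuple
    obs: ObservationSet = field(repr=False, default=None)
    eps: float = DEFAULT_EPS

    @property
    def config(self) -> ScenarioConfig:
        return apply_params(self.template, self.params)

    def to_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "params": dict(self.params),
            "k": self.k,
            "converged": self.converged,
            "n_starts": self.n_starts,
        }


def fit_model(
    obs: ObservationSet,
    template: ScenarioConfig,
    free: list | tuple,
    n_starts: int = 20,
    seed: int = 0,
    eps: float = DEFAULT_EPS,
    maxiter: int = 300,
) -> FitResult:
    """Maximise the clone-sampling likelihood over the named free parameters.

    Bounded local optimisation (L-BFGS-B on a log scale for proportions)
    from ``n_starts`` starting points: the template's own values first,
    then seeded random draws within bounds.  With no free parameters the
    template is simply evaluated (k = 0).
    """
    free = tuple(free)
    if not free:
        ll = total_log_likelihood(template, obs, eps)
        return FitResult(ll, {}, 0, True, 0, -1, template, free, obs, eps)

    names = free
    lo = np.empty(len(names))
    hi = np.empty(len(names))
    for i, name in enumerate(names):
        a, b = param_bounds(name)
        if _is_log_scale(name):
            a, b = math.log10(a), math.log10(b)
        lo[i], hi[i] = a, b

    def to_internal(values: dict) -> np.ndarray:
        x = np.empty(len(names))
        for i, name in enumerate(names):
            v = values[name]
            x[i] = math.log10(v) if _is_log_scale(name) else v
        return np.clip(x, lo, hi)

    def to_params(x: np.ndarray) -> dict:
        return {
            name: (10.0 ** x[i] if _is_log_scale(name) else float(x[i]))
            for i, name in enumerate(names)
        }

    def objective(x: np.ndarray) -> float:
        try:
            return -total_log_likelihood(apply_params(template, to_params(x)), obs, eps)
        except SimulationError:
            return _PENALTY

    rng = np.random.default_rng(seed)
    x_template = to_internal({n: get_param(template, n) for n in names})
    starts = [x_template]
    # half the starts perturb the template (the surface is rugged, with
    # infeasible regions where an introduction's background has died out,
    # so staying near a feasible point pays off); the rest explore globally
    n_local = (n_starts - 1) // 2
    for _ in range(n_local):
        jitter = rng.normal(0.0, 0.15, len(names)) * (hi - lo)
        starts.append(np.clip(x_template + jitter, lo, hi))
    for _ in range(n_starts - 1 - n_local):
        starts.append(lo + rng.random(len(names)) * (hi - lo))

    best = None
    best_idx = -1
    any_converged = False
    for idx, x0 in enumerate(starts):
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": maxiter},
        )
        if res.fun < _PENALTY and res.success:
            any_converged = True
        if best is None or res.fun < best.fun:
            best, best_idx = res, idx
    # simplex polish from the best point: robust near feasibility cliffs
    polish = optimize.minimize(
        objective,
        best.x,
        method="Nelder-Mead",
        bounds=list(zip(lo, hi)),
        options={"maxfev": max(400, 200 * len(names)), "xatol": 1e-6, "fatol": 1e-9},
    )
    if polish.fun < best.fun:
        best = polish
    if best.fun >= _PENALTY:
        raise SimulationError("likelihood non-finite at every start")
    return FitResult(
        loglik=-float(best.fun),
        params=to_params(best.x),
        k=len(names),
        converged=any_converged,
        n_starts=n_starts,
        best_start=best_idx,
        template=template,
        free=names,
        obs=obs,
        eps=eps,
    )


# -- likelihood-ratio testing -------------------------------------------


def chi2_upper_tail(x: float, df: int) -> float:
    """P(Chi2_df >= x), the regularised upper incomplete gamma Q(df/2, x/2)."""
    if x < 0:
        raise ValueError("x must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(special.gammaincc(df / 2.0, x / 2.0))


@dataclass(frozen=True)
class LRTResult:
    lr: float
    df: int
    p_value: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def likelihood_ratio_test(l0: float, l1: float, df: int) -> LRTResult:
    """Compare nested fitted models: LR = 2 (l1 - l0) against Chi2_df.

    ``l0`` is the maximised log-likelihood of the restricted model, ``l1``
    of the richer model; ``l1 < l0`` indicates a non-nested pair or a
    failed fit and raises.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if l1 < l0 - 1e-9:
        raise ValueError(
            f"l1={l1:.4g} < l0={l0:.4g}: models not nested or fit failed"
        )
    lr = max(2.0 * (l1 - l0), 0.0)
    return LRTResult(lr=lr, df=df, p_value=chi2_upper_tail(lr, df))


# -- contamination-scenario scan ----------------------------------------


def scan_contamination(
    obs: ObservationSet,
    template: ScenarioConfig,
    timepoints: list,
    proportions: list | None,
    free: list | tuple = (),
    reference: FitResult | None = None,
    builder=None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit one contamination scenario per (timepoint, proportion) cell.

    ``template`` must contain contamination events whose timing/proportion
    the scan overrides, or a ``builder(timepoint, proportion) -> (config,
    free_names)`` callable may be supplied for structurally tailored
    scenarios.  With ``proportions=None`` the proportion is fitted (a free
    parameter ``"c"`` is added).  Rows report the maximised log-likelihood
    and, when a no-contamination ``reference`` fit is given, the LR, df and
    chi-square p-value against it; rows are sorted by log-likelihood,
    best first.
    """
    if not timepoints:
        raise ValueError("empty timepoint grid")
    cells = [
        (tc, c)
        for tc in timepoints
        for c in (proportions if proportions else [None])
    ]
    rows = []
    for tc, c in cells:
        if builder is not None:
            config, cell_free = builder(tc, c)
            cell_free = tuple(cell_free)
        else:
            contam = tuple(
                replace(ev, after=tc, proportion=(c if c is not None else ev.proportion))
                for ev in template.contamination
            )
            if not contam:
                raise ValueError("template has no contamination events to scan")
            config = replace(template, contamination=contam)
            cell_free = tuple(free)
            if c is None and "c" not in cell_free:
                cell_free = cell_free + ("c",)
        try:
            fit = fit_model(obs, config, cell_free, **fit_kwargs)
        except SimulationError:
            rows.append(
                {
                    "timepoint": tc,
                    "proportion": c,
                    "loglik": -math.inf,
                    "k": len(cell_free),
                    "lr": math.nan,
                    "df": math.nan,
                    "p_value": math.nan,
                }
            )
            continue
        row = {
            "timepoint": tc,
            "proportion": c if c is not None else fit.params.get("c"),
            "loglik": fit.loglik,
            "k": fit.k,
            "lr": math.nan,
            "df": math.nan,
            "p_value": math.nan,
        }
        if reference is not None:
            df = fit.k - reference.k
            lr = 2.0 * (fit.loglik - reference.loglik)
            row["lr"] = lr
            row["df"] = df
            if df >= 1 and lr >= 0:
                row["p_value"] = chi2_upper_tail(lr, df)
        rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values("loglik", ascending=False, ignore_index=True)


def sensitivity_profile(fit: FitResult, param: str, grid) -> pd.DataFrame:
    """Log-likelihood profile of one fitted parameter around the MLE.

    The parameter is swept over *grid* with every other parameter held at
    its maximum-likelihood estimate; the table reports the log-likelihood
    and its drop from the fitted maximum.  Grid points outside the
    parameter's bounds are clipped with a warning.
    """
    if param not in fit.free:
        raise ValueError(f"{param!r} was not free in the fit")
    a, b = param_bounds(param)
    values = []
    for v in grid:
        if v < a or v > b:
            warnings.warn(f"grid point {v} clipped to bounds [{a}, {b}]", stacklevel=2)
            v = min(max(v, a), b)
        values.append(v)
    rows = []
    for v in values:
        params = dict(fit.params)
        params[param] = v
        try:
            ll = total_log_likelihood(
                apply_params(fit.template, params), fit.obs, fit.eps
            )
        except SimulationError:
            ll = -math.inf
        rows.append({"param": param, "value": v, "loglik": ll})
    table = pd.DataFrame(rows)
    table["delta"] = table["loglik"] - fit.loglik
    return table
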