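"""Serial-passage simulator: elementary operations and scenario driver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from alecontam.sim import (
    ANCESTOR,
    Contamination,
    Genotype,
    Introduction,
    Population,
    ScenarioConfig,
    SimulationError,
    contaminate,
    grow,
    introduce_mutation,
    run_scenario,
    sample_clone,
    transfer,
)

MUT = Genotype(frozenset({"m"}))


def two_genotype_pop(f_mut=0.5, total=1.0):
    return Population("A", {ANCESTOR: (1 - f_mut) * total, MUT: f_mut * total})


def config(s=0.1, **kw):
    return ScenarioConfig(mutations=("m",), selection={"m": s}, **kw)


# -- grow ----------------------------------------------------------------


def test_grow_zero_doublings_is_identity():
    pop = two_genotype_pop(0.3)
    before = dict(pop.abundances)
    grow(pop, 0.0, config())
    assert pop.abundances == before


def test_grow_negative_doublings_rejected():
    with pytest.raises(SimulationError):
        grow(two_genotype_pop(), -1.0, config())


def test_grow_closed_form_frequency_shift():
    """50/50 at fitness 1.0 vs 1.1: ten doublings shift the ratio by 2^1 = 2."""
    pop = two_genotype_pop(0.5)
    grow(pop, 10.0, config(s=0.1))
    freqs = pop.frequencies()
    assert freqs[MUT] == pytest.approx(2 / 3, abs=1e-12)
    assert freqs[ANCESTOR] == pytest.approx(1 / 3, abs=1e-12)


def test_grow_equal_fitness_leaves_frequencies():
    pop = two_genotype_pop(0.3)
    grow(pop, 17.5, config(s=0.0))
    assert pop.frequencies()[MUT] == pytest.approx(0.3, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.floats(0.001, 0.999),
    st.floats(0.0, 50.0),
    st.floats(-0.4, 1.5),
)
def test_grow_conserves_total_and_normalisation(f, doublings, s):
    pop = two_genotype_pop(f, total=123.0)
    grow(pop, doublings, config(s=s))
    assert pop.total() == pytest.approx(123.0, rel=1e-9)
    assert sum(pop.frequencies().values()) == pytest.approx(1.0, abs=1e-9)


def test_grow_order_preserving():
    """The fittest genotype's frequency never decreases under growth."""
    pop = two_genotype_pop(0.1)
    last = 0.1
    for _ in range(10):
        grow(pop, 3.0, config(s=0.2))
        now = pop.frequencies()[MUT]
        assert now >= last - 1e-12
        last = now


# -- transfer ------------------------------------------------------------


def test_transfer_deterministic_keeps_frequencies():
    pop = two_genotype_pop(0.37, total=5e8)
    transfer(pop, 1e6, "deterministic")
    assert pop.total() == pytest.approx(1e6)
    assert pop.frequencies()[MUT] == pytest.approx(0.37, abs=1e-12)


def test_transfer_bottleneck_of_one_fixes_one_genotype():
    rng = np.random.default_rng(0)
    pop = two_genotype_pop(0.5)
    transfer(pop, 1, "stochastic", rng)
    assert len(pop.abundances) == 1


def test_transfer_empty_population_rejected():
    with pytest.raises(SimulationError):
        transfer(Population("A", {}), 100, "deterministic")


def test_transfer_stochastic_variance_matches_binomial():
    """Post-transfer frequency variance at f=0.5, N=1000 is f(1-f)/N."""
    rng = np.random.default_rng(42)
    outcomes = []
    for _ in range(2000):
        pop = two_genotype_pop(0.5, total=1e9)
        transfer(pop, 1000, "stochastic", rng)
        outcomes.append(pop.frequencies().get(MUT, 0.0))
    var = np.var(outcomes)
    assert var == pytest.approx(0.25 / 1000, rel=0.2)


# -- introduce_mutation --------------------------------------------------


def test_introduce_on_pure_ancestor():
    pop = Population("A", {ANCESTOR: 1.0})
    ev = Introduction("m", "A", 0.0, frozenset())
    introduce_mutation(pop, ev, pi=0.01)
    freqs = pop.frequencies()
    assert freqs[MUT] == pytest.approx(0.01)
    assert freqs[ANCESTOR] == pytest.approx(0.99)


def test_introduce_conserves_total_abundance():
    pop = Population("A", {ANCESTOR: 7.5})
    introduce_mutation(pop, Introduction("m", "A", 0.0, frozenset()), pi=0.02)
    assert pop.total() == pytest.approx(7.5)


def test_two_sequential_introductions_on_same_background():
    pop = Population("A", {ANCESTOR: 1.0})
    introduce_mutation(pop, Introduction("m1", "A", 0.0, frozenset()), pi=0.01)
    introduce_mutation(pop, Introduction("m2", "A", 0.0, frozenset()), pi=0.01)
    freqs = {g.mutations: f for g, f in pop.frequencies().items()}
    assert freqs[frozenset({"m1"})] == pytest.approx(0.01)
    assert freqs[frozenset({"m2"})] == pytest.approx(0.01)
    assert freqs[frozenset()] == pytest.approx(0.98)


def test_introduce_requires_background_above_pi():
    pop = two_genotype_pop(0.995)  # ancestor at 0.5%
    with pytest.raises(SimulationError, match="<= pi"):
        introduce_mutation(pop, Introduction("x", "A", 0.0, frozenset()), pi=0.01)
    with pytest.raises(SimulationError, match="absent"):
        introduce_mutation(
            pop, Introduction("x", "A", 0.0, frozenset({"nope"})), pi=0.01
        )


# -- contaminate ---------------------------------------------------------


def test_contaminate_extremes():
    rec = Population("A", {Genotype(frozenset({"a"})): 2.0})
    donor = Population("B", {Genotype(frozenset({"b"})): 5.0})
    contaminate(rec, donor, 0.0)
    assert {g.mutations for g in rec.abundances} == {frozenset({"a"})}
    contaminate(rec, donor, 1.0)
    freqs = {g.mutations: f for g, f in rec.frequencies().items()}
    assert freqs[frozenset({"b"})] == pytest.approx(1.0)


def test_contaminate_five_percent_mixture():
    rec = Population("A", {Genotype(frozenset({"a"})): 1.0})
    donor = Population("B", {Genotype(frozenset({"b"})): 1.0})
    contaminate(rec, donor, 0.05)
    freqs = {g.mutations: f for g, f in rec.frequencies().items()}
    assert freqs[frozenset({"a"})] == pytest.approx(0.95)
    assert freqs[frozenset({"b"})] == pytest.approx(0.05)
    assert rec.total() == pytest.approx(1.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_contaminate_affine_composition(c, d):
    """Mixing c then d from the same (frozen) donor state equals mixing
    1 - (1-c)(1-d) once."""
    donor = Population("B", {Genotype(frozenset({"b"})): 3.0})
    rec1 = Population("A", {Genotype(frozenset({"a"})): 2.0})
    contaminate(rec1, donor, c)
    contaminate(rec1, donor, d)
    rec2 = Population("A", {Genotype(frozenset({"a"})): 2.0})
    contaminate(rec2, donor, 1 - (1 - c) * (1 - d))
    f1 = {g.mutations: f for g, f in rec1.frequencies().items()}
    f2 = {g.mutations: f for g, f in rec2.frequencies().items()}
    for key in set(f1) | set(f2):
        assert f1.get(key, 0.0) == pytest.approx(f2.get(key, 0.0), abs=1e-12)


# -- sample_clone --------------------------------------------------------


def test_sample_clone_single_genotype_certain():
    pop = Population("A", {MUT: 4.2})
    assert sample_clone(pop, rng=np.random.default_rng(0)) == MUT


def test_sample_clone_unbiased_law_of_large_numbers():
    rng = np.random.default_rng(7)
    pop = two_genotype_pop(0.1)
    draws = sum(sample_clone(pop, rng=rng) == MUT for _ in range(10_000))
    assert draws / 10_000 == pytest.approx(0.1, abs=0.01)


def test_sample_clone_large_kappa_prefers_fittest():
    rng = np.random.default_rng(7)
    cfg = config(s=0.3)
    pop = two_genotype_pop(0.05)  # fit mutant is rare
    draws = [sample_clone(pop, kappa=200.0, rng=rng, config=cfg) for _ in range(50)]
    assert all(g == MUT for g in draws)


# -- run_scenario --------------------------------------------------------


def test_no_mutations_stays_ancestral():
    cfg = ScenarioConfig(sampling=(10.0, 20.0, 30.0))
    traj = run_scenario(cfg)
    for culture in cfg.cultures:
        for gen in cfg.sampling:
            assert traj.frequency(culture, gen, frozenset()) == pytest.approx(1.0)


def test_two_genotype_logistic_closed_form():
    """Deterministic single-mutant frequency follows
    pi 2^(s g) / (pi 2^(s g) + 1 - pi) exactly."""
    s, pi = 0.1, 0.01
    cfg = ScenarioConfig(
        mutations=("m",),
        selection={"m": s},
        cultures=("A",),
        pi=pi,
        introductions=(Introduction("m", "A", 0.0, frozenset()),),
        sampling=(32.0, 62.0, 108.0, 126.0, 149.0, 177.0, 226.0),
    )
    traj = run_scenario(cfg)
    for g in cfg.sampling:
        expected = pi * 2 ** (s * g) / (pi * 2 ** (s * g) + 1 - pi)
        assert traj.frequency("A", g, frozenset({"m"})) == pytest.approx(
            expected, abs=1e-9
        )


def test_deterministic_mode_is_seed_independent():
    cfg = config(
        cultures=("A",),
        introductions=(Introduction("m", "A", 0.0, frozenset()),),
        sampling=(20.0, 40.0),
    )
    t1 = run_scenario(ScenarioConfig.from_dict({**cfg.to_dict(), "seed": 1}))
    t2 = run_scenario(ScenarioConfig.from_dict({**cfg.to_dict(), "seed": 99}))
    assert t1.frequencies == t2.frequencies


def test_contamination_compositional_check():
    """A deterministic run with B->A mixing after a sampling point equals the
    manual two-step computation: mix the post-T frequency vectors, then grow."""
    s = {"x": 0.1, "y": 0.25}
    cfg = ScenarioConfig(
        mutations=("x", "y"),
        selection=s,
        cultures=("A", "B"),
        pi=0.01,
        introductions=(
            Introduction("x", "A", 0.0, frozenset()),
            Introduction("y", "B", 0.0, frozenset()),
        ),
        sampling=(10.0, 30.0),
        contamination=(Contamination("B", "A", 10.0, 0.05),),
    )
    traj = run_scenario(cfg)
    step = cfg.doublings_per_transfer
    g_c = (math.floor(10.0 / step) + 1) * step

    def logistic(pi, sm, g):
        return pi * 2 ** (sm * g) / (pi * 2 ** (sm * g) + 1 - pi)

    # state at the mixing transfer
    fx = logistic(0.01, s["x"], g_c)
    fy = logistic(0.01, s["y"], g_c)
    mixed = {"x": 0.95 * fx, "y": 0.05 * fy, "": 0.95 * (1 - fx) + 0.05 * (1 - fy)}
    # grow each component to generation 30
    dt = 30.0 - g_c
    grown = {
        "x": mixed["x"] * 2 ** (dt * (1 + s["x"])),
        "y": mixed["y"] * 2 ** (dt * (1 + s["y"])),
        "": mixed[""] * 2 ** dt,
    }
    total = sum(grown.values())
    assert traj.frequency("A", 30.0, frozenset({"x"})) == pytest.approx(
        grown["x"] / total, abs=1e-9
    )
    assert traj.frequency("A", 30.0, frozenset({"y"})) == pytest.approx(
        grown["y"] / total, abs=1e-9
    )


def test_event_beyond_horizon_rejected():
    with pytest.raises(SimulationError, match="beyond"):
        ScenarioConfig(
            mutations=("m",),
            selection={"m": 0.1},
            introductions=(Introduction("m", "A", 500.0, frozenset()),),
            sampling=(32.0, 226.0),
        )


def test_frequencies_sum_to_one_at_every_sampling(reference_config):
    traj = run_scenario(reference_config)
    for culture, per_gen in traj.frequencies.items():
        for gen, vec in per_gen.items():
            assert sum(vec.values()) == pytest.approx(1.0, abs=1e-9)


def test_neutral_clones_exchangeable_across_cultures():
    """With s = 0 everywhere and no contamination, sampled clone genotypes
    are exchangeable across cultures (chi-square independence, alpha=0.01)."""
    cfg = ScenarioConfig(
        mutations=("m",),
        selection={"m": 0.0},
        pi=0.2,
        introductions=tuple(
            Introduction("m", c, 0.0, frozenset()) for c in ("A", "B", "C")
        ),
        sampling=(30.0,),
        bottleneck=500.0,
    )
    counts = {c: [0, 0] for c in cfg.cultures}
    for seed in range(400):
        traj = run_scenario(
            ScenarioConfig.from_dict({**cfg.to_dict(), "seed": seed}),
            mode="stochastic",
            collect_clones=True,
        )
        for c in cfg.cultures:
            clone = traj.clones[c][30.0]
            counts[c]["m" in clone.mutations] += 1
    table = np.array([counts[c] for c in cfg.cultures])
    _, p, _, _ = stats.chi2_contingency(table)
    assert p > 0.01
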