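import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiclone.params import SPParams
from epiclone.sp_model import (
    CloneState,
    basal_size_pmf,
    clone_size_pmf,
    extinction_probability,
    make_generator,
    mean_counts,
    sample_clone_sizes,
    simulate_clone,
    surviving_clone_size_stats,
)

from helpers import empirical_basal_pmf, total_variation


# ---------------------------------------------------------------- generator


def test_generator_rows_sum_to_zero(balanced):
    gen = make_generator(balanced, n_max=15)
    rowsum = np.abs(np.asarray(gen.Q.sum(axis=1))).max()
    assert rowsum < 1e-12


def test_generator_rates_match_event_classes(biased):
    gen = make_generator(biased, n_max=20)
    lam = biased.lam
    p_pp, p_dd, p_pd = biased.fate_probs
    # from state (2, 1): PP division, DD division, PD division, stratification
    assert gen.rate((2, 1), (3, 1)) == pytest.approx(2 * lam * p_pp)
    assert gen.rate((2, 1), (1, 3)) == pytest.approx(2 * lam * p_dd)
    assert gen.rate((2, 1), (2, 2)) == pytest.approx(2 * lam * p_pd)
    assert gen.rate((2, 1), (2, 0)) == pytest.approx(biased.gamma)


# ---------------------------------------------------------------- pmf routes


def test_master_equation_mass_conserved(balanced):
    pmf = clone_size_pmf(balanced, t=4.0, n_max=80)
    assert pmf.total_mass == pytest.approx(1.0, abs=1e-9)
    assert pmf.boundary_mass < 1e-6


def test_generating_function_matches_master_equation(biased):
    me = clone_size_pmf(biased, t=3.0, n_max=120).basal_marginal()
    gf = basal_size_pmf(biased, t=3.0)
    assert total_variation(me, gf) < 1e-7


def test_generating_function_matches_master_equation_balanced(balanced):
    me = clone_size_pmf(balanced, t=6.0, n_max=150).basal_marginal()
    gf = basal_size_pmf(balanced, t=6.0)
    assert total_variation(me, gf) < 1e-7


def test_pmf_at_time_zero_is_initial_state(balanced):
    gf = basal_size_pmf(balanced, t=0.0, init=(1, 0))
    assert gf[1] == pytest.approx(1.0)
    assert gf.sum() == pytest.approx(1.0)


def test_pmf_respects_initial_condition(balanced):
    # two progenitors + one differentiated cell: basal size 3 at t=0
    gf = basal_size_pmf(balanced, t=0.0, init=(2, 1))
    assert gf[3] == pytest.approx(1.0)
    me = clone_size_pmf(balanced, t=2.0, init=(2, 1), n_max=100).basal_marginal()
    gf_t = basal_size_pmf(balanced, t=2.0, init=(2, 1))
    assert total_variation(me, gf_t) < 1e-7


def test_truncation_warning_when_boundary_mass_large(biased):
    with pytest.warns(RuntimeWarning, match="boundary"):
        clone_size_pmf(biased, t=12.0, n_max=10)


def test_negative_time_rejected(balanced):
    with pytest.raises(ValueError):
        basal_size_pmf(balanced, t=-1.0)
    with pytest.raises(ValueError):
        clone_size_pmf(balanced, t=-1.0)


@given(
    r=st.floats(0.1, 0.45),
    delta_frac=st.floats(0.0, 0.8),
    t=st.floats(0.5, 6.0),
)
@settings(max_examples=15, deadline=None)
def test_basal_pmf_is_a_distribution(r, delta_frac, t):
    params = SPParams(r=r, delta=delta_frac * 2 * r)
    pmf = basal_size_pmf(params, t)
    assert np.all(pmf >= 0)
    assert pmf.sum() == pytest.approx(1.0, abs=1e-7)


# ---------------------------------------------------------------- moments


def test_mean_progenitor_growth_is_exponential(biased):
    # E[n_p](t) = exp(lam * delta * t) for a single founding progenitor
    for t in (1.0, 4.0, 12.0):
        expected = np.exp(biased.lam * biased.delta * t)
        assert mean_counts(biased, t)[0] == pytest.approx(expected, rel=1e-9)


def test_pmf_mean_matches_moment_system(biased):
    t = 6.0
    pmf = basal_size_pmf(biased, t)
    mean_pmf = float(np.arange(pmf.size) @ pmf)
    m = mean_counts(biased, t)
    assert mean_pmf == pytest.approx(m[0] + m[1], rel=1e-6)


def test_homeostatic_means_are_stationary_for_balanced_compartments():
    p = SPParams()  # delta = 0
    # start at compartment ratios satisfying gamma D = lam P, mu S = gamma D
    init = (1.0, p.lam / p.gamma, p.lam / p.mu)
    for t in (1.0, 10.0, 52.0):
        assert mean_counts(p, t, init=init) == pytest.approx(init, rel=1e-9)


# ---------------------------------------------------------------- extinction


def test_extinction_matches_critical_birth_death_limit():
    # as gamma -> infinity, basal extinction follows the critical
    # birth-death closed form r*lam*t / (1 + r*lam*t)
    p = SPParams(r=0.25, lam=1.2, gamma=1e4, mu=1.0)
    for t in (1.0, 4.0):
        closed = p.r * p.lam * t / (1.0 + p.r * p.lam * t)
        assert extinction_probability(p, t) == pytest.approx(closed, abs=1e-3)


def test_extinction_agrees_with_pmf_mass_at_zero(biased):
    t = 4.0
    assert extinction_probability(biased, t) == pytest.approx(
        float(basal_size_pmf(biased, t)[0]), abs=1e-7
    )


def test_extinction_zero_at_time_zero(balanced):
    assert extinction_probability(balanced, 0.0) == 0.0


# ---------------------------------------------------------------- stochastic


def test_gillespie_agrees_with_master_equation(balanced):
    sizes = sample_clone_sizes(balanced, t=3.0, n_paths=30_000, seed=11)
    emp = empirical_basal_pmf(sizes, n_max=80)
    exact = clone_size_pmf(balanced, t=3.0, n_max=120).basal_marginal()
    assert total_variation(emp, exact[:81]) < 0.02


def test_sample_determinism(biased):
    a = sample_clone_sizes(biased, t=2.0, n_paths=500, seed=42)
    b = sample_clone_sizes(biased, t=2.0, n_paths=500, seed=42)
    assert np.array_equal(a, b)
    c = sample_clone_sizes(biased, t=2.0, n_paths=500, seed=43)
    assert not np.array_equal(a, c)


def test_single_path_events_are_unit_steps(balanced):
    path = simulate_clone(balanced, t_end=5.0, seed=7)
    assert path[0] == CloneState(1, 0, 0, 0.0)
    for prev, cur in zip(path, path[1:]):
        assert cur.t > prev.t
        dp, dd, ds = cur.n_p - prev.n_p, cur.n_d - prev.n_d, cur.n_s - prev.n_s
        assert (dp, dd, ds) in {
            (1, 0, 0),   # PP
            (-1, 2, 0),  # DD
            (0, 1, 0),   # PD
            (0, -1, 1),  # stratification
            (0, 0, -1),  # shedding
        }
        assert cur.n_p >= 0 and cur.n_d >= 0 and cur.n_s >= 0


def test_every_division_adds_one_basal_cell(balanced):
    # basal size changes only via divisions (+1) and stratification (-1)
    path = simulate_clone(balanced, t_end=4.0, seed=3)
    for prev, cur in zip(path, path[1:]):
        assert abs(cur.basal - prev.basal) <= 1


# ---------------------------------------------------------------- survivors


def test_surviving_size_stats_condition_on_persistence(balanced):
    t = 6.0
    stats = surviving_clone_size_stats(balanced, t)
    pmf = basal_size_pmf(balanced, t)
    survival = 1.0 - pmf[0]
    assert stats["survival"] == pytest.approx(survival, abs=1e-9)
    # conditional mean exceeds unconditional mean for a process with extinction
    assert stats["mean"] > float(np.arange(pmf.size) @ pmf)
    assert stats["quantiles"][0.5] >= 1


def test_surviving_mean_grows_while_population_mean_is_flat(balanced):
    # the classic neutral-drift signature: E[n | survive] grows ~ linearly
    # although E[n] stays 1
    m2 = surviving_clone_size_stats(balanced, 2.0)["mean"]
    m8 = surviving_clone_size_stats(balanced, 8.0)["mean"]
    assert m8 > 2.0 * m2 * 0.8  # roughly proportional to 1 + r lam t
    assert mean_counts(balanced, 8.0)[0] == pytest.approx(1.0, rel=1e-9)
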