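import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from epiclone.competition import (
    CompetitionConfig,
    FrequencySeries,
    fixation_probability_exact,
    muller_table,
    run_competition,
    summarize_runs,
    transgenic_lineage_frequency,
)


def neutral_config(**kw):
    base = dict(n_cells=200, f0=0.05, lam=1.2, delta0=0.0, mut_rate=0.0,
                dmba_fraction=0.0, t_end=12.0)
    base.update(kw)
    return CompetitionConfig(**base)


def test_cell_counts_conserved_at_every_record_time():
    config = CompetitionConfig(n_cells=300, t_end=20.0)
    series, _ = run_competition(config, seed=1)
    assert np.all(series.counts.sum(axis=1) == config.n_cells)
    assert np.allclose(series.frequencies.sum(axis=1), 1.0)


def test_runs_are_deterministic_given_seed():
    config = CompetitionConfig(n_cells=200, t_end=10.0)
    s1, r1 = run_competition(config, seed=9)
    s2, r2 = run_competition(config, seed=9)
    assert np.array_equal(s1.counts, s2.counts)
    pd.testing.assert_frame_equal(r1, r2)


def test_neutral_transgenic_frequency_is_a_martingale():
    config = neutral_config()
    finals = []
    for seed in range(200):
        series, registry = run_competition(config, seed=seed)
        finals.append(transgenic_lineage_frequency(series, registry)[-1])
    finals = np.asarray(finals)
    se = finals.std(ddof=1) / np.sqrt(len(finals))
    assert abs(finals.mean() - config.f0) < 3.0 * se + 1e-12


def test_positive_fate_bias_tracks_replicator_ode():
    config = neutral_config(delta0=0.3, n_cells=400, f0=0.1, t_end=8.0)
    freqs = []
    for seed in range(150):
        series, registry = run_competition(config, seed=seed)
        freqs.append(transgenic_lineage_frequency(series, registry))
    mean_freq = np.mean(freqs, axis=0)

    # exact mean-field of the implemented Moran update (divider chosen
    # proportional to count * (1 + delta), uniform removal):
    #   df/dt = lam * delta0 * f (1 - f) / (1 + delta0 * f),
    # which reduces to the replicator equation df/dt = lam delta0 f(1-f)
    # in the weak-selection limit delta0 -> 0
    def rhs(_, f):
        d = config.delta0
        return config.lam * d * f * (1.0 - f) / (1.0 + d * f)

    series, _ = run_competition(config, seed=0)
    sol = solve_ivp(rhs, (0, config.t_end), [config.f0], t_eval=series.t,
                    rtol=1e-9)
    se = np.std(freqs, axis=0, ddof=1) / np.sqrt(len(freqs))
    # within Monte-Carlo error plus a weak-selection discretisation margin
    assert np.all(np.abs(mean_freq - sol.y[0]) < 4.0 * se + 0.02)


def test_fixation_probability_matches_exact_chain():
    n, delta, k0 = 12, 0.5, 1
    config = neutral_config(n_cells=n, f0=k0 / n, delta0=delta, t_end=400.0)
    fixed = 0
    n_runs = 3000
    for seed in range(n_runs):
        series, registry = run_competition(config, seed=seed)
        f_end = transgenic_lineage_frequency(series, registry)[-1]
        assert f_end in (0.0, 1.0), "run did not absorb; lengthen t_end"
        fixed += f_end == 1.0
    p_exact = fixation_probability_exact(n, delta, k0)
    se = np.sqrt(p_exact * (1 - p_exact) / n_runs)
    assert abs(fixed / n_runs - p_exact) < 3.5 * se


def test_fixation_exact_neutral_is_initial_frequency():
    for n, k0 in ((10, 1), (20, 7)):
        assert fixation_probability_exact(n, 0.0, k0) == pytest.approx(k0 / n)


def test_registry_is_a_forest_rooted_at_founders():
    config = CompetitionConfig(n_cells=500, t_end=26.0)
    _, registry = run_competition(config, seed=3)
    roots = registry.loc[registry["parent_id"] < 0, "clone_id"]
    assert set(roots) == {0, 1}  # wild type and transgenic
    known = set(registry["clone_id"])
    children = registry[registry["parent_id"] >= 0]
    assert children["parent_id"].isin(known).all()
    assert (children["parent_id"] < children["clone_id"]).all()  # birth order


def test_transgenic_lineage_includes_descendants():
    config = CompetitionConfig(n_cells=500, mut_rate=0.05, t_end=26.0)
    series, registry = run_competition(config, seed=4)
    trans = registry[registry["is_transgenic_lineage"]]
    # descendants of transgenic clones are transgenic
    by_id = registry.set_index("clone_id")["is_transgenic_lineage"]
    for _, row in registry[registry["parent_id"] >= 1].iterrows():
        if by_id.loc[row["parent_id"]]:
            assert row["is_transgenic_lineage"]
    assert len(trans) >= 1


def test_fitness_clipping_is_logged():
    config = CompetitionConfig(
        n_cells=200, mut_rate=0.2, dfe_p_neutral=0.0, dfe_p_deleterious=1.0,
        dfe_s_mean=3.0, t_end=10.0,
    )
    _, registry = run_competition(config, seed=5)
    assert registry.attrs["n_fitness_clipped"] > 0
    assert (registry["delta"] >= -1.0).all()


def test_muller_table_round_trips_to_frequencies():
    config = CompetitionConfig(n_cells=300, t_end=15.0)
    series, registry = run_competition(config, seed=6)
    table = muller_table(series, registry)
    wide = table.pivot(index="time_weeks", columns="clone_id",
                       values="frequency").sort_index().sort_index(axis=1)
    assert np.allclose(wide.to_numpy(), series.frequencies)
    assert np.allclose(wide.sum(axis=1), 1.0)


def test_summarize_runs_flags_rise_and_fall():
    t = np.arange(5.0)
    up_down = FrequencySeries(
        t=t, counts=np.array([[99, 1], [90, 10], [60, 40], [90, 10], [99, 1]]),
        n_cells=100,
    )
    flat = FrequencySeries(
        t=t, counts=np.tile([99, 1], (5, 1)), n_cells=100
    )
    registry = pd.DataFrame(
        {"clone_id": [0, 1], "parent_id": [-1, -1], "delta": [0.0, 0.2],
         "is_transgenic_lineage": [False, True], "birth_time": [0.0, 0.0]}
    )
    summary = summarize_runs([(up_down, registry), (flat, registry)], f0=0.01)
    assert summary["rose_then_fell"].tolist() == [True, False]
    assert summary.loc[0, "peak_frequency"] == pytest.approx(0.4)
    assert summary.loc[0, "peak_time"] == 2.0


def test_summarize_requires_at_least_one_run():
    with pytest.raises(ValueError):
        summarize_runs([])


def test_mismatched_registry_rejected():
    config = neutral_config()
    series, registry = run_competition(config, seed=7)
    with pytest.raises(ValueError):
        transgenic_lineage_frequency(series, registry.iloc[:-1])


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        CompetitionConfig(f0=1.5)
    with pytest.raises(ValueError):
        CompetitionConfig(n_cells=0)
    with pytest.raises(ValueError):
        CompetitionConfig(dfe_p_neutral=0.8, dfe_p_deleterious=0.3)
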