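import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from epiclone.synthetic import StudyDesign, gen_variant_table
from epiclone.variants import (
    FilterConfig,
    bh_filter,
    bh_qvalues,
    drop_paired_shared,
    mutation_burden,
    mutation_spectrum,
    run_filter_pipeline,
    strand_filter,
)

KEY = ["chrom", "pos", "ref", "alt", "biopsy_id"]


def variant_row(chrom="chr1", pos=100, ref="C", alt="T", biopsy="b1",
                mouse="m1", exposure="irradiated", p=1e-6, fwd=5, rev=5):
    return {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "biopsy_id": biopsy, "mouse_id": mouse, "exposure": exposure,
        "p_value": p, "fwd_reads": fwd, "rev_reads": rev,
    }


# ---------------------------------------------------------------- BH


def test_bh_matches_statsmodels_on_random_p_sets():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(1, 400))
        p = np.clip(rng.uniform(size=n) ** rng.uniform(0.5, 3.0), 1e-300, 1.0)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.abs(bh_qvalues(p) - expected).max() < 1e-12


def test_bh_hand_computed_example():
    # p = (0.01, 0.02, 0.03, 0.5): q = (0.04, 0.04, 0.04, 0.5)
    q = bh_qvalues(np.array([0.01, 0.02, 0.03, 0.5]))
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])


def test_bh_single_p_value_unchanged():
    assert bh_qvalues(np.array([0.37]))[0] == pytest.approx(0.37)


def test_bh_rejects_invalid_p_values():
    with pytest.raises(ValueError):
        bh_qvalues(np.array([0.5, 1.5]))
    with pytest.raises(ValueError):
        bh_qvalues(np.array([np.nan]))
    with pytest.raises(ValueError):
        bh_qvalues(np.array([0.0]))  # p-values live in (0, 1]


@given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60))
@settings(max_examples=50, deadline=None)
def test_bh_qvalues_are_monotone_in_p(ps):
    p = np.asarray(ps)
    q = bh_qvalues(p)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-15)
    assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)


def test_bh_families_are_independent_per_mouse():
    # the same p-value survives in a small family but not in a large one
    rows = [variant_row(pos=1, mouse="small", biopsy="s1", p=0.02)]
    rows += [
        variant_row(pos=10 + i, mouse="big", biopsy="b1",
                    p=0.02 if i == 0 else 0.9)
        for i in range(20)
    ]
    out = bh_filter(pd.DataFrame(rows), FilterConfig(q_max=0.1))
    assert set(out["mouse_id"]) == {"small"}


# ---------------------------------------------------------------- stages


def test_shared_variant_removed_from_both_biopsies():
    rows = [
        variant_row(pos=1, biopsy="b_uv", exposure="irradiated"),
        variant_row(pos=1, biopsy="b_ctl", exposure="unexposed"),
        variant_row(pos=2, biopsy="b_uv", exposure="irradiated"),
    ]
    out = drop_paired_shared(pd.DataFrame(rows))
    assert out["pos"].tolist() == [2]


def test_same_site_in_two_mice_is_not_shared():
    rows = [
        variant_row(pos=1, mouse="m1", biopsy="a", exposure="irradiated"),
        variant_row(pos=1, mouse="m2", biopsy="b", exposure="unexposed"),
    ]
    out = drop_paired_shared(pd.DataFrame(rows))
    assert len(out) == 2


def test_same_exposure_recurrence_is_kept():
    # two irradiated biopsies of one mouse sharing a site do not span arms
    rows = [
        variant_row(pos=1, biopsy="uv1", exposure="irradiated"),
        variant_row(pos=1, biopsy="uv2", exposure="irradiated"),
    ]
    assert len(drop_paired_shared(pd.DataFrame(rows))) == 2


def test_missing_exposure_label_rejected():
    rows = [variant_row(exposure="")]
    with pytest.raises(ValueError, match="exposure"):
        drop_paired_shared(pd.DataFrame(rows))


def test_strand_filter_requires_both_strands():
    rows = [
        variant_row(pos=1, fwd=3, rev=0),
        variant_row(pos=2, fwd=0, rev=3),
        variant_row(pos=3, fwd=1, rev=1),
    ]
    out = strand_filter(pd.DataFrame(rows))
    assert out["pos"].tolist() == [3]


def test_pipeline_hand_enumerated_fixture():
    rows = [
        variant_row(pos=1, p=1e-8),                      # survives everything
        variant_row(pos=2, p=0.9),                       # fails BH
        variant_row(pos=3, p=1e-8, fwd=4, rev=0),        # fails strand
        variant_row(pos=4, p=1e-8, biopsy="uv"),         # shared below
        variant_row(pos=4, p=1e-8, biopsy="ctl", exposure="unexposed"),
    ]
    survivors, attrition = run_filter_pipeline(pd.DataFrame(rows))
    assert survivors["pos"].tolist() == [1]
    assert attrition["n_in"].tolist() == [5, 3, 2]
    assert attrition["n_out"].tolist() == [3, 2, 1]


def test_pipeline_stages_are_idempotent():
    records, _ = gen_variant_table(StudyDesign(), seed=3)
    records = records.drop(columns=["planted_as"])
    survivors, _ = run_filter_pipeline(records)
    again = drop_paired_shared(survivors)
    assert len(again) == len(survivors)
    again = strand_filter(survivors)
    assert len(again) == len(survivors)
    twice, _ = run_filter_pipeline(survivors.drop(columns=["q_value"]))
    assert len(twice) == len(survivors)


def test_pipeline_recovers_planted_truth():
    records, truth = gen_variant_table(StudyDesign(), seed=4)
    survivors, _ = run_filter_pipeline(records.drop(columns=["planted_as"]))
    got = set(map(tuple, survivors[KEY].itertuples(index=False)))
    want = set(map(tuple, truth[KEY].itertuples(index=False)))
    assert got == want


# ---------------------------------------------------------------- summaries


def test_burden_per_area_uses_biopsy_area():
    rows = [variant_row(pos=i) for i in range(32)]
    burden = mutation_burden(pd.DataFrame(rows), FilterConfig(biopsy_area_mm2=16))
    assert burden.loc[0, "n_mutations"] == 32
    assert burden.loc[0, "burden_per_mm2"] == pytest.approx(2.0)


def test_spectrum_collapses_to_pyrimidine_strand():
    # G>A is the purine-strand report of C>T; A>C of T>G
    rows = [
        variant_row(pos=1, ref="C", alt="T"),
        variant_row(pos=2, ref="G", alt="A"),
        variant_row(pos=3, ref="A", alt="C"),
        variant_row(pos=4, ref="ACG", alt="A"),  # indel: excluded from SNVs
    ]
    spec = mutation_spectrum(pd.DataFrame(rows))
    assert spec["C>T"] == pytest.approx(2.0 / 3.0)
    assert spec["T>G"] == pytest.approx(1.0 / 3.0)
    assert spec["ct_fraction"] == pytest.approx(2.0 / 3.0)
    assert spec["n_snv"] == 3 and spec["non_snv"] == 1


def test_spectrum_of_empty_set_is_flagged_not_zero():
    with pytest.raises(ValueError, match="empty"):
        mutation_spectrum(pd.DataFrame(columns=["ref", "alt"]))


def test_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(q_max=0.0)
    with pytest.raises(ValueError):
        FilterConfig(min_forward=-1)
    with pytest.raises(ValueError):
        FilterConfig(group_by="animal")
    with pytest.raises(ValueError):
        FilterConfig(biopsy_area_mm2=0.0)


def test_missing_columns_reported_by_name():
    with pytest.raises(ValueError, match="p_value"):
        bh_filter(pd.DataFrame({"mouse_id": ["m1"]}))
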