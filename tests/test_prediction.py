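"""Tests of Step 3 testing: stratified Z-scoring, panels, longitudinal
composites, ROC state prediction and Cox trait prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from memtrack import prediction
from memtrack.prediction import (
    Marker,
    longitudinal_measure,
    panel_score,
    predict_state,
    predict_trait,
    zscore_by_stratum,
    zscore_matrix_by_stratum,
)

from conftest import make_visits


def meta_single_stratum(n, retention=None):
    rows = []
    for i in range(n):
        rows.append({"visit_id": f"v{i}", "subject_id": f"s{i}", "gender": "M",
                     "diagnosis": "BP", "day": 0,
                     "retention": 50.0 if retention is None else retention[i],
                     "neuropsych_event": False, "event_day": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# z-scoring

def test_zscore_hand_example():
    meta = meta_single_stratum(3)
    z = zscore_by_stratum(pd.Series([1.0, 2.0, 3.0], index=["v0", "v1", "v2"]), meta)
    np.testing.assert_allclose(z.to_numpy(), [-1.2247448, 0.0, 1.2247448], atol=1e-6)


def test_zscore_constant_stratum_is_zero():
    meta = meta_single_stratum(3)
    z = zscore_by_stratum(pd.Series([5.0, 5.0, 5.0], index=["v0", "v1", "v2"]), meta)
    assert (z == 0).all()


def test_zscore_singleton_stratum_is_zero():
    meta = meta_single_stratum(1)
    z = zscore_by_stratum(pd.Series([7.0], index=["v0"]), meta)
    assert (z == 0).all()


def test_zscore_strata_independent():
    meta = meta_single_stratum(6)
    meta.loc[3:, "gender"] = "F"
    vals = pd.Series([1.0, 2.0, 3.0, 10.0, 20.0, 60.0], index=meta.visit_id)
    z = zscore_by_stratum(vals, meta)
    assert z.iloc[:3].mean() == pytest.approx(0, abs=1e-12)
    assert z.iloc[3:].mean() == pytest.approx(0, abs=1e-12)
    assert z.iloc[:3].std(ddof=0) == pytest.approx(1)
    assert z.iloc[3:].std(ddof=0) == pytest.approx(1)


def test_zscore_matrix_matches_series(small_study):
    expr, visits = small_study.expression, small_study.visits
    zm = zscore_matrix_by_stratum(expr, visits)
    for pid in expr.index[:5]:
        zs = zscore_by_stratum(expr.loc[pid], visits)
        np.testing.assert_allclose(zm.loc[pid].to_numpy(), zs.to_numpy(), atol=1e-10)


# ---------------------------------------------------------------------------
# panels

def test_panel_score_signed_sum():
    z = pd.DataFrame({"v0": [1.0, 0.4]}, index=["A", "B"])
    s = panel_score(z, [("A", "increased_risk"), ("B", "decreased_risk")])
    assert s["v0"] == pytest.approx(0.6)


def test_panel_score_zero_for_zero_z():
    z = pd.DataFrame(np.zeros((3, 4)), index=list("ABC"), columns=list("wxyz"))
    s = panel_score(z, [(m, "increased_risk") for m in "ABC"])
    assert (s == 0).all()


def test_panel_direction_antisymmetry():
    rng = np.random.default_rng(0)
    z = pd.DataFrame(rng.normal(size=(3, 5)), index=list("ABC"),
                     columns=[f"v{i}" for i in range(5)])
    members = [("A", "increased_risk"), ("B", "decreased_risk"), ("C", "increased_risk")]
    flipped = [(m, "decreased_risk" if d == "increased_risk" else "increased_risk")
               for m, d in members]
    pd.testing.assert_series_equal(panel_score(z, members), -panel_score(z, flipped))


def test_panel_missing_member_and_duplicates_rejected():
    z = pd.DataFrame({"v0": [1.0]}, index=["A"])
    with pytest.raises(KeyError, match="NOPE"):
        panel_score(z, [("NOPE", "increased_risk")])
    with pytest.raises(ValueError, match="duplicate"):
        panel_score(z, [("A", "increased_risk"), ("A", "decreased_risk")])


def test_panel_invariant_to_affine_rescaling(small_study):
    """Affine rescaling of a raw marker is absorbed by stratum Z-scoring."""
    expr, visits = small_study.expression, small_study.visits
    members = [(expr.index[0], "increased_risk"), (expr.index[1], "decreased_risk")]
    z1 = zscore_matrix_by_stratum(expr, visits)
    scaled = expr.copy()
    scaled.iloc[0] = 3.5 * scaled.iloc[0] + 11.0
    z2 = zscore_matrix_by_stratum(scaled, visits)
    pd.testing.assert_series_equal(panel_score(z1, members), panel_score(z2, members))


# ---------------------------------------------------------------------------
# longitudinal composite

def test_slope_formula():
    visits = make_visits({"a": [50, 80]})
    levels = pd.Series([8.0, 8.0], index=visits.visit_id)
    # two visits, one stratum -> composite z-scores are all 0, so check the
    # raw slope through a two-subject cohort with distinct slopes instead
    visits2 = make_visits({"a": [50, 80], "b": [50, 80]})
    levels2 = pd.Series([8.0, 8.0, 8.0, 16.0], index=visits2.visit_id)
    comp = longitudinal_measure(levels2, visits2, "increased_risk")
    # subject a slope (8/8)/100 = 0.01; subject b slope (16/8)/100 = 0.02
    # all four measures z-score to [-1, +1] within the stratum
    assert comp.loc[visits2.visit_id.iloc[1]] == pytest.approx(-4.0)
    assert comp.loc[visits2.visit_id.iloc[3]] == pytest.approx(4.0)


def test_running_extrema_by_direction():
    """Levels [7, 9, 8]: running max series [9, 9] for increased markers,
    running min series [7, 7] for decreased ones."""
    visits = make_visits({"a": [50, 80, 40]})
    levels = pd.Series([7.0, 9.0, 8.0], index=visits.visit_id)
    for direction, expected in (("increased_risk", [9.0, 9.0]),
                                ("decreased_risk", [7.0, 7.0])):
        comp = longitudinal_measure(levels, visits, direction, return_components=True)
        assert list(comp["run_ext"]) == expected
        assert list(comp["level"]) == [9.0, 8.0]
        assert comp["slope"].iloc[0] == pytest.approx((9 / 7) / 100)
        assert comp["run_max_slope"].iloc[1] == pytest.approx(max((9 / 7) / 100, (8 / 9) / 100))


def test_single_visit_subjects_excluded():
    visits = make_visits({"a": [50], "b": [50, 80]})
    levels = pd.Series([8.0, 7.0, 9.0], index=visits.visit_id)
    comp = longitudinal_measure(levels, visits, "increased_risk")
    assert visits.visit_id.iloc[0] not in comp.index
    # only second-and-later visits of multi-visit subjects appear
    assert set(comp.index) == {visits.visit_id.iloc[2]}


def test_identical_trajectories_give_constant_composite():
    """When every included visit carries identical level/slope values, all
    four stratum Z-scores are zero and the composite is constant."""
    visits = make_visits({"a": [50, 80], "b": [50, 80], "c": [50, 80]})
    levels = pd.Series(np.tile([7.0, 8.0], 3), index=visits.visit_id)
    comp = longitudinal_measure(levels, visits, "increased_risk")
    assert len(comp) == 3
    assert (comp.abs() < 1e-12).all()


def test_zero_previous_level_excluded():
    visits = make_visits({"a": [50, 80, 60], "b": [50, 70, 60]})
    levels = pd.Series([0.0, 8.0, 7.0, 5.0, 6.0, 7.0], index=visits.visit_id)
    comp = longitudinal_measure(levels, visits, "increased_risk")
    assert visits.visit_id.iloc[1] not in comp.index  # slope undefined
    assert visits.visit_id.iloc[2] in comp.index


def test_nonincreasing_days_rejected():
    visits = make_visits({"a": [50, 80]})
    visits.loc[1, "day"] = 0
    levels = pd.Series([8.0, 9.0], index=visits.visit_id)
    with pytest.raises(ValueError, match="strictly increasing"):
        longitudinal_measure(levels, visits, "increased_risk")


# ---------------------------------------------------------------------------
# state prediction

def brute_force_auc(cases, controls):
    wins = sum(1.0 if c > k else 0.5 if c == k else 0.0
               for c, k in itertools.product(cases, controls))
    return wins / (len(cases) * len(controls))


def test_auc_perfect_separation():
    meta = meta_single_stratum(4, retention=[30, 30, 80, 80])
    m = pd.Series([0.9, 0.8, 0.3, 0.2], index=meta.visit_id)
    res = predict_state(m, meta, grouping="ALL")
    assert res.auc.iloc[0] == 1.0
    assert res.n_low.iloc[0] == 2 and res.n_total.iloc[0] == 4


def test_auc_matches_brute_force_pair_count():
    meta = meta_single_stratum(4, retention=[30, 30, 80, 80])
    m = pd.Series([0.9, 0.3, 0.8, 0.2], index=meta.visit_id)  # one swapped pair
    res = predict_state(m, meta, grouping="ALL")
    assert res.auc.iloc[0] == pytest.approx(0.75)
    assert res.auc.iloc[0] == pytest.approx(brute_force_auc([0.9, 0.3], [0.8, 0.2]))


def test_auc_brute_force_random(small_study):
    rng = np.random.default_rng(5)
    n = 60
    meta = meta_single_stratum(n, retention=rng.uniform(20, 90, n))
    m = pd.Series(rng.normal(size=n), index=meta.visit_id).round(1)  # force ties
    res = predict_state(m, meta, grouping="ALL")
    low = meta.set_index("visit_id").retention <= 40
    assert res.auc.iloc[0] == pytest.approx(
        brute_force_auc(m[low].tolist(), m[~low].tolist())
    )


def test_auc_direction_antisymmetry():
    rng = np.random.default_rng(6)
    meta = meta_single_stratum(50, retention=rng.uniform(20, 90, 50))
    m = pd.Series(rng.normal(size=50), index=meta.visit_id)
    a1 = predict_state(m, meta, "increased_risk", grouping="ALL").auc.iloc[0]
    a2 = predict_state(m, meta, "decreased_risk", grouping="ALL").auc.iloc[0]
    assert a1 + a2 == pytest.approx(1.0)


def test_permutation_null_auc_centered():
    rng = np.random.default_rng(7)
    aucs, ps = [], []
    meta = meta_single_stratum(200, retention=rng.uniform(20, 90, 200))
    for _ in range(200):
        m = pd.Series(rng.normal(size=200), index=meta.visit_id)
        res = predict_state(m, meta, grouping="ALL")
        aucs.append(res.auc.iloc[0])
        ps.append(res.p_value.iloc[0])
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)
    # one-sided p uniform under the null
    assert np.mean(np.array(ps) < 0.25) == pytest.approx(0.25, abs=0.08)


def test_one_class_group_untestable():
    meta = meta_single_stratum(4, retention=[80, 80, 80, 80])
    m = pd.Series([1.0, 2.0, 3.0, 4.0], index=meta.visit_id)
    res = predict_state(m, meta, grouping="ALL")
    assert not res.testable.iloc[0]
    assert np.isnan(res.auc.iloc[0])


def test_groupings_cover_strata(small_study):
    expr, visits = small_study.expression, small_study.visits
    z = zscore_by_stratum(expr.iloc[0], visits)
    for grouping, key in (("gender", "gender"), ("gender_dx", None)):
        res = predict_state(z, visits, grouping=grouping)
        assert res.group_type.eq(grouping).all()
        assert res.n_total.sum() == len(visits)


# ---------------------------------------------------------------------------
# trait prediction

def _trait_meta(scores, events, days):
    meta = meta_single_stratum(len(scores))
    meta["neuropsych_event"] = events
    meta["event_day"] = days
    return meta


def test_cox_sign_check():
    """Higher scores having earlier events must give HR > 1 (two-sample
    closed form: the partial likelihood is maximized at +inf, the fit is
    penalized but the sign must be positive)."""
    rng = np.random.default_rng(8)
    n = 40
    score = rng.normal(size=n)
    days = np.where(score > 0, rng.uniform(100, 500, n), rng.uniform(2000, 4000, n))
    meta = _trait_meta(score, [True] * n, days)
    m = pd.Series(score, index=meta.visit_id)
    res = predict_trait(m, meta, grouping="ALL")
    assert res.hazard_ratio.iloc[0] > 1
    assert res.p_value.iloc[0] < 0.05


def test_cox_zero_events_untestable():
    meta = _trait_meta([1.0, -1.0, 0.5], [False] * 3, [1000.0] * 3)
    m = pd.Series([1.0, -1.0, 0.5], index=meta.visit_id)
    res = predict_trait(m, meta, grouping="ALL")
    assert not res.testable.iloc[0]


def test_cox_null_recovery_centered_at_one():
    rng = np.random.default_rng(9)
    hrs = []
    for _ in range(30):
        n = 100
        score = rng.normal(size=n)
        days = rng.exponential(2000, n)
        events = days < 4000
        meta = _trait_meta(score, events, np.minimum(days, 4000))
        m = pd.Series(score, index=meta.visit_id)
        res = predict_trait(m, meta, grouping="ALL")
        hrs.append(np.log(res.hazard_ratio.iloc[0]))
    assert np.mean(hrs) == pytest.approx(0.0, abs=2.5 * np.std(hrs) / np.sqrt(len(hrs)) + 0.02)


def test_trait_direction_orientation():
    rng = np.random.default_rng(10)
    n = 60
    score = rng.normal(size=n)
    days = np.exp(-0.8 * score) * rng.exponential(1500, n)
    events = days < 4000
    meta = _trait_meta(score, events, np.minimum(days, 4000))
    m = pd.Series(score, index=meta.visit_id)
    hr_inc = predict_trait(m, meta, "increased_risk", "ALL").hazard_ratio.iloc[0]
    hr_dec = predict_trait(m, meta, "decreased_risk", "ALL").hazard_ratio.iloc[0]
    assert hr_inc > 1
    assert hr_dec == pytest.approx(1 / hr_inc, rel=1e-6)


# ---------------------------------------------------------------------------
# end-to-end marker testing

def test_test_marker_planted_panel(small_study):
    from memtrack.cohort import panel_truth_to_definition

    members = panel_truth_to_definition(small_study.truth)
    marker = Marker("PANEL", tuple(members))
    state, trait = prediction.test_marker(small_study.expression, small_study.visits, marker)
    all_c = state[(state.group_type == "ALL") & (state["mode"] == "C")]
    assert all_c.auc.iloc[0] > 0.75
    all_t = trait[(trait.group_type == "ALL") & (trait["mode"] == "C")]
    assert all_t.hazard_ratio.iloc[0] > 1
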