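"""Statistical layer: oracle equivalences (AUC vs pair counting, logistic
OR vs cross-product ratio), tertile contracts, group-comparison behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bifmorph import (
    InsufficientDataError,
    compare_groups,
    multivariate_logistic,
    roc_analysis,
    tertile_split,
    univariate_logistic,
)


def _frame(x, y, name="x"):
    return pd.DataFrame({name: x, "aneurysm": y})


def auc_pair_counting(cases, controls):
    """Exhaustive Mann-Whitney pair counting: win 1, tie 0.5."""
    wins = sum(1.0 if c > k else 0.5 if c == k else 0.0
               for c in cases for k in controls)
    return wins / (len(cases) * len(controls))


# ---------------------------------------------------------------------------
# tertiles
# ---------------------------------------------------------------------------

def test_tertile_split_one_to_nine():
    spec, assign = tertile_split(list(range(1, 10)))
    assert spec.lower_boundary == pytest.approx(11.0 / 3.0, abs=5e-3)
    assert spec.upper_boundary == pytest.approx(19.0 / 3.0, abs=5e-3)
    assert list(assign) == [1, 1, 1, 2, 2, 2, 3, 3, 3]


def test_tertile_boundary_tie_goes_low():
    # for 1..10 the interpolated boundaries fall exactly on the data values
    # 4 and 7, which must then belong to the 1st and 2nd tertile
    spec, assign = tertile_split([float(v) for v in range(1, 11)])
    assert spec.lower_boundary == pytest.approx(4.0, abs=1e-9)
    assert spec.upper_boundary == pytest.approx(7.0, abs=1e-9)
    assert list(assign) == [1, 1, 1, 1, 2, 2, 2, 3, 3, 3]


def test_tertile_split_degenerate_inputs():
    with pytest.raises(InsufficientDataError):
        tertile_split([5.0, 5.0, 5.0, 5.0])
    with pytest.raises(InsufficientDataError):
        tertile_split([1.0, 2.0])


@given(st.lists(st.floats(-1e4, 1e4), min_size=6, max_size=60, unique=True))
def test_tertile_counts_balanced_for_distinct_values(values):
    spec, assign = tertile_split(values)
    assert spec.lower_boundary < spec.upper_boundary
    counts = [int(np.sum(assign == t)) for t in (1, 2, 3)]
    assert sum(counts) == len(values)
    assert max(counts) - min(counts) <= 1


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

def test_auc_small_example_with_tie():
    x = [2.0, 3.0, 4.0, 1.0, 2.0]
    y = [1, 1, 1, 0, 0]
    res = roc_analysis(_frame(x, y), "x")
    assert res.auc == pytest.approx(5.5 / 6.0, abs=1e-12)


def test_perfectly_separated_predictor():
    x = [10.0, 11.0, 12.0, 1.0, 2.0, 3.0]
    y = [1, 1, 1, 0, 0, 0]
    res = roc_analysis(_frame(x, y), "x")
    assert res.auc == 1.0
    assert res.youden_j == pytest.approx(1.0)
    assert 3.0 < res.cutoff < 10.0


def test_youden_tie_breaks_to_lowest_cutoff():
    # J = 1 at every midpoint between 2 and 10
    x = [10.0, 12.0, 1.0, 2.0]
    y = [1, 1, 0, 0]
    res = roc_analysis(_frame(x, y), "x")
    assert res.cutoff == pytest.approx(6.0)  # lowest maximising midpoint


def test_roc_single_class_errors():
    with pytest.raises(InsufficientDataError):
        roc_analysis(_frame([1.0, 2.0], [1, 1]), "x")


@given(st.integers(0, 2**31 - 1))
def test_auc_equals_pair_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    n1, n0 = rng.integers(2, 15, size=2)
    # coarse grid forces plenty of ties
    cases = rng.integers(0, 6, size=n1).astype(float)
    controls = rng.integers(0, 6, size=n0).astype(float)
    res = roc_analysis(
        _frame(np.r_[cases, controls], np.r_[np.ones(n1), np.zeros(n0)]), "x")
    assert res.auc == pytest.approx(auc_pair_counting(cases, controls),
                                    abs=1e-12)


def test_null_auc_near_half(rng):
    x = rng.normal(size=1000)
    y = rng.permutation(np.r_[np.ones(500), np.zeros(500)]).astype(int)
    res = roc_analysis(_frame(x, y), "x")
    assert abs(res.auc - 0.5) < 0.05


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def test_binary_logistic_or_equals_cross_product():
    x = [1] * 8 + [0] * 2 + [1] * 4 + [0] * 6
    y = [1] * 10 + [0] * 10
    res = univariate_logistic(_frame([float(v) for v in x], y), "x")
    assert res.rows[0].odds_ratio == pytest.approx(6.0, rel=1e-6)
    assert res.rows[0].ci_low < 6.0 < res.rows[0].ci_high


def test_null_predictor_ci_contains_one(rng):
    x = rng.normal(size=500)
    y = rng.permutation(np.r_[np.ones(250), np.zeros(250)]).astype(int)
    res = univariate_logistic(_frame(x, y), "x")
    row = res.rows[0]
    assert row.ci_low < 1.0 < row.ci_high


def test_perfect_separation_flagged_not_crashed():
    x = np.r_[np.linspace(5, 6, 12), np.linspace(1, 2, 12)]
    y = np.r_[np.ones(12), np.zeros(12)].astype(int)
    res = univariate_logistic(_frame(x, y), "x")
    assert res.rows[0].separation


def test_constant_predictor_errors():
    x = np.ones(30)
    y = np.r_[np.ones(15), np.zeros(15)].astype(int)
    with pytest.raises(InsufficientDataError):
        univariate_logistic(_frame(x, y), "x")


def test_tertile_coding_reference_and_monotone_effect(rng):
    n = 300
    x = rng.normal(100, 25, size=n)
    logit = 0.08 * (x - 100)
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
    res = univariate_logistic(_frame(x, y), "x", coding="tertile")
    assert [r.level for r in res.rows] == ["2nd tertile", "3rd tertile"]
    assert res.rows[1].odds_ratio > res.rows[0].odds_ratio > 1.0


def test_multivariate_drops_duplicate_and_gates_entry(rng):
    n = 600
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    noise = rng.normal(size=n)
    logit = 1.2 * a + 1.0 * b
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
    frame = pd.DataFrame({
        "a": a, "a_dup": a * 2.0 + 1.0,  # correlation 1 with a
        "b": b, "noise": noise, "aneurysm": y,
    })
    res = multivariate_logistic(
        frame,
        [("a", "continuous"), ("a_dup", "continuous"),
         ("b", "continuous"), ("noise", "continuous")],
    )
    assert ("a" in res.included) != ("a_dup" in res.included)  # exactly one
    assert any(d[0] in ("a", "a_dup") for d in res.excluded_correlated)
    assert "noise" not in res.included  # univariate p ~ 0.5 never enters
    # both true effects recovered with CI excluding 1
    for pred in set(res.included) & {"a", "b"}:
        row = next(r for r in res.rows if r.predictor == pred)
        assert row.ci_low > 1.0
    assert "b" in res.included


def test_multivariate_empty_candidate_set_errors(rng):
    n = 200
    frame = pd.DataFrame({
        "noise": rng.normal(size=n),
        "aneurysm": rng.permutation(np.r_[np.ones(n // 2),
                                          np.zeros(n // 2)]).astype(int),
    })
    with pytest.raises(InsufficientDataError):
        multivariate_logistic(frame, [("noise", "continuous")])


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _group_frame(samples: dict) -> pd.DataFrame:
    rows = []
    for g, vals in samples.items():
        rows += [{"group": g, "x": float(v)} for v in vals]
    return pd.DataFrame(rows)


def test_identical_groups_rarely_rejected():
    hits = 0
    reps = 100
    for i in range(reps):
        rng = np.random.default_rng(1000 + i)
        frame = _group_frame({
            g: rng.normal(10, 2, size=50) for g in ("g1", "g2", "g3")})
        if compare_groups(frame, "x").omnibus_p <= 0.05:
            hits += 1
    assert hits / reps <= 0.10


def test_large_effect_detected_with_posthoc(rng):
    frame = _group_frame({"g1": rng.normal(0, 1, 50),
                          "g2": rng.normal(3, 1, 50)})
    res = compare_groups(frame, "x")
    assert res.omnibus_p < 0.001
    assert res.posthoc, "post-hoc must be reported when omnibus significant"
    (pair, p), = res.posthoc
    assert set(pair) == {"g1", "g2"}
    assert p < 0.05


def test_skewed_data_takes_kruskal_dunn_path(rng):
    frame = _group_frame({
        "g1": rng.lognormal(0.0, 1.0, 60),
        "g2": rng.lognormal(1.0, 1.0, 60),
        "g3": rng.lognormal(0.0, 1.0, 60),
    })
    res = compare_groups(frame, "x")
    assert res.test_used == "kruskal_wallis_mc"
    assert res.omnibus_p < 0.05
    sig_pairs = {frozenset(pair) for pair, p in res.posthoc if p < 0.05}
    assert frozenset({"g1", "g2"}) in sig_pairs


def test_undefined_values_excluded_from_n(rng):
    frame = _group_frame({"g1": rng.normal(0, 1, 30),
                          "g2": rng.normal(0, 1, 30)})
    frame.loc[frame.index[:5], "x"] = np.nan
    res = compare_groups(frame, "x")
    assert res.group_stats["g1"][0] == 25
    assert res.group_stats["g2"][0] == 30


def test_tiny_group_raises_named_error():
    frame = _group_frame({"g1": [1.0, 2.0], "g2": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(InsufficientDataError, match="g1"):
        compare_groups(frame, "x")
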