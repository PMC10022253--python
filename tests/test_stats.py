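"""ROM conversion, Pearson correlation, ICC, and the Model/Results front ends.

Statistical functions are checked against independent oracles: a from-scratch
product-moment/t-CDF evaluation for Pearson, an explicit two-way ANOVA for
ICC(2,1), and pingouin's intraclass_corr as a third, library-independent route.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import stdtr

from glenovol import (DegenerateVarianceError, ReliabilityModel, ShapeError,
                      VocabularyError, VolumeROMModel, correlation_matrix, describe,
                      icc, icc_category, irb_to_score, pearson, score_to_irb)
from glenovol.errors import DegenerateSampleWarning
from glenovol.stats import IRB_LEVELS

# ------------------------------------------------------------------ oracles


def pearson_oracle(x, y):
    """Brute-force product-moment formula and two-sided t-CDF p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * (1 - stdtr(n - 2, abs(t)))
    return r, p


def icc21_oracle(X):
    """Two-way ANOVA mean squares evaluated with explicit loops."""
    X = np.asarray(X, float)
    n, k = X.shape
    grand = X.mean()
    row_means = [X[i].mean() for i in range(n)]
    col_means = [X[:, j].mean() for j in range(k)]
    msr = k * sum((m - grand) ** 2 for m in row_means) / (n - 1)
    msc = n * sum((m - grand) ** 2 for m in col_means) / (k - 1)
    sse = sum((X[i, j] - row_means[i] - col_means[j] + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# ------------------------------------------------------------------ IRb scale

@pytest.mark.parametrize("label,score", [
    ("buttock", 1), ("L5", 2), ("L1", 6), ("T12", 7), ("T7", 12), ("T1", 18),
    ("BUTTOCK", 1), (" t1 ", 18),
])
def test_irb_to_score_published_scheme(label, score):
    assert irb_to_score(label) == score


def test_irb_scale_is_monotone_bijection():
    scores = [irb_to_score(lab) for lab in IRB_LEVELS]
    assert scores == list(range(1, 19))
    assert [score_to_irb(s) for s in scores] == list(IRB_LEVELS)


@pytest.mark.parametrize("bad", ["S1", "C7", "", "L6"])
def test_irb_unknown_label_rejected(bad):
    with pytest.raises(VocabularyError, match="accepted labels"):
        irb_to_score(bad)


# ---------------------------------------------------------------- descriptives

def test_describe_hand_arithmetic():
    df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
    row = describe(df).loc["v"]
    assert (row["mean"], row["sd"], row["min"], row["max"]) == (2.0, 1.0, 1.0, 3.0)


def test_describe_single_row_flags_degenerate_sample():
    with pytest.warns(DegenerateSampleWarning):
        row = describe(pd.DataFrame({"v": [5.0]})).loc["v"]
    assert row["sd"] == 0.0


def test_describe_empty_cohort_errors():
    with pytest.raises(ValueError):
        describe(pd.DataFrame())


def test_describe_counts_sex():
    df = pd.DataFrame({"v": [1.0, 2.0], "sex": ["m", "f"]})
    out = describe(df)
    assert out.loc["sex=m", "n"] == 1 and out.loc["sex=f", "n"] == 1


# -------------------------------------------------------------------- Pearson

def test_pearson_self_and_anti_correlation():
    x = np.array([1.0, 2.0, 4.0, 7.0])
    assert pearson(x, x).r == pytest.approx(1.0)
    assert pearson(x, -x).r == pytest.approx(-1.0)


def test_pearson_matches_brute_force_oracle():
    x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]
    res = pearson(x, y)
    r0, p0 = pearson_oracle(x, y)
    assert res.r == pytest.approx(r0, abs=1e-12)
    assert res.p == pytest.approx(p0, abs=1e-12)
    assert res.n == 4


def test_pearson_error_cases():
    with pytest.raises(ShapeError):
        pearson([1, 2, 3], [1, 2])
    with pytest.raises(ShapeError):
        pearson([1, 2], [1, 2])
    with pytest.raises(DegenerateVarianceError):
        pearson([1, 1, 1], [1, 2, 3])


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), a=st.floats(0.1, 5.0), b=st.floats(-10, 10))
def test_pearson_symmetry_and_affine_invariance(seed, a, b):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = rng.normal(size=12) + 0.5 * x
    r_xy, r_yx = pearson(x, y).r, pearson(y, x).r
    assert r_xy == pytest.approx(r_yx, abs=1e-12)
    assert pearson(a * x + b, y).r == pytest.approx(r_xy, abs=1e-9)
    assert pearson(-a * x + b, y).r == pytest.approx(-r_xy, abs=1e-9)


def test_p_monotone_in_abs_r_and_n():
    """p decreases with |r| at fixed n and with n at fixed r."""
    def p_of(r, n):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        return 2 * (1 - stdtr(n - 2, abs(t)))
    assert p_of(0.5, 20) < p_of(0.3, 20) < p_of(0.1, 20)
    assert p_of(0.3, 80) < p_of(0.3, 20)


# ---------------------------------------------------------- correlation matrix

def test_correlation_matrix_identical_columns_give_r_one():
    rng = np.random.default_rng(0)
    v = rng.normal(10, 3, size=40)
    cohort = pd.DataFrame({"Vol.TJ": v, "Vol.AIQ": v / 4, "Vol.ASQ": v / 4,
                           "Vol.PSQ": v / 4, "Vol.PIQ": v / 4,
                           "Sc": v, "ERs": v, "ER90": v, "IRb": v})
    grid = correlation_matrix(cohort)
    assert np.allclose(grid.r["Vol.TJ"], 1.0)
    assert grid.significant.all().all()


def test_correlation_matrix_listwise_deletion_reports_per_pair_n():
    rng = np.random.default_rng(1)
    cohort = pd.DataFrame({c: rng.normal(size=30) for c in
                           ("Vol.TJ", "Vol.AIQ", "Vol.ASQ", "Vol.PSQ", "Vol.PIQ",
                            "Sc", "ERs", "ER90", "IRb")})
    cohort.loc[:4, "Sc"] = np.nan
    grid = correlation_matrix(cohort)
    assert grid.n.loc["Sc", "Vol.TJ"] == 25
    assert grid.n.loc["ERs", "Vol.TJ"] == 30


def test_correlation_matrix_missing_column_errors():
    with pytest.raises(ShapeError, match="missing columns"):
        correlation_matrix(pd.DataFrame({"Sc": [1, 2, 3]}))


# ------------------------------------------------------------------------ ICC

def test_icc_perfect_agreement():
    x = np.arange(10.0)
    res = icc(np.column_stack([x, x]))
    assert res.value == pytest.approx(1.0)
    assert res.category == "excellent"


def test_icc_matches_hand_anova_on_6x2_table():
    table = np.array([[9.1, 9.3], [10.2, 10.8], [8.4, 8.1],
                      [12.0, 11.5], [10.9, 11.2], [7.6, 8.0]])
    res = icc(table)
    assert res.value == pytest.approx(icc21_oracle(table), abs=1e-12)


def test_icc_matches_pingouin_cross_check():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    X = rng.normal(10, 3, size=(20, 1)) + rng.normal(0, 1, size=(20, 3))
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(20), 3),
        "rater": np.tile(np.arange(3), 20),
        "score": X.ravel()})
    expected = pg.intraclass_corr(long, targets="subject", raters="rater",
                                  ratings="score").set_index("Type").loc["ICC(A,1)", "ICC"]
    assert icc(X).value == pytest.approx(float(expected), abs=1e-9)


def test_icc_error_cases():
    with pytest.raises(ShapeError):
        icc(np.zeros((3, 2)))
    with pytest.raises(DegenerateVarianceError):
        icc(np.full((6, 2), 3.0))
    with pytest.raises(ShapeError):
        icc(np.array([[1.0, np.nan]] * 6))


@pytest.mark.parametrize("value,category", [
    (0.49, "poor"), (0.5, "fair"), (0.74, "fair"), (0.75, "good"),
    (0.8, "good"), (0.89, "good"), (0.9, "excellent"), (1.0, "excellent"),
    (-0.2, "poor"),
])
def test_icc_category_half_open_boundaries(value, category):
    assert icc_category(value) == category


def test_icc_estimator_recovery_across_true_values():
    """Mean ICC estimate over replicates tracks the variance-implied truth."""
    rng = np.random.default_rng(11)
    for true_icc in (0.5, 0.75, 0.9):
        sd_err = np.sqrt((1 - true_icc) / true_icc)  # true-score SD 1
        est = []
        for _ in range(120):
            subj = rng.normal(0, 1, size=(200, 1))
            X = subj + rng.normal(0, sd_err, size=(200, 2))
            est.append(icc(X).value)
        assert abs(np.mean(est) - true_icc) < 0.03


# --------------------------------------------------------------- front ends

def test_volume_rom_model_converts_irb_labels():
    rng = np.random.default_rng(2)
    df = pd.DataFrame({c: rng.normal(10, 2, 20) for c in
                       ("Vol.TJ", "Vol.AIQ", "Vol.ASQ", "Vol.PSQ", "Vol.PIQ",
                        "Sc", "ERs", "ER90")})
    df["IRb_label"] = [IRB_LEVELS[i % 18] for i in range(20)]
    model = VolumeROMModel(df)
    assert model.cohort["IRb"].tolist() == [(i % 18) + 1 for i in range(20)]
    results = model.fit()
    assert "Pearson correlations" in results.summary()
    assert results.scatter_data("Sc", "Vol.TJ").shape == (20, 2)


def test_volume_rom_model_rejects_duplicate_patients():
    df = pd.DataFrame({"patient_id": ["a", "a"], "Sc": [1, 2]})
    with pytest.raises(ShapeError, match="duplicate"):
        VolumeROMModel(df)


def test_reliability_model_summary():
    rng = np.random.default_rng(3)
    ratings = pd.DataFrame(rng.normal(10, 3, (30, 1)) + rng.normal(0, 1, (30, 2)),
                           columns=["surgeon1", "surgeon2"])
    res = ReliabilityModel(ratings).fit()
    assert res.icc.model.startswith("two-way random")
    assert "ICC" in res.summary() and "surgeon1" in res.summary()
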