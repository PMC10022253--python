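"""ROM handling and the cohort statistics: descriptives, Pearson correlations, ICC.

Two statsmodels-style front ends wrap the low-level functions:

* :class:`VolumeROMModel` — built from a cohort table (per-patient joint
  volumes and range-of-motion values); ``fit()`` returns
  :class:`VolumeROMResults` holding the demographics-table-style descriptives and the
  motion x volume Pearson correlation grid with per-pair p-values and counts.
* :class:`ReliabilityModel` — built from an n_subjects x k_raters ratings
  matrix; ``fit()`` returns :class:`ReliabilityResults` with the intraclass
  correlation ICC(2,1) and its reliability category.

Internal rotation on back (IRb) is recorded as the highest vertebral level
reached by the thumb and converted to a contiguous ordinal score: buttock = 1,
L5..L1 = 2..6, T12..T1 = 7..18.

p-values are not adjusted for multiple testing; reports state this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (DegenerateSampleWarning, DegenerateVarianceError, ShapeError,
                     VocabularyError)

__all__ = ["IRB_LEVELS", "irb_to_score", "score_to_irb", "describe",
           "CorrelationResult", "pearson", "correlation_matrix", "CorrelationGrid",
           "ICCResult", "icc", "icc_category",
           "VolumeROMModel", "VolumeROMResults", "ReliabilityModel", "ReliabilityResults",
           "MOTION_COLUMNS", "VOLUME_COLUMNS"]

#: IRb vertebral-level vocabulary, caudal to cranial; index + 1 is the score
IRB_LEVELS = ("buttock", "L5", "L4", "L3", "L2", "L1",
              "T12", "T11", "T10", "T9", "T8", "T7",
              "T6", "T5", "T4", "T3", "T2", "T1")

_IRB_SCORE = {lab.lower(): i + 1 for i, lab in enumerate(IRB_LEVELS)}

MOTION_COLUMNS = ("Sc", "ERs", "ER90", "IRb")
VOLUME_COLUMNS = ("Vol.TJ", "Vol.AIQ", "Vol.ASQ", "Vol.PSQ", "Vol.PIQ")

#: physiologic upper bounds used for validation warnings (degrees)
ANGLE_BOUNDS = {"Sc": 180.0, "ERs": 120.0, "ER90": 120.0}


def irb_to_score(label: str) -> int:
    """Ordinal score (1-18) for an internal-rotation vertebral-level label.

    buttock -> 1, L5..L1 -> 2..6, T12..T1 -> 7..18; case-insensitive.
    """
    try:
        return _IRB_SCORE[str(label).strip().lower()]
    except KeyError:
        raise VocabularyError(
            f"unknown internal-rotation level {label!r}; accepted labels are "
            f"{', '.join(IRB_LEVELS)}") from None


def score_to_irb(score: int) -> str:
    """Inverse of :func:`irb_to_score`."""
    score = int(score)
    if not 1 <= score <= 18:
        raise VocabularyError(f"IRb score must be in 1..18, got {score}")
    return IRB_LEVELS[score - 1]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided p-value and sample count."""

    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    The p-value uses ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees
    of freedom.

    Raises
    ------
    ShapeError
        If the vectors differ in length or n < 3.
    DegenerateVarianceError
        If either vector has zero variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ShapeError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if n < 3:
        raise ShapeError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateVarianceError("correlation is undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def describe(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographics-table-style summary: mean, sample SD, min, max, n per numeric column.

    SD uses the n - 1 denominator.  A single-row cohort yields SD 0 together
    with a :class:`DegenerateSampleWarning`.  A ``sex`` column, if present, is
    summarized as category counts in extra rows (count in ``n``).
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    rows = []
    numeric = cohort.select_dtypes(include=[np.number])
    for col in numeric.columns:
        vals = numeric[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        if vals.size == 1:
            warnings.warn(f"column {col!r} has a single observation; SD reported as 0",
                          DegenerateSampleWarning, stacklevel=2)
            sd = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
        rows.append({"variable": col, "mean": float(np.mean(vals)), "sd": sd,
                     "min": float(np.min(vals)), "max": float(np.max(vals)),
                     "n": int(vals.size)})
    if "sex" in cohort.columns:
        for level, count in cohort["sex"].value_counts().items():
            rows.append({"variable": f"sex={level}", "mean": np.nan, "sd": np.nan,
                         "min": np.nan, "max": np.nan, "n": int(count)})
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class CorrelationGrid:
    """Motion x volume grid of Pearson correlations with per-pair n."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    @property
    def significant(self) -> pd.DataFrame:
        return self.p < 0.05

    def cell(self, motion: str, volume: str) -> CorrelationResult:
        return CorrelationResult(r=float(self.r.loc[motion, volume]),
                                 p=float(self.p.loc[motion, volume]),
                                 n=int(self.n.loc[motion, volume]))


def correlation_matrix(cohort: pd.DataFrame,
                       motion_cols=MOTION_COLUMNS,
                       volume_cols=VOLUME_COLUMNS) -> CorrelationGrid:
    """Pairwise Pearson correlations between each motion and each volume column.

    Missing values are dropped listwise per pair, and the per-pair n is
    reported in the grid.
    """
    missing = [c for c in (*motion_cols, *volume_cols) if c not in cohort.columns]
    if missing:
        raise ShapeError(f"cohort table is missing columns: {missing}")
    r = pd.DataFrame(index=list(motion_cols), columns=list(volume_cols), dtype=float)
    p = r.copy()
    n = pd.DataFrame(index=list(motion_cols), columns=list(volume_cols), dtype=int)
    for m in motion_cols:
        for v in volume_cols:
            pair = cohort[[m, v]].dropna()
            res = pearson(pair[m], pair[v])
            r.loc[m, v], p.loc[m, v], n.loc[m, v] = res.r, res.p, res.n
    return CorrelationGrid(r=r, p=p, n=n)


def icc_category(value: float) -> str:
    """Reliability category for an ICC: poor / fair / good / excellent.

    Half-open bins with the upper category winning at the knots:
    < 0.5 poor; [0.5, 0.75) fair; [0.75, 0.9) good; >= 0.9 excellent.
    """
    if value > 1.0:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "fair"
    if value < 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation with the model descriptor and reliability category."""

    value: float
    model: str
    category: str
    n_subjects: int
    n_raters: int


#: descriptor for the ICC form computed by :func:`icc`
ICC_MODEL = "two-way random effects, absolute agreement, single measures (ICC(2,1))"


def icc(ratings) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the mean squares of the two-way ANOVA decomposition of an
    ``n_subjects x k_raters`` matrix with no missing cells:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC, MSE are the subject, rater, and residual mean squares.

    Raises
    ------
    ShapeError
        If fewer than 5 subjects, fewer than 2 raters, or missing cells.
    DegenerateVarianceError
        If all ratings are identical.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2:
        raise ShapeError("ratings must be a 2-D subjects x raters matrix")
    n, k = X.shape
    if n < 5 or k < 2:
        raise ShapeError(f"need >= 5 subjects and >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(X)):
        raise ShapeError("ratings matrix has missing or non-finite cells")
    if np.ptp(X) == 0:
        raise DegenerateVarianceError("all ratings identical; ICC is undefined")

    grand = X.mean()
    ssr = k * float(((X.mean(axis=1) - grand) ** 2).sum())   # subjects (rows)
    ssc = n * float(((X.mean(axis=0) - grand) ** 2).sum())   # raters (columns)
    sst = float(((X - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return ICCResult(value=float(value), model=ICC_MODEL,
                     category=icc_category(float(value)), n_subjects=n, n_raters=k)


class VolumeROMModel:
    """Joint-volume vs range-of-motion analysis for a patient cohort.

    Parameters
    ----------
    cohort
        Per-patient table containing the volume columns ``Vol.TJ``,
        ``Vol.AIQ``, ``Vol.ASQ``, ``Vol.PSQ``, ``Vol.PIQ`` (mL) and the
        motion columns ``Sc``, ``ERs``, ``ER90`` (degrees) and ``IRb``
        (ordinal score 1-18, or an ``IRb_label`` vertebral-level column that
        is converted on construction).

    Examples
    --------
    >>> results = VolumeROMModel(cohort).fit()      # doctest: +SKIP
    >>> print(results.summary())                    # doctest: +SKIP
    """

    def __init__(self, cohort: pd.DataFrame,
                 motion_cols=MOTION_COLUMNS, volume_cols=VOLUME_COLUMNS):
        cohort = cohort.copy()
        if "IRb" not in cohort.columns and "IRb_label" in cohort.columns:
            cohort["IRb"] = cohort["IRb_label"].map(irb_to_score)
        if "patient_id" in cohort.columns and cohort["patient_id"].duplicated().any():
            dupes = cohort.loc[cohort["patient_id"].duplicated(), "patient_id"].tolist()
            raise ShapeError(f"duplicate patient_id values: {dupes[:5]}")
        for col, bound in ANGLE_BOUNDS.items():
            if col in cohort.columns:
                bad = cohort[col].dropna()
                if ((bad < 0) | (bad > bound)).any():
                    warnings.warn(f"{col} values outside [0, {bound}] degrees",
                                  UserWarning, stacklevel=2)
        self.cohort = cohort
        self.motion_cols = tuple(motion_cols)
        self.volume_cols = tuple(volume_cols)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "VolumeROMModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> "VolumeROMResults":
        descriptives = describe(self.cohort)
        grid = correlation_matrix(self.cohort, self.motion_cols, self.volume_cols)
        return VolumeROMResults(model=self, descriptives=descriptives, grid=grid)


@dataclass
class VolumeROMResults:
    """Fitted cohort analysis: descriptives plus the correlation grid."""

    model: VolumeROMModel
    descriptives: pd.DataFrame
    grid: CorrelationGrid

    @property
    def r(self) -> pd.DataFrame:
        return self.grid.r

    @property
    def pvalues(self) -> pd.DataFrame:
        return self.grid.p

    @property
    def nobs(self) -> pd.DataFrame:
        return self.grid.n

    @property
    def significant(self) -> pd.DataFrame:
        return self.grid.significant

    def scatter_data(self, motion: str, volume: str) -> pd.DataFrame:
        """The paired, complete-case observations behind one correlation cell."""
        return self.model.cohort[[volume, motion]].dropna().reset_index(drop=True)

    def summary(self) -> str:
        """Text report: cohort descriptives and the motion x volume correlations."""
        lines = ["Joint volume vs range of motion", "=" * 58,
                 f"patients: {len(self.model.cohort)}", "",
                 "Cohort summary (mean +/- SD, range)", "-" * 58]
        for var, row in self.descriptives.iterrows():
            if np.isnan(row["mean"]):
                lines.append(f"{var:>12s}  n={int(row['n'])}")
            else:
                lines.append(f"{var:>12s}  {row['mean']:8.2f} +/- {row['sd']:6.2f}  "
                             f"({row['min']:.2f}-{row['max']:.2f})  n={int(row['n'])}")
        lines += ["", "Pearson correlations, motion x volume (* p < 0.05)", "-" * 58,
                  "        " + "".join(f"{v:>12s}" for v in self.model.volume_cols)]
        for m in self.model.motion_cols:
            cells = []
            for v in self.model.volume_cols:
                c = self.grid.cell(m, v)
                cells.append(f"{c.r:9.2f}{'*' if c.significant else ' '}  ")
            lines.append(f"{m:>8s}" + "".join(cells))
        lines += ["", "p-values are two-sided and unadjusted for multiplicity."]
        return "\n".join(lines)


class ReliabilityModel:
    """Inter- or intra-observer reliability of repeated volume measurements.

    ``ratings`` is an n_subjects x k_raters matrix (DataFrame or array); for
    intra-observer analysis the repeated sessions take the place of raters.
    """

    def __init__(self, ratings):
        if isinstance(ratings, pd.DataFrame):
            self.rater_names = [str(c) for c in ratings.columns]
            ratings = ratings.to_numpy(dtype=float)
        else:
            ratings = np.asarray(ratings, dtype=float)
            self.rater_names = [f"rater{i + 1}" for i in range(ratings.shape[1])]
        self.ratings = ratings

    @classmethod
    def from_csv(cls, path) -> "ReliabilityModel":
        df = pd.read_csv(path)
        return cls(df.drop(columns=[c for c in ("subject", "patient_id") if c in df.columns]))

    def fit(self) -> "ReliabilityResults":
        return ReliabilityResults(model=self, icc=icc(self.ratings))


@dataclass
class ReliabilityResults:
    """Fitted reliability analysis wrapping an :class:`ICCResult`."""

    model: ReliabilityModel
    icc: ICCResult

    @property
    def value(self) -> float:
        return self.icc.value

    @property
    def category(self) -> str:
        return self.icc.category

    def summary(self) -> str:
        return "\n".join([
            "Measurement reliability", "=" * 40,
            f"subjects: {self.icc.n_subjects}   raters: {self.icc.n_raters} "
            f"({', '.join(self.model.rater_names)})",
            f"ICC model: {self.icc.model}",
            f"ICC = {self.icc.value:.3f}  ->  {self.icc.category} reliability",
        ])
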