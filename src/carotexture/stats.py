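"""Cohort statistics: two-way ANOVA, interaction contrasts, Spearman
correlations by sex, and intra-reader reproducibility.

The analysis plan mirrors a small longitudinal imaging cohort with a
fixed two-way sex-by-week design:

* a fixed-effects two-way ANOVA (cell-means model, partial Type-III
  sums of squares via sum-coded factors) relates each outcome to sex,
  week and their interaction;
* between-week comparisons within one sex are sex-by-week interaction
  contrasts: the cell-mean difference tested against the pooled
  residual mean square;
* associations between outcomes are mid-rank Spearman correlations,
  computed separately per sex on pairwise-complete observations;
* reader reproducibility of repeated readings is summarized by the mean
  absolute difference, the within-subject standard deviation
  ``sqrt(sum d_i^2 / 2n)`` and a two-way random-effects,
  absolute-agreement, single-measurement ICC with an F-based 95% CI.

All p-values are two-sided; no multiplicity adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import CarotextureError

__all__ = [
    "CellStats",
    "AnovaResult",
    "ContrastResult",
    "IccResult",
    "ReproResult",
    "cell_statistics",
    "two_way_anova",
    "week_contrast_within_sex",
    "residual_plot_data",
    "spearman_by_sex",
    "icc_single",
    "repro_summary",
    "simulate_null_interaction_pvalues",
]


# ---------------------------------------------------------------------------
# cell summaries and the pooled residual


@dataclass(frozen=True)
class CellStats:
    """Per-(sex, week) cell means/SDs/ns and the pooled within-cell MS.

    The pooled within-cell mean square equals the residual mean square
    of the saturated (full-interaction) cell-means model, so contrasts
    can be computed without refitting.
    """

    table: pd.DataFrame  # columns sex, week, n, mean, sd
    residual_df: int
    residual_ms: float

    def cell(self, sex, week) -> pd.Series:
        m = self.table[(self.table["sex"] == sex) & (self.table["week"] == week)]
        if m.empty or m.iloc[0]["n"] == 0:
            raise CarotextureError(f"empty cell ({sex}, {week})")
        return m.iloc[0]


def cell_statistics(df: pd.DataFrame, outcome: str, sex_col: str = "sex",
                    week_col: str = "week") -> CellStats:
    d = df[[sex_col, week_col, outcome]].dropna()
    g = d.groupby([sex_col, week_col], sort=True)[outcome]
    table = g.agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
    table = table.rename(columns={sex_col: "sex", week_col: "week"})
    n_total = int(table["n"].sum())
    n_cells = int((table["n"] > 0).sum())
    residual_df = n_total - n_cells
    sse = float(((g.count() - 1) * g.var(ddof=1)).fillna(0.0).sum())
    residual_ms = sse / residual_df if residual_df > 0 else np.nan
    return CellStats(table=table, residual_df=residual_df, residual_ms=residual_ms)


# ---------------------------------------------------------------------------
# two-way ANOVA


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA table plus the cell summaries behind it."""

    outcome: str
    anova_table: pd.DataFrame  # index: sex, week, sex:week, Residual
    cells: CellStats
    fitted: pd.Series = field(repr=False, default=None)
    residuals: pd.Series = field(repr=False, default=None)
    inestimable: tuple[str, ...] = ()

    def effect(self, term: str) -> pd.Series:
        return self.anova_table.loc[term]

    def summary(self) -> str:
        lines = [f"Two-way ANOVA for {self.outcome} (Type III, sum coding)",
                 self.anova_table.to_string(float_format=lambda v: f"{v:.6g}")]
        if self.inestimable:
            lines.append(f"inestimable terms (empty cells): {', '.join(self.inestimable)}")
        return "\n".join(lines)


def two_way_anova(df: pd.DataFrame, outcome: str, sex_col: str = "sex",
                  week_col: str = "week") -> AnovaResult:
    """Fixed-effects sex x week ANOVA with partial (Type III) SS.

    Unbalanced cells are handled by least squares with sum-coded
    factors.  If an empty cell makes the interaction inestimable, the
    additive model is fitted instead and the interaction is flagged in
    ``inestimable``.
    """
    d = df[[sex_col, week_col, outcome]].dropna().copy()
    d.columns = ["sex", "week", "y"]
    d["sex"] = d["sex"].astype(str)
    d["week"] = d["week"].astype(str)
    cells = cell_statistics(d, "y")
    n_sex, n_week = d["sex"].nunique(), d["week"].nunique()
    if len(cells.table) < 2:
        raise CarotextureError("at least two non-empty cells are required")
    if cells.residual_df <= 0:
        raise CarotextureError("no residual degrees of freedom")

    # drop inestimable terms: single-level factors, interactions with
    # empty cells; the remaining terms are still reported
    inestimable = []
    terms = []
    if n_sex > 1:
        terms.append("C(sex, Sum)")
    else:
        inestimable.append("sex")
    if n_week > 1:
        terms.append("C(week, Sum)")
    else:
        inestimable.append("week")
    if n_sex > 1 and n_week > 1 and len(cells.table) == n_sex * n_week:
        terms.append("C(sex, Sum):C(week, Sum)")
    else:
        inestimable.append("sex:week")
    if not terms:
        raise CarotextureError("no estimable factor: need >= 2 levels of sex or week")
    formula = "y ~ " + " + ".join(terms)

    model = smf.ols(formula, data=d).fit()
    table = anova_lm(model, typ=3).rename(
        index={
            "C(sex, Sum)": "sex",
            "C(week, Sum)": "week",
            "C(sex, Sum):C(week, Sum)": "sex:week",
        }
    )
    table = table.drop(index="Intercept", errors="ignore")
    table = table.rename(columns={"PR(>F)": "p"})
    # a term with zero SS explains nothing: define F = 0 (p = 1) even when
    # the residual MS is itself zero (noise-free degenerate designs)
    zero = table.index != "Residual"
    zero &= np.isclose(table["sum_sq"].to_numpy(), 0.0, atol=1e-12)
    table.loc[zero, "F"] = 0.0
    table.loc[zero, "p"] = 1.0
    # re-key cells back to the caller's original labels
    out_cells = cell_statistics(df, outcome, sex_col=sex_col, week_col=week_col)
    return AnovaResult(
        outcome=outcome,
        anova_table=table,
        cells=out_cells,
        fitted=model.fittedvalues,
        residuals=model.resid,
        inestimable=tuple(inestimable),
    )


def residual_plot_data(result: AnovaResult) -> pd.DataFrame:
    """Residual-vs-fitted pairs for checking the model assumptions."""
    return pd.DataFrame({"fitted": result.fitted, "residual": result.residuals})


# ---------------------------------------------------------------------------
# interaction contrasts


@dataclass(frozen=True)
class ContrastResult:
    """A between-week cell-mean contrast within one sex."""

    sex: str
    week_a: object
    week_b: object
    estimate: float
    se: float
    t: float
    p: float
    df: int
    zero_variance: bool = False


def week_contrast_within_sex(cells: CellStats | AnovaResult, sex, week_a, week_b) -> ContrastResult:
    """Contrast ``mean(sex, week_b) - mean(sex, week_a)``.

    The standard error uses the pooled residual mean square of the
    cell-means model and the two cell sizes; the two-sided p comes from
    a t distribution on the residual df.  On noise-free data the pooled
    MS is zero: the result is flagged ``zero_variance`` with p
    degenerating to 0 (nonzero estimate) or 1 (zero estimate).
    """
    if isinstance(cells, AnovaResult):
        cells = cells.cells
    a = cells.cell(sex, week_a)
    b = cells.cell(sex, week_b)
    est = float(b["mean"] - a["mean"])
    mse, dof = cells.residual_ms, cells.residual_df
    if dof <= 0 or not np.isfinite(mse):
        raise CarotextureError("residual degrees of freedom exhausted")
    se = float(np.sqrt(mse * (1.0 / a["n"] + 1.0 / b["n"])))
    if se == 0.0:
        return ContrastResult(sex=sex, week_a=week_a, week_b=week_b, estimate=est,
                              se=0.0, t=np.inf if est else 0.0,
                              p=0.0 if est else 1.0, df=dof, zero_variance=True)
    t = est / se
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return ContrastResult(sex=sex, week_a=week_a, week_b=week_b, estimate=est,
                          se=se, t=float(t), p=p, df=dof)


# ---------------------------------------------------------------------------
# Spearman correlations by sex


def spearman_by_sex(df: pd.DataFrame, x: str, y: str, sex_col: str = "sex") -> pd.DataFrame:
    """Mid-rank Spearman rho and two-sided p per sex.

    Rows with a missing value in either variable are dropped pairwise
    (per sex).  Constant vectors leave rho undefined (NaN) and are
    flagged in the ``defined`` column.
    """
    rows = []
    for sex, g in df.groupby(sex_col, sort=True):
        d = g[[x, y]].dropna()
        n = len(d)
        if n < 3:
            raise CarotextureError(f"need >= 3 complete pairs for sex {sex!r}, got {n}")
        if d[x].nunique() == 1 or d[y].nunique() == 1:
            rows.append({"sex": sex, "rho": np.nan, "p": np.nan, "n": n, "defined": False})
            continue
        rho, p = sps.spearmanr(d[x], d[y])
        rows.append({"sex": sex, "rho": float(rho), "p": float(p), "n": n, "defined": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reproducibility


@dataclass(frozen=True)
class IccResult:
    """Two-way random, absolute-agreement, single-measurement ICC."""

    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int = 2


def icc_single(t1, t2, confidence: float = 0.95) -> IccResult:
    """ICC(A,1): two-way random effects, absolute agreement, single reading.

    Computed from the two-way mean squares of the subjects-by-readings
    layout; the CI uses the standard F-distribution bounds with
    Satterthwaite denominator degrees of freedom.
    """
    y = np.column_stack([np.asarray(t1, float), np.asarray(t2, float)])
    n, k = y.shape
    if n < 3:
        raise CarotextureError("need >= 3 paired readings")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom > 0 else 1.0

    alpha = 1.0 - confidence
    if mse == 0 or icc >= 1.0:
        return IccResult(icc=icc, ci_low=icc, ci_high=icc, n=n, k=k)
    # Satterthwaite df for the (MSC, MSE) mixture, then F-distribution bounds
    fj = msc / mse
    term = n * (1.0 + (k - 1) * icc) - k * icc
    v_num = (k - 1) * (n - 1) * (k * icc * fj + term) ** 2
    v_den = (n - 1) * k**2 * icc**2 * fj**2 + term**2
    v = v_num / v_den
    f_u = sps.f.ppf(1.0 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1.0 - alpha / 2, v, n - 1)
    lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return IccResult(icc=icc, ci_low=float(lo), ci_high=float(hi), n=n, k=k)


@dataclass(frozen=True)
class ReproResult:
    """Repeat-reading reproducibility summary for one feature."""

    feature: str
    mean_t1: float
    sd_t1: float
    mean_t2: float
    sd_t2: float
    mean_abs_diff: float
    sd_abs_diff: float
    within_subject_sd: float
    icc: IccResult | None
    n: int

    def summary(self) -> str:
        base = (
            f"{self.feature}: t1 {self.mean_t1:.4g} ({self.sd_t1:.4g}), "
            f"t2 {self.mean_t2:.4g} ({self.sd_t2:.4g}); "
            f"|diff| {self.mean_abs_diff:.4g} ({self.sd_abs_diff:.4g}); "
            f"s_w {self.within_subject_sd:.4g}"
        )
        if self.icc is not None:
            base += f"; ICC {self.icc.icc:.3f} (95% CI {self.icc.ci_low:.3f}-{self.icc.ci_high:.3f})"
        return base


def repro_summary(t1, t2, feature: str = "") -> ReproResult:
    """Mean absolute difference, within-subject SD and ICC of repeat readings.

    The within-subject SD is ``sqrt(sum d_i^2 / (2 n))`` over the paired
    differences ``d_i``; it is sign-insensitive and in the feature's
    original units.
    """
    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    if t1.shape != t2.shape or t1.ndim != 1:
        raise CarotextureError("readings must be equal-length 1-D paired arrays")
    d = t2 - t1
    n = d.size
    return ReproResult(
        feature=feature,
        mean_t1=float(t1.mean()), sd_t1=float(t1.std(ddof=1)),
        mean_t2=float(t2.mean()), sd_t2=float(t2.std(ddof=1)),
        mean_abs_diff=float(np.abs(d).mean()),
        sd_abs_diff=float(np.abs(d).std(ddof=1)),
        within_subject_sd=float(np.sqrt(np.sum(d * d) / (2.0 * n))),
        icc=icc_single(t1, t2) if n >= 3 else None,
        n=n,
    )


# ---------------------------------------------------------------------------
# null calibration of the interaction test


def simulate_null_interaction_pvalues(
    n_sex: int = 2, n_week: int = 3, n_per_cell: int = 1000,
    n_reps: int = 500, rng=None,
) -> np.ndarray:
    """Interaction-test p-values on balanced null (pure-noise) designs.

    Uses the balanced-design closed form of the two-way F statistic
    (vectorized over replicates); a test verifies it agrees with
    :func:`two_way_anova` to numerical precision on individual draws.
    """
    rng = np.random.default_rng(rng)
    a, b, n = n_sex, n_week, n_per_cell
    y = rng.standard_normal((n_reps, a, b, n))
    cell = y.mean(axis=3)
    row = cell.mean(axis=2, keepdims=True)
    col = cell.mean(axis=1, keepdims=True)
    grand = cell.mean(axis=(1, 2), keepdims=True)
    ss_int = n * np.sum((cell - row - col + grand) ** 2, axis=(1, 2))
    df_int = (a - 1) * (b - 1)
    sse = np.sum((y - cell[..., None]) ** 2, axis=(1, 2, 3))
    df_e = a * b * (n - 1)
    f = (ss_int / df_int) / (sse / df_e)
    return sps.f.sf(f, df_int, df_e)
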