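"""Longitudinal and group statistics for cohort tables.

Implements the study-style analyses on per-(subject, VOI, timepoint)
measurements: six-month difference values (delta = month6 - month0, positive
means an increase), one-sample t-tests of delta against zero, mixed-effects
group comparisons with random intercepts for subject (and VOI within subject
when repeated timepoints are analyzed together), ordinary least-squares
associations, and the Mann-Whitney U test for ordinal clinical scores.

No multiple-comparison correction is applied anywhere; every reported
p-value is unadjusted. Normality diagnostics (skewness, kurtosis) are
computed for reporting only and never gate an analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FitError

logger = logging.getLogger(__name__)

__all__ = [
    "DiffRecord",
    "TTestResult",
    "RegressionResult",
    "MixedCompareResult",
    "average_timepoints",
    "longitudinal_diff",
    "one_sample_t",
    "mixed_group_compare",
    "linear_regress",
    "mann_whitney",
    "percent_change",
    "group_summary",
    "normality_diagnostics",
]


@dataclass
class DiffRecord:
    """Per-VOI longitudinal difference of one measure (later minus earlier)."""

    subject_id: str
    voi_id: str
    measure: str
    delta: float


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero sample variance


@dataclass
class RegressionResult:
    rc: float  # regression coefficient (slope)
    r2: float
    p: float
    n: int


@dataclass
class MixedCompareResult:
    effect: float  # group contrast on the response scale
    se: float
    p: float
    variance_components: dict[str, float]
    downgraded: bool = False  # fell back to a subject-mean two-sample test


def average_timepoints(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Cross-sectional value per VOI: unweighted mean over available timepoints."""
    cols = ["subject_id", "voi_id", "group"]
    out = (
        table.dropna(subset=[measure])
        .groupby(cols, as_index=False)[measure]
        .mean()
    )
    return out


def longitudinal_diff(
    table: pd.DataFrame,
    measure: str,
    baseline: str = "mo0",
    followup: str = "mo6",
) -> list[DiffRecord]:
    """Per-VOI difference ``followup - baseline``; VOIs missing either endpoint
    are skipped with a log entry."""
    out: list[DiffRecord] = []
    for (sid, vid), sub in table.groupby(["subject_id", "voi_id"]):
        tp = sub.set_index("timepoint")[measure]
        if baseline not in tp.index or followup not in tp.index:
            logger.info("VOI (%s, %s) missing %s or %s; skipped", sid, vid, baseline, followup)
            continue
        delta = float(tp[followup] - tp[baseline])
        if np.isnan(delta):
            logger.info("VOI (%s, %s) has NaN endpoint; skipped", sid, vid)
            continue
        out.append(DiffRecord(subject_id=str(sid), voi_id=str(vid), measure=measure, delta=delta))
    return out


def one_sample_t(deltas) -> TTestResult:
    """Classical one-sample Student's t-test of mean delta = 0 (two-sided)."""
    x = np.asarray([d.delta if isinstance(d, DiffRecord) else d for d in deltas], dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t-test needs n >= 2")
    if np.std(x, ddof=1) == 0:
        return TTestResult(t=float("nan"), df=x.size - 1, p=float("nan"), degenerate=True)
    res = sps.ttest_1samp(x, 0.0)
    return TTestResult(t=float(res.statistic), df=x.size - 1, p=float(res.pvalue))


def mixed_group_compare(
    table: pd.DataFrame,
    response: str,
    group_col: str = "group",
    groups: tuple[str, str] | None = None,
    sex_covariate: bool = False,
    voi_random: bool | None = None,
) -> MixedCompareResult:
    """Two-group comparison with subject random intercepts (REML + Wald).

    ``groups`` selects the two levels to compare (default: the two present);
    the effect is level2 minus level1. When several timepoints per VOI are in
    the table (or ``voi_random=True``), a nested VOI-within-subject random
    intercept is added. Non-convergence falls back to an ordinary two-sample
    comparison of subject means, flagged ``downgraded``.
    """
    import statsmodels.formula.api as smf

    df = table.dropna(subset=[response]).copy()
    levels = sorted(df[group_col].unique()) if groups is None else list(groups)
    if len(levels) < 2:
        raise ValueError("mixed_group_compare needs two groups")
    df = df[df[group_col].isin(levels)]
    if df.groupby(group_col)["subject_id"].nunique().min() < 2:
        raise ValueError("need at least 2 subjects per group")
    df["_grp"] = (df[group_col] == levels[1]).astype(float)

    if voi_random is None:
        reps = df.groupby(["subject_id", "voi_id"]).size()
        voi_random = bool((reps > 1).any()) and df["voi_id"].nunique() > 1
    df["_voi_uid"] = df["subject_id"].astype(str) + ":" + df["voi_id"].astype(str)

    fixed = f"{response} ~ _grp"
    if sex_covariate and "sex" in df.columns and df["sex"].nunique() > 1:
        fixed += " + C(sex)"
    vc = {"voi": "0 + C(_voi_uid)"} if voi_random else None

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(fixed, df, groups=df["subject_id"], vc_formula=vc)
            try:
                fit = model.fit(reml=True)
            except np.linalg.LinAlgError:
                fit = model.fit(reml=True, method="powell")
        effect = float(fit.params["_grp"])
        se = float(fit.bse["_grp"])
        p = float(fit.pvalues["_grp"])
        vcs = {"subject": float(fit.cov_re.iloc[0, 0]), "residual": float(fit.scale)}
        if voi_random and "voi Var" in fit.params.index:
            vcs["voi"] = float(fit.params["voi Var"]) * float(fit.scale)
        if not np.isfinite(se) or not np.isfinite(p):
            raise FitError("mixed model produced non-finite inference")
        return MixedCompareResult(effect=effect, se=se, p=p, variance_components=vcs)
    except (Exception) as exc:  # noqa: BLE001 -- statsmodels raises many types
        logger.warning("mixed model failed (%s); downgrading to subject-mean t-test", exc)
        means = df.groupby(["subject_id", "_grp"], as_index=False)[response].mean()
        a = means.loc[means["_grp"] == 0, response].to_numpy()
        b = means.loc[means["_grp"] == 1, response].to_numpy()
        t = sps.ttest_ind(b, a, equal_var=False)
        effect = float(b.mean() - a.mean())
        se = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
        return MixedCompareResult(
            effect=effect, se=se, p=float(t.pvalue),
            variance_components={}, downgraded=True,
        )


def linear_regress(x, y) -> RegressionResult:
    """Ordinary least squares association with two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("linear regression needs n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope undefined")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return RegressionResult(rc=float(res.slope), r2=r2, p=p, n=int(x.size))


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U with exact enumeration for small tie-free samples.

    Exact two-sided p when ``n_a + n_b <= 12`` and there are no ties; normal
    approximation with tie correction otherwise. Returns (U of sample a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def percent_change(delta: float, reference: float, ndigits: int | None = 1) -> float:
    """Percent change ``100 * delta / reference``, rounded for reporting."""
    if reference == 0:
        raise ValueError("zero reference value")
    pct = 100.0 * delta / reference
    return round(pct, ndigits) if ndigits is not None else pct


def group_summary(table: pd.DataFrame, measures: list[str]) -> pd.DataFrame:
    """Group mean (SD) per measure and timepoint plus the all-timepoint pool."""
    rows = []
    for measure in measures:
        sub = table.dropna(subset=[measure])
        for group, g in sub.groupby("group"):
            rows.append(
                {
                    "measure": measure, "group": group, "timepoint": "all",
                    "mean": g[measure].mean(), "sd": g[measure].std(ddof=1),
                    "n": len(g),
                }
            )
            for tp, gt in g.groupby("timepoint"):
                rows.append(
                    {
                        "measure": measure, "group": group, "timepoint": tp,
                        "mean": gt[measure].mean(), "sd": gt[measure].std(ddof=1),
                        "n": len(gt),
                    }
                )
    return pd.DataFrame(rows)


def normality_diagnostics(values) -> dict[str, float]:
    """Sample skewness and excess kurtosis (report-only)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    return {
        "skewness": float(sps.skew(x)) if x.size > 2 else float("nan"),
        "excess_kurtosis": float(sps.kurtosis(x)) if x.size > 3 else float("nan"),
        "n": int(x.size),
    }
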