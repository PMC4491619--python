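"""Cohort-level statistics: tertile stratification, the three-way mixed
ANOVA on coherence, Pearson correlations, and age-corrected W scores.

Stratification uses the alpha3/alpha2 ratio with either fixed cutoffs
(default 1.0 and 1.17, the published convention, with half-open intervals
[0,1) / [1,1.17) / [1.17,inf) so every ratio maps to exactly one group)
or empirical tertiles of the sample.

The coherence ANOVA is a split-plot design: group is the between-subject
factor and frequency band x electrode pair the fully crossed
within-subject grid. The group x band x pair interaction is tested with
numerator df (g-1)(f-1)(p-1) and the subject-within-group x band x pair
residual as the error term; the Greenhouse-Geisser epsilon (from the
pooled within-group covariance projected onto the interaction contrast
space) corrects both df, and Mauchly's sphericity statistic is reported
alongside (the correction is always reported, never gated on the test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DesignError, NormError


# ---------------------------------------------------------------------------
# tertile stratification

@dataclass(frozen=True)
class TertileCutoffs:
    """Boundaries of the low/middle/high ratio groups."""

    low_hi: float = 1.0
    high_lo: float = 1.17

    def __post_init__(self) -> None:
        if not (0 < self.low_hi <= self.high_lo):
            raise DesignError(
                f"cutoffs must satisfy 0 < {self.low_hi} <= {self.high_lo}")


def classify_tertile(ratio: float, cutoffs: TertileCutoffs = TertileCutoffs()) -> str:
    """Assign a ratio to 'low', 'middle', or 'high'.

    Half-open convention: low for ratio < low_hi, high for
    ratio >= high_lo, middle otherwise — so exactly 1.0 is middle and
    exactly 1.17 is high, and the published gap between 1.16 and 1.17 is
    closed without ambiguity.
    """
    if not np.isfinite(ratio) or ratio < 0:
        raise ValueError(f"ratio must be finite and >= 0, got {ratio}")
    if ratio < cutoffs.low_hi:
        return "low"
    if ratio >= cutoffs.high_lo:
        return "high"
    return "middle"


def derive_tertiles(ratios) -> TertileCutoffs:
    """Empirical tertile cutoffs (linear-interpolation quantiles)."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 3:
        raise DesignError("need at least 3 ratios to derive tertiles")
    lo, hi = np.quantile(ratios, [1.0 / 3.0, 2.0 / 3.0])
    if np.isclose(lo, hi):
        warnings.warn(
            "degenerate tertile cutoffs (1/3 and 2/3 quantiles coincide)",
            stacklevel=2)
        hi = lo + np.finfo(float).eps * max(1.0, abs(lo))
    return TertileCutoffs(low_hi=float(lo), high_lo=float(hi))


# ---------------------------------------------------------------------------
# split-plot ANOVA

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts (Helmert, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(1, k):
        c[i - 1, :i] = 1.0 / i
        c[i - 1, i] = -1.0
        c[i - 1] /= np.linalg.norm(c[i - 1])
    return c


def gg_epsilon(scores: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for within-subject scores.

    ``scores`` is (n_subjects, k) of within-cell values; ``contrasts`` a
    (d, k) orthonormal contrast basis for the effect of interest. Epsilon
    is the Box index tr(E)^2 / (d tr(E^2)) of E = C S C', clipped to
    [1/d, 1].
    """
    s = np.cov(scores, rowvar=False, ddof=1)
    e = contrasts @ np.atleast_2d(s) @ contrasts.T
    d = e.shape[0]
    tr = np.trace(e)
    denom = d * np.trace(e @ e)
    if denom <= 0:
        return 1.0
    return float(np.clip(tr**2 / denom, 1.0 / d, 1.0))


def _pooled_interaction_cov(cells: np.ndarray, groups: np.ndarray,
                            contrasts: np.ndarray) -> tuple[np.ndarray, int]:
    """Pooled within-group covariance projected onto the contrast space."""
    d = contrasts.shape[0]
    pooled = np.zeros((d, d))
    df = 0
    for g in np.unique(groups):
        sub = cells[groups == g]
        if sub.shape[0] < 2:
            continue
        proj = sub @ contrasts.T
        pooled += (sub.shape[0] - 1) * np.cov(proj, rowvar=False, ddof=1)
        df += sub.shape[0] - 1
    if df == 0:
        raise DesignError("every group needs >= 2 subjects for the ANOVA")
    return pooled / df, df


def mixed_anova(values: np.ndarray, groups) -> dict:
    """Group x frequency x pair interaction of a split-plot design.

    Parameters
    ----------
    values
        ``(n_subjects, n_freq, n_pairs)`` array; every subject must have
        the full band x pair grid (missing cells are a design error).
    groups
        Group label per subject (>= 2 distinct labels).

    Returns
    -------
    dict with ``F``, ``df_num``, ``df_den``, ``p``, ``gg_epsilon``,
    ``gg_p``, ``mauchly_w``, ``mauchly_p``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.ndim != 3:
        raise DesignError("values must be subject x frequency x pair")
    if np.isnan(values).any():
        raise DesignError("missing cells in the within-subject grid")
    n, f, p = values.shape
    if groups.shape != (n,):
        raise DesignError("one group label per subject required")
    labels = np.unique(groups)
    g = labels.size
    if g < 2:
        raise DesignError("need >= 2 groups")
    if f < 2 or p < 2:
        raise DesignError("both within factors need >= 2 levels")

    # project each subject's band x pair matrix onto the interaction space
    # (double-centering across both within factors)
    mats = values  # (n, f, p)
    row = mats.mean(axis=2, keepdims=True)
    col = mats.mean(axis=1, keepdims=True)
    grand = mats.mean(axis=(1, 2), keepdims=True)
    resid = mats - row - col + grand          # (n, f, p) interaction scores
    cells = resid.reshape(n, f * p)

    group_means = np.vstack([cells[groups == lab].mean(axis=0) for lab in labels])
    counts = np.array([(groups == lab).sum() for lab in labels])
    overall = (counts @ group_means) / n

    ss_inter = float(counts @ ((group_means - overall) ** 2).sum(axis=1))
    within = cells - group_means[np.searchsorted(labels, groups)]
    ss_err = float((within ** 2).sum())

    df_num = (g - 1) * (f - 1) * (p - 1)
    df_den = (n - g) * (f - 1) * (p - 1)
    if df_den <= 0:
        raise DesignError("no residual degrees of freedom")
    f_stat = (ss_inter / df_num) / (ss_err / df_den) if ss_err > 0 else (
        0.0 if ss_inter == 0 else np.inf)
    p_unc = float(scipy.stats.f.sf(f_stat, df_num, df_den))

    contrasts = np.kron(_orthonormal_contrasts(f), _orthonormal_contrasts(p))
    cov, pooled_df = _pooled_interaction_cov(cells, groups, contrasts)
    d = contrasts.shape[0]
    tr = np.trace(cov)
    eps = 1.0
    denom = d * np.trace(cov @ cov)
    if denom > 0:
        eps = float(np.clip(tr**2 / denom, 1.0 / d, 1.0))
    gg_p = float(scipy.stats.f.sf(f_stat, df_num * eps, df_den * eps))

    # Mauchly's sphericity statistic on the pooled projected covariance
    eigvals = np.linalg.eigvalsh(cov)
    mauchly_w = np.nan
    mauchly_p = np.nan
    if np.all(eigvals > 0) and tr > 0:
        mauchly_w = float(np.prod(eigvals) / (tr / d) ** d)
        chi_df = d * (d + 1) // 2 - 1
        factor = pooled_df - (2 * d**2 + d + 2) / (6.0 * d)
        chi2 = -factor * np.log(mauchly_w)
        mauchly_p = float(scipy.stats.chi2.sf(chi2, chi_df))

    return {
        "F": float(f_stat),
        "df_num": df_num,
        "df_den": df_den,
        "p": p_unc,
        "gg_epsilon": eps,
        "gg_p": gg_p,
        "mauchly_w": mauchly_w,
        "mauchly_p": mauchly_p,
    }


def pairwise_group_contrasts(values: np.ndarray, groups) -> pd.DataFrame:
    """Uncorrected pairwise Welch t contrasts on the subject means.

    A transparent replacement for stepwise multiple-range post hocs; the
    p-values are not adjusted for multiplicity (note in the output), so
    interpret them descriptively.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    subject_means = values.reshape(values.shape[0], -1).mean(axis=1)
    labels = list(np.unique(groups))
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            res = scipy.stats.ttest_ind(
                subject_means[groups == a], subject_means[groups == b],
                equal_var=False)
            rows.append({"group_a": a, "group_b": b,
                         "t": float(res.statistic), "p_uncorrected": float(res.pvalue)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations and W scores

def pearson_r(x, y) -> dict:
    """Pearson correlation with its two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = scipy.stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue)}


@dataclass(frozen=True)
class ControlNorm:
    """Age regression fitted on controls for one measure."""

    intercept: float
    slope: float
    resid_sd: float

    def __post_init__(self) -> None:
        if not (self.resid_sd > 0):
            raise NormError("residual SD must be positive")


def fit_control_norm(values, ages) -> ControlNorm:
    """Least-squares age regression on a control sample.

    The residual SD uses ddof=1, so the control sample's own W scores
    have mean 0 and SD exactly 1.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.size < 3:
        raise NormError("need >= 3 controls")
    if np.std(ages) == 0:
        raise NormError("control ages must vary")
    slope, intercept = np.polyfit(ages, values, 1)
    resid = values - (intercept + slope * ages)
    sd = float(np.std(resid, ddof=1))
    if sd == 0:
        raise NormError("controls fit the age line exactly; W undefined")
    return ControlNorm(intercept=float(intercept), slope=float(slope), resid_sd=sd)


def w_score(value: float, age: float, norm: ControlNorm) -> float:
    """Age-corrected standardized deviation from the control prediction."""
    return (value - (norm.intercept + norm.slope * age)) / norm.resid_sd


# ---------------------------------------------------------------------------
# group summary

SUMMARY_COLUMNS = ("age", "education", "mmse", "alpha3_alpha2")


def group_summary(records: pd.DataFrame,
                  columns=SUMMARY_COLUMNS) -> pd.DataFrame:
    """Per-group mean +/- SD and range for covariates and the ratio.

    ``records`` needs a ``group`` column plus the summarized columns.
    Groups with a single subject report SD 0 with ``sd_degenerate`` set.
    """
    if "group" not in records.columns:
        raise DesignError("records must carry a 'group' column")
    rows = []
    for group, sub in records.groupby("group", sort=False):
        if len(sub) == 0:
            raise DesignError(f"empty group {group}")
        row: dict = {"group": group, "n": len(sub),
                     "sd_degenerate": len(sub) < 2}
        for col in columns:
            vals = sub[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[f"{col}_min"] = float(vals.min())
            row[f"{col}_max"] = float(vals.max())
        rows.append(row)
    order = {"low": 0, "middle": 1, "high": 2}
    rows.sort(key=lambda r: order.get(r["group"], 99))
    return pd.DataFrame(rows)
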