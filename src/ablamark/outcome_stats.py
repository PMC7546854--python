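"""Outcome statistics for ablative-margin cohorts.

Covers the statistical layer used to relate the ablative margin (AM) to
local tumor progression (LTP): Kaplan-Meier estimation and log-rank
comparison of margin groups, forward-stepwise Cox proportional-hazards
modelling of LTP risk factors, DeLong's test for the difference of two
correlated ROC AUCs, cross-tabulation summaries of two margin-assessment
methods, and Mann-Whitney / chi-square / Fisher group comparisons.

Kaplan-Meier, log-rank and Cox fitting are delegated to lifelines (Efron
handling of tied event times); the DeLong machinery and the stepwise
selection loop are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .imaging_core import ValidationError

__all__ = [
    "COHORT_BINARY_COLUMNS",
    "validate_cohort",
    "KMEstimate",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "CoxResult",
    "CoxConvergenceError",
    "cox_fit",
    "DeLongResult",
    "delong_compare",
    "CrossTab",
    "reference_crosstab",
    "crosstab_summaries",
    "GroupCompareResult",
    "group_compare",
    "binary_status_at_horizon",
]

COHORT_BINARY_COLUMNS = (
    "age_ge65",
    "sex",
    "margin_le5",
    "abutting_vessel",
    "afp_gt200",
    "comorbidity",
    "cirrhosis",
)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check the per-patient table: required columns, no missing, binary codes."""
    required = {"months", "ltp_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"cohort table lacks columns: {sorted(missing)}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValidationError(f"cohort table has missing values in {bad}")
    if (df["months"] < 0).any():
        raise ValidationError("follow-up months must be >= 0")
    for col in ("ltp_event", *COHORT_BINARY_COLUMNS):
        if col in df.columns and not df[col].isin((0, 1)).all():
            raise ValidationError(f"column {col!r} must be binary-coded 0/1")
    return df


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass
class KMEstimate:
    """Product-limit estimate with per-time risk sets.

    ``times`` are the distinct observed times (events and censorings),
    ``survival`` the step-function value just after each time, ``at_risk``
    the risk-set size at each time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        if t < 0:
            raise ValidationError("time must be >= 0")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def cumulative_ltp_at(self, t: float) -> float:
        """Cumulative incidence scale: 1 - S(t)."""
        return 1.0 - self.survival_at(t)


def km_estimate(times, events) -> KMEstimate:
    """Right-censoring-aware Kaplan-Meier estimate of LTP-free probability."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise ValidationError("need at least one subject")
    if times.shape != events.shape:
        raise ValidationError("times and events must have the same length")
    if (times < 0).any():
        raise ValidationError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    obs_times = table.index.to_numpy(dtype=float)
    keep = obs_times >= 0
    sf = kmf.survival_function_["KM_estimate"].to_numpy()
    return KMEstimate(
        times=obs_times[keep],
        survival=sf[keep],
        at_risk=table["at_risk"].to_numpy()[keep],
        n=int(times.size),
    )


@dataclass
class LogrankResult:
    statistic: float
    p_value: float


def logrank_test(group_labels, times, events) -> LogrankResult:
    """Two-group log-rank test; p from chi-square with 1 df."""
    g = np.asarray(group_labels)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(int)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {levels.size}")
    a, b = (g == levels[0], g == levels[1])
    if a.sum() == 0 or b.sum() == 0:
        raise ValidationError("each group needs at least one subject")
    res = _ll_logrank(times[a], times[b], events[a], events[b])
    return LogrankResult(float(res.test_statistic), float(res.p_value))


# ---------------------------------------------------------------------------
# Cox proportional hazards with forward-stepwise selection
# ---------------------------------------------------------------------------


class CoxConvergenceError(Exception):
    """Partial-likelihood maximization failed (e.g. complete separation)."""


@dataclass
class CoxResult:
    """Hazard ratios with 95% CIs and Wald p-values for the final model."""

    table: pd.DataFrame
    selected: list[str] = field(default_factory=list)
    log_likelihood: float = np.nan


def _fit_cph(df: pd.DataFrame, covariates: list[str], duration_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    sub = df[covariates + [duration_col, event_col]]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise CoxConvergenceError(
            f"Cox fit failed for covariates {covariates} "
            f"(possible complete separation / monotone likelihood): {exc}"
        ) from exc
    if not np.all(np.isfinite(cph.params_.to_numpy())):
        raise CoxConvergenceError(f"non-finite coefficients for covariates {covariates}")
    return cph


def _hr_table(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    return pd.DataFrame(
        {
            "covariate": s.index,
            "hr": s["exp(coef)"].to_numpy(),
            "ci_lower": s["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": s["exp(coef) upper 95%"].to_numpy(),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list[str],
    forward_stepwise: bool = False,
    alpha_enter: float = 0.05,
    duration_col: str = "months",
    event_col: str = "ltp_event",
) -> CoxResult:
    """Cox PH fit (Efron ties), optionally with pure forward selection.

    Forward mode starts from the null model and at each step adds the
    candidate with the smallest likelihood-ratio p-value, while that value
    is below ``alpha_enter``; there is no removal step.
    """
    validate_cohort(cohort)
    if not covariates:
        raise ValidationError("need at least one covariate")
    for c in covariates:
        if c not in cohort.columns:
            raise ValidationError(f"covariate {c!r} not in cohort table")
    if int(cohort[event_col].sum()) < 2:
        raise ValidationError("need at least 2 events for a Cox fit")

    if not forward_stepwise:
        cph = _fit_cph(cohort, list(covariates), duration_col, event_col)
        return CoxResult(_hr_table(cph), list(covariates), float(cph.log_likelihood_))

    selected: list[str] = []
    ll_current: float | None = None  # null-model partial log-likelihood, lazily derived
    remaining = list(covariates)
    best_fit = None
    while remaining:
        best = None
        for cand in remaining:
            try:
                cph = _fit_cph(cohort, selected + [cand], duration_col, event_col)
            except CoxConvergenceError:
                continue
            ll = float(cph.log_likelihood_)
            if ll_current is None:
                # 2*(ll - ll_null) is the reported LR statistic of this fit
                lr_full = float(cph.log_likelihood_ratio_test().test_statistic)
                ll_current = ll - lr_full / 2.0
            lr = 2.0 * (ll - ll_current)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if best is None or p < best[0]:
                best = (p, cand, cph, ll)
        if best is None or best[0] >= alpha_enter:
            break
        _, cand, cph, ll = best
        selected.append(cand)
        remaining.remove(cand)
        ll_current = ll
        best_fit = cph
    if best_fit is None:
        empty = pd.DataFrame(columns=["covariate", "hr", "ci_lower", "ci_upper", "p"])
        return CoxResult(empty, [], np.nan)
    return CoxResult(_hr_table(best_fit), selected, float(best_fit.log_likelihood_))


# ---------------------------------------------------------------------------
# DeLong comparison of correlated AUCs
# ---------------------------------------------------------------------------


@dataclass
class DeLongResult:
    auc_1: float
    auc_2: float
    p_value: float
    z: float


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components V10 (cases) and V01 (controls) for one predictor."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r = _midranks(pos)
    neg_r = _midranks(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_compare(binary_outcome, score_1, score_2) -> DeLongResult:
    """Compare the AUCs of two paired predictors of a binary outcome.

    AUCs use the Mann-Whitney identity (ties count 1/2); the variance and
    covariance of the paired AUCs come from the DeLong structural
    components, and the difference is tested with a two-sided normal test.
    """
    y = np.asarray(binary_outcome).astype(int)
    s1 = np.asarray(score_1, dtype=np.float64)
    s2 = np.asarray(score_2, dtype=np.float64)
    if not (y.shape == s1.shape == s2.shape):
        raise ValidationError("outcome and both score vectors must be the same length")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValidationError("both outcome classes must be present")
    auc1, v10_1, v01_1 = _delong_components(s1, y)
    auc2, v10_2, v01_2 = _delong_components(s2, y)
    m, n = int((y == 1).sum()), int((y == 0).sum())
    s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ cov @ contrast)
    diff = auc1 - auc2
    if var <= 1e-300:
        z = 0.0
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(auc1, auc2, p, float(z))


def binary_status_at_horizon(df: pd.DataFrame, horizon_months: float = 24.0) -> pd.DataFrame:
    """Binary LTP-by-horizon outcome among subjects evaluable at the horizon.

    Subjects with an event at or before the horizon are positives; subjects
    followed beyond it without an event are negatives; subjects censored
    earlier are dropped (their horizon status is unknown).
    """
    validate_cohort(df)
    event_by = (df["ltp_event"] == 1) & (df["months"] <= horizon_months)
    evaluable = event_by | (df["months"] >= horizon_months)
    out = df.loc[evaluable].copy()
    out["ltp_by_horizon"] = event_by.loc[evaluable].astype(int)
    return out


# ---------------------------------------------------------------------------
# Cross-tabulation of two margin-assessment methods
# ---------------------------------------------------------------------------


@dataclass
class CrossTab:
    """2x2x2 counts indexed by (DIR group, conventional group, LTP status).

    Index 0 on the first two axes is the AM <= 5 mm group (group A), index 1
    the AM > 5 mm group (group B); the last axis is 0 = no LTP, 1 = LTP.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2, 2):
            raise ValidationError(f"counts must be 2x2x2, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("counts must be >= 0")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


def reference_crosstab() -> CrossTab:
    """Published DIR-vs-conventional margin cross-tabulation (141 patients).

    Rows (DIR): AM <= 5 mm n=61, AM > 5 mm n=80; columns split the
    conventional assessment the same way, with each cell split by LTP status.
    """
    counts = np.zeros((2, 2, 2), dtype=np.int64)
    counts[0, 0, 1], counts[0, 0, 0] = 8, 34   # DIR <=5, conventional <=5
    counts[0, 1, 1], counts[0, 1, 0] = 8, 11   # DIR <=5, conventional >5
    counts[1, 0, 1], counts[1, 0, 0] = 3, 26   # DIR >5,  conventional <=5
    counts[1, 1, 1], counts[1, 1, 0] = 0, 51   # DIR >5,  conventional >5
    return CrossTab(counts)


def _odds_ratio(ltp_a: int, no_a: int, ltp_b: int, no_b: int) -> float:
    cells = np.array([ltp_a, no_a, ltp_b, no_b], dtype=float)
    if np.any(cells == 0):  # Haldane-Anscombe correction
        cells = cells + 0.5
    return float((cells[0] * cells[3]) / (cells[1] * cells[2]))


def crosstab_summaries(ct: CrossTab) -> dict:
    """Marginals, LTP counts, method agreement and per-method odds ratios."""
    c = ct.counts
    dir_sizes = c.sum(axis=(1, 2))
    conv_sizes = c.sum(axis=(0, 2))
    ltp_dir = c[:, :, 1].sum(axis=1)
    ltp_conv = c[:, :, 1].sum(axis=0)
    total = ct.n_total
    ltp_total = int(c[:, :, 1].sum())
    agreement = int(c[0, 0].sum() + c[1, 1].sum())
    return {
        "n_total": total,
        "dir_group_sizes": {"le5": int(dir_sizes[0]), "gt5": int(dir_sizes[1])},
        "conventional_group_sizes": {"le5": int(conv_sizes[0]), "gt5": int(conv_sizes[1])},
        "ltp_by_dir_group": {"le5": int(ltp_dir[0]), "gt5": int(ltp_dir[1])},
        "ltp_by_conventional_group": {"le5": int(ltp_conv[0]), "gt5": int(ltp_conv[1])},
        "ltp_total": ltp_total,
        "ltp_proportion_pct": 100.0 * ltp_total / total if total else np.nan,
        "method_agreement": agreement,
        "odds_ratio_dir": _odds_ratio(
            int(ltp_dir[0]), int(dir_sizes[0] - ltp_dir[0]),
            int(ltp_dir[1]), int(dir_sizes[1] - ltp_dir[1]),
        ),
        "odds_ratio_conventional": _odds_ratio(
            int(ltp_conv[0]), int(conv_sizes[0] - ltp_conv[0]),
            int(ltp_conv[1]), int(conv_sizes[1] - ltp_conv[1]),
        ),
    }


# ---------------------------------------------------------------------------
# Two-group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupCompareResult:
    p_value: float
    method: str
    statistic: float


def group_compare(
    values, group, categorical: bool | None = None, method: str = "auto"
) -> GroupCompareResult:
    """Two-group comparison following the conventional decision rules.

    Continuous data use the Mann-Whitney U test (two-sided normal
    approximation with tie correction, no continuity correction, so
    identical samples give p = 1 exactly).  Categorical data use Pearson's
    chi-square, switching to Fisher's exact test when any expected 2x2 cell
    is below 5 (Cochran's rule); ``method="fisher"`` or ``"chi-square"``
    forces a specific categorical test.  ``categorical=None`` infers:
    non-numeric values, or integers with at most a handful of levels, are
    categorical.
    """
    if method not in ("auto", "fisher", "chi-square"):
        raise ValidationError(f"method must be auto/fisher/chi-square, got {method!r}")
    values = np.asarray(values)
    group = np.asarray(group)
    if values.shape != group.shape:
        raise ValidationError("values and group must have the same length")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels.size}")
    a = values[group == levels[0]]
    b = values[group == levels[1]]
    if a.size == 0 or b.size == 0:
        raise ValidationError("each group needs at least one observation")

    if categorical is None:
        if values.dtype.kind in "OUSb":
            categorical = True
        else:
            uniq = np.unique(values)
            categorical = uniq.size <= 5 and np.allclose(uniq, np.round(uniq.astype(float)))

    if not categorical:
        af, bf = a.astype(float), b.astype(float)
        pooled = np.concatenate([af, bf])
        if np.ptp(pooled) == 0:
            return GroupCompareResult(1.0, "mann-whitney", float(af.size * bf.size / 2))
        res = stats.mannwhitneyu(af, bf, alternative="two-sided", method="asymptotic", use_continuity=False)
        return GroupCompareResult(float(res.pvalue), "mann-whitney", float(res.statistic))

    table = pd.crosstab(pd.Series(values), pd.Series(group)).to_numpy()
    chi2_res = stats.chi2_contingency(table, correction=False)
    use_fisher = method == "fisher" or (
        method == "auto" and table.shape == (2, 2) and (chi2_res.expected_freq < 5).any()
    )
    if use_fisher:
        if table.shape != (2, 2):
            raise ValidationError("Fisher's exact test needs a 2x2 table")
        odds, p = stats.fisher_exact(table)
        return GroupCompareResult(float(p), "fisher", float(odds))
    return GroupCompareResult(float(chi2_res.pvalue), "chi-square", float(chi2_res.statistic))
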