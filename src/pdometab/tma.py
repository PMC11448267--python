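"""TMA H-score scoring, survival cut-point derivation and association tests.

An immunohistochemistry H-score is the product of the percent of epithelial
cells staining positive (0-100) and an ordinal staining-intensity tier
(0-3), giving a 0-300 range. Duplicate cores are resolved by taking the
maximum per case. A survival-optimal threshold for "high" vs "low"
expressers is found by maximally selected log-rank: every midpoint between
adjacent observed case scores is a candidate cut, the two-group log-rank
statistic is evaluated at each admissible split, and the maximizing cut is
returned (a depth-1 survival partition). Kaplan-Meier summaries and
clinicopathologic association tests (Fisher exact for binary covariates,
likelihood-ratio chi-square for grade) complete the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import chi2

from .stats import TestResult, bh_adjust, fisher_exact, lr_chisq, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

INTENSITY_TIERS = (0, 1, 2, 3)


@dataclass(frozen=True)
class CoreScore:
    """One TMA core: percent positive epithelial cells and intensity tier."""

    case_id: str
    core_id: str
    pct_positive: float
    intensity: int

    def __post_init__(self) -> None:
        if not 0 <= self.pct_positive <= 100:
            raise ValueError("pct_positive must lie in [0, 100]")
        if self.intensity not in INTENSITY_TIERS:
            raise ValueError("intensity must be one of {0, 1, 2, 3}")


@dataclass
class TmaCaseRecord:
    """Case-level record: resolved H-score, survival and covariates."""

    case_id: str
    h_score: float
    time_months: float
    event: int
    grade: int | None = None
    lvi: int | None = None
    pni: int | None = None
    subtype: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.h_score <= 300:
            raise ValueError("case H-score must lie in [0, 300]")
        if self.time_months < 0:
            raise ValueError("survival time must be non-negative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class CutpointResult:
    """Maximally selected log-rank cut with its full candidate profile."""

    cut: float
    statistic: float
    pvalue: float
    pvalue_corrected: float
    n_low: int
    n_high: int
    profile: pd.DataFrame


def h_score(core: CoreScore) -> float:
    """H-score = percent positive x intensity tier (0-300)."""
    return core.pct_positive * core.intensity


def weighted_h_score(pct_by_tier: dict[int, float]) -> float:
    """Classic weighted H-score: sum over tiers of pct_i x tier i.

    Optional alternative to the single-product score; expects percent of
    cells in each tier (tiers 1-3; percentages must not exceed 100 total).
    """
    total_pct = sum(pct_by_tier.values())
    if total_pct > 100 + 1e-9:
        raise ValueError("tier percentages exceed 100")
    if any(t not in INTENSITY_TIERS for t in pct_by_tier):
        raise ValueError("tiers must be in {0, 1, 2, 3}")
    return float(sum(pct * tier for tier, pct in pct_by_tier.items()))


def case_score(cores) -> float:
    """Resolve duplicate cores: the core with the highest H-score scores the case."""
    cores = list(cores)
    if not cores:
        raise ValueError("case has zero cores")
    return max(h_score(c) for c in cores)


def cases_from_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-core cohort table to one row per case (max-core rule)."""
    df = cohort.copy()
    df["core_h"] = df["pct_positive"] * df["intensity"]
    if ((df["pct_positive"] < 0) | (df["pct_positive"] > 100)).any():
        raise ValueError("pct_positive outside [0, 100]")
    if not df["intensity"].isin(INTENSITY_TIERS).all():
        raise ValueError("intensity outside {0, 1, 2, 3}")
    first = df.groupby("case_id").first()
    out = first[[c for c in ("time_months", "dss_event", "grade", "lvi", "pni", "subtype")
                 if c in first.columns]].copy()
    out["h_score"] = df.groupby("case_id")["core_h"].max()
    return out.reset_index()


def logrank(time, event, group) -> TestResult:
    """Two-group log-rank test with hypergeometric variance and tie handling.

    ``group`` is a boolean mask for arm membership. Statistic distributed
    chi-square(1) under the null; two-sided p.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int).astype(bool)
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        raise ValueError("both arms must be non-empty")
    if not event.any():
        raise ValueError("no events observed")
    stat = _logrank_statistic(time, event, group)
    return TestResult(stat, float(chi2.sf(stat, 1)), df=1.0)


def _logrank_statistic(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    event_times = np.unique(time[event])
    # at risk at t: subjects with time >= t
    sorted_all = np.sort(time)
    sorted_grp = np.sort(time[group])
    n_at_risk = len(time) - np.searchsorted(sorted_all, event_times, side="left")
    n1_at_risk = group.sum() - np.searchsorted(sorted_grp, event_times, side="left")
    d_total = np.array([(event & (time == t)).sum() for t in event_times], dtype=float)
    d1 = np.array([(event & group & (time == t)).sum() for t in event_times], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d_total * n1_at_risk / n_at_risk
        var = np.where(
            n_at_risk > 1,
            d_total
            * (n1_at_risk / n_at_risk)
            * (1 - n1_at_risk / n_at_risk)
            * (n_at_risk - d_total)
            / (n_at_risk - 1),
            0.0,
        )
    observed_minus_expected = (d1 - expected).sum()
    v = var.sum()
    if v == 0:
        return 0.0
    return float(observed_minus_expected**2 / v)


def find_cutpoint(
    cases: pd.DataFrame,
    min_group_frac: float = 0.1,
    score_col: str = "h_score",
    time_col: str = "time_months",
    event_col: str = "dss_event",
) -> CutpointResult:
    """Maximally selected log-rank cut-point over observed-score midpoints.

    Candidates are midpoints between adjacent sorted unique case scores
    whose induced low/high split keeps at least ``min_group_frac`` of cases
    in both arms. Ties on the statistic resolve to the smaller cut. The
    unadjusted p at the selected cut is reported (matching the convention
    of reporting the raw log-rank p at the derived threshold) together with
    a conservative Bonferroni bound over the candidate grid.
    """
    scores = cases[score_col].to_numpy(dtype=float)
    time = cases[time_col].to_numpy(dtype=float)
    event = cases[event_col].to_numpy(dtype=int).astype(bool)
    unique = np.unique(scores)
    if unique.size < 2:
        raise ValueError("need at least 2 distinct case scores")
    if not event.any():
        raise ValueError("no events in cohort")
    candidates = (unique[:-1] + unique[1:]) / 2.0
    n = scores.size
    min_n = min_group_frac * n
    rows = []
    for cut in candidates:
        low = scores < cut
        n_low, n_high = int(low.sum()), int((~low).sum())
        if n_low < min_n or n_high < min_n:
            continue
        stat = _logrank_statistic(time, event, low)
        rows.append({"cut": cut, "statistic": stat, "n_low": n_low, "n_high": n_high})
    if not rows:
        raise ValueError("no candidate cut satisfies the group-size constraint")
    profile = pd.DataFrame(rows)
    best = profile["statistic"].idxmax()  # first max -> smallest cut on ties
    cut = float(profile.loc[best, "cut"])
    stat = float(profile.loc[best, "statistic"])
    p = float(chi2.sf(stat, 1))
    return CutpointResult(
        cut=cut,
        statistic=stat,
        pvalue=p,
        pvalue_corrected=min(1.0, p * len(profile)),
        n_low=int(profile.loc[best, "n_low"]),
        n_high=int(profile.loc[best, "n_high"]),
        profile=profile,
    )


def km_summary(time, event) -> tuple[float, bool, pd.DataFrame]:
    """Kaplan-Meier product-limit summary of one arm.

    Returns (median survival in months, undefined flag, survival-curve
    table). The median is the earliest time the estimate drops to <= 0.5;
    when the curve never reaches 0.5 the median is NaN and flagged.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty arm")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    median = kmf.median_survival_time_
    undefined = not np.isfinite(median)
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    return (np.nan if undefined else float(median)), undefined, curve


def covariate_associations(cases: pd.DataFrame, cut: float) -> pd.DataFrame:
    """Association of the low/high split with clinicopathologic covariates.

    Binary covariates (LVI, PNI, dichotomized subtype) use Fisher's exact
    test; grade (3 levels) uses the likelihood-ratio chi-square. Per-group
    frequencies are reported; BH adjustment spans the tested covariates.
    """
    low = cases["h_score"] < cut
    rows = []
    for cov in ("lvi", "pni", "subtype", "grade"):
        if cov not in cases.columns:
            continue
        sub = cases[[cov]].copy()
        sub["low"] = low
        sub = sub.dropna(subset=[cov])
        table = pd.crosstab(sub["low"], sub[cov])
        if table.shape[0] < 2 or table.shape[1] < 2 or (table.to_numpy() == 0).all(0).any():
            logger.warning("covariate %s skipped: empty stratum", cov)
            continue
        try:
            if table.shape[1] == 2:
                res = fisher_exact(table.to_numpy())
                test = "fisher"
            else:
                res = lr_chisq(table.to_numpy())
                test = "lr_chisq"
        except ValueError as exc:
            logger.warning("covariate %s skipped: %s", cov, exc)
            continue
        freq = table.div(table.sum(axis=1), axis=0)
        rows.append(
            {
                "covariate": cov,
                "test": test,
                "statistic": res.statistic,
                "p": res.pvalue,
                "freq_low": freq.loc[True].to_dict() if True in freq.index else {},
                "freq_high": freq.loc[False].to_dict() if False in freq.index else {},
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def compare_scores_by_subtype(cases: pd.DataFrame) -> dict:
    """Rank-sum contrast of case H-scores between basal-like and classical."""
    sub = cases.dropna(subset=["subtype"])
    basal = sub.loc[sub["subtype"] == "basal-like", "h_score"].to_numpy()
    classical = sub.loc[sub["subtype"] == "classical", "h_score"].to_numpy()
    if basal.size == 0 or classical.size == 0:
        raise ValueError("both subtypes must be present")
    res = wilcoxon_rank_sum(basal, classical)
    def _summ(v):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {"median": float(med), "iqr": (float(q1), float(q3)), "n": int(v.size)}
    return {
        "statistic": res.statistic,
        "p": res.pvalue,
        "basal-like": _summ(basal),
        "classical": _summ(classical),
    }
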