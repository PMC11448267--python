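"""Extracellular-flux stress-test analysis.

Segments plate kinetic series (ECAR for the glycolysis stress test, OCR for
the mito stress test) into injection phases, normalizes rates to well
confluency, and derives the standard bioenergetic parameters per well:

glycolysis test (ECAR, mpH/min):
    NGA (non-glycolytic acidification), baseline glycolysis, glycolytic
    capacity, glycolytic reserve = capacity - baseline.
mito test (OCR, pmol O2/min):
    NMR (non-mitochondrial respiration), basal respiration, ATP-linked
    respiration, proton leak, maximal respiration, spare capacity =
    maximal - basal.

Phase aggregators are configurable; the defaults follow the conventional
stress-test report (max over stimulated phases, last pre-injection
measurement for basal, min over inhibited phases, pooled mean for the
background phases) and are recorded in the output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stats import TestResult, bh_adjust, t_test

logger = logging.getLogger(__name__)

GLYC = "glyc"
MITO = "mito"
GLYC_LABELS = ("glucose", "oligomycin", "2-DG")
MITO_LABELS = ("oligomycin", "FCCP", "rot/AA")
PRE_PHASE = "pre"

GLYC_METRICS = ("nga", "baseline_glycolysis", "glycolytic_capacity", "glycolytic_reserve")
MITO_METRICS = (
    "nmr",
    "basal_respiration",
    "atp_linked",
    "proton_leak",
    "maximal_respiration",
    "spare_capacity",
)

_AGGREGATORS = {
    "max": lambda w: w.max(axis=1),
    "min": lambda w: w.min(axis=1),
    "mean": lambda w: w.mean(axis=1),
    "last": lambda w: w[:, -1],
}


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered injection events: (label, first measurement cycle after injection)."""

    assay_kind: str
    events: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.assay_kind not in (GLYC, MITO):
            raise ValueError(f"unknown assay_kind {self.assay_kind!r}")
        expected = GLYC_LABELS if self.assay_kind == GLYC else MITO_LABELS
        labels = tuple(label for label, _ in self.events)
        if labels != expected:
            raise ValueError(
                f"{self.assay_kind} schedule must inject {expected} in order, got {labels}"
            )
        idx = [i for _, i in self.events]
        if idx[0] <= 0:
            raise ValueError("first injection must leave a pre-injection phase")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("injection cycle indices must be strictly increasing")

    @classmethod
    def default(cls, assay_kind: str, cycles_per_phase: int = 3) -> "InjectionSchedule":
        labels = GLYC_LABELS if assay_kind == GLYC else MITO_LABELS
        events = tuple(
            (label, cycles_per_phase * (k + 1)) for k, label in enumerate(labels)
        )
        return cls(assay_kind, events)


@dataclass
class PlateKineticSeries:
    """Per-well rate trajectories with injection schedule and confluency.

    ``rates`` is wells x cycles, ECAR in mpH/min or OCR in pmol O2/min;
    ``wells`` carries well_id / group / treatment metadata aligned row-wise.
    """

    assay_kind: str
    wells: pd.DataFrame
    rates: np.ndarray
    confluency: np.ndarray
    schedule: InjectionSchedule
    normalized: bool = False

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.confluency = np.asarray(self.confluency, dtype=float)
        if self.rates.ndim != 2 or self.rates.shape[0] != len(self.wells):
            raise ValueError("rates must be wells x cycles aligned with well table")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("non-finite rates")
        if self.confluency.shape != (self.rates.shape[0],):
            raise ValueError("one confluency value per well required")
        with np.errstate(invalid="ignore"):
            if np.any(self.confluency > 1.0):
                raise ValueError("confluency is a fraction in (0, 1]")
        last = self.schedule.events[-1][1]
        if self.rates.shape[1] <= last:
            raise ValueError("schedule index beyond last measurement cycle")
        if self.schedule.assay_kind != self.assay_kind:
            raise ValueError("schedule assay_kind mismatch")

    @property
    def n_cycles(self) -> int:
        return self.rates.shape[1]


def normalize_to_confluency(series: PlateKineticSeries) -> PlateKineticSeries:
    """Divide each well's rates by its confluency fraction.

    Wells with missing or non-positive confluency are excluded with a logged
    reason; an all-excluded plate halts the pipeline.
    """
    conf = series.confluency
    keep = np.isfinite(conf) & (conf > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = series.wells.loc[~keep, "well_id"].tolist()
        logger.warning(
            "excluding %d well(s) with missing/non-positive confluency: %s",
            n_dropped,
            dropped,
        )
    if not keep.any():
        raise ValueError("all wells excluded: no usable confluency values")
    return PlateKineticSeries(
        assay_kind=series.assay_kind,
        wells=series.wells.loc[keep].reset_index(drop=True),
        rates=series.rates[keep] / conf[keep, None],
        confluency=np.ones(int(keep.sum())),
        schedule=series.schedule,
        normalized=True,
    )


def segment_phases(series: PlateKineticSeries) -> dict[str, tuple[int, int]]:
    """Half-open cycle windows for the pre-injection phase and each injection.

    The four windows are contiguous, non-overlapping and cover every cycle.
    """
    bounds = [0] + [i for _, i in series.schedule.events] + [series.n_cycles]
    labels = [PRE_PHASE] + [label for label, _ in series.schedule.events]
    return {lab: (a, b) for lab, a, b in zip(labels, bounds, bounds[1:])}


def _window(series: PlateKineticSeries, phases, label) -> np.ndarray:
    a, b = phases[label]
    if b <= a:
        raise ValueError(f"empty phase window {label!r}")
    return series.rates[:, a:b]


def _require_normalized(series: PlateKineticSeries) -> None:
    if not series.normalized:
        raise ValueError("series must be confluency-normalized first")


def _flag_negative(df: pd.DataFrame, metrics) -> pd.Series:
    neg = df[list(metrics)] < 0
    return neg.apply(lambda row: ",".join(row.index[row]), axis=1)


def extract_glycolysis_profile(
    series: PlateKineticSeries,
    response_aggregate: str = "max",
    nga_mode: str = "both",
) -> pd.DataFrame:
    """Per-well glycolysis stress-test metrics from a normalized ECAR plate.

    NGA is the pooled mean of the pre-glucose and/or post-2-DG windows
    (``nga_mode``: "pre" | "post" | "both"); baseline glycolysis and
    glycolytic capacity subtract NGA from the aggregated glucose and
    oligomycin windows. Negative values are reported as-is and flagged.
    """
    if series.assay_kind != GLYC:
        raise ValueError("glycolysis profile requires a glyc assay")
    _require_normalized(series)
    if response_aggregate not in _AGGREGATORS:
        raise ValueError(f"unknown aggregator {response_aggregate!r}")
    phases = segment_phases(series)
    agg = _AGGREGATORS[response_aggregate]

    nga_parts = {
        "pre": [_window(series, phases, PRE_PHASE)],
        "post": [_window(series, phases, "2-DG")],
        "both": [_window(series, phases, PRE_PHASE), _window(series, phases, "2-DG")],
    }
    if nga_mode not in nga_parts:
        raise ValueError(f"unknown nga_mode {nga_mode!r}")
    nga = np.hstack(nga_parts[nga_mode]).mean(axis=1)

    baseline = agg(_window(series, phases, "glucose")) - nga
    capacity = agg(_window(series, phases, "oligomycin")) - nga
    out = series.wells.copy()
    out["nga"] = nga
    out["baseline_glycolysis"] = baseline
    out["glycolytic_capacity"] = capacity
    out["glycolytic_reserve"] = capacity - baseline
    out["qc_negative"] = _flag_negative(out, GLYC_METRICS)
    out.attrs["aggregate"] = response_aggregate
    out.attrs["nga_mode"] = nga_mode
    return out


def extract_mito_profile(
    series: PlateKineticSeries,
    basal_aggregate: str = "last",
    inhibited_aggregate: str = "min",
    response_aggregate: str = "max",
) -> pd.DataFrame:
    """Per-well mito stress-test metrics from a normalized OCR plate.

    NMR = aggregated rot/AA window; basal respiration = pre-oligomycin
    aggregate - NMR; ATP-linked = pre-oligomycin aggregate - oligomycin
    aggregate; proton leak = oligomycin aggregate - NMR; maximal = FCCP
    aggregate - NMR; spare capacity = maximal - basal.
    """
    if series.assay_kind != MITO:
        raise ValueError("mito profile requires a mito assay")
    _require_normalized(series)
    for name in (basal_aggregate, inhibited_aggregate, response_aggregate):
        if name not in _AGGREGATORS:
            raise ValueError(f"unknown aggregator {name!r}")
    phases = segment_phases(series)
    pre = _AGGREGATORS[basal_aggregate](_window(series, phases, PRE_PHASE))
    oligo = _AGGREGATORS[inhibited_aggregate](_window(series, phases, "oligomycin"))
    fccp = _AGGREGATORS[response_aggregate](_window(series, phases, "FCCP"))
    nmr = _AGGREGATORS[inhibited_aggregate](_window(series, phases, "rot/AA"))

    out = series.wells.copy()
    out["nmr"] = nmr
    out["basal_respiration"] = pre - nmr
    out["atp_linked"] = pre - oligo
    out["proton_leak"] = oligo - nmr
    out["maximal_respiration"] = fccp - nmr
    out["spare_capacity"] = out["maximal_respiration"] - out["basal_respiration"]
    out["qc_negative"] = _flag_negative(out, MITO_METRICS)
    out.attrs["aggregates"] = {
        "basal": basal_aggregate,
        "inhibited": inhibited_aggregate,
        "response": response_aggregate,
    }
    return out


def ocr_ecar_ratio(
    mito_profiles: pd.DataFrame,
    glyc_profiles: pd.DataFrame,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group baseline OCR:ECAR ratio summaries (mean +/- SEM).

    Wells are not shared across assay plates, so pairing is at group level:
    each mito well's basal respiration is divided by its group's mean
    baseline glycolysis. Groups with a non-positive ECAR denominator are
    flagged undefined and excluded.
    """
    rows = []
    shared = sorted(
        set(mito_profiles[group_col]).intersection(glyc_profiles[group_col])
    )
    if not shared:
        raise ValueError("no groups shared between mito and glyc profiles")
    for group in shared:
        ocr = mito_profiles.loc[mito_profiles[group_col] == group, "basal_respiration"]
        denom = glyc_profiles.loc[
            glyc_profiles[group_col] == group, "baseline_glycolysis"
        ].mean()
        if not np.isfinite(denom) or denom <= 0:
            logger.warning("group %s: non-positive ECAR denominator, ratio undefined", group)
            rows.append(
                {group_col: group, "n": 0, "ratio_mean": np.nan, "ratio_sem": np.nan,
                 "ecar_denominator": denom, "undefined": True}
            )
            continue
        ratios = ocr.to_numpy() / denom
        rows.append(
            {
                group_col: group,
                "n": ratios.size,
                "ratio_mean": ratios.mean(),
                "ratio_sem": ratios.std(ddof=1) / np.sqrt(ratios.size)
                if ratios.size > 1
                else np.nan,
                "ecar_denominator": denom,
                "undefined": False,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    profiles: pd.DataFrame,
    metrics,
    group_col: str = "group",
    contrasts: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Group contrasts per metric: means, SEM, Welch t, raw and BH-adjusted p.

    BH adjustment spans the whole metric family of the call (one assay's
    metrics across the requested contrasts). Groups with fewer than 2 wells
    are skipped with a warning.
    """
    groups = {g: sub for g, sub in profiles.groupby(group_col)}
    if contrasts is None:
        labels = sorted(groups)
        contrasts = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    rows = []
    for metric in metrics:
        for a, b in contrasts:
            xa = groups.get(a, pd.DataFrame()).get(metric, pd.Series(dtype=float))
            xb = groups.get(b, pd.DataFrame()).get(metric, pd.Series(dtype=float))
            if len(xa) < 2 or len(xb) < 2:
                logger.warning("contrast %s vs %s on %s skipped: <2 wells", a, b, metric)
                continue
            res: TestResult = t_test(xa, xb)
            rows.append(
                {
                    "metric": metric,
                    "group_a": a,
                    "group_b": b,
                    "mean_a": xa.mean(),
                    "sem_a": xa.std(ddof=1) / np.sqrt(len(xa)),
                    "mean_b": xb.mean(),
                    "sem_b": xb.std(ddof=1) / np.sqrt(len(xb)),
                    "t": res.statistic,
                    "p": res.pvalue,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table
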