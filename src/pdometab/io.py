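"""Plain-text readers/writers for the pipeline's tabular interchange formats.

Plate TSV: well_id, group, treatment, confluency, cycle_1..cycle_N columns,
with the injection schedule in a YAML sidecar. Tracing TSV: metabolite,
condition, replicate, M0..Mn. Expression TSV: genes x samples counts plus a
two-column gene-length TSV. Cohort CSV: one row per core with case-level
survival and covariates repeated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .seahorse import InjectionSchedule, PlateKineticSeries


def write_plate_tsv(series: PlateKineticSeries, plate_path, schedule_path) -> None:
    df = series.wells.copy()
    df["confluency"] = series.confluency
    for i in range(series.n_cycles):
        df[f"cycle_{i + 1}"] = series.rates[:, i]
    df.to_csv(plate_path, sep="\t", index=False)
    with open(schedule_path, "w") as fh:
        yaml.safe_dump(
            {
                "assay_kind": series.assay_kind,
                "injections": [
                    {"label": label, "cycle": int(idx)}
                    for label, idx in series.schedule.events
                ],
            },
            fh,
        )


def read_plate_tsv(plate_path, schedule_path) -> PlateKineticSeries:
    df = pd.read_csv(plate_path, sep="\t")
    with open(schedule_path) as fh:
        sched = yaml.safe_load(fh)
    schedule = InjectionSchedule(
        assay_kind=sched["assay_kind"],
        events=tuple((e["label"], int(e["cycle"])) for e in sched["injections"]),
    )
    cycle_cols = sorted(
        (c for c in df.columns if c.startswith("cycle_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return PlateKineticSeries(
        assay_kind=sched["assay_kind"],
        wells=df[["well_id", "group", "treatment"]].copy(),
        rates=df[cycle_cols].to_numpy(dtype=float),
        confluency=df["confluency"].to_numpy(dtype=float),
        schedule=schedule,
    )


def write_tracing_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tracing_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_tsv(matrix, counts_path, lengths_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene")
    matrix.lengths.to_frame().to_csv(lengths_path, sep="\t", index_label="gene")


def read_expression_tsv(counts_path, lengths_path):
    from .subtype import ExpressionMatrix

    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene").iloc[:, 0]
    return ExpressionMatrix(counts=counts, lengths=lengths)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subtype" in df.columns:
        df["subtype"] = df["subtype"].replace({np.nan: None})
    return df
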