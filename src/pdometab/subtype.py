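"""Transcriptomic subtype calling: RPKM normalization and a rank-pair classifier.

Implements the single-sample top-scoring-pair scheme used to assign PDAC
basal-like vs classical subtypes: k ordered gene pairs (gene_a, gene_b),
each contributing a binary indicator I[expr(a) > expr(b)], combined through
a logistic model into a basal-like probability; samples score > 0.5 are
called basal-like, otherwise classical. Because the indicators depend only
on within-sample ranks, calls are invariant to any strictly monotone
per-sample transform of expression, so raw counts, RPKM and log-RPKM give
identical labels when library depth is shared within a sample.

The published 8-pair coefficients are a loadable config artifact; the engine
here is agnostic to the specific genes and weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .stats import bh_adjust, spearman

logger = logging.getLogger(__name__)

BASAL = "basal-like"
CLASSICAL = "classical"


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with per-gene lengths (bp).

    ``log_rpkm`` is a derived layer populated by :func:`rpkm_log10`.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    log_rpkm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs a length")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts < 0).to_numpy().any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass(frozen=True)
class ClassifierModel:
    """Ordered gene pairs with logistic weights and intercept."""

    pairs: tuple[tuple[str, str], ...]
    weights: tuple[float, ...]
    intercept: float

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("need at least one gene pair")
        if len(self.weights) != len(self.pairs):
            raise ValueError("one weight per pair required")
        if any(a == b for a, b in self.pairs):
            raise ValueError("genes within a pair must be distinct")
        if not np.all(np.isfinite(list(self.weights) + [self.intercept])):
            raise ValueError("weights and intercept must be finite")

    @property
    def k(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        return cls(
            pairs=tuple((p["gene_a"], p["gene_b"]) for p in d["pairs"]),
            weights=tuple(float(p["weight"]) for p in d["pairs"]),
            intercept=float(d["intercept"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "pairs": [
                {"gene_a": a, "gene_b": b, "weight": w}
                for (a, b), w in zip(self.pairs, self.weights)
            ],
        }


@dataclass
class SubtypeCall:
    """Basal-like probability score, dichotomous label and pair indicators."""

    sample_id: str
    score: float
    label: str
    indicators: np.ndarray
    tie: bool = False


def rpkm_log10(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Attach the log10(RPKM + pseudocount) layer.

    RPKM = count * 1e9 / (library_total * length_bp). The pseudocount
    (default 1) keeps zero counts at a log value of exactly 0.
    """
    lib = matrix.counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library total")
    rpkm = matrix.counts * 1e9
    rpkm = rpkm.div(lib, axis=1).div(matrix.lengths, axis=0)
    return ExpressionMatrix(
        counts=matrix.counts,
        lengths=matrix.lengths,
        log_rpkm=np.log10(rpkm + pseudocount),
    )


def pair_indicators(expression: pd.Series, model: ClassifierModel) -> np.ndarray:
    """Binary vector: 1 where expr(gene_a) > expr(gene_b), ties count as 0."""
    missing = [g for pair in model.pairs for g in pair if g not in expression.index]
    if missing:
        raise KeyError(f"genes missing from expression matrix: {sorted(set(missing))}")
    return np.array(
        [int(expression[a] > expression[b]) for a, b in model.pairs], dtype=int
    )


def classify(
    expression: pd.Series, model: ClassifierModel, sample_id: str = ""
) -> SubtypeCall:
    """Single-sample subtype call: logistic(intercept + sum w_j * I_j).

    Label is basal-like iff score > 0.5; a score of exactly 0.5 is called
    classical with a tie flag (the label rule defines only strict > and <).
    """
    ind = pair_indicators(expression, model)
    eta = model.intercept + float(np.dot(model.weights, ind))
    score = 1.0 / (1.0 + np.exp(-eta))
    tie = score == 0.5
    label = BASAL if score > 0.5 else CLASSICAL
    return SubtypeCall(sample_id=sample_id, score=score, label=label,
                       indicators=ind, tie=bool(tie))


def classify_samples(
    matrix: ExpressionMatrix, model: ClassifierModel, layer: str = "counts"
) -> pd.DataFrame:
    """Classify every sample of a matrix; layer = "counts" | "log_rpkm"."""
    data = matrix.counts if layer == "counts" else matrix.log_rpkm
    if data is None:
        raise ValueError(f"layer {layer!r} not populated")
    rows = []
    for sample in data.columns:
        call = classify(data[sample], model, sample_id=sample)
        rows.append(
            {"sample_id": sample, "score": call.score, "label": call.label,
             "tie": call.tie}
        )
    return pd.DataFrame(rows)


def propagate_subtype(
    biopsy_calls: pd.DataFrame, pdo_manifest: pd.DataFrame
) -> pd.DataFrame:
    """Assign each PDO the subtype of the biopsy it was derived from.

    ``biopsy_calls`` needs columns sample_id/label; ``pdo_manifest`` needs
    pdo_id/biopsy_id with at most one biopsy per PDO. PDOs without a
    classified biopsy are flagged (label NaN) and should be excluded from
    contrasts.
    """
    if pdo_manifest["pdo_id"].duplicated().any():
        raise ValueError("each PDO must map to exactly one biopsy")
    merged = pdo_manifest.merge(
        biopsy_calls[["sample_id", "label"]],
        left_on="biopsy_id",
        right_on="sample_id",
        how="left",
    ).drop(columns="sample_id")
    merged["flagged"] = merged["label"].isna()
    if merged["flagged"].any():
        logger.warning(
            "%d PDO(s) without a classified biopsy flagged", int(merged["flagged"].sum())
        )
    return merged


def glycolytic_gene_correlation(
    tumor_matrix: ExpressionMatrix,
    pdo_matrix: ExpressionMatrix,
    gene_set,
    sample_pairs: list[tuple[str, str]],
    layer: str = "log_rpkm",
) -> pd.DataFrame:
    """Spearman correlation of a gene set between matched tumor/PDO samples.

    For each (tumor sample, PDO sample) pair, rho over the shared gene-set
    log-RPKM values; BH adjustment across pairings.
    """
    t_data = tumor_matrix.log_rpkm if layer == "log_rpkm" else tumor_matrix.counts
    p_data = pdo_matrix.log_rpkm if layer == "log_rpkm" else pdo_matrix.counts
    if t_data is None or p_data is None:
        raise ValueError(f"layer {layer!r} not populated on both matrices")
    shared = [g for g in gene_set if g in t_data.index and g in p_data.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes between matrices")
    rows = []
    for tumor_s, pdo_s in sample_pairs:
        res = spearman(t_data.loc[shared, tumor_s], p_data.loc[shared, pdo_s])
        rows.append(
            {"tumor_sample": tumor_s, "pdo_sample": pdo_s,
             "rho": res.statistic, "p": res.pvalue, "n_genes": len(shared)}
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table
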