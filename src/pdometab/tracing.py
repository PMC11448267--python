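"""Stable-isotope (13C-glucose) tracing: mass-isotopomer distributions.

Raw GC-MS isotopologue intensities of a derivatized metabolite fragment mix
the tracer signal with mass shifts from naturally occurring heavy isotopes
(13C in non-tracer positions, 2H, 15N, 17O/18O, 29Si/30Si from the tBDMS
derivatization group, 33S/34S). This module builds the natural-abundance
correction matrix for a fragment's elemental formula, deconvolves raw
intensity vectors into corrected mass-isotopomer distributions (MIDs) by
non-negative least squares, and compares labelled fractions (e.g. M+2, M+3)
across conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import binom

from .stats import bh_adjust, t_test

logger = logging.getLogger(__name__)

#: Standard terrestrial heavy-isotope abundances as mass-shift pmfs per atom.
#: Key: element symbol -> {mass shift: probability}; shift 0 holds the
#: remaining (light isotope) probability.
DEFAULT_ABUNDANCES: dict[str, dict[int, float]] = {
    "C": {1: 0.0107},
    "H": {1: 0.000115},
    "N": {1: 0.00364},
    "O": {1: 0.00038, 2: 0.00205},
    "Si": {1: 0.04685, 2: 0.03092},
    "S": {1: 0.0075, 2: 0.0425},
}


@dataclass(frozen=True)
class FragmentFormula:
    """Element counts of a derivatized fragment plus its labelable carbons.

    ``n_labelable`` is the number of backbone carbons that can carry tracer
    label (<= total carbon count; the derivatization group contributes
    carbons that can only be naturally enriched).
    """

    C: int
    H: int = 0
    N: int = 0
    O: int = 0
    Si: int = 0
    S: int = 0
    n_labelable: int = 1

    def __post_init__(self) -> None:
        counts = self.element_counts()
        if any(v < 0 for v in counts.values()):
            raise ValueError("element counts must be non-negative")
        if not (1 <= self.n_labelable <= self.C):
            raise ValueError("n_labelable must be in [1, C]")

    def element_counts(self) -> dict[str, int]:
        return {"C": self.C, "H": self.H, "N": self.N, "O": self.O,
                "Si": self.Si, "S": self.S}


@dataclass
class RawMassDistribution:
    """Raw M+0..M+n intensity vector for one metabolite/condition/replicate."""

    metabolite: str
    condition: str
    replicate: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class MassIsotopomerDistribution:
    """Fractional M+0..M+n abundances; sums to 1 after correction."""

    metabolite: str
    condition: str
    fractions: np.ndarray
    replicate: int = 0
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)


def _atom_pmf(element: str, abundances: dict[str, dict[int, float]]) -> np.ndarray:
    if element not in abundances:
        raise ValueError(f"element {element!r} missing from abundance table")
    shifts = abundances[element]
    if any(not (0.0 <= v <= 1.0) for v in shifts.values()):
        raise ValueError("abundances must lie in [0, 1]")
    heavy = sum(shifts.values())
    if heavy > 1.0:
        raise ValueError(f"heavy-isotope abundances of {element} exceed 1")
    pmf = np.zeros(max(shifts, default=0) + 1)
    pmf[0] = 1.0 - heavy
    for shift, prob in shifts.items():
        pmf[shift] = prob
    return pmf


def _element_pmf(element: str, count: int, abundances) -> np.ndarray:
    """Mass-shift pmf of ``count`` identical atoms (iterated convolution)."""
    pmf = np.array([1.0])
    if count == 0:
        return pmf
    atom = _atom_pmf(element, abundances)
    for _ in range(count):
        pmf = np.convolve(pmf, atom)
    return pmf


def natural_abundance_matrix(
    formula: FragmentFormula,
    abundances: dict[str, dict[int, float]] | None = None,
    tracer_purity: float = 1.0,
) -> np.ndarray:
    """(n+1) x (n+1) correction matrix for a fragment, n = labelable carbons.

    Column j is the mass-shift distribution (truncated to n+1 rows) of a
    fragment whose j labelable carbons carry tracer while every other atom
    follows natural isotope abundance; ``tracer_purity`` < 1 lets labelled
    positions revert to 12C with probability 1 - purity (off by default).
    """
    if abundances is None:
        abundances = DEFAULT_ABUNDANCES
    if not (0.0 < tracer_purity <= 1.0):
        raise ValueError("tracer_purity must be in (0, 1]")
    n = formula.n_labelable
    counts = formula.element_counts()
    matrix = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        pmf = _element_pmf("C", counts["C"] - j, abundances)
        for element in ("H", "N", "O", "Si", "S"):
            pmf = np.convolve(pmf, _element_pmf(element, counts[element], abundances))
        # labelled positions shift mass by Binomial(j, purity)
        label_pmf = binom.pmf(np.arange(j + 1), j, tracer_purity)
        pmf = np.convolve(label_pmf, pmf)
        matrix[:, j] = pmf[: n + 1]
    return matrix


def correct_distribution(
    raw: RawMassDistribution | np.ndarray,
    matrix: np.ndarray,
    method: str = "nnls",
) -> MassIsotopomerDistribution:
    """Deconvolve a raw intensity vector into a corrected MID.

    Solves matrix @ x ~= raw under x >= 0 (non-negative least squares,
    default) or by direct inversion (``method="inverse"``; may produce
    negative fractions and exists for oracle cross-checks), then
    renormalizes to sum 1. The residual norm is recorded as QC.
    """
    if isinstance(raw, RawMassDistribution):
        vec = raw.intensities
        meta = (raw.metabolite, raw.condition, raw.replicate)
    else:
        vec = np.asarray(raw, dtype=float)
        meta = ("", "", 0)
    if vec.shape[0] != matrix.shape[0]:
        raise ValueError("matrix dimension does not match raw vector length")
    if not np.any(vec > 0):
        raise ValueError("all-zero raw vector: no pool detected")
    if method == "nnls":
        x, rnorm = nnls(matrix, vec)
    elif method == "inverse":
        x = np.linalg.solve(matrix, vec)
        rnorm = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    total = x.sum()
    if total <= 0:
        raise ValueError("correction produced an empty distribution")
    return MassIsotopomerDistribution(
        metabolite=meta[0], condition=meta[1], replicate=meta[2],
        fractions=x / total, residual=float(rnorm),
    )


def labelled_fraction(mid: MassIsotopomerDistribution, k: int) -> float:
    """Fraction of the M+k isotopologue."""
    if not 0 <= k < mid.fractions.size:
        raise ValueError(f"k={k} outside 0..{mid.fractions.size - 1}")
    return float(mid.fractions[k])


def summarize_fractions(mids, k: int) -> tuple[float, float]:
    """Mean +/- SEM of the M+k fraction over a replicate set."""
    vals = np.array([labelled_fraction(m, k) for m in mids])
    sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
    return float(vals.mean()), float(sem)


def correct_table(
    raw_df: pd.DataFrame,
    formulas: dict[str, FragmentFormula],
    abundances: dict[str, dict[int, float]] | None = None,
    method: str = "nnls",
) -> pd.DataFrame:
    """Correct a long-format raw intensity table into per-isotopologue fractions.

    Expects columns metabolite, condition, replicate and M0..Mn intensity
    columns (trailing NaN columns allowed for shorter fragments). Emits both
    corrected and uncorrected (raw-normalized) fractions per row.
    """
    rows = []
    for _, row in raw_df.iterrows():
        met = row["metabolite"]
        if met not in formulas:
            raise ValueError(f"metabolite {met!r} lacks a fragment formula")
        frag = formulas[met]
        n = frag.n_labelable
        vec = np.array([row[f"M{i}"] for i in range(n + 1)], dtype=float)
        matrix = natural_abundance_matrix(frag, abundances)
        mid = correct_distribution(
            RawMassDistribution(met, row["condition"], int(row["replicate"]), vec),
            matrix,
            method=method,
        )
        uncorrected = vec / vec.sum()
        for k in range(n + 1):
            rows.append(
                {
                    "metabolite": met,
                    "condition": row["condition"],
                    "replicate": int(row["replicate"]),
                    "k": k,
                    "fraction": mid.fractions[k],
                    "fraction_uncorrected": uncorrected[k],
                    "residual": mid.residual,
                }
            )
    return pd.DataFrame(rows)


def compare_conditions(
    fractions: pd.DataFrame,
    contrast: tuple[str, str],
    k_by_metabolite: dict[str, int] | None = None,
    value_col: str = "fraction",
) -> pd.DataFrame:
    """Per-metabolite labelled-fraction contrast between two condition arms.

    Two-sided two-sample t-test per metabolite (at the isotopologue of
    interest); delta = mean(arm_a) - mean(arm_b); BH adjustment across
    metabolites within the contrast.
    """
    arm_a, arm_b = contrast
    rows = []
    for (met, k), sub in fractions.groupby(["metabolite", "k"]):
        if k_by_metabolite is not None and k_by_metabolite.get(met) != k:
            continue
        xa = sub.loc[sub["condition"] == arm_a, value_col].to_numpy()
        xb = sub.loc[sub["condition"] == arm_b, value_col].to_numpy()
        if xa.size < 2 or xb.size < 2:
            if xa.size == 0 or xb.size == 0:
                logger.warning("contrast %s: missing arm for %s M+%d, skipped",
                               contrast, met, k)
                continue
            raise ValueError("need >=2 replicates per arm")
        res = t_test(xa, xb)
        rows.append(
            {
                "metabolite": met,
                "k": k,
                "delta": xa.mean() - xb.mean(),
                "t": res.statistic,
                "p": res.pvalue,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table
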