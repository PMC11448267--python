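"""Synthetic dataset generation for every pipeline stage.

Each generator draws from an explicit :class:`SyntheticScenario` parameter
bundle and a seeded random stream, producing data with the statistical
structure the corresponding analysis stage assumes, together with the
planted ground truth used by parameter-recovery tests:

* flux plates — phase-plateau rates = group truth x confluency + Gaussian noise;
* tracing tables — true MIDs convolved with the fragment's natural-abundance
  distribution, scaled and multiplied by log-normal noise;
* expression matrices — negative-binomial counts with planted rank-pair
  structure separating the two subtypes;
* TMA cohorts — quantized duplicate-core H-scores with exponential survival
  whose hazard switches at a planted cut-point, exponential censoring, and
  group-dependent clinicopathologic covariates.

The global seed is split into fixed per-generator substreams, so adding a
generator never perturbs another generator's output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .seahorse import GLYC, MITO, InjectionSchedule, PlateKineticSeries
from .subtype import ClassifierModel, ExpressionMatrix
from .tracing import FragmentFormula, natural_abundance_matrix

_STREAMS = {"seahorse_glyc": 0, "seahorse_mito": 1, "tracing": 2,
            "expression": 3, "tma": 4}


@dataclass
class SyntheticScenario:
    """Parameter bundle (group effects, noise, seed) for all four generators."""

    seed: int
    seahorse: dict
    tracing: dict
    expression: dict
    tma: dict
    _extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        sh = self.seahorse
        if sh["n_wells_per_group"] <= 0 or sh["cycles_per_phase"] <= 0:
            raise ValueError("well and cycle counts must be positive")
        if sh["noise_sd"] < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = sh["confluency_range"]
        if not (0 < lo <= hi <= 1):
            raise ValueError("confluency range must lie within (0, 1]")
        for met, conds in self.tracing["mid_truth"].items():
            for cond, frac in conds.items():
                f = np.asarray(frac, dtype=float)
                if np.any((f < 0) | (f > 1)) or abs(f.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"mid_truth[{met}][{cond}] must be fractions summing to 1"
                    )
        tma = self.tma
        if tma["base_hazard"] <= 0 or tma["hazard_ratio"] <= 0:
            raise ValueError("hazard parameters must be strictly positive")
        if tma["censor_rate"] < 0:
            raise ValueError("censor_rate must be non-negative")
        if tma["n_cases"] <= 0 or self.expression["n_pairs"] <= 0:
            raise ValueError("all counts must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Per-generator substream of the scenario seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)

    @classmethod
    def from_dict(cls, d: dict, seed: int | None = None) -> "SyntheticScenario":
        d = dict(d)
        if seed is not None:
            d["seed"] = seed
        known = {k: d[k] for k in ("seed", "seahorse", "tracing", "expression", "tma")}
        extra = {k: v for k, v in d.items() if k not in known}
        return cls(**known, _extra=extra)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "SyntheticScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), seed=seed)


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """The shipped default scenario with the planted study-effect directions."""
    text = resources.files("pdometab.data").joinpath("default_scenario.yaml").read_text()
    return SyntheticScenario.from_dict(yaml.safe_load(text), seed=seed)


# ---------------------------------------------------------------------------
# flux plates

def _phase_truth(assay_kind: str, params: dict) -> list[float]:
    """Plateau rate per phase (pre + 3 injections) implied by the group truth."""
    if assay_kind == GLYC:
        return [
            params["nga"],
            params["nga"] + params["baseline_glycolysis"],
            params["nga"] + params["glycolytic_capacity"],
            params["nga"],
        ]
    return [
        params["nmr"] + params["basal_respiration"],
        params["nmr"] + params["basal_respiration"] - params["atp_linked"],
        params["nmr"] + params["maximal_respiration"],
        params["nmr"],
    ]


def gen_seahorse_plate(scenario: SyntheticScenario, assay_kind: str) -> PlateKineticSeries:
    """Simulate one stress-test plate across all groups and treatment arms."""
    if assay_kind not in (GLYC, MITO):
        raise ValueError(f"unknown assay_kind {assay_kind!r}")
    sh = scenario.seahorse
    rng = scenario.rng("seahorse_glyc" if assay_kind == GLYC else "seahorse_mito")
    cpp = sh["cycles_per_phase"]
    schedule = InjectionSchedule.default(assay_kind, cycles_per_phase=cpp)
    lo, hi = sh["confluency_range"]

    meta_rows, rate_rows, conf = [], [], []
    widx = 0
    for group, arms in sh["groups"].items():
        for treatment, params in arms.items():
            plateau = np.repeat(_phase_truth(assay_kind, params), cpp)
            for _ in range(sh["n_wells_per_group"]):
                c = rng.uniform(lo, hi)
                noise = rng.normal(0.0, sh["noise_sd"], size=plateau.size) \
                    if sh["noise_sd"] > 0 else 0.0
                rate_rows.append(plateau * c + noise)
                conf.append(c)
                meta_rows.append(
                    {"well_id": f"W{widx:03d}", "group": group, "treatment": treatment}
                )
                widx += 1
    return PlateKineticSeries(
        assay_kind=assay_kind,
        wells=pd.DataFrame(meta_rows),
        rates=np.array(rate_rows),
        confluency=np.array(conf),
        schedule=schedule,
    )


# ---------------------------------------------------------------------------
# tracing

def gen_tracing_experiment(scenario: SyntheticScenario) -> pd.DataFrame:
    """Raw isotopologue intensity tables for every metabolite and condition.

    Raw intensities are the true MID convolved with the fragment's
    natural-abundance distribution, scaled to the pool size, with
    multiplicative log-normal noise; replicates share the truth.
    """
    tr = scenario.tracing
    rng = scenario.rng("tracing")
    formulas = load_formulas(tr["fragment_formulas"])
    missing = [m for m in tr["mid_truth"] if m not in formulas]
    if missing:
        raise ValueError(f"metabolite(s) lacking a fragment formula: {missing}")
    sigma = math.sqrt(math.log(1.0 + tr["noise_cv"] ** 2))
    nmax = max(f.n_labelable for f in formulas.values())
    rows = []
    for met, conds in tr["mid_truth"].items():
        frag = formulas[met]
        matrix = natural_abundance_matrix(frag)
        for cond, truth in conds.items():
            expected = matrix @ np.asarray(truth, dtype=float) * tr["pool_scale"]
            for rep in range(1, tr["n_replicates"] + 1):
                noise = (
                    np.exp(rng.normal(0.0, sigma, size=expected.size))
                    if sigma > 0
                    else 1.0
                )
                vec = expected * noise
                row = {"metabolite": met, "condition": cond, "replicate": rep}
                for i in range(nmax + 1):
                    row[f"M{i}"] = vec[i] if i < vec.size else np.nan
                rows.append(row)
    return pd.DataFrame(rows)


def load_formulas(spec: dict) -> dict[str, FragmentFormula]:
    """Build FragmentFormula objects from a config mapping."""
    out = {}
    for met, d in spec.items():
        out[met] = FragmentFormula(
            C=d["C"], H=d.get("H", 0), N=d.get("N", 0), O=d.get("O", 0),
            Si=d.get("Si", 0), S=d.get("S", 0), n_labelable=d["n_labelable"],
        )
    return out


# ---------------------------------------------------------------------------
# expression

def gen_expression(
    scenario: SyntheticScenario,
) -> tuple[ExpressionMatrix, pd.Series, ClassifierModel]:
    """Counts matrix with planted rank-pair subtype structure.

    Returns the matrix, the true per-sample subtype labels, and the
    classifier model matching the planted pairs. A dispersion of exactly 0
    is the noise-free limit: counts equal their means deterministically.
    """
    ex = scenario.expression
    rng = scenario.rng("expression")
    k = ex["n_pairs"]
    margin = math.sqrt(ex["pair_margin"])
    base = ex["base_mean"]

    samples, labels = [], []
    for subtype, n in ex["n_samples"].items():
        for i in range(n):
            samples.append(f"{subtype[:1].upper()}{i:03d}")
            labels.append(subtype)
    labels = pd.Series(labels, index=samples, name="subtype")

    genes = [f"PAIR{j}_{suffix}" for j in range(k) for suffix in ("UP", "DN")]
    genes += [f"BG{i:04d}" for i in range(ex["n_background"])]
    bg_means = rng.lognormal(mean=math.log(base), sigma=1.0, size=ex["n_background"])

    means = np.empty((len(genes), len(samples)))
    is_basal = (labels == "basal-like").to_numpy()
    for j in range(k):
        up = base * np.where(is_basal, margin, 1.0 / margin)
        dn = base * np.where(is_basal, 1.0 / margin, margin)
        means[2 * j] = up
        means[2 * j + 1] = dn
    means[2 * k :] = bg_means[:, None]

    alpha = ex["dispersion"]
    if alpha > 0:
        size = 1.0 / alpha
        counts = rng.negative_binomial(size, size / (size + means))
    else:
        counts = np.round(means)
    lengths = pd.Series(
        rng.integers(ex["length_range"][0], ex["length_range"][1] + 1, size=len(genes)),
        index=genes, name="length_bp",
    )
    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples, dtype=int),
        lengths=lengths,
    )
    model = ClassifierModel(
        pairs=tuple((f"PAIR{j}_UP", f"PAIR{j}_DN") for j in range(k)),
        weights=tuple([ex["model_weight"]] * k),
        intercept=-ex["model_weight"] * k / 2.0,
    )
    return matrix, labels, model


# ---------------------------------------------------------------------------
# TMA cohort

def _quantize_core(score: float, increment: float) -> tuple[float, int]:
    """Decompose a latent core score into (pct_positive, intensity tier).

    Percent positivity is scored on a fixed increment grid the way a
    pathologist reads a slide, so attainable H-scores are discrete.
    """
    if score <= 0:
        return 0.0, 0
    intensity = min(3, max(1, math.ceil(score / 100.0)))
    pct = score / intensity
    pct = float(np.clip(round(pct / increment) * increment, 0.0, 100.0))
    return pct, intensity


def gen_tma_cohort(scenario: SyntheticScenario) -> tuple[pd.DataFrame, dict]:
    """Per-core cohort table plus the planted ground truth.

    Case latent H-scores come from a two-component (low/high expresser)
    normal mixture clipped to [0, 300]; each case has two cores (the second
    attenuated), survival is exponential with the hazard switching at the
    true cut-point applied to the resolved case score, censoring is an
    independent exponential, and covariate frequencies depend on the
    low/high group.
    """
    t = scenario.tma
    rng = scenario.rng("tma")
    n = t["n_cases"]
    mix = t["mixture"]
    cov = t["covariates"]

    is_low_comp = rng.random(n) < mix["w_low"]
    latent = np.where(
        is_low_comp,
        rng.normal(mix["low_mean"], mix["low_sd"], size=n),
        rng.normal(mix["high_mean"], mix["high_sd"], size=n),
    )
    latent = np.clip(latent, 0.0, 300.0)

    att_lo, att_hi = t["second_core_attenuation"]
    rows = []
    case_scores = np.empty(n)
    for i in range(n):
        cores = []
        for cid, target in (("a", latent[i]),
                            ("b", latent[i] * rng.uniform(att_lo, att_hi))):
            pct, intensity = _quantize_core(target, t["pct_increment"])
            cores.append((cid, pct, intensity))
        case_scores[i] = max(p * it for _, p, it in cores)
        rows.append(cores)

    low = case_scores < t["true_cut"]
    hazard = t["base_hazard"] * np.where(low, t["hazard_ratio"], 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if t["censor_rate"] > 0:
        t_cens = rng.exponential(1.0 / t["censor_rate"], size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    grade_p = np.where(low[:, None], cov["grade_probs_low"], cov["grade_probs_high"])
    grade = np.array([rng.choice([1, 2, 3], p=p / p.sum()) for p in grade_p])
    lvi = (rng.random(n) < np.where(low, *cov["lvi"])).astype(int)
    pni = (rng.random(n) < np.where(low, *cov["pni"])).astype(int)
    has_subtype = rng.random(n) < t["subtype_available_frac"]
    basal = rng.random(n) < np.where(low, *cov["basal"])
    subtype = np.where(
        has_subtype, np.where(basal, "basal-like", "classical"), None
    )

    records = []
    for i in range(n):
        for cid, pct, intensity in rows[i]:
            records.append(
                {
                    "case_id": f"C{i:03d}",
                    "core_id": cid,
                    "pct_positive": pct,
                    "intensity": intensity,
                    "time_months": time[i],
                    "dss_event": event[i],
                    "grade": grade[i],
                    "lvi": lvi[i],
                    "pni": pni[i],
                    "subtype": subtype[i],
                }
            )
    truth = {
        "true_cut": t["true_cut"],
        "hazard_ratio": t["hazard_ratio"],
        "n_low": int(low.sum()),
        "n_high": int((~low).sum()),
        "censor_frac": float(1 - event.mean()),
    }
    return pd.DataFrame(records), truth
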