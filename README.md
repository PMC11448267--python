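# pdometab

Analysis pipeline for metabolic subtyping of pancreatic ductal
adenocarcinoma (PDAC) patient-derived organoids (PDOs) and tumor cohorts.
PDAC tumors fall into two prognostic transcriptome subtypes — basal-like
(worse prognosis) and classical — that differ in how they use glucose.
`pdometab` implements the quantitative stages needed to characterize those
differences in organoid and cohort data:

* **`pdometab.seahorse`** — extracellular-flux stress-test analysis:
  segments ECAR/OCR kinetic series at the injection boundaries
  (glucose → oligomycin → 2-DG, or oligomycin → FCCP → rotenone/antimycin-A),
  normalizes to well confluency, and derives per-well bioenergetic
  parameters (non-glycolytic acidification, baseline glycolysis, glycolytic
  capacity/reserve; non-mitochondrial, basal, ATP-linked, proton-leak,
  maximal and spare respiration) plus group contrasts.
* **`pdometab.tracing`** — ¹³C-glucose isotopologue analysis: builds the
  natural-abundance correction matrix from a fragment's elemental formula,
  deconvolves raw GC-MS intensity vectors into corrected mass-isotopomer
  distributions (non-negative least squares), and compares labelled
  M+k fractions across conditions.
* **`pdometab.subtype`** — RPKM/log₁₀ expression normalization and a
  single-sample rank-pair classifier: score =
  logistic(β₀ + Σⱼ wⱼ·I[expr(aⱼ) > expr(bⱼ)]) over k gene pairs, basal-like
  iff score > 0.5, with subtype propagation from biopsies to derived PDOs.
* **`pdometab.tma`** — immunohistochemistry H-scores
  (percent-positive × intensity tier, 0–300; duplicate cores resolved by
  maximum), survival-optimal cut-points by maximally selected log-rank,
  Kaplan–Meier summaries and clinicopathologic association tests.
* **`pdometab.stats`** — the shared test kernel (Welch t, Wilcoxon rank-sum,
  Spearman, Fisher exact, likelihood-ratio G-test, Benjamini–Hochberg).
* **`pdometab.synthetic`** — seeded generators producing datasets with the
  statistical structure each stage assumes and known planted truth, used
  throughout the test suite for parameter-recovery checks.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a glycolysis stress test and a 252-case TMA cohort, then run the
two analyses:

```python
from pdometab.synthetic import default_scenario, gen_seahorse_plate, gen_tma_cohort
import pdometab.seahorse as sh
import pdometab.tma as tm

sc = default_scenario(seed=42)

plate = sh.normalize_to_confluency(gen_seahorse_plate(sc, "glyc"))
prof = sh.extract_glycolysis_profile(plate)
dmso = prof[prof["treatment"] == "DMSO"]
print(sh.compare_groups(dmso, ["baseline_glycolysis", "glycolytic_reserve"]))

cohort, truth = gen_tma_cohort(sc)
cases = tm.cases_from_cohort(cohort)
res = tm.find_cutpoint(cases)
print(res.cut, res.statistic, res.pvalue, res.n_low, res.n_high)
```

Output (seed 42):

```
             metric    group_a   group_b    mean_a    mean_b          t        p_adj
baseline_glycolysis basal-like classical 16.195111 31.369304 -32.936920 3.900387e-17
 glycolytic_reserve basal-like classical 29.719322  9.863502  40.729851 6.328728e-20
cut=52.5  chi2=35.34  p=2.76e-09  n_low=85  n_high=167
```

Reading it: the simulated basal-like organoids run lower baseline
glycolysis (16.2 vs 31.4 mpH/min, confluency-normalized) but hold a larger
glycolytic reserve (29.7 vs 9.9 mpH/min) than classical ones — the planted
directions — with BH-adjusted Welch p-values far below 0.05. On the TMA
cohort, the maximally selected log-rank scan selects a cut at an H-score of
52.5, splitting 85 low vs 167 high expressers (planted change-point: scores
below 55 carry a 2.5-fold hazard); the Kaplan–Meier median disease-specific
survival is 10.9 months below the cut vs 23.5 months above it.

The same stages are scriptable from the shell:

```sh
pdometab simulate --out data/ --seed 42
pdometab seahorse --plate data/plate_glyc.tsv --schedule data/schedule_glyc.yaml --out out/
pdometab tma --cohort data/tma_cohort.csv --out out/
```

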