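# comorbinet

Comorbidity-pattern analysis for periodontitis cohorts.

Periodontitis (PD) patients frequently carry systemic diseases, and the
*pattern* of those diseases — not just their individual prevalences —
matters for treatment planning and referral policy. `comorbinet`
implements the complete analysis pipeline for a patient-level PD cohort
with demographics (age, sex, socioeconomic position, smoking), periodontal
metrics (teeth, pockets ≥ 6 mm, bleeding on probing, PISA) and a 26-item
binary medical-history questionnaire:

1. **Descriptive accounting** — disease-count distribution, comorbidity
   (≥ 1 systemic disease) and multimorbidity (≥ 2) prevalence, stratified
   prevalence tables, and pooled-variance *t* / Pearson χ² group
   comparisons.
2. **Two-step clustering** of patients on the 26 binary disease
   indicators: a leader-pass pre-clustering stage followed by hierarchical
   agglomerative merging under the log-likelihood (entropy) distance

   ξ_v = N_v · Σ_k Ê_vk,  d(a, b) = ξ_⟨a,b⟩ − ξ_a − ξ_b,

   with BIC(J) = 2 Σ_v ξ_v + J·K·ln N recorded for each candidate cluster
   count and k selected by the conventional two-stage ratio criterion.
3. **Covariate-adjusted prevalence comparison** — binomial logistic
   regression of each disease (and each ICD-11-adapted organ-system group)
   on cluster membership, adjusting for age, sex, SEP and smoking, with
   Wald odds ratios, 95 % CIs and separation guards.
4. **Hypergraph co-occurrence network** over multimorbid patients: from
   the diseases × patients incidence matrix M, the adjacency
   A = M Mᵀ − D_n (D_n = diag(M Mᵀ)) counts pairwise co-occurrences, and
   disease centrality is the principal (Perron) eigenvector of A. Unique
   disease combinations are cataloged as hyperedges, with a
   ≥ 8-occurrence filter for visualization exports.
5. **Synthetic cohort generator** — a three-class mixture (disease-free;
   respiratory/allergy; cardiometabolic) with class-conditional Bernoulli
   disease flags and demographic distributions calibrated to the published
   summary tables of a 3171-patient referral-practice cohort, so the whole
   pipeline is testable without access to patient data.

## Worked example

```python
from comorbinet import (default_spec, generate, count_distribution,
                        TwoStepCluster, build_incidence, adjacency, centrality)

cohort, labels = generate(default_spec(n=3171, seed=1))
dist = count_distribution(cohort)
print(f"comorbidity: {100*dist.comorbidity_prevalence:.1f}%   "
      f"multimorbidity: {100*dist.multimorbidity_prevalence:.1f}%")

res = TwoStepCluster(cohort.comorbid(1), seed=1).fit()
print(res.summary())

cent = centrality(adjacency(build_incidence(cohort)))
print("top-3 central diseases:", ", ".join(cent.top(3)))
```

prints

```
comorbidity: 46.0%   multimorbidity: 22.9%
Two-step cluster analysis (log-likelihood distance, binary attributes)
records: 1460   leaves: 361   selected k: 2
cluster sizes: 1: 751 (51.4%), 2: 709 (48.6%)
BIC(J): 1: 15660.6, 2: 13696.3, 3: 12974.9, ...
top discriminating diseases (prevalence by cluster):
  hypertension: 0.457, 0.010
  allergic_rhinitis: 0.111, 0.436
  allergy: 0.196, 0.487
  cardiac_arrhythmia: 0.174, 0.000
  hyperventilation: 0.148, 0.000
top-3 central diseases: allergy, hypertension, allergic_rhinitis
```

Nearly half of the simulated PD patients are comorbid; the clustering
recovers a cardiometabolic cluster (hypertension, cardiac arrhythmia) and
a respiratory/allergy cluster (allergic rhinitis, allergy), and the
co-occurrence network ranks allergy, hypertension and allergic rhinitis as
the most central diseases — the pattern the generator was calibrated to.

## Command line

```bash
comorbinet synth --n 3171 --seed 1 --out cohort.csv --labels labels.csv
comorbinet cluster --cohort cohort.csv --comorbid-only --out clusters.csv
comorbinet hypergraph --cohort cohort.csv --min-diseases 2 --min-count 8 --out-dir results/
comorbinet run --seed 1 --out-dir results/          # full pipeline bundle
comorbinet reproduce --n-seeds 20                   # Monte-Carlo table reproduction
```

`comorbinet run` accepts a YAML config (`--config config.yaml`) with the
fields of `PipelineConfig` (mode, n, seed, min_diseases,
hyperedge_min_count, out_dir, ...) and writes `table1.csv`, `table2.csv`,
`figure2.csv`, `clusters.csv`, `bic.csv`, `adjusted_comparisons.csv`, the
hypergraph exports and a run manifest.

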