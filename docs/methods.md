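# Methods

This note documents the statistical procedures `comorbinet` implements,
the calibration of its synthetic cohort generator, the numerical choices
made where the published procedure leaves them open, and the known
limitations of what the synthetic experiments can demonstrate.

## Cohort model

A cohort is a patient-level table: demographics (age ≥ 18 years; sex;
socioeconomic-position score SEP ∈ [−1, 1], derived from residential-area
statistics and carried as a given covariate; smoking yes/no), periodontal
metrics (number of teeth 0–32; number of pockets ≥ 6 mm; bleeding on
probing, %; periodontal inflammatory surface area PISA, mm²), and 26
binary indicators for systemic diseases from a medical-history
questionnaire. Twenty of the 26 diseases carry an ICD-11-adapted
organ-system group label (cardiovascular ×8; endocrine/nutritional/
metabolic ×3; respiratory tract ×3; digestive ×2; blood ×2; neoplasms ×2);
six (artificial heart valve/pacemaker/hip, hyperventilation, epilepsy,
allergy, chronic kidney disease, contagious disease) are ungrouped.
"Allergy" and "allergic rhinitis" are distinct indicators.

Reading a CSV cohort drops and counts rows that violate the inclusion
rules of an adult cohort with a mandatory questionnaire (age < 18, any
missing disease flag); SEP may be missing and is dropped listwise by the
analyses that use it (missingness in the motivating data is ≈ 0.9 %, so
imputation is not warranted). Comorbidity means ≥ 1 systemic disease;
multimorbidity means ≥ 2.

## Synthetic cohort generator

The generator emulates the structure the downstream analyses assume: a
three-class mixture — disease-free (52.9 %), a respiratory/allergy class
(21.6 % = 47.1 % × 45.8 %), and a cardiometabolic class (25.5 % = 47.1 %
× 54.2 %). Within a class, disease flags are independent Bernoulli draws
with the per-cluster prevalences of the published tables (e.g. allergic
rhinitis 0.475 in the respiratory class, hypertension 0.436 in the
cardiometabolic class); demographics and periodontal metrics are
class-conditional (truncated) normals and Bernoullis with the published
per-cluster means and SDs (PISA is drawn on the mm² scale from the
cm²-scale table values). Counts (teeth, pockets) are rounded after
truncation. A single root seed drives every draw in fixed order, so a
cohort is byte-reproducible from (spec, seed).

**Conditioning correction.** Comorbid-class members must carry ≥ 1
disease, enforced by rejection sampling. Conditioning on ≥ 1 success
inflates marginal rates, so the generator first deflates each comorbid
class's rate vector p to q = s·p with s the fixed point of
s = 1 − Π(1 − s·p). Then P(flag_d = 1 | ≥ 1 disease) = q_d / (1 − Π(1 −
q_d)) = p_d exactly: the drawn class-conditional prevalences match the
calibration targets in expectation. Feasibility requires Σp > 1 (a
patient with ≥ 1 disease averages ≥ 1 disease); infeasible target vectors
are rejected with a clear error. Both calibrated classes satisfy this
comfortably (Σp = 1.39 and 2.01).

**What the generator does and does not reproduce.** Matching the
class-conditional prevalences under within-class independence fixes the
rest of the count distribution. The mean disease count among comorbid
patients comes out at 1.72 (matching the published 1.7 ± 1.1), but the
multimorbid share is ≈ 49 % of comorbid patients versus ≈ 43 % observed:
real disease counts are more right-skewed (up to 11 diseases) than an
independent-flag model allows. Conditioning on ≥ 1 also induces mild
negative pairwise dependence within a class (cov(i, j) = −p_i p_j (1 −
s)), strongest between the two most common respiratory-class diseases.
Passing tests therefore demonstrate correct behaviour under a calibrated
conditional-independence model, not under the dependence structure of
real questionnaire data. No copulas or correlated-flag models are
provided.

**Class separability.** Under this calibration the Bayes-optimal
classifier of comorbid patients into the two classes attains ≈ 92 %
accuracy (many patients carry a single ambiguous disease — e.g.
allergy-only occurs in both classes), corresponding to an adjusted Rand
index of ≈ 0.7 against planted labels. No clustering can beat this
ceiling in expectation; recovered cluster shares are likewise pulled
toward 50/50 by the irreducible misassignment. Label-recovery experiments
should be read against this ceiling.

## Descriptive statistics

Group comparisons use the two-sample Student *t*-test with pooled
variance for continuous variables (Welch available behind a flag) and
Pearson's uncorrected χ² for 2 × 2 tables — the defaults of the software
environment the analysis mirrors. P-values are two-sided and
uncorrected per variable; a Benjamini–Hochberg option exists and is off
by default. Percentages are displayed rounded half-up to one decimal;
stored values are unrounded. An empty stratum reports a missing percent;
a zero-variance comparison is flagged rather than silently computed.

## Two-step clustering

Clustering operates on the 26 binary flags only (typically the comorbid
subset). For a cluster v, the log-likelihood cost is the total entropy
ξ_v = N_v Σ_k Ê_vk with Ê_vk = −Σ_l (N_vkl/N_v) ln(N_vkl/N_v) (natural
log; 0·ln 0 := 0); the distance between clusters is the pooled-entropy
increase d(a, b) = ξ_⟨a,b⟩ − ξ_a − ξ_b ≥ 0.

*Pre-clustering.* A sequential leader pass assigns each record to its
nearest leaf when the distance increase is ≤ a threshold (default 0, so
leaves are exactly the distinct disease profiles), else opens a new leaf,
capped at `max_leaves` (default 512); on overflow the threshold doubles
(from 2 ln 2 when zero) and the pass rebuilds. The leader pass is
order-dependent, so records are visited in a seeded random shuffle by
default. An absolute epsilon (1e-9) in the join test absorbs float
cancellation in exact-zero distances. Entropy terms use an integer
n·ln n lookup table for speed and exact cancellation of pure-cluster
costs.

*Agglomeration.* Greedy closest-pair merging down to one cluster, ties
broken on the lowest index pair; BIC(J) = 2 Σ_v ξ_v + J·K·ln N (K = 26
binary attributes contribute one free parameter each per cluster) and the
closest-pair distance d_min(J) are recorded for J ≤ J_max (default 15).

*Selection of k.* The conventional two-stage criterion: the coarse bound
is the smallest J whose relative BIC improvement R₁(J) = [BIC(J−1) −
BIC(J)] / [BIC(1) − BIC(2)] falls below 0.04; among J up to that bound,
the distance ratio R₂(J) = d_min(J)/d_min(J+1) picks the J with the
largest R₂ when the top two R₂ differ by a factor ≥ 1.15, else the larger
J. The 0.04 and 1.15 constants are configurable conventions, not
estimates. Note that raw BIC keeps decreasing with J on any data with
non-degenerate marginals (splitting on a single common attribute always
buys more entropy than the J·K·ln N penalty costs), which is precisely
why the ratio criterion, not the BIC minimum, selects k. A degenerate
trace (no improvement from 1 to 2 clusters) yields k = 1. Fitted
clusters are labeled 1..k by descending size; the per-cluster disease
prevalence profiles identify which cluster is which.

No outlier/noise-leaf handling and no mixed continuous-categorical
distance are implemented; the analysis clusters on diseases only.

## Adjusted prevalence comparison

For each disease (and each organ-system group, as the indicator of ≥ 1
member disease), a binomial logistic regression of the outcome on a
cluster-2 indicator plus age, sex, SEP and smoking (all linear,
untransformed) is fitted by IRLS. Inference on the cluster term is a
two-sided Wald test with a 95 % Wald CI on the odds ratio; the enriched
cluster is reported explicitly so the reference coding is immaterial
(relabeling clusters inverts the OR). Outcomes absent in both clusters
are marked untestable. Quasi-complete separation — expected here, since
several diseases have zero cases in one cluster — is detected from
standardized coefficients exceeding 15 and flagged rather than corrected
(no Firth penalty), keeping the estimator transparent and surfacing the
pathology. Missing SEP drops the record from that model only.

## Hypergraph co-occurrence network

Multimorbid patients (≥ 2 diseases) define the diseases × patients
incidence matrix M. The adjacency is A = M Mᵀ − D_n. "D_n with entries
equal to the prevalences" is read as D_n = diag(M Mᵀ) — occurrence
*counts*, which zeroes the diagonal and makes A_ij the number of patients
carrying both i and j; subtracting prevalence *proportions* instead would
leave a meaningless mixed-scale diagonal, but that reading is available
behind `adjacency(..., diagonal="proportions")`.

Unique patient disease-sets form the hyperedge catalog; the ≥ 8
occurrence filter is applied for visualization exports only — centrality
is computed on the full multimorbid matrix. Centrality is the principal
eigenvector of A, computed by power iteration from the uniform vector
(max-norm convergence 1e-12, cap 1e5 iterations) on the positively
shifted matrix A + σI with σ the maximum row sum: the shift preserves
eigenvectors while making the Perron eigenvalue strictly dominant (a
bipartite-like A has λ_min = −λ_max and would otherwise oscillate).
Scores are sign-fixed non-negative, unit Euclidean norm; isolated
diseases score exactly 0; a near-degenerate top eigenvalue (relative gap
< 1e-9, checked by a cheap dense eigendecomposition over the 26 diseases)
is flagged as non-unique.

## Pipeline and reproducibility

The pipeline (synthetic or CSV input) runs descriptives → comorbid-subset
clustering → adjusted comparisons → hypergraph analysis, emitting the
table/figure CSV analogues, cluster assignments, BIC trace, adjusted
comparisons, hypergraph exports, and a manifest (seed, config echo,
exclusion counts, stage summaries). One root seed fans out
deterministically to the generator and the cluster shuffler; a rerun with
the same config is byte-identical. An optional first clustering pass on
the total population (which separates comorbid from disease-free
patients) is available as a sanity step, off by default.

Monte-Carlo experiments (cluster recovery, type-I behaviour of the
adjusted comparison, centrality ranking) use 20 seeded replicates at the
study scale of n = 3171 — enough for stable medians and hit rates while
keeping the whole suite and the acceptance script in the seconds-to-
minutes range on one CPU.

## Known limitations

- Within-class conditional independence understates the skew of real
  disease-count distributions (see above); the multimorbid subcohort is
  correspondingly ≈ 12 % larger than the real-data analogue.
- The class overlap of the calibrated mixture caps label recovery at
  ARI ≈ 0.7; experiments demanding near-perfect recovery are not
  achievable under this calibration and are reported as measured.
- The leader pass is exact only in the sense of the seeded shuffle;
  different shuffles can move borderline records between leaves.
- PISA is carried as a numeric field; its root-surface-area derivation,
  SEP-score construction, and the 2018 periodontitis staging/grading
  scheme are out of scope.
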