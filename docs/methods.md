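# Methods

This note documents the statistical procedures implemented in `tcrep`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data validation does and does not establish.

## Data model and filtering

A repertoire is a sample's table of CDR3β amino-acid clonotypes with template
(molecule) counts. Input rows are taken as reported — the CDR3 string is used
exactly as provided, conserved C…F bounds included, with no trimming.
Analysis uses *productive* clonotypes only: records flagged in-frame whose
sequence contains only the 20 standard residues. Stops (`*`), ambiguity
codes (`X`) and the non-standard letters B, J, O, U, Z all cause a record to
be dropped at filtering, because the physicochemical scales downstream are
undefined for them. Clonotypes are collapsed on the CDR3 amino-acid sequence
alone (not per V/J context); V/J calls are retained only when unanimous
among merged records. Healthy donors under 40 years can be excluded at
metadata load (`drop_young_healthy`), the standard mitigation when healthy
reference cohorts skew young and clonality rises with age.

Two input dialects are accepted: ImmunoSEQ-style exports in either header
style (`aminoAcid`/`count (templates/reads)`/`frame_type`, or
`amino_acid`/`templates`; `frame_type == "In"` ⇔ productive) and AIRR
Rearrangement TSV (`junction_aa`/`duplicate_count`/`productive`; when
`duplicate_count` is absent the fallback order is `consensus_count`, then 1
with a warning, since AIRR makes counts optional).

## Clonality

Sequencing depth spans orders of magnitude between samples, so clonality is
computed after downsampling every repertoire to a common template total —
by default the cohort minimum. The draw is multivariate hypergeometric over
the expanded template pool (templates sampled without replacement; no
refitting of an abundance model), one seeded draw per sample. This is the
only reading of "downsample without probabilistic simulation" that yields
exact target totals.

Clonality is the population Gini coefficient of the clone-count vector,

    G = Σᵢ Σⱼ |xᵢ − xⱼ| / (2 n² x̄) = Σᵢ (2i − n − 1) x₍ᵢ₎ / (n Σ x),

computed in the sorted form, with zeros excluded and no small-sample
correction — the convention used across repertoire analysis. G = 0 for a
perfectly even repertoire; values near 1 indicate domination by few clones.
Note that G is *not* monotone under clonotype merging: collapsing two
equal-count clonotypes can move G in either direction depending on the rest
of the distribution, so no such monotonicity is asserted anywhere.

Group comparisons use two-sided Wilcoxon rank-sum tests (exact enumeration
when n₁ + n₂ ≤ 20 without ties, otherwise the normal approximation with
tie-corrected variance and continuity correction); paired contrasts use the
signed-rank test (exact for n ≤ 15). Because clonality increases with age
and patient groups skew older, the age-adjusted comparison is an OLS of Gini
on age plus diagnosis indicators with healthy as the reference level; a
rank-deficient design is rejected with the collinear columns named.

## Sequence clustering

All baseline samples' productive CDR3s are pooled into one cluster universe
(per-sample projection afterwards). Pooling, rather than per-sample
clustering, is what makes cross-group cluster exclusivity and per-sample
cluster counts well-defined.

Edges connect equal-length sequences at Hamming distance exactly 1. All such
pairs are found by deletion-key hashing: each sequence of length L is
indexed under the L strings obtained by deleting one position; two distinct
sequences share a key iff they differ at exactly that position. Pairs are
verified before acceptance, and the edge set is provably identical to the
O(n²) pairwise scan (tested against it). No substitution-matrix weighting is
used — exactness and testability over biochemical nuance.

Connected components are refined by Markov clustering on the
column-stochastic random-walk matrix with self-loops: expansion (matrix
power 2), inflation (entrywise power 2 with renormalization), pruning of
entries below 1e-5, to convergence at tolerance 1e-8 or at most 100
iterations (non-convergence returns the current partition with a warning).
Attractor rows define the clusters. Components are processed independently
(disconnected components can never merge under MCL), which keeps the dense
per-component computation small. Clusters need ≥ 2 members; singletons are
excluded from the sample × cluster matrix but retained for annotation.

Cluster abundance in a sample is the summed clone fraction of member
sequences; presence is abundance > 0. Per-sample cluster-level Gini uses the
nonzero cluster abundances.

## Differential cluster prevalence and exclusivity

Prevalence is sample-level presence/absence, not read counts — each
cluster's 2×2 table counts diseased/healthy samples with and without the
cluster. The two-sided Fisher exact p follows the probability-mass rule
(sum of hypergeometric probabilities of all tables with the observed margins
whose probability is at most the observed one, relative tie tolerance
1e-12), computed in log space; per-margin log-pmf vectors are cached because
every cluster tested against one split shares margins. Benjamini–Hochberg
q-values are reported, and candidate clusters are selected at a nominal
α = 0.001 — at desk scale as at full scale, individual clusters rarely
survive FDR control, so nominal selection feeds the classifier while q is
kept for honesty. Selection sees only the training split: prevalence tables
are computed on training rows, so test-split presence values cannot leak
into feature selection.

Group exclusivity (share of clusters whose carriers all belong to one
diagnosis group) is calibrated by shuffling sample labels with group sizes
preserved (default 1,000 permutations). Empirical p-values use the add-one
convention (1 + #extreme)/(B + 1), so the smallest attainable p is
1/(B + 1), and both tails are always reported — observed exclusivity can sit
below as well as above its null expectation, and the interesting side is not
known in advance.

## Physicochemical descriptors

Nine descriptors per CDR3: length; GRAVY (mean Kyte–Doolittle hydropathy);
mean Zimmerman bulkiness; mean Grantham polarity; Ikai's aliphatic index
X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) in mole percent; net charge; and the
fractions of positions that are basic {R, H, K}, acidic {D, E} and aromatic
{H, F, W, Y}. Net charge is Henderson–Hasselbalch over ionizable side chains
only (R, H, K positive; D, E, C, Y negative) at pH 7.4 with the EMBOSS pK
set — free termini are excluded because the CDR3 is an internal peptide
fragment. The residue tables ship as data files (`data/aa_scales.tsv`,
`data/pk_sidechain.tsv`) so alternative scales are pluggable. All
descriptors are composition-based and exactly invariant under residue
permutation. Cluster summaries are unweighted means over members;
z-normalization is per property across clusters, with zero-variance
properties set to z = 0 with a warning. Healthy- vs disease-enriched
property distributions are compared by the same rank-sum test, one row per
descriptor.

## Classification

Features are the selected clusters' per-sample summed clone fractions,
log10(x + 10⁻⁶)-transformed (abundances are heavy-tailed; the offset is
below any attainable nonzero clone fraction at realistic depths) and
standardized inside each model pipeline on training statistics. The fixed
70/30 train/test split is stratified per class with at most one sample's
deviation from the fraction, deterministic given its seed, and shared across
all analyses.

Six families with small fixed grids, tuned by stratified 5-fold inner CV
maximizing AUROC: elastic-net logistic regression (l1_ratio ∈ {0.1, 0.5,
0.9}, C ∈ {0.1, 1, 10}), random forest (500 trees, max_features ∈ {sqrt,
0.33}), RBF SVM (C ∈ {0.1, 1, 10}), single-hidden-layer neural network
(5 units, weight decay ∈ {1e-4, 1e-2, 1}), gradient boosting (100 stages,
depth ∈ {1, 3}), and k-NN (k ∈ {5, 11, 21, 43}, pruned to the training-fold
size, standardized distances). Internal validation repeats a stratified
80/20 holdout five times inside the training split (degenerate single-class
folds are redrawn, at most 20 times); metrics are summarized by the mean and
the empirical percentile 95% interval, which at five repeats is necessarily
coarse (near min/max). External validation refits each tuned model on the
full training split and scores the untouched test split once.

Metrics: AUROC in the Mann–Whitney midrank form P(s₊ > s₋) + ½P(tie);
accuracy, sensitivity, specificity and Cohen's κ = (p_o − p_e)/(1 − p_e) at
a 0.5 probability threshold with diseased as the positive class (the
ecosystem default; no attempt to optimize the operating point). Paired model
comparisons use the fast DeLong test on midrank placement values, with the
degenerate zero-variance case (a model against itself) defined as z = 0,
p = 1. Variable importance is model-native where the family defines one
(|standardized coefficients|, impurity decrease, absolute connection-weight
products through the hidden layer) and otherwise permutation importance
(mean AUROC drop over 10 single-feature shuffles), normalized so the top
feature scores 100. When feature selection returns nothing — routine on null
cohorts — every model degenerates to a constant 0.5 score, i.e. chance-level
AUROC, rather than failing.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
full ground truth, at desk scale:

- **Depth**: per-sample template totals log-normal (default median 25,000,
  log-sd 0.4), truncated so every clonotype can hold ≥ 1 template. Real
  cohorts run 10⁴–10⁶ productive sequences per sample; desk-scale defaults
  (5,000 clonotypes per sample) keep a full pipeline run in tens of seconds,
  and depth is config-driven for anyone wanting more.
- **Clone abundances**: each clonotype receives one template plus a
  multinomial share with truncated-Zipf rank weights (default exponent 1.3)
  — the heavy-tailed structure the Gini statistic responds to, at trivial
  cost compared to a mechanistic V(D)J model.
- **Age effect**: the Zipf exponent rises by `age_slope` (default 0.004) per
  year from age 50, so older samples are more clonal, reproducing the
  age–clonality confound the OLS stage must remove.
- **Public clones**: a configurable fraction (default 0.3) of each sample's
  clonotypes comes from a shared pool organized as Hamming-1 *families*
  (default 2,000 families of 3: a seed plus single-substitution variants).
  Random uniform CDR3s essentially never sit at Hamming distance 1, so a
  pool without local similarity structure would produce a near-empty cluster
  universe; convergent-recombination neighbourhoods are exactly what makes
  real pooled repertoires cluster richly even without disease signal, and
  the family pool reproduces that property. Null-cohort calibration runs use
  5,000 families to present the differential-abundance stage with a
  realistic multiple-testing burden.
- **Spiked clusters**: planted signal. Each spiked cluster is a seed CDR3
  plus `motif_size − 1` Hamming-1 variants (default 8 members); a sample
  carries one uniformly chosen member with probability `prevalence_in`
  (default 0.8) if it belongs to the cluster's target group, else
  `prevalence_out` (default 0.1), inserted at the sample's median clone
  count. Members are Hamming-1 *neighbours of the seed*, not of each other,
  so the clustering stage — not an oracle — must reunite them. Target groups
  rotate over the disease groups present; with several disease groups the
  pooled healthy-vs-diseased prevalence contrast is correspondingly diluted,
  so discrimination-power checks use a two-group (healthy vs MM, 60 vs 60)
  configuration. No effect-size scale is published for real cluster
  prevalence differences; these defaults are chosen for test power, not
  biological fidelity.
- **Determinism**: one global seed; per-stage and per-sample generators are
  derived at fixed offsets, so cohorts are byte-identical across runs and
  stages are independent.

What passing the synthetic validation shows: the pipeline's stages are
correct (oracle equivalence), calibrated (type-I control, permutation and
DeLong uniformity under the null), and able to recover planted structure at
the configured effect sizes. What it does not show: performance on real
repertoires, whose V/J-driven sequence composition, length distribution,
sequencing error and batch structure the generator deliberately does not
model.

## Numerical and design choices

- Fisher tie tolerance 1e-12 (relative, applied in log space); margins
  cached per split.
- MCL attractor threshold 1e-9 on the diagonal; numerically orphaned nodes
  become singletons rather than being silently dropped.
- Downsampling uses one seeded draw per sample (averaging over draws is not
  attempted; the seed is recorded in the manifest).
- Spearman correlation on fewer than 3 paired samples, or with zero rank
  variance, is reported as NaN with a warning rather than a number.
- The empirical 95% CI over five repeats uses linear-interpolation
  percentiles; with n = 5 this is effectively the min/max envelope and is
  documented as low-resolution.
- The miniature cohorts used in fast tests can lose a spiked cluster's hub
  seed (no sample carries it), in which case its variants need not be
  mutually adjacent; recovery bounds at that scale are deliberately loose,
  and power claims are made only at the 60 vs 60 scale.

## Known limitations

- Exact Hamming-1 edges only; no substitution-matrix or embedding-based
  similarity, so biochemically conservative two-position variants never
  cluster.
- The optional coarse pre-partition for very large pools trades exactness
  for memory and can split true clusters; desk-scale runs use the exact
  component decomposition.
- Cluster prevalence is binary presence; count-based differential abundance
  models (negative binomial, compositional) are out of scope.
- Specificity annotation is exact sequence matching against user-supplied
  snapshots, without V-gene conditioning.
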