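# tcrep

Analysis of bulk TCRβ CDR3 repertoires from peripheral blood, aimed at the
question whether patients with plasma cell dyscrasias (MGUS, smoldering
myeloma, multiple myeloma) can be distinguished from healthy donors by the
*composition* of their T-cell receptor repertoire when overall clonality
cannot. The package provides, as a tested and reusable pipeline:

- **ingestion** of ImmunoSEQ-style and AIRR Rearrangement TSVs into a common
  clonotype container, with productive-sequence filtering (in-frame CDR3β
  amino-acid sequences over the 20 standard residues, no early stop);
- **clonality**: depth normalization by exact without-replacement downsampling
  to a common template total, the Gini coefficient
  G = Σᵢ(2i − n − 1)x₍ᵢ₎ / (n Σx) over clone counts, Wilcoxon group
  comparisons, and an age-adjusted OLS of Gini on age + diagnosis;
- **clustering**: pooled CDR3β sequences connected at Hamming distance 1
  (deletion-key hashing) and partitioned by Markov clustering (expansion 2,
  inflation 2), projected back onto samples as a clusters × samples
  clone-fraction matrix;
- **differential abundance**: per-cluster two-sided Fisher exact tests on
  sample-level prevalence (healthy vs diseased), BH-FDR, nominal selection at
  α = 0.001 on the training split only, and permutation-calibrated group
  exclusivity (labels shuffled with group sizes preserved, add-one empirical
  p, both tails);
- **physicochemical profiling**: nine descriptors per CDR3 (length, GRAVY,
  bulkiness, aliphatic index, polarity, net side-chain charge at pH 7.4,
  basic/acidic/aromatic fractions), cluster means and z-scores;
- **classification**: six model families (elastic-net logistic regression,
  random forest, RBF SVM, single-hidden-layer neural network, gradient
  boosting, k-NN) evaluated by repeated stratified 80/20 holdout inside a
  fixed 70/30 train/test split, external validation on the held-out 30%,
  paired DeLong AUROC comparisons and variable importance;
- **annotation** of cluster members against local antigen-specificity
  snapshot tables (exact amino-acid match, convergence flags);
- a **synthetic cohort generator** with full ground truth — Zipf clone
  abundances, log-normal depths, public Hamming-1 sequence families,
  age-linked clonality, and group-associated spiked motif clusters at
  controlled prevalence — so every stage can be validated against known
  truth.

## Worked example

Generate a two-group cohort (60 healthy vs 60 myeloma samples, 5,000
clonotypes each, 50 spiked clusters carried at prevalence 0.8 in the target
group vs 0.1 elsewhere) and run the full analysis:

```python
from tcrep import GeneratorConfig, generate_cohort, AnalysisConfig, analyze_cohort

cfg = GeneratorConfig(n_per_group={"healthy": 60, "MM": 60}, seed=1)
repertoires, metadata, truth = generate_cohort(cfg)
res = analyze_cohort(
    repertoires, metadata,
    AnalysisConfig(n_permutations=200,
                   model_families=("random_forest", "penalized_logistic"),
                   seed=1),
    ground_truth=truth,
)
print(f"clusters: {len(res.cluster_set.clusters)}")
print(f"selected at alpha=0.001: {len(res.selected)}")
print(f"spiked-cluster recall: {res.ground_truth_eval['recall']:.2f}")
print(f"spiked-cluster selection rate: {res.ground_truth_eval['selection_rate']:.2f}")
print(f"sequence-vs-cluster Gini Spearman: {res.gini_spearman:.3f}")
rf = res.external_metrics["random_forest"]
print(f"random forest external AUROC: {rf['auroc']:.3f}  kappa: {rf['kappa']:.3f}")
```

prints

```
clusters: 2957
selected at alpha=0.001: 53
spiked-cluster recall: 1.00
spiked-cluster selection rate: 1.00
sequence-vs-cluster Gini Spearman: 0.574
random forest external AUROC: 1.000  kappa: 1.000
```

Reading: pooled clustering found 2,957 clusters of size ≥ 2; the Fisher stage
selected 53 of them at the nominal threshold on the training split, covering
all 50 planted motifs (selection rate 1.00), each reunited into a single
cluster by Markov clustering (recall 1.00). Cluster-level clonality tracks
sequence-level clonality (Spearman 0.574), and the random forest trained on
the selected clusters' clone fractions separates the held-out test samples
perfectly — at this planted effect size the discrimination task is easy; the
interesting behaviour is that on *null* cohorts (no planted signal) the same
pipeline selects ≤ 0.2 % of clusters and external AUROC stays at chance.

The same analysis is available from a shell:

```bash
tcrep --seed 1 --outdir run1 all          # simulate + full pipeline + report
tcrep --config cfg.yaml --outdir run2 all # custom cohort / thresholds
```

Each stage writes its artifacts (TSV/MatrixMarket/JSON, plus figures) and a
manifest with config hash and output checksums; reruns with identical config
reproduce identical checksums.

## Layout

```
src/tcrep/
  io.py          rearrangement/metadata parsing, filtering, aggregation
  simulate.py    synthetic cohorts with ground truth
  diversity.py   downsampling, Gini, rank tests, age-adjusted OLS
  cluster.py     Hamming-1 graph, MCL, cluster matrix
  da.py          Fisher prevalence tests, BH-FDR, permutation exclusivity
  properties.py  physicochemical descriptors (scales in data/)
  classify.py    splits, six model families, metrics, DeLong, importance
  annotate.py    specificity snapshot matching
  pipeline.py    end-to-end orchestration
  plots.py       standard figures
  cli.py         click-based stage runner (`tcrep`)
docs/methods.md  model and design notes
```
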