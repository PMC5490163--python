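# Methods

This note records the model implemented by `isown`, the parameters and their
defaults, what the synthetic cohort generator does and does not emulate, the
numerical choices, and the design decisions taken where the method leaves room
for interpretation.

## 1. Problem and pipeline

Given single-nucleotide variant (SNV) calls from a cohort of tumour samples
with **no matched normals**, label every unique allele as *somatic* (acquired
by the tumour) or *germline* (inherited polymorphism). The pipeline is:

1. **Read and filter calls** (`variant_io`). Per-sample VCFs are read with
   pysam. A call is kept if it is a simple SNV with a non-`N` reference base,
   passes the caller's filters, has depth ≥ 10× (sum of allelic depths when
   `AD` is present, else `DP`), and falls in coding sequence with non-silent
   effect. Filters are applied in a fixed order and every drop is counted, so
   kept + dropped always equals the input call count. Homozygous-call removal
   is available but off by default (flanking assessment needs heterozygous
   polymorphisms, which are identified per-candidate instead).
2. **Annotate** (`annotate`). Each allele is looked up in four external
   tables: a somatic mutation catalogue (recurrence count `cnt`), a common
   polymorphism catalogue, a rare polymorphism catalogue, and a population
   exome resource; plus two functional-impact predictions (a seven-level
   category including stop-gain/stop-loss, and a four-level category). Stop
   effects override the first predictor's category because such predictors do
   not score nonsense changes.
3. **Per-call features** (`features`). VAF, its Clopper–Pearson 95 % interval,
   the pyrimidine-normalised substitution pattern (6 levels), the forward-strand
   trinucleotide context (64 levels), and the flanking-region assessment
   (§ 2).
4. **Collapse** (`collapse`). Calls are collapsed to unique alleles keyed by
   (chromosome, position, ref, alt). Per-allele aggregates: number of carrier
   samples, sample frequency = carriers / cohort size, mean VAF, and the
   flank weight (§ 2). Conflicting reference bases at one site raise an error.
5. **Pre-label** (`prelabel`). Two disjoint rules: catalogue recurrence
   `cnt ≥ 100` ⇒ somatic; present in the common-polymorphism catalogue *and*
   `cnt = 0` ⇒ germline. Pre-labelled alleles bypass the classifier and are
   reported with provenance `prelabeled` and score 1.0 / 0.0.
6. **Classify** (`classify`). The remaining alleles are scored by a supervised
   classifier trained on the pre-labelled (or, in evaluation, truth-labelled)
   alleles; score ≥ 0.5 ⇒ somatic.

## 2. Flanking-region feature

For each call, the nearest common-polymorphism call strictly upstream and the
nearest strictly downstream in the *same sample*, within 2 Mbp and not
homozygous (VAF interval entirely above 0.95 is excluded), serve as witnesses
of the local allelic balance. With `x` the candidate's VAF interval and
`v1`, `v2` the witnesses':

- `germline_like` if `x` overlaps both `v1` and `v2`;
- `somatic_like` if `x` overlaps neither while `v1` and `v2` overlap each
  other;
- `not_applicable` otherwise, including when either witness is missing.

Intervals are closed; overlap means `max(lo) ≤ min(hi)`. Per unique allele,
`flank_weight` = (# `germline_like` calls) / (# all calls), with
`not_applicable` calls kept in the denominator; if every call is
`not_applicable` the feature is missing. Rationale: a germline heterozygote
rides the same local copy-number/allelic-balance regime as its neighbouring
SNPs, whereas a subclonal somatic mutation does not.

## 3. Feature schema and classifiers

Ten features per unique allele: `cnt` (integer ≥ 0), `in_exac` (binary),
`in_dbsnp_rare` (binary), `ma_category` (7 levels incl. `missing`),
`pp2_category` (4 levels incl. `missing`), `context` (64 trinucleotides +
`missing`), `pattern` (6 substitution classes), `sample_frequency`,
`mean_vaf`, `flank_weight` (continuous in [0, 1], possibly missing).

**Naive Bayes (authored in-repo).** Categorical likelihoods use Laplace
smoothing, `(count + 1) / (n_class + n_levels)`, with `missing` a regular
level. Continuous features use Gaussian likelihoods with population variance
and a variance floor of 1e-9; a missing continuous value is simply omitted
from that allele's likelihood product rather than imputed. Posteriors are
normalised; the somatic posterior is the score. This missing-value semantics
is the main reason for an in-repo implementation: scikit-learn's naive Bayes
variants neither mix categorical and Gaussian features nor skip missing
values.

**Other back-ends** (scikit-learn behind a one-hot encoding with fixed level
sets; missing continuous values become a −1 sentinel plus an indicator
column): `tree_ensemble` (random forest, 200 trees), `boosted_tree`
(histogram gradient boosting — a stand-in for boosted decision trees),
`logistic`, `svm` (RBF, probability estimates). Unknown categorical levels at
prediction time are mapped to `missing` with a warning.

**Training sets.** `balanced_sets(n_sets, per_class=700)` draws balanced
somatic/germline sets with replacement across sets (without replacement
within a set); if a class has fewer than `per_class` members, all are used
and a warning is emitted. `train_from_samples` builds a training set from a
subset of samples: all somatic alleles called in those samples plus an equal
number of germline alleles (reduced to the minority count when germline
alleles are scarcer).

**Evaluation.** Stratified tenfold cross-validation pools out-of-fold scores
before computing measures. Six measures: recall, precision, F1, false
positive rate, accuracy, AUC; any measure with an empty denominator is
reported as undefined (`None`/`null`), never as 0. AUC is the Mann–Whitney
U statistic computed from scipy rank data with ties shared. `select_best`
orders models by AUC, then F1, then name. Information gain uses base-2
entropy with continuous features discretised into 10 equal-frequency bins
and missing values as their own bin.

**Held-out evaluation** (`pipeline.evaluate_holdout`): a seeded permutation
picks training samples; the model trains on their truth-labelled alleles
(pre-labelling applied first); performance is reported on alleles **never
called in any training sample**, both for the full pipeline (rules +
classifier) and for classifier-handled alleles only.

## 4. Synthetic cohort generator

`synthetic.simulate_cohort` writes a reference FASTA, per-sample VCFs
(`GT:DP:AD`), the four annotation tables, an impact table, per-allele truth,
and the configuration used. Defaults (all overridable in `CohortConfig`):

| parameter | default | rationale |
|---|---|---|
| `n_samples` | 50 | typical discovery cohort size |
| `n_chromosomes` × `chrom_length` | 4 × 1 Mb | large enough for flanking structure, small enough to run in seconds |
| `common_pool_size` | 3000 | yields roughly a 9:1 germline:somatic call ratio, inside the range seen in real tumour-only exomes |
| common-allele population frequency | Beta(1.2, 6) | right-skewed site frequency spectrum |
| `rare_per_sample` | 40 | private/rare inherited variants per sample |
| `somatic_per_sample` | Poisson(60) | exome-scale mutation burden |
| hotspots | 15 sites, carrier prob. 0.08 | recurrent drivers, exercise the `cnt` feature |
| somatic VAF | Beta, mean 0.25, concentration 12, × purity | subclonality; mean inside the 0.22–0.50 range of real tumours |
| germline VAF | Binomial reads around 0.5 (or 1/3, 2/3 in copy-number segments) | heterozygote balance and its CN distortion |
| `cn_segment_fraction` | 0.15 | fraction of genome in CN-shifted segments |
| `purity` | 0.85 | stromal dilution of somatic VAFs |
| depth | negative binomial, mean 100, dispersion r = 20 | overdispersed exome coverage |
| database coverage | common 95 % in dbSNP-common, rare 40 % in dbSNP-rare, ExAC 90 %/35 %; contamination knobs for somatic alleles appearing in databases | imperfect, leaky annotations |
| class-specific skews | substitution-pattern and impact-category priors differ by class | somatic mutations are enriched for damaging changes and particular substitution classes |

Everything is driven by `numpy.random.default_rng(seed)`; identical
configurations produce byte-identical files.

**What the generator does not emulate:** sequencing error and caller
artefacts (every emitted call is a real simulated allele), indels and
multi-allelic sites, linkage between germline variants, mutational-signature
context dependence beyond the pattern prior, sample contamination and
tumour-in-normal effects, and population structure. Consequently the
classification task is somewhat easier than on real data; absolute
performance numbers should be read as properties of the implementation, not
as clinical estimates.

## 5. Numerical choices

- **Clopper–Pearson intervals** via `scipy.stats.beta.ppf`
  (`lo = Beta.ppf(α/2; k, n−k+1)`, `hi = Beta.ppf(1−α/2; k+1, n−k)`), with
  the exact boundary conventions `lo = 0` at `k = 0` and `hi = 1` at `k = n`.
  Verified against a direct bisection of the binomial tail probabilities to
  < 1e-8 for all `k ≤ n ≤ 200`.
- **Closed-interval overlap** for the flanking rule; ties at interval
  endpoints count as overlap.
- **Nearest flank** is chosen strictly upstream/downstream by position;
  a co-located variant cannot witness itself or its site.
- **Variance floor 1e-9** in the Gaussian likelihood prevents degenerate
  zero-variance features from producing infinities.
- **Laplace (+1) smoothing** keeps unseen categorical levels from zeroing the
  posterior.
- **Equal-frequency (decile) binning** for information gain on continuous
  features, so the statistic does not depend on the features' scales.
- **Classification threshold 0.5** on the somatic posterior; `predict`
  accepts another threshold when a different operating point is wanted.
- Metric confidence intervals in cross-validation are normal-approximation
  95 % intervals over the per-set values.

## 6. Design decisions

- **Held-out semantics.** "Held out" means alleles never called in any
  training sample, not merely samples excluded from training — shared common
  polymorphisms seen during training would otherwise leak. Both
  full-pipeline and classifier-only measures are reported, since the
  rule-handled alleles are almost always correct and inflate the former.
- **Pre-labelled ≠ trusted for training in evaluation.** When truth labels
  exist (simulation), training uses truth; in a real run training labels come
  from the pre-labelling rules. The pipeline asserts that pre-labelled and
  classifier-handled sets are disjoint.
- **Mixed evidence at collapse.** If different calls of one allele carry
  contradictory truth labels, the allele's label is `excluded` and it is
  dropped from training rather than arbitrated.
- **Trinucleotide context is not strand-collapsed** (65 levels including
  `missing`); the substitution *pattern* is pyrimidine-normalised instead, so
  the two features carry complementary information.
- **Germline shortfall handling.** When a training-sample subset contains
  fewer germline than somatic alleles, the somatic side is reduced to match
  (with a warning) instead of sampling germline alleles with replacement.
- **Boosted trees.** Histogram gradient boosting stands in for boosted
  decision trees; rule-based learners (RIPPER-style) have no maintained
  Python implementation and are omitted.

## 7. Limitations

Performance is characterised only on synthetic cohorts (see § 4 for the
realism gap). The flanking feature needs common polymorphisms near the
candidate in the same sample; in sparse targeted panels it degrades to
missing. The pre-labelling rules inherit the biases of the somatic and
polymorphism catalogues: a common polymorphism that is also a recurrent
catalogue entry is deliberately *not* pre-labelled germline and must be
resolved by the classifier. Cohorts with very few samples weaken the
cohort-level features (sample frequency, flank weight), although on synthetic
data performance saturates quickly with cohort size.
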