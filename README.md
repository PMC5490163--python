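# isown — somatic variant classification without matched normals

`isown` separates **somatic mutations** from **germline polymorphisms** in
tumour sequencing cohorts for which no matched normal tissue is available.
Tumour-only calling reports every position where the tumour differs from the
reference genome, so the call set is dominated by the patient's inherited
(germline) variation — typically several germline variants for every somatic
mutation even after database filtering. Distinguishing the two matters because
only somatic events are informative about the tumour itself.

The package combines three ideas:

1. **External knowledge as features, not filters.** Presence in population
   databases (common/rare polymorphism catalogues, a population exome resource)
   and recurrence counts in a somatic mutation catalogue are encoded as
   features, so the classifier can weigh conflicting evidence instead of
   discarding variants outright.
2. **Cohort-level signal.** Calls are collapsed across samples into unique
   alleles. The fraction of samples carrying an allele (sample frequency), the
   mean variant allele fraction (VAF), and a *flanking-region* feature — does
   the call's VAF confidence interval behave like those of nearby known common
   polymorphisms in the same sample? — all exploit the cohort rather than a
   single tumour.
3. **Rule-based pre-labelling + supervised learning.** Unambiguous alleles
   (heavily recurrent in the somatic catalogue, or known-common and never seen
   somatic) are labelled by rules and used to train a classifier for everything
   else, so no external truth set is required.

Each unique allele is described by ten features: somatic-catalogue recurrence
count, presence in a population exome resource, presence as a *rare*
polymorphism, predicted functional-impact category, a second impact predictor's
category, trinucleotide sequence context, pyrimidine-normalised substitution
pattern, sample frequency, mean VAF, and the flanking-region weight. Missing
values are first-class: the in-repo naive Bayes treats "missing" as its own
categorical level and omits missing continuous values from the likelihood
product. Random-forest, gradient-boosted-tree, logistic and SVM back-ends are
also provided.

Because real tumour cohorts with truth labels cannot ship with the package, a
**synthetic cohort generator** produces multi-sample VCFs, a small reference
FASTA, annotation tables, and per-allele truth labels with realistic structure:
Beta-distributed population allele frequencies, subclonal somatic VAFs scaled
by purity, copy-number segments that displace germline VAFs off 0.5, recurrent
hotspots, negative-binomial depth, and class-specific substitution and impact
biases.

## Worked example

Simulate a 20-sample cohort, train on 15 samples, predict, and evaluate on the
alleles never seen in a training sample (output below is what the commands
actually print):

```bash
isown simulate --seed 7 --n-samples 20 --out demo/cohort
# wrote cohort to demo/cohort (20 samples, 5051 truth alleles)

isown train demo/cohort --truth demo/cohort/truth.tsv \
    --classifier naive_bayes --n-train-samples 15 --seed 7 \
    --model-out demo/model.joblib
# filter: kept 10895 calls from 20 samples; dropped {'non-coding/silent': 1231, 'non-PASS': 142}
# collapse: 4087 unique variants
# prelabel: 2035 prelabeled, 2052 to classify
# trained naive_bayes on 15 samples -> demo/model.joblib

isown predict demo/cohort --model demo/model.joblib --out demo/predictions.tsv
# 4087 unique variants (1083 somatic) -> demo/predictions.tsv

isown evaluate demo/cohort --truth demo/cohort/truth.tsv \
    --n-train-samples 15 --seed 7
```

The evaluate command prints JSON with the six performance measures for the
full pipeline (rules + classifier) and for classifier-handled alleles only:

```json
{
  "pipeline": {
    "recall": 0.9764705882352941,
    "precision": 0.9764705882352941,
    "f1": 0.9764705882352941,
    "fpr": 0.017699115044247787,
    "accuracy": 0.9797979797979798,
    "auc": 0.9974897333564694
  },
  "classified_only": {
    "recall": 0.9754098360655737,
    "precision": 0.9754098360655737,
    "f1": 0.9754098360655737,
    "fpr": 0.029411764705882353,
    "accuracy": 0.9732142857142857,
    "auc": 0.9956404693024751
  },
  "n_heldout_alleles": 594
}
```

The first few predictions (`demo/predictions.tsv`):

```
chrom  pos   ref  alt  predicted_label  score     provenance  n_samples_with_call
chr1   2333  T    C    germline         0.000000  prelabeled  1
chr1   5217  C    T    germline         0.000000  prelabeled  5
chr1   8688  A    C    germline         0.000000  prelabeled  4
```

`isown crossval demo/cohort --truth demo/cohort/truth.tsv` additionally runs
stratified tenfold cross-validation on balanced 700+700 training sets, and
`isown evaluate ... --by-vaf-tier` breaks performance down by VAF band.

The same functionality is available from Python — see `isown.pipeline`
(`prepare`, `train_on_samples`, `classify_variants`, `evaluate_holdout`) and
`isown.synthetic.simulate_cohort`.

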