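"""End-to-end pipeline: filter -> annotate -> features -> collapse ->
pre-label -> classify.

The stages mirror how a tumor-only cohort is processed in practice: the
per-sample VCFs are filtered and annotated, intrinsic features are
computed per call, calls are collapsed to unique alleles, deterministic
rules pre-label the easy alleles, and a classifier trained on a labeled
subset of samples predicts the rest. Pre-labeled alleles never reach the
classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from isown import classify as clf
from isown.annotate import AnnotationSources, check_chromosomes, load_sources
from isown.collapse import UniqueVariant, apply_truth, collapse
from isown.features import (
    DEFAULT_CI_LEVEL,
    DEFAULT_FLANK_WINDOW_BP,
    compute_call_features,
)
from isown.prelabel import DEFAULT_CNT_THRESHOLD, prelabel
from isown.variant_io import CohortCallSet, FilterConfig, read_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to (re)run the pipeline on one cohort."""

    vcf_paths: list[str] = field(default_factory=list)
    genome: Optional[str] = None
    cosmic: Optional[str] = None
    dbsnp_common: Optional[str] = None
    dbsnp_rare: Optional[str] = None
    exac: Optional[str] = None
    impact: Optional[str] = None
    # filters
    min_depth: int = 10
    require_pass: bool = True
    drop_homozygous: bool = False
    coding_only: bool = True
    include_silent: bool = False
    # intrinsic features
    flank_window_bp: int = DEFAULT_FLANK_WINDOW_BP
    ci_level: float = DEFAULT_CI_LEVEL
    # pre-labeling and classification
    prelabel_cnt_threshold: int = DEFAULT_CNT_THRESHOLD
    classifier: str = "naive_bayes"
    threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_dir(cls, cohort_dir: str | Path, **overrides) -> "RunConfig":
        """Configuration for a directory laid out by the simulator."""
        d = Path(cohort_dir)
        return cls(
            vcf_paths=[str(p) for p in sorted(d.glob("sample_*.vcf"))],
            genome=str(d / "genome.fa"),
            cosmic=str(d / "cosmic.tsv"),
            dbsnp_common=str(d / "dbsnp_common.tsv"),
            dbsnp_rare=str(d / "dbsnp_rare.tsv"),
            exac=str(d / "exac.tsv"),
            impact=str(d / "impact.tsv"),
            **overrides,
        )

    def provenance(self) -> dict:
        return asdict(self)


@dataclass
class PreparedCohort:
    """Cohort after filtering, feature computation and collapsing."""

    cohort: CohortCallSet
    sources: AnnotationSources
    variants: list[UniqueVariant]


def prepare(config: RunConfig) -> PreparedCohort:
    """Run the deterministic front half of the pipeline."""
    sources = load_sources(
        somatic_catalogue=config.cosmic,
        common_poly=config.dbsnp_common,
        rare_poly=config.dbsnp_rare,
        population_exome=config.exac,
        impact=config.impact,
        genome=config.genome,
    )
    fc = FilterConfig(
        min_depth=config.min_depth,
        require_pass=config.require_pass,
        drop_homozygous=config.drop_homozygous,
        coding_only=config.coding_only,
        include_silent=config.include_silent,
    )
    cohort = read_cohort(config.vcf_paths, fc, sources.coding_table())
    logger.info(
        "filter: kept %d calls from %d samples; dropped %s",
        len(cohort.calls), cohort.n_samples, dict(cohort.filter_log),
    )
    check_chromosomes({c.chrom for c in cohort.calls}, sources)
    feats = compute_call_features(
        cohort.calls, sources.genome, sources.common_poly,
        window=config.flank_window_bp, ci_level=config.ci_level,
    )
    variants = collapse(cohort, feats, sources)
    logger.info("collapse: %d unique variants", len(variants))
    return PreparedCohort(cohort=cohort, sources=sources, variants=variants)


def split_prelabeled(
    variants: Sequence[UniqueVariant], cnt_threshold: int = DEFAULT_CNT_THRESHOLD
) -> tuple[list[UniqueVariant], list[UniqueVariant]]:
    """Apply pre-labeling; returns (prelabeled, to_classify).

    Pre-labeled variants get their prediction fields set (score 1 or 0,
    provenance 'prelabeled').
    """
    pre: list[UniqueVariant] = []
    rest: list[UniqueVariant] = []
    for v in variants:
        res = prelabel(v.ann, cnt_threshold)
        if res.decision == "unlabeled":
            rest.append(v)
        else:
            v.predicted_label = res.decision
            v.score = 1.0 if res.decision == "somatic" else 0.0
            v.provenance = "prelabeled"
            pre.append(v)
    logger.info("prelabel: %d prelabeled, %d to classify", len(pre), len(rest))
    return pre, rest


def train_on_samples(
    variants: Sequence[UniqueVariant],
    truth: dict[tuple, str],
    train_sample_ids: Sequence[str],
    kind: str = "naive_bayes",
    cnt_threshold: int = DEFAULT_CNT_THRESHOLD,
    seed: int = 0,
) -> clf.TrainedModel:
    """Train a classifier from truth labels restricted to the given samples.

    Only variants that survive pre-labeling contribute to training: the
    classifier models the residual distribution it will actually score.
    The training set is all somatic alleles called in the chosen samples
    plus an equal number of randomly selected germline alleles.
    """
    apply_truth(variants, truth)
    _, candidates = split_prelabeled([v for v in variants], cnt_threshold)
    labeled = [v for v in candidates if v.label in ("somatic", "germline")]
    training = clf.train_from_samples(labeled, train_sample_ids, seed=seed)
    matrix, labels = clf.build_matrix(training)
    return clf.train(
        kind, matrix, labels.to_numpy(dtype=object), seed=seed,
        provenance={"n_train_samples": len(train_sample_ids), "source": "cohort-truth"},
    )


def classify_variants(
    variants: Sequence[UniqueVariant],
    model: clf.TrainedModel,
    cnt_threshold: int = DEFAULT_CNT_THRESHOLD,
    threshold: float = 0.5,
) -> list[UniqueVariant]:
    """Pre-label then classify; every variant comes back with a prediction."""
    pre, rest = split_prelabeled(variants, cnt_threshold)
    if rest:
        matrix, _ = clf.build_matrix(rest)
        labels, scores = clf.predict(model, matrix, threshold=threshold)
        for v, lab, s in zip(rest, labels, scores):
            v.predicted_label = str(lab)
            v.score = float(s)
            v.provenance = "classified"
    assert not ({v.key for v in pre} & {v.key for v in rest})
    return list(pre) + list(rest)


def evaluate_holdout(
    prepared: PreparedCohort,
    truth: dict[tuple, str],
    n_train_samples: int,
    kind: str = "naive_bayes",
    cnt_threshold: int = DEFAULT_CNT_THRESHOLD,
    threshold: float = 0.5,
    seed: int = 0,
) -> dict:
    """Train on a random subset of samples, evaluate on held-out alleles.

    Held-out alleles are those never called in a training sample, so the
    evaluation set shares no allele with the training pool. Metrics are
    reported for the full pipeline (pre-labeled + classified) and for the
    classified subset alone.
    """
    rng = np.random.default_rng(seed)
    sample_ids = list(prepared.cohort.sample_ids)
    if n_train_samples >= len(sample_ids):
        raise ValueError("n_train_samples must leave at least one held-out sample")
    order = rng.permutation(len(sample_ids))
    train_ids = [sample_ids[i] for i in order[:n_train_samples]]
    train_set = set(train_ids)

    model = train_on_samples(
        prepared.variants, truth, train_ids, kind=kind,
        cnt_threshold=cnt_threshold, seed=int(rng.integers(2**31 - 1)),
    )
    held_out = [v for v in prepared.variants if not (v.sample_ids & train_set)]
    predicted = classify_variants(held_out, model, cnt_threshold, threshold)

    def report(subset: Sequence[UniqueVariant]) -> clf.MetricsReport:
        y_true = [truth[v.key] for v in subset]
        y_pred = [v.predicted_label for v in subset]
        scores = [v.score for v in subset]
        return clf.evaluate_predictions(y_true, y_pred, scores)

    classified_only = [v for v in predicted if v.provenance == "classified"]
    return {
        "model": model,
        "train_sample_ids": train_ids,
        "n_heldout_alleles": len(predicted),
        "pipeline": report(predicted),
        "classified_only": report(classified_only) if classified_only else None,
        "predicted": predicted,
    }


VAF_TIERS = ((0.0, 0.2), (0.2, 0.4), (0.4, 1.01))


def metrics_by_vaf_tier(
    predicted: Sequence[UniqueVariant], truth: dict[tuple, str]
) -> dict[str, clf.MetricsReport]:
    """Performance within mean-VAF tiers (low/subclonal, mid, clonal)."""
    out = {}
    for lo, hi in VAF_TIERS:
        subset = [v for v in predicted if lo <= v.mean_vaf < hi]
        if subset:
            out[f"[{lo:.1f},{min(hi, 1.0):.1f})"] = clf.evaluate_predictions(
                [truth[v.key] for v in subset],
                [v.predicted_label for v in subset],
                [v.score for v in subset],
            )
    return out
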