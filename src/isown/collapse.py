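"""Variant collapsing: total per-sample calls -> unique alleles.

A cohort's calls are merged by (chrom, pos, ref, alt) under the working
assumption that a given allele is either somatic or germline across all
samples. External annotations are shared by construction; the
per-sample VAFs are averaged, the flanking assessments are converted to
a fractional weight, and the sample frequency is the fraction of cohort
samples carrying the allele.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from isown.annotate import AnnotationRecord, AnnotationSources, annotate_allele
from isown.features import (
    GERMLINE_LIKE,
    NOT_APPLICABLE,
    SOMATIC_LIKE,
    CallFeatures,
)
from isown.variant_io import CohortCallSet


class CollapseError(Exception):
    """Fatal inconsistency in the cohort call set."""


@dataclass
class UniqueVariant:
    """One collapsed allele with its aggregated ten-feature evidence."""

    chrom: str
    pos: int
    ref: str
    alt: str
    n_samples_with_call: int
    sample_frequency: float
    mean_vaf: float
    flank_weight: Optional[float]
    ann: AnnotationRecord
    context: Optional[str]
    pattern: str
    sample_ids: frozenset = frozenset()
    label: str = "unlabeled"  # somatic | germline | unlabeled | excluded
    predicted_label: Optional[str] = None
    score: Optional[float] = None
    provenance: Optional[str] = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def flank_weight(assessments: Sequence[str]) -> Optional[float]:
    """Fraction of germline-like flanking assessments over all samples.

    not_applicable entries stay in the denominator; when every entry is
    not_applicable the weight itself is missing.
    """
    if not assessments:
        raise ValueError("assessments must be non-empty")
    if all(a == NOT_APPLICABLE for a in assessments):
        return None
    return sum(a == GERMLINE_LIKE for a in assessments) / len(assessments)


def resolve_label(truth_labels: Sequence[str]) -> str:
    """Unanimous per-sample truth label, or ``excluded`` when mixed.

    Mixed labels contradict the collapsing assumption; such alleles are
    dropped from training and from accuracy denominators.
    """
    if not truth_labels:
        raise ValueError("truth_labels must be non-empty")
    labels = set(truth_labels)
    if labels <= {"somatic", "germline"}:
        return truth_labels[0] if len(labels) == 1 else "excluded"
    raise ValueError(f"invalid labels {labels - {'somatic', 'germline'}}")


def collapse(
    cohort: CohortCallSet,
    per_call_features: Sequence[CallFeatures],
    sources: AnnotationSources,
) -> list[UniqueVariant]:
    """Collapse a cohort into unique variants with aggregated features.

    Conserves counts: the sum of ``n_samples_with_call`` over the output
    equals the number of input calls. Output order is genomic.
    """
    if len(per_call_features) != len(cohort.calls):
        raise CollapseError("features and calls are misaligned")
    ref_at: dict[tuple[str, int], str] = {}
    groups: dict[tuple, list[tuple]] = {}
    for call, feats in zip(cohort.calls, per_call_features):
        prev = ref_at.setdefault((call.chrom, call.pos), call.ref)
        if prev != call.ref:
            raise CollapseError(
                f"conflicting reference alleles at {call.chrom}:{call.pos}: {prev} vs {call.ref}"
            )
        groups.setdefault(call.key, []).append((call, feats))
    out: list[UniqueVariant] = []
    n = cohort.n_samples
    for key in sorted(groups):
        members = groups[key]
        chrom, pos, ref, alt = key
        vafs = [f.vaf for _, f in members]
        assessments = [f.flanking for _, f in members]
        contexts = [f.context for _, f in members if f.context is not None]
        out.append(
            UniqueVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                n_samples_with_call=len(members),
                sample_frequency=len(members) / n,
                mean_vaf=sum(vafs) / len(vafs),
                flank_weight=flank_weight(assessments),
                ann=annotate_allele(key, sources),
                context=contexts[0] if contexts else None,
                pattern=members[0][1].pattern,
                sample_ids=frozenset(c.sample_id for c, _ in members),
            )
        )
    return out


def apply_truth(
    variants: Sequence[UniqueVariant],
    truth: dict[tuple, str],
    calls_by_key: Optional[dict[tuple, list[str]]] = None,
) -> None:
    """Attach resolved truth labels in place.

    ``truth`` maps allele keys to a single label (allele-level truth) or,
    when ``calls_by_key`` carries per-sample labels, those are resolved
    with :func:`resolve_label`. Alleles without truth stay unlabeled.
    """
    for v in variants:
        if calls_by_key is not None and v.key in calls_by_key:
            v.label = resolve_label(calls_by_key[v.key])
        elif v.key in truth:
            v.label = truth[v.key]


_DUMP_COLUMNS = [
    "chrom", "pos", "ref", "alt", "n_samples_with_call", "sample_frequency",
    "mean_vaf", "flank_weight", "cnt", "in_exac", "in_dbsnp_common",
    "in_dbsnp_rare", "ma_category", "pp2_category", "context", "pattern", "label",
]


def write_collapsed(variants: Sequence[UniqueVariant], path: str | Path) -> None:
    """Dump the collapsed matrix as TSV (classifier interchange format)."""
    with Path(path).open("w") as handle:
        w = csv.writer(handle, delimiter="\t", lineterminator="\n")
        w.writerow(_DUMP_COLUMNS)
        for v in variants:
            w.writerow([
                v.chrom, v.pos, v.ref, v.alt, v.n_samples_with_call,
                f"{v.sample_frequency:.10g}", f"{v.mean_vaf:.10g}",
                "NA" if v.flank_weight is None else f"{v.flank_weight:.10g}",
                v.ann.cnt, int(v.ann.in_exac), int(v.ann.in_dbsnp_common),
                int(v.ann.in_dbsnp_rare), v.ann.ma_category, v.ann.pp2_category,
                v.context if v.context is not None else "NA", v.pattern, v.label,
            ])


def read_collapsed(path: str | Path) -> list[UniqueVariant]:
    """Read back a collapsed-matrix TSV."""
    out: list[UniqueVariant] = []
    with Path(path).open() as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            fw = row["flank_weight"]
            ctx = row["context"]
            out.append(
                UniqueVariant(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    n_samples_with_call=int(row["n_samples_with_call"]),
                    sample_frequency=float(row["sample_frequency"]),
                    mean_vaf=float(row["mean_vaf"]),
                    flank_weight=None if fw == "NA" else float(fw),
                    ann=AnnotationRecord(
                        cnt=int(row["cnt"]),
                        in_exac=bool(int(row["in_exac"])),
                        in_dbsnp_common=bool(int(row["in_dbsnp_common"])),
                        in_dbsnp_rare=bool(int(row["in_dbsnp_rare"])),
                        ma_category=row["ma_category"],
                        pp2_category=row["pp2_category"],
                    ),
                    context=None if ctx == "NA" else ctx,
                    pattern=row["pattern"],
                    label=row["label"],
                )
            )
    return out
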