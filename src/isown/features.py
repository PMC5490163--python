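"""Cohort-intrinsic per-call features.

Four features are computed from the calls themselves rather than from
external databases: the six-category substitution pattern, the
trinucleotide sequence context, the variant allele frequency (VAF), and
a flanking-region assessment that compares the binomial confidence
interval of a call's VAF with those of the nearest known common
polymorphisms in the same sample — a proxy for shared copy-number
context, since copy-number alterations are typically much larger than
the 2 Mbp search window.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.stats import beta as _beta

from isown.variant_io import BASES, VariantCall

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six pyrimidine-reference substitution categories
SUBSTITUTION_PATTERNS = ("CA", "CG", "CT", "TA", "TC", "TG")

GERMLINE_LIKE = "germline_like"
SOMATIC_LIKE = "somatic_like"
NOT_APPLICABLE = "not_applicable"

DEFAULT_FLANK_WINDOW_BP = 2_000_000
DEFAULT_CI_LEVEL = 0.95


def substitution_pattern(ref: str, alt: str) -> str:
    """Two-base substitution category with pyrimidine-reference normalization.

    Purine-reference substitutions are complemented onto the opposite
    strand, so all 12 ordered base pairs collapse to six categories
    (e.g. G>T maps to CA, A>G maps to TC).
    """
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in ("A", "G"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return ref + alt


def sequence_context(genome, chrom: str, pos: int) -> Optional[str]:
    """Forward-strand trinucleotide centred on ``pos`` (1-based).

    Returns None (missing) at chromosome ends or when the context
    contains a non-ACGT base. Unlike the substitution pattern the context
    is NOT strand-collapsed: all 64 trinucleotides are distinct levels.
    """
    if pos < 2:
        return None
    try:
        seq = str(genome[chrom][pos - 2 : pos + 1]).upper()
    except (KeyError, IndexError, ValueError):
        return None
    if len(seq) != 3 or any(b not in BASES for b in seq):
        return None
    return seq


def vaf(alt_count: int, depth: int) -> float:
    """Variant allele frequency: alt-supporting reads over total reads."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0 <= alt_count <= depth):
        raise ValueError("alt_count outside [0, depth]")
    return alt_count / depth


@dataclass(frozen=True)
class VafInterval:
    """Point VAF with an equal-tailed binomial confidence interval."""

    point: float
    lo: float
    hi: float
    level: float = DEFAULT_CI_LEVEL

    def overlaps(self, other: "VafInterval") -> bool:
        # closed-interval overlap
        return self.lo <= other.hi and other.lo <= self.hi


def binomial_ci(successes: int, trials: int, level: float = DEFAULT_CI_LEVEL) -> VafInterval:
    """Exact (Clopper-Pearson) equal-tailed binomial interval.

    lo = 0 when successes = 0 and hi = 1 when successes = trials, by
    convention of the exact interval.
    """
    if trials < 1 or not (0 <= successes <= trials):
        raise ValueError(f"invalid counts ({successes}, {trials})")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(_beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(_beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return VafInterval(point=successes / trials, lo=lo, hi=hi, level=level)


def flanking_decision(
    x: VafInterval,
    v1: Optional[VafInterval],
    v2: Optional[VafInterval],
) -> str:
    """Classify a call's VAF interval against its two flanking common SNPs.

    Both flanks found and both overlap x -> germline_like; x overlaps
    neither flank while the flanks overlap each other -> somatic_like;
    anything else (including a missing flank) -> not_applicable.
    """
    if v1 is None or v2 is None:
        return NOT_APPLICABLE
    if x.overlaps(v1) and x.overlaps(v2):
        return GERMLINE_LIKE
    if not x.overlaps(v1) and not x.overlaps(v2) and v1.overlaps(v2):
        return SOMATIC_LIKE
    return NOT_APPLICABLE


@dataclass(frozen=True)
class CallFeatures:
    """Intrinsic features of one per-sample call."""

    vaf: float
    ci: VafInterval
    pattern: str
    context: Optional[str]
    flanking: str  # germline_like | somatic_like | not_applicable


def _is_flank_candidate(call: VariantCall, common_poly: set) -> bool:
    # flanks must be known common polymorphisms called in the same sample;
    # homozygous calls are excluded because their VAF carries no dosage signal
    return call.key in common_poly and call.genotype_class != "hom"


def flanking_assessment(
    x: VariantCall,
    sample_calls: Sequence[VariantCall],
    common_poly: set,
    window: int = DEFAULT_FLANK_WINDOW_BP,
    ci_level: float = DEFAULT_CI_LEVEL,
) -> str:
    """Flanking assessment for a single call against its sample's call list.

    The 5' flank (V1) is the nearest qualifying call strictly upstream of
    x within ``window`` bp on the same chromosome; V2 likewise downstream.
    x itself never serves as its own flank.
    """
    up: Optional[VariantCall] = None
    down: Optional[VariantCall] = None
    for c in sample_calls:
        if c.chrom != x.chrom or (c.pos == x.pos and c.alt == x.alt and c.ref == x.ref):
            continue
        if not _is_flank_candidate(c, common_poly):
            continue
        if c.pos < x.pos and x.pos - c.pos <= window:
            if up is None or c.pos > up.pos:
                up = c
        elif c.pos > x.pos and c.pos - x.pos <= window:
            if down is None or c.pos < down.pos:
                down = c
    xi = binomial_ci(x.alt_count, x.depth, ci_level)
    v1 = binomial_ci(up.alt_count, up.depth, ci_level) if up is not None else None
    v2 = binomial_ci(down.alt_count, down.depth, ci_level) if down is not None else None
    return flanking_decision(xi, v1, v2)


def compute_call_features(
    calls: Sequence[VariantCall],
    genome,
    common_poly: set,
    window: int = DEFAULT_FLANK_WINDOW_BP,
    ci_level: float = DEFAULT_CI_LEVEL,
) -> list[CallFeatures]:
    """Compute intrinsic features for every call of a cohort.

    The flanking search is done per sample with position-sorted indexes,
    so cohorts of tens of thousands of calls stay fast. Ties at equal
    distance up/downstream resolve to the lower coordinate (handled
    naturally: the upstream candidate sits at the lower coordinate).
    """
    # per (sample, chrom): sorted positions of qualifying flank candidates
    flank_index: dict[tuple[str, str], tuple[list[int], list[VariantCall]]] = {}
    tmp: dict[tuple[str, str], list[VariantCall]] = {}
    for c in calls:
        if _is_flank_candidate(c, common_poly):
            tmp.setdefault((c.sample_id, c.chrom), []).append(c)
    for k, lst in tmp.items():
        lst.sort(key=lambda c: c.pos)
        flank_index[k] = ([c.pos for c in lst], lst)

    ci_cache: dict[tuple[int, int], VafInterval] = {}

    def ci_of(call: VariantCall) -> VafInterval:
        ck = (call.alt_count, call.depth)
        iv = ci_cache.get(ck)
        if iv is None:
            iv = binomial_ci(call.alt_count, call.depth, ci_level)
            ci_cache[ck] = iv
        return iv

    out: list[CallFeatures] = []
    for c in calls:
        positions, cands = flank_index.get((c.sample_id, c.chrom), ([], []))
        i = bisect.bisect_left(positions, c.pos)
        up = None
        j = i - 1
        while j >= 0:  # strictly upstream: skip co-located candidates
            cand = cands[j]
            if cand.pos < c.pos:
                up = cand if c.pos - cand.pos <= window else None
                break
            j -= 1
        down = None
        j = bisect.bisect_right(positions, c.pos)
        # calls at the same position (different alt) are neither up nor down
        while j < len(positions) and positions[j] == c.pos:
            j += 1
        if j < len(positions):
            cand = cands[j]
            if cand.pos - c.pos <= window:
                down = cand
        xi = ci_of(c)
        decision = flanking_decision(
            xi,
            ci_of(up) if up is not None else None,
            ci_of(down) if down is not None else None,
        )
        out.append(
            CallFeatures(
                vaf=vaf(c.alt_count, c.depth),
                ci=xi,
                pattern=substitution_pattern(c.ref, c.alt),
                context=sequence_context(genome, c.chrom, c.pos) if genome is not None else None,
                flanking=decision,
            )
        )
    return out


def impact_features(ann) -> tuple[str, str]:
    """Pass-through of the two impact categories of an annotation record."""
    return ann.ma_category, ann.pp2_category
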