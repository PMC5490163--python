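"""Cohort VCF ingestion, quality filtering, and prediction output.

Reads one single-sample VCF per tumor, applies the standard call-set
filters (SNV-only, PASS, minimum depth, optional homozygous and
coding/silent exclusion) and returns a clean :class:`CohortCallSet`.
Every dropped record is accounted for in a per-reason filter log, with
one primary reason per record checked in a fixed order.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

BASES = frozenset("ACGT")

#: order in which drop reasons are assigned; the first failing check wins
FILTER_ORDER = (
    "parse",
    "non-SNV",
    "N-ref",
    "non-PASS",
    "low-depth",
    "homozygous",
    "non-coding/silent",
)


class CohortError(Exception):
    """Fatal cohort-level configuration or data error."""


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample (1-based VCF coordinates)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    filter_status: str = "PASS"
    genotype_class: str = "unknown"  # het | hom | unknown

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT allele {self.ref}>{self.alt}")
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}]"
            )
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Call-set quality filters.

    ``min_depth`` is total read depth at the site (default 10x);
    ``require_pass`` honours the VCF FILTER column; ``drop_homozygous``
    removes homozygous-alt calls (a dataset-consistency option, off by
    default); ``coding_only``/``include_silent`` control the functional
    filter applied when a coding-effect table is supplied.
    """

    min_depth: int = 10
    require_pass: bool = True
    drop_homozygous: bool = False
    coding_only: bool = True
    include_silent: bool = False

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise CohortError("min_depth must be >= 1")


@dataclass
class CohortCallSet:
    calls: list[VariantCall]
    sample_ids: list[str]
    filter_log: Counter = field(default_factory=Counter)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def calls_by_sample(self) -> dict[str, list[VariantCall]]:
        out: dict[str, list[VariantCall]] = {s: [] for s in self.sample_ids}
        for c in self.calls:
            out[c.sample_id].append(c)
        return out


def is_snv(ref: str, alt: str) -> bool:
    """True iff both alleles are single bases in {A,C,G,T}."""
    return len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES


def _genotype_class(record: "pysam.VariantRecord", sample: str) -> str:
    try:
        gt = record.samples[sample].get("GT")
    except (KeyError, ValueError):
        return "unknown"
    if gt is None or any(a is None for a in gt) or len(gt) < 2:
        return "unknown"
    alleles = set(gt)
    if len(alleles) == 1 and 0 not in alleles:
        return "hom"
    if len(alleles) > 1:
        return "het"
    return "unknown"


def _depths(record: "pysam.VariantRecord", sample: str) -> Optional[tuple[int, int]]:
    """(total depth, alt depth); depth is the AD sum when AD is present."""
    fmt = record.samples[sample]
    ad = fmt.get("AD")
    if ad is not None and len(ad) >= 2 and all(a is not None for a in ad):
        return int(sum(ad)), int(ad[1])
    return None


def _drop_reason(
    record: "pysam.VariantRecord",
    sample: str,
    config: FilterConfig,
    coding_table: Optional[Mapping[tuple[str, int, str, str], str]],
) -> Optional[str]:
    if record.ref is None or record.alts is None or len(record.alts) != 1:
        # multi-allelic records are excluded rather than decomposed
        return "non-SNV" if record.ref is not None and record.alts else "parse"
    ref, alt = record.ref.upper(), record.alts[0].upper()
    if len(ref) != 1 or len(alt) != 1:
        return "non-SNV"
    if ref == "N":
        return "N-ref"
    if ref not in BASES or alt not in BASES:
        return "non-SNV"
    if config.require_pass:
        filters = set(record.filter.keys())
        if filters and filters != {"PASS"}:
            return "non-PASS"
    d = _depths(record, sample)
    if d is None:
        dp = record.samples[sample].get("DP")
        if dp is None:
            return "parse"
        d = (int(dp), 0)
    depth, _ = d
    if depth < config.min_depth:
        return "low-depth"
    if config.drop_homozygous and _genotype_class(record, sample) == "hom":
        return "homozygous"
    if config.coding_only and coding_table is not None:
        effect = coding_table.get((record.chrom, record.pos, ref, alt), "unknown")
        if effect == "unknown":
            return "non-coding/silent"
        if effect == "silent" and not config.include_silent:
            return "non-coding/silent"
    return None


def read_cohort(
    vcf_paths: Sequence[str | Path],
    config: FilterConfig = FilterConfig(),
    coding_table: Optional[Mapping[tuple[str, int, str, str], str]] = None,
) -> CohortCallSet:
    """Read per-sample VCFs, filter, and assemble the cohort call set.

    ``coding_table`` maps (chrom, pos, ref, alt) to a coding effect in
    {nonsilent, silent, stopgain, stoploss, unknown}; when supplied and
    ``config.coding_only`` is set, silent (unless ``include_silent``)
    and unknown-effect records are dropped.
    """
    calls: list[VariantCall] = []
    sample_ids: list[str] = []
    log: Counter = Counter()
    seen: set[str] = set()
    for path in vcf_paths:
        path = Path(path)
        if not path.exists():
            raise CohortError(f"unreadable VCF: {path}")
        try:
            vf = pysam.VariantFile(str(path))
        except (OSError, ValueError) as exc:
            raise CohortError(f"unreadable VCF: {path}: {exc}") from exc
        with vf:
            names = list(vf.header.samples)
            sample = names[0] if names else path.stem
            if sample in seen:
                raise CohortError(f"duplicate sample id: {sample}")
            seen.add(sample)
            sample_ids.append(sample)
            for record in vf:
                reason = _drop_reason(record, sample, config, coding_table)
                if reason is not None:
                    log[reason] += 1
                    continue
                depth, alt_count = _depths(record, sample)
                calls.append(
                    VariantCall(
                        sample_id=sample,
                        chrom=record.chrom,
                        pos=record.pos,
                        ref=record.ref.upper(),
                        alt=record.alts[0].upper(),
                        depth=depth,
                        alt_count=alt_count,
                        filter_status=";".join(record.filter.keys()) or "PASS",
                        genotype_class=_genotype_class(record, sample),
                    )
                )
    return CohortCallSet(calls=calls, sample_ids=sample_ids, filter_log=log)


_TSV_HEADER = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "predicted_label",
    "score",
    "provenance",
    "n_samples_with_call",
]


def write_predictions(variants: Iterable, path: str | Path, format: str = "tsv") -> None:
    """Write predicted unique variants as TSV or a minimal sites-only VCF.

    Each variant must carry ``predicted_label`` in {somatic, germline},
    ``score`` in [0, 1], and ``provenance`` in {prelabeled, classified}.
    """
    path = Path(path)
    variants = list(variants)
    for v in variants:
        if v.predicted_label not in ("somatic", "germline"):
            raise ValueError(f"missing or invalid prediction on {v.key}")
        if not (0.0 <= v.score <= 1.0):
            raise ValueError(f"score outside [0,1] on {v.key}")
        if v.provenance not in ("prelabeled", "classified"):
            raise ValueError(f"invalid provenance on {v.key}")
    try:
        handle = path.open("w")
    except OSError as exc:
        raise CohortError(f"unwritable output path: {path}: {exc}") from exc
    with handle:
        if format == "tsv":
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(_TSV_HEADER)
            for v in variants:
                writer.writerow(
                    [v.chrom, v.pos, v.ref, v.alt, v.predicted_label,
                     f"{v.score:.6f}", v.provenance, v.n_samples_with_call]
                )
        elif format == "vcf":
            handle.write("##fileformat=VCFv4.2\n")
            handle.write('##INFO=<ID=ISOWN_LABEL,Number=1,Type=String,Description="Predicted origin">\n')
            handle.write('##INFO=<ID=ISOWN_SCORE,Number=1,Type=Float,Description="Somatic score">\n')
            handle.write('##INFO=<ID=ISOWN_SRC,Number=1,Type=String,Description="prelabeled or classified">\n')
            handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
                info = (
                    f"ISOWN_LABEL={v.predicted_label};"
                    f"ISOWN_SCORE={v.score:.6f};ISOWN_SRC={v.provenance}"
                )
                handle.write(
                    f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\n"
                )
        else:
            raise ValueError(f"unknown output format: {format}")


def read_predictions(path: str | Path) -> list[dict]:
    """Read back a TSV prediction file (round-trip counterpart)."""
    rows = []
    with Path(path).open() as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            rows.append(
                {
                    "chrom": row["chrom"],
                    "pos": int(row["pos"]),
                    "ref": row["ref"],
                    "alt": row["alt"],
                    "predicted_label": row["predicted_label"],
                    "score": float(row["score"]),
                    "provenance": row["provenance"],
                    "n_samples_with_call": int(row["n_samples_with_call"]),
                }
            )
    return rows
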