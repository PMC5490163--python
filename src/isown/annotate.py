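"""External-evidence annotation of variant alleles.

Five position-keyed evidence sources are consumed as pre-extracted TSV
tables: a somatic catalogue with per-variant tumor-sample counts (CNT),
common- and rare-polymorphism sets, a population-exome set, and a
functional-impact table (conservation-based 4-level impact, a 3-level
missense-damage predictor, and the coding effect). Absence from a source
is itself a valid annotation state.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

AlleleKey = tuple[str, int, str, str]

MA_LEVELS = ("high", "medium", "low", "neutral", "stopgain", "stoploss", "missing")
PP2_LEVELS = ("probably_damaging", "possibly_damaging", "benign", "missing")
EFFECTS = ("nonsilent", "silent", "stopgain", "stoploss", "unknown")


class AnnotationError(Exception):
    """Fatal annotation-table parse or consistency error."""


@dataclass(frozen=True)
class AnnotationRecord:
    """External-database evidence for one allele.

    ``cnt`` is the somatic-catalogue tumor-sample count (0 means the
    allele is absent from the catalogue). Stop-gain/stop-loss effects are
    mutually exclusive with the four conservation-impact levels and are
    carried as extra categories of ``ma_category``.
    """

    cnt: int = 0
    in_exac: bool = False
    in_dbsnp_common: bool = False
    in_dbsnp_rare: bool = False
    ma_category: str = "missing"
    pp2_category: str = "missing"
    coding_effect: str = "unknown"

    def __post_init__(self) -> None:
        if self.cnt < 0:
            raise ValueError("cnt must be >= 0")
        if self.ma_category not in MA_LEVELS:
            raise ValueError(f"unknown ma_category {self.ma_category!r}")
        if self.pp2_category not in PP2_LEVELS:
            raise ValueError(f"unknown pp2_category {self.pp2_category!r}")


@dataclass
class AnnotationSources:
    """Allele-keyed evidence maps (1-based coordinates throughout)."""

    somatic_catalogue: dict[AlleleKey, int] = field(default_factory=dict)
    common_poly: set[AlleleKey] = field(default_factory=set)
    rare_poly: set[AlleleKey] = field(default_factory=set)
    population_exome: set[AlleleKey] = field(default_factory=set)
    impact_tables: dict[AlleleKey, tuple[str, str, str]] = field(default_factory=dict)
    genome: Optional[object] = None  # pyfaidx.Fasta-like accessor

    def coding_table(self) -> dict[AlleleKey, str]:
        """(chrom,pos,ref,alt) -> coding effect, stop-gain/loss collapse to nonsilent."""
        out = {}
        for key, (_, _, effect) in self.impact_tables.items():
            out[key] = "nonsilent" if effect in ("stopgain", "stoploss") else effect
        return out


def _read_table(path: str | Path, value_cols: tuple[str, ...]) -> list[tuple[AlleleKey, tuple]]:
    rows: list[tuple[AlleleKey, tuple]] = []
    with Path(path).open() as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = ("chrom", "pos", "ref", "alt") + value_cols
        if reader.fieldnames is None or any(c not in reader.fieldnames for c in required):
            raise AnnotationError(
                f"{path}: header must contain {', '.join(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (row["chrom"], int(row["pos"]), row["ref"].upper(), row["alt"].upper())
                values = tuple(row[c] for c in value_cols)
            except (KeyError, TypeError, ValueError) as exc:
                raise AnnotationError(f"{path}:{lineno}: malformed row: {exc}") from exc
            rows.append((key, values))
    return rows


def load_sources(
    somatic_catalogue: Optional[str | Path] = None,
    common_poly: Optional[str | Path] = None,
    rare_poly: Optional[str | Path] = None,
    population_exome: Optional[str | Path] = None,
    impact: Optional[str | Path] = None,
    genome: Optional[str | Path] = None,
) -> AnnotationSources:
    """Load annotation sources from TSV tables and an indexed FASTA.

    Lookups are exact-match on (chrom, pos, ref, alt); keys absent from a
    table yield the "absent" defaults (cnt 0, flags false, categories
    missing).
    """
    src = AnnotationSources()
    if somatic_catalogue is not None:
        for key, (cnt,) in _read_table(somatic_catalogue, ("cnt",)):
            try:
                src.somatic_catalogue[key] = int(cnt)
            except ValueError as exc:
                raise AnnotationError(f"{somatic_catalogue}: non-integer cnt {cnt!r}") from exc
    if common_poly is not None:
        src.common_poly = {key for key, _ in _read_table(common_poly, ())}
    if rare_poly is not None:
        src.rare_poly = {key for key, _ in _read_table(rare_poly, ())}
    if population_exome is not None:
        src.population_exome = {key for key, _ in _read_table(population_exome, ())}
    if impact is not None:
        for key, (ma, pp2, effect) in _read_table(impact, ("ma", "pp2", "effect")):
            if ma not in MA_LEVELS or pp2 not in PP2_LEVELS or effect not in EFFECTS:
                raise AnnotationError(
                    f"{impact}: invalid impact categories {(ma, pp2, effect)} at {key}"
                )
            src.impact_tables[key] = (ma, pp2, effect)
    if genome is not None:
        import pyfaidx

        src.genome = pyfaidx.Fasta(str(genome))
    return src


def check_chromosomes(vcf_chroms: set[str], sources: AnnotationSources) -> None:
    """Fail fast when VCF and FASTA chromosome names do not line up."""
    if sources.genome is None:
        return
    fasta_chroms = set(sources.genome.keys())
    missing = sorted(vcf_chroms - fasta_chroms)
    if missing:
        raise AnnotationError(
            f"chromosomes absent from reference FASTA: {', '.join(missing)}"
        )


def annotate_allele(key: AlleleKey, sources: AnnotationSources) -> AnnotationRecord:
    """Join one allele against all evidence sources.

    Pure function of (key, sources). Stop-gain/stop-loss coding effects
    override the conservation-impact category (the two are mutually
    exclusive by construction of the upstream annotators).
    """
    cnt = sources.somatic_catalogue.get(key, 0)
    ma, pp2, effect = sources.impact_tables.get(key, ("missing", "missing", "unknown"))
    if effect in ("stopgain", "stoploss"):
        ma_category = effect
        coding_effect = "nonsilent"
    else:
        ma_category = ma
        coding_effect = effect
    return AnnotationRecord(
        cnt=cnt,
        in_exac=key in sources.population_exome,
        in_dbsnp_common=key in sources.common_poly,
        in_dbsnp_rare=key in sources.rare_poly,
        ma_category=ma_category,
        pp2_category=pp2,
        coding_effect=coding_effect,
    )
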