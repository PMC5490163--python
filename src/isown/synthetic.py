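"""Self-contained synthetic cancer-cohort generator.

Emits everything the pipeline consumes — a reference genome, one VCF per
tumor sample, the five annotation tables, and allele-level truth labels —
with the statistical structure the classifier exploits:

* germline heterozygous VAFs centred at 0.5 (binomial read sampling),
  coherently shifted inside simulated copy-number segments;
* somatic VAFs subclonal (beta-distributed, default mean 0.25, scaled by
  tumor purity);
* common germline polymorphisms recurring across samples at their
  population frequencies (high sample frequency), somatic mutations
  mostly private, with a few recurrent hotspots;
* a heavy-tailed somatic-catalogue count (CNT) for a fraction of somatic
  alleles and a small germline "contamination" with low CNT;
* per-class skews in functional-impact categories and in the six
  substitution patterns.

Truth labels are allele-level, consistent across samples, matching the
variant-collapsing assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from isown.classify import ConfusionCounts
from isown.features import COMPLEMENT

BASES = "ACGT"


class SimulationConfigError(Exception):
    pass


def _pattern_of(ref: str, alt: str) -> str:
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return ref + alt


# per-class substitution-pattern weights over (CA, CG, CT, TA, TC, TG):
# somatic enriched in C>A/G>T, germline in T>C/A>G
SOMATIC_PATTERN_WEIGHTS = {
    "CA": 0.32, "CG": 0.08, "CT": 0.28, "TA": 0.08, "TC": 0.12, "TG": 0.12,
}
GERMLINE_PATTERN_WEIGHTS = {
    "CA": 0.08, "CG": 0.08, "CT": 0.30, "TA": 0.06, "TC": 0.38, "TG": 0.10,
}

# impact-category probabilities (ma levels incl. stopgain/stoploss; pp2)
SOMATIC_MA = {
    "high": 0.14, "medium": 0.28, "low": 0.20, "neutral": 0.25,
    "stopgain": 0.03, "stoploss": 0.01, "missing": 0.09,
}
GERMLINE_MA = {
    "high": 0.03, "medium": 0.14, "low": 0.25, "neutral": 0.42,
    "stopgain": 0.002, "stoploss": 0.001, "missing": 0.157,
}
SOMATIC_PP2 = {"probably_damaging": 0.40, "possibly_damaging": 0.25, "benign": 0.25, "missing": 0.10}
GERMLINE_PP2 = {"probably_damaging": 0.10, "possibly_damaging": 0.15, "benign": 0.60, "missing": 0.15}


@dataclass(frozen=True)
class CohortConfig:
    """Simulation parameters; the defaults are the package's reference
    study conditions (50 tumor-only exomes, roughly 9:1 germline:somatic
    calls per sample, 100x mean depth)."""

    seed: int = 0
    n_samples: int = 50
    n_chromosomes: int = 4
    chrom_length: int = 1_000_000
    # germline structure
    common_pool_size: int = 3000
    common_freq_alpha: float = 1.2
    common_freq_beta: float = 6.0
    rare_per_sample: float = 40.0
    # somatic structure
    somatic_per_sample: float = 60.0
    n_hotspots: int = 15
    hotspot_carrier_prob: float = 0.08
    somatic_vaf_mean: float = 0.25
    somatic_vaf_concentration: float = 12.0
    purity: float = 1.0
    # sequencing
    depth_mean: float = 100.0
    depth_dispersion: float = 20.0
    non_pass_rate: float = 0.01
    # copy-number segments shifting germline allele fractions coherently
    cn_segment_fraction: float = 0.15
    cn_segment_length: int = 150_000
    # somatic-catalogue counts
    somatic_cnt_positive_frac: float = 0.30
    somatic_high_cnt_frac: float = 0.05
    high_cnt_min: int = 100
    high_cnt_max: int = 2000
    germline_cnt_contamination: float = 0.02
    # database coverage / contamination
    dbsnp_common_coverage: float = 0.90
    dbsnp_rare_coverage: float = 0.80
    somatic_dbsnp_rare_frac: float = 0.02
    exac_common_coverage: float = 0.95
    exac_rare_coverage: float = 0.50
    somatic_exac_frac: float = 0.02
    # coding effect
    silent_frac_germline: float = 0.08
    silent_frac_somatic: float = 0.05
    unknown_effect_frac: float = 0.02

    def validate(self) -> None:
        usable = self.n_chromosomes * (self.chrom_length - 2)
        expected = (
            self.common_pool_size
            + self.n_hotspots
            + int(2.0 * self.n_samples * (self.rare_per_sample + self.somatic_per_sample))
        )
        if expected > usable // 2:
            raise SimulationConfigError(
                f"allele pool (~{expected}) too large for genome ({usable} usable positions)"
            )
        for name in (
            "purity", "non_pass_rate", "cn_segment_fraction", "somatic_cnt_positive_frac",
            "somatic_high_cnt_frac", "germline_cnt_contamination", "dbsnp_common_coverage",
            "dbsnp_rare_coverage", "somatic_dbsnp_rare_frac", "exac_common_coverage",
            "exac_rare_coverage", "somatic_exac_frac", "silent_frac_germline",
            "silent_frac_somatic", "unknown_effect_frac",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationConfigError(f"{name}={v} outside [0, 1]")
        if self.rare_per_sample < 0 or self.somatic_per_sample < 0:
            raise SimulationConfigError("per-sample rates must be >= 0")


@dataclass
class Allele:
    chrom: str
    pos: int
    ref: str
    alt: str
    label: str  # somatic | germline
    cnt: int = 0
    in_dbsnp_common: bool = False
    in_dbsnp_rare: bool = False
    in_exac: bool = False
    ma: str = "missing"
    pp2: str = "missing"
    effect: str = "nonsilent"  # nonsilent | silent | stopgain | stoploss; or omitted
    effect_known: bool = True
    pop_freq: float = 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimTruth:
    """Ground truth for one simulated cohort."""

    labels: dict[tuple, str]
    alleles: dict[tuple, Allele]
    calls_by_sample: dict[str, list[tuple]]
    config: CohortConfig

    def n_class(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)


@dataclass
class SimulatedCohort:
    outdir: Path
    genome_path: Path
    vcf_paths: list[Path]
    table_paths: dict[str, Path]
    truth: SimTruth


def _choose_alt(rng: np.random.Generator, ref: str, weights: dict[str, float]) -> str:
    alts = [b for b in BASES if b != ref]
    w = np.array([weights[_pattern_of(ref, a)] for a in alts], dtype=float)
    w /= w.sum()
    return alts[rng.choice(3, p=w)]


def _choose_cat(rng: np.random.Generator, probs: dict[str, float]) -> str:
    names = list(probs)
    p = np.array([probs[n] for n in names], dtype=float)
    p /= p.sum()
    return names[rng.choice(len(names), p=p)]


def _nbinom_depth(rng: np.random.Generator, mean: float, r: float, size: int) -> np.ndarray:
    p = r / (r + mean)
    return np.maximum(rng.negative_binomial(r, p, size=size), 1)


def simulate_cohort(config: CohortConfig, outdir: str | Path) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``outdir``.

    Writes genome.fa, sample_###.vcf, cosmic.tsv, dbsnp_common.tsv,
    dbsnp_rare.tsv, exac.tsv, impact.tsv, truth.tsv and config.json.
    Identical (config, outdir contents) for identical seeds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {
        c: "".join(np.array(list(BASES))[rng.integers(0, 4, size=config.chrom_length)])
        for c in chroms
    }

    # copy-number segments: contiguous blocks where germline allele
    # fractions shift to 1/3 or 2/3 (one-copy gain/loss of the other allele)
    cn_segments: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chroms}
    for c in chroms:
        covered = 0
        target = config.cn_segment_fraction * config.chrom_length
        while covered < target:
            start = int(rng.integers(1, config.chrom_length - config.cn_segment_length))
            af = 1 / 3 if rng.random() < 0.5 else 2 / 3
            cn_segments[c].append((start, start + config.cn_segment_length, af))
            covered += config.cn_segment_length

    def cn_af(chrom: str, pos: int) -> Optional[float]:
        for start, end, af in cn_segments[chrom]:
            if start <= pos < end:
                return af
        return None

    # one global pool of distinct positions, assigned on demand
    n_positions = (
        config.common_pool_size
        + config.n_hotspots
        + int(3 * config.n_samples * (config.rare_per_sample + config.somatic_per_sample))
        + 1000
    )
    per_chrom = n_positions // len(chroms) + 1
    position_pool: list[tuple[str, int]] = []
    for c in chroms:
        pos = rng.choice(np.arange(2, config.chrom_length), size=min(per_chrom, config.chrom_length - 3), replace=False)
        position_pool.extend((c, int(p)) for p in pos)
    rng.shuffle(position_pool)
    pool_iter = iter(position_pool)

    def new_allele(label: str) -> Allele:
        try:
            chrom, pos = next(pool_iter)
        except StopIteration:  # pragma: no cover - guarded by validate()
            raise SimulationConfigError("position pool exhausted")
        ref = genome[chrom][pos - 1]
        weights = SOMATIC_PATTERN_WEIGHTS if label == "somatic" else GERMLINE_PATTERN_WEIGHTS
        alt = _choose_alt(rng, ref, weights)
        return Allele(chrom=chrom, pos=pos, ref=ref, alt=alt, label=label)

    def decorate(a: Allele) -> None:
        """Draw annotation memberships and impact categories for one allele."""
        silent_frac = (
            config.silent_frac_somatic if a.label == "somatic" else config.silent_frac_germline
        )
        if rng.random() < config.unknown_effect_frac:
            a.effect_known = False
        elif rng.random() < silent_frac:
            a.effect = "silent"
            a.ma, a.pp2 = "missing", "missing"
        else:
            ma = _choose_cat(rng, SOMATIC_MA if a.label == "somatic" else GERMLINE_MA)
            if ma in ("stopgain", "stoploss"):
                a.effect = ma
                a.ma = "missing"  # impact predictor ignores stop variants
                a.pp2 = "missing"
            else:
                a.effect = "nonsilent"
                a.ma = ma
                a.pp2 = _choose_cat(rng, SOMATIC_PP2 if a.label == "somatic" else GERMLINE_PP2)
        if a.label == "somatic":
            u = rng.random()
            if u < config.somatic_high_cnt_frac:
                a.cnt = int(rng.integers(config.high_cnt_min, config.high_cnt_max + 1))
            elif u < config.somatic_cnt_positive_frac:
                a.cnt = int(rng.geometric(0.35))
            a.in_dbsnp_rare = rng.random() < config.somatic_dbsnp_rare_frac
            a.in_exac = rng.random() < config.somatic_exac_frac
        else:
            if rng.random() < config.germline_cnt_contamination:
                a.cnt = int(rng.integers(1, 6))
            if a.pop_freq > 0:  # common-pool allele
                a.in_dbsnp_common = rng.random() < config.dbsnp_common_coverage
                a.in_exac = rng.random() < config.exac_common_coverage
            else:
                a.in_dbsnp_rare = rng.random() < config.dbsnp_rare_coverage
                a.in_exac = rng.random() < config.exac_rare_coverage

    # --- allele universes -------------------------------------------------
    common_pool: list[Allele] = []
    freqs = rng.beta(config.common_freq_alpha, config.common_freq_beta, size=config.common_pool_size)
    for f in freqs:
        a = new_allele("germline")
        a.pop_freq = float(f)
        decorate(a)
        common_pool.append(a)

    hotspots: list[Allele] = []
    for _ in range(config.n_hotspots):
        a = new_allele("somatic")
        decorate(a)
        if a.cnt < config.high_cnt_min and rng.random() < 0.5:
            # recurrent hotspots are often well catalogued
            a.cnt = int(rng.integers(config.high_cnt_min, config.high_cnt_max + 1))
        hotspots.append(a)

    sample_ids = [f"sample_{i:03d}" for i in range(config.n_samples)]
    alleles: dict[tuple, Allele] = {a.key: a for a in common_pool + hotspots}
    calls_by_sample: dict[str, list[tuple]] = {}

    # per-sample carriers
    vaf_a = config.somatic_vaf_mean * config.somatic_vaf_concentration
    vaf_b = (1 - config.somatic_vaf_mean) * config.somatic_vaf_concentration
    sample_records: dict[str, list[dict]] = {}
    for sid in sample_ids:
        records: list[dict] = []
        # common germline
        carry = rng.random(config.common_pool_size) < freqs
        carried = [common_pool[i] for i in np.flatnonzero(carry)]
        # rare (private) germline
        for _ in range(rng.poisson(config.rare_per_sample)):
            a = new_allele("germline")
            decorate(a)
            alleles[a.key] = a
            carried.append(a)
        germline_alleles = carried
        # somatic: private + hotspots
        somatic_alleles: list[Allele] = []
        for _ in range(rng.poisson(config.somatic_per_sample)):
            a = new_allele("somatic")
            decorate(a)
            alleles[a.key] = a
            somatic_alleles.append(a)
        for h in hotspots:
            if rng.random() < config.hotspot_carrier_prob:
                somatic_alleles.append(h)

        all_alleles = germline_alleles + somatic_alleles
        depths = _nbinom_depth(rng, config.depth_mean, config.depth_dispersion, len(all_alleles))
        for a, depth in zip(all_alleles, depths):
            if a.label == "germline":
                seg = cn_af(a.chrom, a.pos)
                af = 0.5 if seg is None else 0.5 + config.purity * (seg - 0.5)
            else:
                af = config.purity * float(rng.beta(vaf_a, vaf_b))
            alt_count = int(rng.binomial(depth, af))
            alt_count = min(max(alt_count, 1), int(depth))
            records.append(
                {
                    "allele": a,
                    "depth": int(depth),
                    "alt_count": alt_count,
                    "filter": "lowqual" if rng.random() < config.non_pass_rate else "PASS",
                    "gt": "0/1",
                }
            )
        records.sort(key=lambda r: (r["allele"].chrom, r["allele"].pos, r["allele"].alt))
        sample_records[sid] = records
        calls_by_sample[sid] = [r["allele"].key for r in records]

    # --- write files ------------------------------------------------------
    genome_path = outdir / "genome.fa"
    with genome_path.open("w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            seq = genome[c]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    vcf_paths: list[Path] = []
    for sid in sample_ids:
        path = outdir / f"{sid}.vcf"
        vcf_paths.append(path)
        with path.open("w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FILTER=<ID=lowqual,Description="Low quality call">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
            for c in chroms:
                fh.write(f"##contig=<ID={c},length={config.chrom_length}>\n")
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sid}\n")
            for r in sample_records[sid]:
                a = r["allele"]
                ad = f"{r['depth'] - r['alt_count']},{r['alt_count']}"
                fh.write(
                    f"{a.chrom}\t{a.pos}\t.\t{a.ref}\t{a.alt}\t.\t{r['filter']}\t.\t"
                    f"GT:DP:AD\t{r['gt']}:{r['depth']}:{ad}\n"
                )

    def write_table(name: str, rows: list[list], header: list[str]) -> Path:
        path = outdir / name
        with path.open("w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in sorted(rows):
                fh.write("\t".join(str(x) for x in row) + "\n")
        return path

    ordered = sorted(alleles.values(), key=lambda a: a.key)
    table_paths = {
        "cosmic": write_table(
            "cosmic.tsv",
            [[a.chrom, a.pos, a.ref, a.alt, a.cnt] for a in ordered if a.cnt > 0],
            ["chrom", "pos", "ref", "alt", "cnt"],
        ),
        "dbsnp_common": write_table(
            "dbsnp_common.tsv",
            [[a.chrom, a.pos, a.ref, a.alt] for a in ordered if a.in_dbsnp_common],
            ["chrom", "pos", "ref", "alt"],
        ),
        "dbsnp_rare": write_table(
            "dbsnp_rare.tsv",
            [[a.chrom, a.pos, a.ref, a.alt] for a in ordered if a.in_dbsnp_rare],
            ["chrom", "pos", "ref", "alt"],
        ),
        "exac": write_table(
            "exac.tsv",
            [[a.chrom, a.pos, a.ref, a.alt] for a in ordered if a.in_exac],
            ["chrom", "pos", "ref", "alt"],
        ),
        "impact": write_table(
            "impact.tsv",
            [
                [a.chrom, a.pos, a.ref, a.alt, a.ma, a.pp2, a.effect]
                for a in ordered
                if a.effect_known
            ],
            ["chrom", "pos", "ref", "alt", "ma", "pp2", "effect"],
        ),
        "truth": write_table(
            "truth.tsv",
            [[a.chrom, a.pos, a.ref, a.alt, a.label] for a in ordered],
            ["chrom", "pos", "ref", "alt", "label"],
        ),
    }
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")

    truth = SimTruth(
        labels={a.key: a.label for a in ordered},
        alleles=alleles,
        calls_by_sample=calls_by_sample,
        config=config,
    )
    return SimulatedCohort(
        outdir=outdir,
        genome_path=genome_path,
        vcf_paths=vcf_paths,
        table_paths=table_paths,
        truth=truth,
    )


def load_truth(path: str | Path) -> dict[tuple, str]:
    """Read a truth.tsv back into an allele-key -> label map."""
    import csv

    out: dict[tuple, str] = {}
    with Path(path).open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[(row["chrom"], int(row["pos"]), row["ref"], row["alt"])] = row["label"]
    return out


def truth_confusion(predictions: dict[tuple, str], truth: SimTruth | dict) -> ConfusionCounts:
    """Allele-level confusion counts of predictions against simulated truth
    (somatic = positive). Alleles labeled ``excluded`` are omitted.
    """
    labels = truth.labels if isinstance(truth, SimTruth) else truth
    tp = fp = tn = fn = 0
    for key, pred in predictions.items():
        true = labels.get(key)
        if true is None:
            raise KeyError(f"prediction for allele absent from truth: {key}")
        if pred == "excluded" or true == "excluded":
            continue
        if true == "somatic":
            if pred == "somatic":
                tp += 1
            else:
                fn += 1
        else:
            if pred == "somatic":
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
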