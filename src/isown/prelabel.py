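"""Deterministic pre-labeling rules that bypass machine learning.

Two rules resolve the easy cases before classification: alleles present
in the common-polymorphism set but absent from the somatic catalogue are
germline; alleles recorded in many catalogue tumor samples (CNT at or
above a threshold, default 100) are somatic. Pre-labeled alleles never
reach the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

from isown.annotate import AnnotationRecord

DEFAULT_CNT_THRESHOLD = 100


class PrelabelConfigError(Exception):
    pass


@dataclass(frozen=True)
class PrelabelResult:
    decision: str  # germline | somatic | unlabeled
    rule: str  # dbsnp_not_cosmic | high_cnt | none

    def __post_init__(self) -> None:
        valid = {
            ("germline", "dbsnp_not_cosmic"),
            ("somatic", "high_cnt"),
            ("unlabeled", "none"),
        }
        if (self.decision, self.rule) not in valid:
            raise ValueError(f"inconsistent result {(self.decision, self.rule)}")


def prelabel(ann: AnnotationRecord, cnt_threshold: int = DEFAULT_CNT_THRESHOLD) -> PrelabelResult:
    """Apply the two pre-labeling rules to one annotated allele.

    The rules are disjoint: the germline rule requires complete absence
    from the somatic catalogue (cnt = 0), so no allele can satisfy both.
    """
    if cnt_threshold < 1:
        raise PrelabelConfigError("cnt_threshold must be >= 1")
    if ann.cnt >= cnt_threshold:
        return PrelabelResult("somatic", "high_cnt")
    if ann.in_dbsnp_common and ann.cnt == 0:
        return PrelabelResult("germline", "dbsnp_not_cosmic")
    return PrelabelResult("unlabeled", "none")
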