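import pytest

from isown.annotate import AnnotationRecord
from isown.collapse import UniqueVariant
from isown.synthetic import CohortConfig, simulate_cohort


def make_variant(
    chrom="chr1",
    pos=100,
    ref="C",
    alt="T",
    n_samples_with_call=1,
    sample_frequency=0.1,
    mean_vaf=0.3,
    flank_weight=None,
    ann=None,
    context="ACA",
    pattern="CT",
    sample_ids=frozenset({"s0"}),
    label="unlabeled",
):
    return UniqueVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        n_samples_with_call=n_samples_with_call,
        sample_frequency=sample_frequency,
        mean_vaf=mean_vaf,
        flank_weight=flank_weight,
        ann=ann or AnnotationRecord(),
        context=context,
        pattern=pattern,
        sample_ids=sample_ids,
        label=label,
    )


SMALL_CONFIG = CohortConfig(
    seed=7,
    n_samples=10,
    n_chromosomes=2,
    chrom_length=400_000,
    common_pool_size=600,
    rare_per_sample=15.0,
    somatic_per_sample=30.0,
)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """One small simulated cohort shared by tests that only read it."""
    outdir = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(SMALL_CONFIG, outdir)
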