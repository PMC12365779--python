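import pytest

import methylfollicle as mf


@pytest.fixture(scope="session")
def planted_cohort() -> mf.SimulatedCohort:
    """Default-sized cohort (10/4/10) with the standard planted truth."""
    cfg = mf.SimulationConfig(seed=11, planted_regions=mf.study_planted_regions())
    return mf.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def annotation_index(planted_cohort) -> mf.AnnotationIndex:
    return mf.AnnotationIndex(planted_cohort.islands, planted_cohort.genes)


def make_records(counts, group, sample_prefix="s", chrom="chr1"):
    """counts: {pos: [(meth, unmeth), ...]} one pair per sample."""
    records = []
    for pos, pairs in counts.items():
        for i, (m, u) in enumerate(pairs):
            records.append(
                mf.CpGRecord(chrom, pos, m, u, f"{sample_prefix}{i}", group)
            )
    return records
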