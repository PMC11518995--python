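import numpy as np
import pytest

from embryophylo.cohort import CohortTable, VariantSite
from embryophylo.quality import apply_quality_filters
from embryophylo.simulate import case_study_config, simulate_cohort

GOOD_QC = {"CLPM": 0.0, "ASMD": 160.0, "MAPQ": 60.0, "BASEQ": 37.0}


def make_site(chrom="1", pos=100, ref="A", alt="T", vclass="", qc=None):
    return VariantSite(
        chrom=chrom, pos=pos, ref=ref, alt=alt, variant_class=vclass,
        qc=dict(GOOD_QC if qc is None else qc),
    )


def make_table(n_sites, samples, alt, depth, qc=None):
    sites = [make_site(pos=100 + i, qc=qc) for i in range(n_sites)]
    return CohortTable(sites, samples, np.asarray(alt), np.asarray(depth))


@pytest.fixture(scope="session")
def case_study():
    """Packaged fixed-seed case-study cohort: (table, cn_profiles, truth)."""
    return simulate_cohort(case_study_config())


@pytest.fixture(scope="session")
def case_study_passed(case_study):
    table, _cn, _truth = case_study
    passed, _report = apply_quality_filters(table)
    return passed
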