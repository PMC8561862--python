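import numpy as np
import pandas as pd
import pytest

from gutload.datamodel import AbsoluteAbundanceTable, FeatureTable
from gutload.pipeline import quantify
from gutload.synthetic import CohortConfig, generate_cohort

COHORT_SEED = 7
PAIRED_SEED = 1


@pytest.fixture(scope="session")
def cohort():
    """Default 250-subject synthetic cohort (duodenum only, fixed seed)."""
    return generate_cohort(CohortConfig(n_paired_saliva=0), COHORT_SEED)


@pytest.fixture(scope="session")
def quantified(cohort):
    """The cohort pushed through the full measurement chain."""
    return quantify(cohort.duodenum_counts, cohort.dpcr_records, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def paired_cohort():
    """21 paired saliva-duodenum subjects (fixed seed)."""
    return generate_cohort(CohortConfig(n_subjects=21, n_paired_saliva=21), PAIRED_SEED)


@pytest.fixture(scope="session")
def paired_quantified(paired_cohort):
    duo = quantify(paired_cohort.duodenum_counts, paired_cohort.dpcr_records, seed=PAIRED_SEED)
    sal = quantify(paired_cohort.saliva_counts, paired_cohort.dpcr_records, seed=PAIRED_SEED)
    usable = {
        s: pair
        for s, pair in paired_cohort.subject_map.items()
        if pair[0] in set(duo.table.sample_ids) and pair[1] in set(sal.table.sample_ids)
    }
    return duo, sal, usable


def make_abs_table(loads: dict, lod_records=None, filtered=False) -> AbsoluteAbundanceTable:
    """Small absolute-abundance table from {sample: {taxon: load}}."""
    df = pd.DataFrame(loads).T.fillna(0.0).astype(float)
    return AbsoluteAbundanceTable(df, df.sum(axis=1), lod_records=lod_records, filtered=filtered)


def make_feature_table(counts: dict) -> FeatureTable:
    return FeatureTable(pd.DataFrame(counts).T.fillna(0).astype(int))
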