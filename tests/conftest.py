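"""Shared fixtures: scaled-down synthetic cohorts reused across the suite."""

import numpy as np
import pandas as pd
import pytest

import irlncpair as ip
from irlncpair.io import ExpressionMatrix

# one-cluster cohort with four planted pairs: the workhorse for signature tests
SMALL_KW = dict(n_tumour=250, n_normal=12, n_lncrna=60, n_immune_genes=30,
                n_other_genes=30, n_coexpressed_lnc=30, n_de_lnc_up=18,
                n_de_lnc_down=4, n_planted_pairs=4, planted_beta=0.8,
                n_clusters=1)


def surv_arrays(clinical: pd.DataFrame, ids=None):
    s = clinical.set_index("sample_id")
    if ids is not None:
        s = s.loc[list(ids)]
    return s["os_days"].to_numpy(float), s["os_event"].to_numpy(int)


@pytest.fixture(scope="session")
def small_bundle():
    return ip.generate_cohort(ip.CohortConfig(**SMALL_KW, seed=11))


@pytest.fixture(scope="session")
def small_expr(small_bundle):
    return ExpressionMatrix(small_bundle.expression, small_bundle.condition)


@pytest.fixture(scope="session")
def small_pairmatrix(small_bundle, small_expr):
    """Filtered pair matrix over the true DE genes (tumour samples)."""
    de = small_bundle.truth.de_lnc_ids_up + small_bundle.truth.de_lnc_ids_down
    pm = ip.encode_pairs(small_bundle.expression[small_expr.tumour_samples], de)
    return ip.filter_pairs(pm)


@pytest.fixture(scope="session")
def null_bundle():
    """No planted survival signal anywhere: betas 0, one cluster, no associations."""
    cfg = ip.CohortConfig(n_tumour=300, n_normal=12, n_lncrna=50,
                          n_immune_genes=25, n_other_genes=25,
                          n_coexpressed_lnc=25, n_de_lnc_up=14, n_de_lnc_down=4,
                          n_planted_pairs=0, n_clusters=1, clinical_assoc=0.0,
                          infiltration_assoc=0.0, drug_assoc=0.0, seed=21)
    return ip.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
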