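import numpy as np
import pytest

import sepsistypes as st


@pytest.fixture(scope="session")
def signal_cohort():
    """Default-scale two-subtype cohort with a strong (delta=3) contrast."""
    return st.generate_cohort(st.CohortSpec(seed=7, n_decoy_genes=30))


@pytest.fixture(scope="session")
def signal_matrix(signal_cohort):
    return st.impute_missing(signal_cohort.expression)


@pytest.fixture(scope="session")
def matched_pair():
    """Matched derivation/validation cohorts sharing one gene panel."""
    der_spec = st.CohortSpec(seed=7, n_decoy_genes=30)
    val_spec = st.CohortSpec(
        n_samples=71, subtype_proportion=0.35, missing_rate=0.05, seed=11, n_decoy_genes=30
    )
    return st.generate_cohort_pair(der_spec, val_spec)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-repetition discovery configuration used throughout the suite."""
    return st.DiscoveryConfig(
        n_reps=20, n_outer=20, n_inner=20, top_m=40, sam_permutations=100, seed=3
    )


@pytest.fixture(scope="session")
def discovery(matched_pair, fast_config):
    der, _ = matched_pair
    m = st.impute_missing(der.expression)
    return m, st.discover(m, der.sepsis_gene_list, fast_config)


@pytest.fixture
def four_points_distance():
    """1-D samples at 0, 1, 10, 11 — the classic two-tight-pairs instance."""
    pts = np.array([0.0, 1.0, 10.0, 11.0])
    return st.DistanceMatrix(np.abs(pts[:, None] - pts[None, :]))
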