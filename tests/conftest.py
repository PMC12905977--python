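import numpy as np
import pytest

from methylvar import (
    SimConfig,
    simulate_cohort,
    residualize_phenotype,
    residualize_and_standardize_markers,
)


def standardize_cols(A: np.ndarray) -> np.ndarray:
    """Plain column z-scores (ddof=1), the sampler's input convention."""
    A = np.asarray(A, dtype=float)
    return (A - A.mean(axis=0)) / A.std(axis=0, ddof=1)


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort shared by read-only tests (truth 0.25/0.55)."""
    cfg = SimConfig(n_individuals=600, n_probes=300, n_snps=400, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    """Residualized phenotype + standardized marker sets for the cohort."""
    d = small_cohort
    y = residualize_phenotype(d.phenotype, d.covariates)
    zm = residualize_and_standardize_markers(d.methylation, d.probe_ids, d.covariates)
    zg = residualize_and_standardize_markers(d.genotypes, d.snp_ids, None)
    return d, y, zm, zg
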