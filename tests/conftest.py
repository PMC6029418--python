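import numpy as np
import pytest

from mixpop.simulate import SyntheticConfig, generate_cohort, sample_mixture

# fitted trimodal parameters of the full-cohort index-gene distribution
TABLE1_ALL = {
    "weights": (0.26, 0.38, 0.36),
    "means": (6.25, 7.89, 10.58),
    "sds": (0.39, 1.12, 0.86),
    "amplitudes": (104.0, 54.0, 68.0),
    "sizes": (515.0, 752.0, 713.0),
}
TABLE1_ERPOS = {
    "amplitudes": (35.0, 49.0, 67.0),
    "sds": (0.37, 1.10, 0.84),
}


@pytest.fixture(scope="session")
def trimodal_sample():
    """n = 1980 draws from the trimodal mixture, with true labels."""
    return sample_mixture(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """Full synthetic cohort under default study conditions."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_truth():
    """True component labels matching ``default_cohort``."""
    values, labels = sample_mixture(SyntheticConfig(seed=11))
    return values, labels


@pytest.fixture(scope="session")
def small_null_cohort():
    """Small cohort with no real co-expression structure (null screen).

    ER status must be decoupled from the mixture component here: the ESR1
    analogue tracks ER status, so with the default ER model it correlates
    with the index gene and the cohort would not be null.
    """
    cfg = SyntheticConfig(
        n_patients=250,
        n_corr_genes_low=10,
        n_corr_genes_high=10,
        corr_strength=0.0,
        n_null_genes=80,
        er_model=(0.1, 0.1),
        seed=7,
    )
    return generate_cohort(cfg)
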