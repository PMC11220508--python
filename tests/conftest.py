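import numpy as np
import pytest

from mcifusion.synthetic import SyntheticConfig, generate_cohort, cohort_to_feature_matrices


@pytest.fixture(scope="session")
def planted_cohort():
    """Single-channel cohort with a strong planted effect (d=1.5, 10 ROIs)."""
    cfg = SyntheticConfig(
        n_subjects=400, frac_converted=0.5, visits_per_subject=1,
        modalities=("m1",), planted_rois={"m1": frozenset(range(10))},
        effect_size={"m1": 1.5}, frac_complete=1.0, seed=1,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_matrix(planted_cohort):
    return cohort_to_feature_matrices(planted_cohort)["m1"]


@pytest.fixture(scope="session")
def tiny_multimodal_cohort():
    """Small 4-modality cohort with missingness, for bookkeeping tests."""
    cfg = SyntheticConfig(
        n_subjects=80, frac_converted=0.4, visits_per_subject=2, n_rois=16,
        modalities=("smri-gm", "av45-cerebellum", "fdg-gm", "dti-md"),
        planted_rois={c: frozenset(range(6)) for c in
                      ("smri-gm", "av45-cerebellum", "fdg-gm", "dti-md")},
        effect_size={"smri-gm": 1.0, "av45-cerebellum": 1.4, "fdg-gm": 1.0, "dti-md": 0.4},
        frac_complete=0.5, missing_modality_rate=0.4, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
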