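import numpy as np
import pytest

from odvbm.grid import GridGeometry
from odvbm.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """12^3 cohort with a planted effect, shared across read-only tests."""
    cfg = SynthConfig(
        grid=GridGeometry.centered((12, 12, 12)),
        n_per_group=8,
        effect_size=0.15,
        noise_sigma=0.05,
        seed=11,
        n_sites=3,
    )
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture()
def labels_of():
    def _labels(cohort):
        return np.array([r.covariates.group for r in cohort], dtype=np.int8)

    return _labels
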