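import warnings

import numpy as np
import pytest

from octa_intereye import (CohortGenParams, ImageGenParams,
                           generate_angiogram_pair, generate_metrics_cohort)

# ETDRS grids built from annotated FAZ centroids routinely clip the 6-mm disc
# by a sub-pixel sliver; the warning is QC information, not a test failure.
warnings.filterwarnings("ignore", message="ETDRS 6-mm disc clipped")


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free synthetic eye pair with planted coverage 0.25 (session-wide)."""
    params = ImageGenParams(noise_sd=0.0, capillary_fraction=0.25, seed=7)
    right, left, truth_r, truth_l = generate_angiogram_pair(params)
    return params, right, left, truth_r, truth_l


@pytest.fixture(scope="session")
def small_pair():
    """Fast 250-px pair (6 mm at 0.024 mm/px) for pipeline-level tests."""
    params = ImageGenParams(image_size=250, pixel_pitch=0.024, big_vessel_width=3,
                            noise_sd=0.0, seed=11)
    right, left, truth_r, truth_l = generate_angiogram_pair(params)
    return params, right, left, truth_r, truth_l


@pytest.fixture(scope="session")
def default_cohort():
    """Metrics-level cohort at the default (study-like) generator settings."""
    return generate_metrics_cohort(CohortGenParams(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
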