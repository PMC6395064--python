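"""Shared fixtures: small, fast synthetic islets for unit tests."""

import numpy as np
import pytest

from isletquant import ImagingParams, StagePreset


@pytest.fixture
def small_preset() -> StagePreset:
    """A compact islet preset that renders in well under a second."""
    return StagePreset(
        name="test_small",
        n_cells_mean=10, n_cells_sd=0.0,
        frac_responsive_mantle=0.5, frac_responsive_core=0.5,
        amp_mean_mantle=1.0, amp_sd_mantle=0.2,
        amp_mean_core=1.0, amp_sd_core=0.2,
        vessel_penetration=0.5,
        onset_delay_mean=10.0, onset_delay_sd=3.0,
    )


@pytest.fixture
def fast_params() -> ImagingParams:
    return ImagingParams()


@pytest.fixture
def noise_free_params() -> ImagingParams:
    return ImagingParams(psf_sigma=(1e-12, 1e-12, 1e-12),
                         photon_scale=np.inf, read_noise_sd=0.0)


@pytest.fixture
def short_run():
    """Duration/stimulus pair for fast end-to-end runs."""
    return dict(duration=120.0, stim_time=20.0)
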