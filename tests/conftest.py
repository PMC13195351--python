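import numpy as np
import pytest

from gastromri import (
    AreaTimeCurve,
    PeristalsisTruth,
    RasterSpec,
    StudyDesign,
)


@pytest.fixture(scope="session")
def spec() -> RasterSpec:
    """Default acquisition raster (140x140 over 200x200 mm, 6.24 fps, 180 s)."""
    return RasterSpec()


@pytest.fixture(scope="session")
def tiny_design() -> StudyDesign:
    """A one-subject, one-arm design for fast end-to-end runs."""
    return StudyDesign(
        n_subjects=1,
        arms=("solid",),
        vol_timepoints_min=(-5, 3, 41, 61, 81),
        rt_timepoints_min=(7, 45),
        n_slices=3,
    )


@pytest.fixture
def clean_sinusoid_truth() -> PeristalsisTruth:
    """Noiseless 3 cpm sinusoid: baseline 600 mm², amplitude 120 mm²."""
    return PeristalsisTruth(
        f0_cpm=3.0,
        mean_area_mm2=600.0,
        amp_mm2=120.0,
        phase_rad=0.0,
        resp_amp_mm2=0.0,
        drift_mm2_per_s=0.0,
        noise_sd_mm2=0.0,
        seed=0,
    )


def on_bin_curve(
    f_hz: float = 0.05,
    fs: float = 5.0,
    duration_s: float = 180.0,
    mean: float = 600.0,
    amp: float = 120.0,
) -> AreaTimeCurve:
    """Sinusoid whose frequency sits exactly on a DFT bin (k = f * duration)."""
    n = int(round(duration_s * fs))
    assert abs(f_hz * n / fs - round(f_hz * n / fs)) < 1e-12, "not on a bin"
    t = np.arange(n) / fs
    areas = mean + amp * np.sin(2 * np.pi * f_hz * t)
    return AreaTimeCurve.from_areas(areas, fs)
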