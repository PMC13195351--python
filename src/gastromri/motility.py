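"""Spectral gastric-motility metrics from area-time curves.

The antral contraction frequency is read off the discrete amplitude
spectrum of a luminal area-time curve, restricted to the physiological
peristalsis band 0.03–0.07 Hz (1.8–4.2 contractions per minute, cpm).
A detected peak counts as genuine peristalsis only if it is *dominant*:

    dominance factor = peak in-band amplitude / mean in-band amplitude,

with validity threshold 2.0.  A subject × timepoint contributes a
frequency (and hence a velocity) only when at least two of the three
sagittal slices carry a valid peak.

From the frequency an *apparent propagation speed* follows from the
slice geometry alone, assuming one contraction wave traverses the
spatial extent spanned by the three slices per period:

    speed (mm/s) = frequency (cpm) / 60 × propagation distance (mm)
    propagation distance = 3 × slice thickness + 2 × inter-slice distance.

*Occlusion* quantifies luminal narrowing as a surrogate of contraction
amplitude: each frame's area is compared with a per-sequence reference,
the median of the top-10% largest areas,

    occlusion % = 100 × (1 − area / reference),  clipped below at 0%,

so a fully relaxed lumen scores 0% and complete antral closure 100%.

Numerical conventions (documented assumptions, the source measurements
being stated only to band/bin precision): curves are mean-removed and
linearly detrended before the FFT so that slow drift cannot leak into
the bins adjacent to the band; band membership is a bin-center test,
inclusive at both edges; no zero padding or peak interpolation is
applied by default, so the reported frequency is an exact bin center;
amplitude ties break toward the lower frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend

from .extraction import AreaTimeCurve

__all__ = [
    "Band",
    "SliceGeometry",
    "BandSpectrum",
    "SpectralResult",
    "OcclusionResult",
    "band_spectrum",
    "dominant_frequency",
    "timepoint_frequency",
    "apparent_speed",
    "occlusion_series",
]

#: tolerance for the inclusive bin-center band test (guards float rounding)
_EDGE_EPS = 1e-12


@dataclass(frozen=True)
class Band:
    """Peristalsis detection band in Hz (defaults: 0.03–0.07 Hz = 1.8–4.2 cpm)."""

    low_hz: float = 0.03
    high_hz: float = 0.07

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("require 0 < low_hz < high_hz")

    @property
    def low_cpm(self) -> float:
        return self.low_hz * 60.0

    @property
    def high_cpm(self) -> float:
        return self.high_hz * 60.0


@dataclass(frozen=True)
class SliceGeometry:
    """Sagittal slice geometry of the real-time acquisition.

    Three parallel slices of ``slice_thickness_mm`` are separated by a gap
    of ``distance_factor × thickness`` (the scanner's distance factor,
    adapted per subject within 1.5–3.0, i.e. gaps of 7.5–15 mm at 5 mm
    thickness).  The propagation distance is the full spatial extent
    spanned by the slices.
    """

    slice_thickness_mm: float = 5.0
    distance_factor: float = 2.5
    n_slices: int = 3

    def __post_init__(self) -> None:
        if not self.slice_thickness_mm > 0:
            raise ValueError("slice_thickness_mm must be positive")
        if not 0 < self.distance_factor:
            raise ValueError("distance_factor must be positive")
        if self.n_slices < 2:
            raise ValueError("need at least 2 slices")

    @property
    def inter_slice_distance_mm(self) -> float:
        return self.distance_factor * self.slice_thickness_mm

    @property
    def propagation_distance_mm(self) -> float:
        """3 × thickness + 2 × inter-slice distance (40 mm at 5 mm / factor 2.5)."""
        return 3.0 * self.slice_thickness_mm + 2.0 * self.inter_slice_distance_mm


@dataclass(frozen=True)
class BandSpectrum:
    """In-band discrete amplitude spectrum of one area-time curve."""

    freqs_hz: np.ndarray
    amplitudes: np.ndarray
    band: Band
    n_samples: int
    frame_rate_fps: float

    @property
    def n_band_bins(self) -> int:
        return len(self.freqs_hz)

    @property
    def bin_width_hz(self) -> float:
        return self.frame_rate_fps / self.n_samples


@dataclass(frozen=True)
class SpectralResult:
    """Dominant in-band frequency and its validity."""

    peak_freq_hz: float
    dominance_factor: float
    valid: bool
    threshold: float
    n_band_bins: int

    @property
    def peak_freq_cpm(self) -> float:
        return self.peak_freq_hz * 60.0


@dataclass(frozen=True)
class OcclusionResult:
    """Per-frame occlusion series and its per-sequence summary."""

    reference_area_mm2: float
    occlusion_pct: np.ndarray
    mean_occlusion_pct: float


def band_spectrum(curve: AreaTimeCurve, band: Band | None = None) -> BandSpectrum:
    """Discrete amplitude spectrum of ``curve`` restricted to ``band``.

    The curve is mean-removed and linearly detrended, then the one-sided
    amplitude spectrum ``2 |X_k| / n`` is evaluated at the bin frequencies
    ``k × frame_rate / n`` and the bins whose center lies in
    ``[low, high]`` (inclusive) are returned.
    """
    band = band or Band()
    n = len(curve)
    if n < 16:
        raise ValueError(f"curve too short for spectral analysis ({n} < 16 samples)")
    nyquist = curve.frame_rate_fps / 2.0
    if not band.high_hz < nyquist:
        raise ValueError(
            f"band upper edge {band.high_hz} Hz not below Nyquist {nyquist} Hz"
        )
    signal = detrend(curve.areas_mm2, type="linear")
    amps = np.abs(np.fft.rfft(signal)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / curve.frame_rate_fps)
    in_band = (freqs >= band.low_hz - _EDGE_EPS) & (freqs <= band.high_hz + _EDGE_EPS)
    if not in_band.any():
        min_duration = 1.0 / (band.high_hz - band.low_hz)
        raise ValueError(
            f"no spectral bins in band [{band.low_hz}, {band.high_hz}] Hz; "
            f"a record of at least {min_duration:.0f} s is required"
        )
    return BandSpectrum(
        freqs_hz=freqs[in_band],
        amplitudes=amps[in_band],
        band=band,
        n_samples=n,
        frame_rate_fps=curve.frame_rate_fps,
    )


def dominant_frequency(spectrum: BandSpectrum, threshold: float = 2.0) -> SpectralResult:
    """Locate the in-band peak and test it against the dominance criterion.

    The dominance factor is peak amplitude over the mean amplitude across
    *all* in-band bins (peak included).  Amplitude ties resolve to the
    lowest frequency.  An all-zero band yields dominance factor 0 and an
    invalid result.
    """
    amps = spectrum.amplitudes
    if len(amps) < 2:
        raise ValueError("need at least 2 in-band bins for a dominance factor")
    peak_idx = int(np.argmax(amps))  # argmax returns the first = lowest-frequency tie
    peak_amp = float(amps[peak_idx])
    mean_amp = float(amps.mean())
    # a numerically empty band (e.g. a constant curve, where only float
    # round-off survives detrending) carries no peristaltic signal at all
    if peak_amp < 1e-9 or mean_amp <= 0:
        df = 0.0
    else:
        df = peak_amp / mean_amp
    return SpectralResult(
        peak_freq_hz=float(spectrum.freqs_hz[peak_idx]),
        dominance_factor=df,
        valid=bool(df >= threshold),
        threshold=threshold,
        n_band_bins=len(amps),
    )


def timepoint_frequency(
    slice_results: list[SpectralResult], min_valid: int = 2
) -> float | None:
    """Mean frequency (cpm) over the valid slices of one timepoint.

    Returns ``None`` (record excluded) when fewer than ``min_valid`` slices
    carry a dominant peak — the two-of-three rule.  Only valid slices enter
    the mean; invalid slices carry no trustworthy peak.
    """
    if not slice_results:
        raise ValueError("timepoint_frequency requires at least one slice result")
    valid = [r.peak_freq_cpm for r in slice_results if r.valid]
    if len(valid) < min_valid:
        return None
    return float(np.mean(valid))


def apparent_speed(freq_cpm: float, geom: SliceGeometry) -> float:
    """Apparent propagation speed (mm/s) from frequency and slice geometry."""
    if freq_cpm < 0:
        raise ValueError("frequency must be non-negative")
    return freq_cpm / 60.0 * geom.propagation_distance_mm


def occlusion_series(
    curve: AreaTimeCurve, top_fraction: float = 0.10
) -> OcclusionResult:
    """Per-frame luminal occlusion relative to the top-10%-median reference.

    The reference is the median of the ``k = max(1, ceil(top_fraction × n))``
    largest areas of the sequence; each frame then scores
    ``max(0, 100 × (1 − area / reference))``.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    areas = curve.areas_mm2
    n = len(areas)
    if n < 10:
        raise ValueError(f"curve too short for occlusion analysis ({n} < 10 frames)")
    k = max(1, math.ceil(top_fraction * n))
    top_k = np.sort(areas)[-k:]
    reference = float(np.median(top_k))
    if reference <= 0:
        raise ValueError("zero reference area: curve has no positive areas")
    occ = np.maximum(0.0, 100.0 * (1.0 - areas / reference))
    return OcclusionResult(
        reference_area_mm2=reference,
        occlusion_pct=occ,
        mean_occlusion_pct=float(occ.mean()),
    )
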