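"""Dominant-peak feature extraction.

Every sweep of a loaded cell shows a dominant resonance between 22 and
24 kHz whose exact bin wanders by a few grid steps from phantom to phantom.
The glucose-response statistic is built in four steps: locate the band peak,
shift (rectify) each spectrum so its peak sits at a common reference bin,
cut the nine-value peak-centred window (peak plus four bins per side), and
integrate the window area by the trapezoidal rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import FrequencyGrid
from .synth import AcousticSpectrum, SpectrumDataset

__all__ = [
    "PeakLocation",
    "PeakWindowFeature",
    "find_peak",
    "shift_spectrum",
    "rectify",
    "extract_window",
    "integrate_window",
    "average_rounds",
    "compute_snr",
    "extract_features",
    "DEFAULT_BAND",
    "DEFAULT_CENTER_KHZ",
    "DEFAULT_HALF_WIDTH",
    "MAX_SHIFT_BINS",
]

#: Search band for the dominant (second) resonance, kHz.
DEFAULT_BAND = (22.0, 24.0)
#: Common centring frequency; the reference bin is the nearest grid point.
DEFAULT_CENTER_KHZ = 23.05
#: Window half-width in bins (9 values total).
DEFAULT_HALF_WIDTH = 4
#: Rectification shifts beyond this many bins mark an outlier sweep.
MAX_SHIFT_BINS = 10


@dataclass(frozen=True)
class PeakLocation:
    bin_index: int
    freq_khz: float
    amplitude_uv: float


@dataclass
class PeakWindowFeature:
    """Nine-value window around the rectified peak and its integrated area."""

    spectrum_id: str
    center_bin: int
    values_uv: np.ndarray
    integral: float
    applied_shift_bins: int

    def __post_init__(self) -> None:
        self.values_uv = np.asarray(self.values_uv, dtype=float)


def find_peak(
    spectrum: AcousticSpectrum,
    band_lo_khz: float = DEFAULT_BAND[0],
    band_hi_khz: float = DEFAULT_BAND[1],
) -> PeakLocation:
    """Argmax of the amplitude over grid bins inside the closed band.

    Ties are broken toward the lowest bin index (``argmax`` returns the
    first maximum), which keeps the result deterministic on flat spectra.
    """
    idx = spectrum.grid.band_indices(band_lo_khz, band_hi_khz)
    local = spectrum.amplitudes_uv[idx]
    best = idx[int(np.argmax(local))]
    return PeakLocation(
        bin_index=int(best),
        freq_khz=float(spectrum.grid.values[best]),
        amplitude_uv=float(spectrum.amplitudes_uv[best]),
    )


def shift_spectrum(amplitudes: np.ndarray, shift_bins: int) -> np.ndarray:
    """Shift a spectrum right by ``shift_bins`` (left if negative).

    Vacated edge bins are filled with the spectrum's own edge value; the
    analysis window sits far from the grid edges, so the fill rule cannot
    reach it for the few-bin shifts seen in practice.
    """
    a = np.asarray(amplitudes, dtype=float)
    if shift_bins == 0:
        return a.copy()
    out = np.empty_like(a)
    if shift_bins > 0:
        out[shift_bins:] = a[:-shift_bins]
        out[:shift_bins] = a[0]
    else:
        out[:shift_bins] = a[-shift_bins:]
        out[shift_bins:] = a[-1]
    return out


def rectify(
    spectra: list[AcousticSpectrum],
    reference_bin: int | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    max_shift_bins: int = MAX_SHIFT_BINS,
) -> tuple[list[AcousticSpectrum], list[int]]:
    """Centre every spectrum's band peak at a common reference bin.

    Returns the shifted spectra and the applied whole-bin shifts.  A shift
    whose magnitude exceeds ``max_shift_bins`` indicates a sweep whose peak
    is nowhere near the expected resonance and is rejected as an outlier.
    """
    if not spectra:
        raise ValueError("no spectra to rectify")
    grid = spectra[0].grid
    if reference_bin is None:
        reference_bin = grid.nearest_bin(DEFAULT_CENTER_KHZ)
    out, shifts = [], []
    for sp in spectra:
        peak = find_peak(sp, *band)
        shift = reference_bin - peak.bin_index
        if abs(shift) > max_shift_bins:
            raise ValueError(
                f"outlier sweep {sp.spectrum_id}: rectification shift {shift} "
                f"bins exceeds {max_shift_bins}"
            )
        out.append(
            AcousticSpectrum(
                grid=sp.grid,
                amplitudes_uv=shift_spectrum(sp.amplitudes_uv, shift),
                day=sp.day,
                round_idx=sp.round_idx,
                glucose_mgdl=sp.glucose_mgdl,
                sample_kind=sp.sample_kind,
            )
        )
        shifts.append(int(shift))
    return out, shifts


def extract_window(
    spectrum: AcousticSpectrum,
    center_bin: int,
    half_width: int = DEFAULT_HALF_WIDTH,
    applied_shift_bins: int = 0,
) -> PeakWindowFeature:
    """Cut the ``2*half_width + 1`` values centred on ``center_bin``."""
    n = spectrum.grid.n_points
    lo, hi = center_bin - half_width, center_bin + half_width
    if lo < 0 or hi >= n:
        raise ValueError(
            f"window [{lo}, {hi}] crosses the grid edge (0..{n - 1})"
        )
    values = spectrum.amplitudes_uv[lo : hi + 1].copy()
    return PeakWindowFeature(
        spectrum_id=spectrum.spectrum_id,
        center_bin=center_bin,
        values_uv=values,
        integral=integrate_window(values, spectrum.grid.step_khz),
        applied_shift_bins=applied_shift_bins,
    )


def integrate_window(values: np.ndarray | PeakWindowFeature, step_khz: float) -> float:
    """Trapezoidal area (uV*kHz) of a window sampled at ``step_khz`` spacing."""
    if isinstance(values, PeakWindowFeature):
        values = values.values_uv
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("window values must be finite")
    return float(np.trapezoid(values, dx=step_khz))


def average_rounds(spectra: list[AcousticSpectrum]) -> AcousticSpectrum:
    """Per-bin arithmetic mean of repeated sweeps of one sample."""
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].grid
    if any(sp.grid != grid for sp in spectra):
        raise ValueError("cannot average spectra on different grids")
    mean = np.mean([sp.amplitudes_uv for sp in spectra], axis=0)
    first = spectra[0]
    return AcousticSpectrum(
        grid=grid,
        amplitudes_uv=mean,
        day=first.day,
        round_idx=0,
        glucose_mgdl=first.glucose_mgdl,
        sample_kind=first.sample_kind,
    )


def compute_snr(
    signal_spectrum: AcousticSpectrum,
    noise_spectrum: AcousticSpectrum,
    band: tuple[float, float] | None = None,
) -> float:
    """Band-mean signal amplitude over band-mean noise amplitude."""
    if signal_spectrum.grid != noise_spectrum.grid:
        raise ValueError("signal and noise spectra must share one grid")
    if band is None:
        g = signal_spectrum.grid
        band = (g.start_khz, g.last_khz)
    idx = signal_spectrum.grid.band_indices(*band)
    noise_mean = float(noise_spectrum.amplitudes_uv[idx].mean())
    if noise_mean == 0:
        raise ValueError("noise spectrum has zero mean over the band; SNR undefined")
    return float(signal_spectrum.amplitudes_uv[idx].mean()) / noise_mean


def extract_features(
    dataset: SpectrumDataset,
    band: tuple[float, float] = DEFAULT_BAND,
    center_khz: float = DEFAULT_CENTER_KHZ,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> pd.DataFrame:
    """Rectify all phantom sweeps and tabulate their peak-window features.

    Returns one row per sweep with columns ``spectrum_id, day, round,
    glucose_mgdl, center_bin, shift, w0..w8, integral``.
    """
    phantoms = dataset.phantoms()
    grid = dataset.config.grid
    ref_bin = grid.nearest_bin(center_khz)
    rectified, shifts = rectify(phantoms, reference_bin=ref_bin, band=band)
    rows = []
    for sp, shift in zip(rectified, shifts):
        feat = extract_window(sp, ref_bin, half_width, applied_shift_bins=shift)
        row = {
            "spectrum_id": feat.spectrum_id,
            "day": sp.day,
            "round": sp.round_idx,
            "glucose_mgdl": sp.glucose_mgdl,
            "center_bin": feat.center_bin,
            "shift": shift,
        }
        row.update({f"w{i}": v for i, v in enumerate(feat.values_uv)})
        row["integral"] = feat.integral
        rows.append(row)
    return pd.DataFrame(rows)
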