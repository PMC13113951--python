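"""Frequency grid for lock-in frequency sweeps.

The acquisition sweeps the laser modulation frequency over a closed interval
with a fixed step; every spectrum in a study shares one grid.  The default
sweep (12–40 kHz, 0.15 kHz step) yields 187 points ending at 39.9 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrequencyGrid", "make_frequency_grid", "DEFAULT_GRID"]

# tolerance used when deciding whether (stop-start)/step lands on an integer
_REL_EPS = 1e-9


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform frequency grid in kHz.

    Parameters
    ----------
    start_khz : float
        First grid frequency.
    stop_khz : float
        Upper bound of the sweep; the last grid point is the largest
        ``start + k*step`` not exceeding it.
    step_khz : float
        Positive step between adjacent points.
    """

    start_khz: float
    stop_khz: float
    step_khz: float

    def __post_init__(self) -> None:
        if self.step_khz <= 0:
            raise ValueError(f"step_khz must be positive, got {self.step_khz}")
        if self.stop_khz <= self.start_khz:
            raise ValueError(
                f"stop_khz ({self.stop_khz}) must exceed start_khz ({self.start_khz})"
            )

    @property
    def n_points(self) -> int:
        span = (self.stop_khz - self.start_khz) / self.step_khz
        return int(np.floor(span + _REL_EPS)) + 1

    @property
    def values(self) -> np.ndarray:
        """Grid frequencies in kHz, strictly increasing."""
        return self.start_khz + self.step_khz * np.arange(self.n_points)

    @property
    def last_khz(self) -> float:
        return self.start_khz + (self.n_points - 1) * self.step_khz

    def nearest_bin(self, freq_khz: float) -> int:
        """0-based index of the grid point closest to ``freq_khz``."""
        idx = int(round((freq_khz - self.start_khz) / self.step_khz))
        return min(max(idx, 0), self.n_points - 1)

    def band_indices(self, lo_khz: float, hi_khz: float) -> np.ndarray:
        """Indices of grid points inside the closed band [lo, hi]."""
        v = self.values
        idx = np.where((v >= lo_khz) & (v <= hi_khz))[0]
        if idx.size == 0:
            raise ValueError(
                f"band [{lo_khz}, {hi_khz}] kHz does not intersect the grid "
                f"[{self.start_khz}, {self.last_khz}] kHz"
            )
        return idx


def make_frequency_grid(
    start_khz: float, stop_khz: float, step_khz: float
) -> FrequencyGrid:
    """Build a :class:`FrequencyGrid`, validating the sweep definition."""
    return FrequencyGrid(start_khz, stop_khz, step_khz)


#: Default sweep used throughout: 12–40 kHz in 0.15 kHz steps (187 points).
DEFAULT_GRID = FrequencyGrid(12.0, 40.0, 0.15)
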