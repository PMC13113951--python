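"""Synthetic photoacoustic spectra for a resonant-cell glucose study.

The generator emulates a frequency-swept photoacoustic measurement of
skin-mimicking glucose phantoms in a two-resonance acoustic cell.  Each
sweep is modelled as

    amplitude(f) = gain * [L(f; f1, Q1, a1*s) + L(f; f2 + shift, Q2, a2*s) + bg]
                   + |noise(f)|

where ``L`` is a Lorentzian amplitude profile ``a / (1 + (2Q(f-f0)/f0)^2)``,
``s = (1 + rel_step)^i`` scales the whole acoustic response with the glucose
class index ``i``, ``gain`` is a single multiplicative factor per sweep
(round-to-round coupling/pressure variation, correlated across frequency),
``shift`` is a small per-phantom displacement of the dominant resonance
(placement and surface-arch variation, shared by the three rounds of one
phantom), and the additive term is the microphone noise floor of the lock-in
magnitude output (non-negative, tightly fluctuating around its mean).

A study is 2 days x 12 glucose classes (85–250 mg/dL in 15 mg/dL steps)
x 3 rounds = 72 phantom sweeps, with a larger gain jitter on day one than on
day two.  Calibration sweeps (laser-off noise, lens-on background, carbon
plate) are generated separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .grid import FrequencyGrid, DEFAULT_GRID

__all__ = [
    "ResonatorModel",
    "GlucoseResponseModel",
    "NoiseModel",
    "AcousticSpectrum",
    "SpectrumDataset",
    "DatasetConfig",
    "lorentzian",
    "phantom_resonator",
    "carbon_resonator",
    "simulate_spectrum",
    "simulate_dataset",
    "simulate_calibration",
    "GLUCOSE_CLASSES",
]

#: Glucose class centres in mg/dL: 85, 100, ..., 250 (12 classes).
GLUCOSE_CLASSES: tuple[int, ...] = tuple(range(85, 251, 15))

# Relative bin-to-bin fluctuation of the lens-on background measurement.
_BACKGROUND_REL_SD = 0.45


def lorentzian(f: np.ndarray, f0: float, q: float, a: float) -> np.ndarray:
    """Lorentzian amplitude profile ``a / (1 + (2 q (f - f0) / f0)^2)``."""
    return a / (1.0 + (2.0 * q * (f - f0) / f0) ** 2)


@dataclass(frozen=True)
class ResonatorModel:
    """Two-resonance acoustic cell response.

    ``f1``/``f2`` are the resonance centres in kHz (the cell's design
    eigenfrequencies are 16.5 and 21.8 kHz; under a loaded phantom the
    second resonance sits near 23.1 kHz), ``q1``/``q2`` dimensionless
    quality factors, ``a1``/``a2`` peak amplitudes in uV, and
    ``background_uv`` the mean broadband (lens-on) background level.
    """

    f1_khz: float
    f2_khz: float
    q1: float
    q2: float
    a1: float
    a2: float
    background_uv: float = 4.5

    def __post_init__(self) -> None:
        if self.q1 <= 0 or self.q2 <= 0:
            raise ValueError("quality factors must be positive")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("peak amplitudes must be non-negative")
        if not self.f1_khz < self.f2_khz:
            raise ValueError("f1_khz must be below f2_khz")


def phantom_resonator() -> ResonatorModel:
    """Loaded-cell response for glucose phantoms.

    Amplitudes and widths are calibrated so the lowest-class noiseless
    spectrum has a mean amplitude of ~14.5 uV and a peak of ~51.3 uV at the
    loaded second resonance (23.1 kHz, the grid point nearest the centring
    frequency used in the analysis).
    """
    return ResonatorModel(
        f1_khz=16.5, f2_khz=23.1, q1=8.0, q2=14.0, a1=36.2, a2=43.6,
        background_uv=4.5,
    )


def carbon_resonator() -> ResonatorModel:
    """Unloaded-cell response of the carbon calibration plate.

    Carbon absorbs strongly and uniformly in the NIR, producing a large
    broadband photoacoustic pedestal on top of the cell resonances; the
    constants are calibrated to a mean of ~306 uV and a maximum of ~724 uV
    at the 21.8 kHz design resonance.
    """
    return ResonatorModel(
        f1_khz=16.5, f2_khz=21.8, q1=4.0, q2=4.0, a1=195.0, a2=585.0,
        background_uv=111.0,
    )


@dataclass(frozen=True)
class GlucoseResponseModel:
    """Multiplicative glucose response of the photoacoustic signal.

    The acoustic amplitude of class ``i`` (``i = 0`` at
    ``baseline_class_mgdl``) scales as ``(1 + rel_step)**i``; the default
    step of 2.6% per 15 mg/dL is the mean of the observed consecutive-class
    signal differences.  ``baseline_peak_uv`` optionally overrides the
    resonator's second-resonance amplitude for the lowest class.
    """

    baseline_class_mgdl: float = 85.0
    step_mgdl: float = 15.0
    rel_step: float = 0.026
    baseline_peak_uv: float | None = None

    def __post_init__(self) -> None:
        if self.rel_step < 0:
            raise ValueError("rel_step must be non-negative")
        if self.step_mgdl <= 0:
            raise ValueError("step_mgdl must be positive")

    def class_index(self, glucose_mgdl: float) -> int:
        """Index of ``glucose_mgdl`` on the class grid; rejects off-grid values."""
        ratio = (glucose_mgdl - self.baseline_class_mgdl) / self.step_mgdl
        idx = round(ratio)
        if abs(ratio - idx) > 1e-9 or idx < 0:
            raise ValueError(
                f"glucose {glucose_mgdl} mg/dL is not on the class grid "
                f"{self.baseline_class_mgdl} + k*{self.step_mgdl}"
            )
        return int(idx)

    def scale(self, glucose_mgdl: float) -> float:
        """Amplitude scale ``(1 + rel_step)**i`` for a concentration."""
        return (1.0 + self.rel_step) ** self.class_index(glucose_mgdl)


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic components of a sweep.

    ``floor_uv`` is the mean additive microphone noise amplitude and
    ``floor_sd_uv`` its bin-to-bin fluctuation (amplitudes are folded
    normal, i.e. ``|N(floor, sd)|``, matching the non-negative magnitude
    output of a lock-in with a long time constant, whose displayed floor is
    a stable level with small fluctuation).  ``round_jitter_rel`` is the
    per-sweep multiplicative gain SD, either one value or a mapping
    day -> SD.  ``shift_bins_max`` bounds the continuous per-phantom
    resonance displacement (uniform on +-shift_bins_max grid bins; each
    phantom's placement, mass and surface arch move its loaded resonance by
    a fraction of a kilohertz, constant across its three rounds), and
    ``round_shift_sd_bins`` adds a small round-to-round drift of that
    displacement.  ``seed`` makes the generator fully deterministic.
    """

    floor_uv: float = 2.3
    floor_sd_uv: float = 0.2
    round_jitter_rel: float | Mapping[int, float] = field(
        default_factory=lambda: {1: 0.0101, 2: 0.0051}
    )
    shift_bins_max: float = 1.5
    round_shift_sd_bins: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.floor_uv < 0 or self.floor_sd_uv < 0:
            raise ValueError("noise floor parameters must be non-negative")
        jitters = (
            [self.round_jitter_rel]
            if isinstance(self.round_jitter_rel, (int, float))
            else list(self.round_jitter_rel.values())
        )
        if any(j < 0 for j in jitters):
            raise ValueError("round jitter SDs must be non-negative")
        if self.shift_bins_max < 0 or self.round_shift_sd_bins < 0:
            raise ValueError("shift parameters must be non-negative")

    def jitter_for_day(self, day: int) -> float:
        if isinstance(self.round_jitter_rel, (int, float)):
            return float(self.round_jitter_rel)
        try:
            return float(self.round_jitter_rel[day])
        except KeyError:
            raise KeyError(f"no round jitter SD configured for day {day}") from None


@dataclass
class AcousticSpectrum:
    """One frequency sweep of lock-in amplitudes (uV) with provenance tags."""

    grid: FrequencyGrid
    amplitudes_uv: np.ndarray
    day: int = 1
    round_idx: int = 1
    glucose_mgdl: float | None = None
    sample_kind: str = "phantom"

    def __post_init__(self) -> None:
        self.amplitudes_uv = np.asarray(self.amplitudes_uv, dtype=float)
        if self.amplitudes_uv.shape != (self.grid.n_points,):
            raise ValueError(
                f"amplitude vector has length {self.amplitudes_uv.size}, "
                f"grid has {self.grid.n_points} points"
            )
        if not np.all(np.isfinite(self.amplitudes_uv)):
            raise ValueError("amplitudes must be finite")
        if np.any(self.amplitudes_uv < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def spectrum_id(self) -> str:
        if self.glucose_mgdl is None:
            return f"{self.sample_kind}_d{self.day}_r{self.round_idx}"
        return f"d{self.day}_g{int(self.glucose_mgdl):03d}_r{self.round_idx}"


@dataclass(frozen=True)
class DatasetConfig:
    """Full study design: grid, physics models, and the measurement plan."""

    grid: FrequencyGrid = DEFAULT_GRID
    resonator: ResonatorModel = field(default_factory=phantom_resonator)
    response: GlucoseResponseModel = field(default_factory=GlucoseResponseModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    days: tuple[int, ...] = (1, 2)
    classes_mgdl: tuple[float, ...] = GLUCOSE_CLASSES
    rounds: int = 3

    def to_dict(self) -> dict:
        d = asdict(self)
        noise = dict(d["noise"])
        if isinstance(noise["round_jitter_rel"], Mapping):
            noise["round_jitter_rel"] = dict(noise["round_jitter_rel"])
        d["noise"] = noise
        return d


@dataclass
class SpectrumDataset:
    """Collection of simulated sweeps plus the configuration that made them."""

    spectra: list[AcousticSpectrum]
    config: DatasetConfig
    seed: int

    def __len__(self) -> int:
        return len(self.spectra)

    def phantoms(self) -> list[AcousticSpectrum]:
        return [s for s in self.spectra if s.sample_kind == "phantom"]


def _noise_floor(noise: NoiseModel, n: int, rng: np.random.Generator) -> np.ndarray:
    return np.abs(rng.normal(noise.floor_uv, noise.floor_sd_uv, n))


def _clean_response(
    grid: FrequencyGrid,
    resonator: ResonatorModel,
    scale: float,
    a2: float,
    shift_khz: float,
) -> np.ndarray:
    f = grid.values
    # the glucose scale multiplies both resonances (the photoacoustic
    # response of the sample) but not the broadband background, which is
    # stray-light reflection off the cavity walls and sample-independent
    return (
        lorentzian(f, resonator.f1_khz, resonator.q1, resonator.a1 * scale)
        + lorentzian(f, resonator.f2_khz + shift_khz, resonator.q2, a2 * scale)
        + resonator.background_uv
    )


def simulate_spectrum(
    grid: FrequencyGrid,
    resonator: ResonatorModel,
    response: GlucoseResponseModel,
    noise: NoiseModel,
    day: int = 1,
    round_idx: int = 1,
    glucose_mgdl: float = 85.0,
    rng: np.random.Generator | None = None,
    shift_bins: float | None = None,
) -> AcousticSpectrum:
    """Simulate one phantom sweep.

    ``shift_bins`` fixes the phantom's resonance displacement (in grid
    bins, continuous) for the sweep; when None it is drawn uniformly from
    ``[-shift_bins_max, shift_bins_max]``.  A per-round drift of SD
    ``round_shift_sd_bins`` is added on top either way.  Passing an
    explicit ``rng`` lets a caller thread one random stream through many
    sweeps.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    scale = response.scale(glucose_mgdl)  # validates the class grid
    if shift_bins is None:
        shift_bins = rng.uniform(-noise.shift_bins_max, noise.shift_bins_max)
    shift_bins = shift_bins + (
        rng.normal(0.0, noise.round_shift_sd_bins) if noise.round_shift_sd_bins else 0.0
    )
    a2 = resonator.a2 if response.baseline_peak_uv is None else response.baseline_peak_uv
    clean = _clean_response(grid, resonator, scale, a2, shift_bins * grid.step_khz)
    gain = rng.normal(1.0, noise.jitter_for_day(day))
    amps = gain * clean + _noise_floor(noise, grid.n_points, rng)
    return AcousticSpectrum(
        grid=grid,
        amplitudes_uv=np.maximum(amps, 0.0),
        day=day,
        round_idx=round_idx,
        glucose_mgdl=float(glucose_mgdl),
        sample_kind="phantom",
    )


def simulate_dataset(config: DatasetConfig | None = None) -> SpectrumDataset:
    """Simulate the full measurement campaign.

    Draw order is fixed (per day, per class: one phantom shift; per round:
    the shift drift, one gain, then the noise vector) so that a given
    (config, seed) pair reproduces every amplitude bit-exactly.  The
    resonance shift is drawn once per phantom — the three rounds of one
    sample share the phantom and its placement — which is what makes peak
    rectification across samples both necessary and possible.
    """
    cfg = config or DatasetConfig()
    rng = np.random.default_rng(cfg.noise.seed)
    spectra: list[AcousticSpectrum] = []
    for day in cfg.days:
        for glucose in cfg.classes_mgdl:
            shift = rng.uniform(-cfg.noise.shift_bins_max, cfg.noise.shift_bins_max)
            for round_idx in range(1, cfg.rounds + 1):
                spectra.append(
                    simulate_spectrum(
                        cfg.grid,
                        cfg.resonator,
                        cfg.response,
                        cfg.noise,
                        day=day,
                        round_idx=round_idx,
                        glucose_mgdl=glucose,
                        rng=rng,
                        shift_bins=shift,
                    )
                )
    return SpectrumDataset(spectra=spectra, config=cfg, seed=cfg.noise.seed)


def simulate_calibration(
    kind: str,
    grid: FrequencyGrid | None = None,
    resonator: ResonatorModel | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> AcousticSpectrum:
    """Simulate a calibration sweep.

    ``kind`` is one of ``noise`` (laser off: microphone floor only),
    ``background`` (laser on, no focusing lens: broadband offset), or
    ``carbon`` (carbon calibration plate on the unloaded cell).
    """
    grid = grid or DEFAULT_GRID
    noise = noise or NoiseModel()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    if kind == "noise":
        amps = _noise_floor(noise, grid.n_points, rng)
    elif kind == "background":
        resonator = resonator or phantom_resonator()
        bg = resonator.background_uv
        amps = np.abs(rng.normal(bg, _BACKGROUND_REL_SD * bg, grid.n_points))
    elif kind == "carbon":
        resonator = resonator or carbon_resonator()
        clean = _clean_response(grid, resonator, 1.0, resonator.a2, 0.0)
        amps = clean + _noise_floor(noise, grid.n_points, rng)
    else:
        raise ValueError(f"unknown calibration kind {kind!r}")
    return AcousticSpectrum(
        grid=grid,
        amplitudes_uv=np.maximum(amps, 0.0),
        day=1,
        round_idx=1,
        glucose_mgdl=None,
        sample_kind=kind,
    )
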