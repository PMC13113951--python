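"""Interchange formats: long-format spectra CSV, features CSV, JSON, YAML.

Units are fixed across all files: frequencies in kHz, amplitudes in uV,
concentrations in mg/dL.  Floats are serialised at full (round-trip)
precision so a write/read cycle is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .grid import FrequencyGrid
from .synth import (
    AcousticSpectrum,
    DatasetConfig,
    GlucoseResponseModel,
    NoiseModel,
    ResonatorModel,
    SpectrumDataset,
)

__all__ = [
    "spectra_to_frame",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_features_csv",
    "read_features_csv",
    "write_json",
    "read_json",
    "load_config",
    "dump_config",
]

SPECTRA_COLUMNS = ["day", "sample_kind", "round", "glucose_mgdl", "freq_khz", "amplitude_uv"]


def spectra_to_frame(dataset: SpectrumDataset) -> pd.DataFrame:
    """Long-format table: one row per (spectrum, frequency bin)."""
    frames = []
    for sp in dataset.spectra:
        n = sp.grid.n_points
        frames.append(
            pd.DataFrame(
                {
                    "day": np.full(n, sp.day),
                    "sample_kind": np.full(n, sp.sample_kind),
                    "round": np.full(n, sp.round_idx),
                    "glucose_mgdl": np.full(n, np.nan if sp.glucose_mgdl is None else sp.glucose_mgdl),
                    "freq_khz": sp.grid.values,
                    "amplitude_uv": sp.amplitudes_uv,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_spectra_csv(dataset: SpectrumDataset, path: str | Path) -> None:
    # %.17g guarantees bit round-trip of float64 amplitudes
    spectra_to_frame(dataset).to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path: str | Path, config: DatasetConfig | None = None) -> SpectrumDataset:
    """Rebuild a dataset from a long-format spectra CSV.

    Each (day, sample_kind, round, glucose) group must contain one complete
    sweep with a strictly increasing, uniform frequency column.  When the
    generating ``config`` is not supplied, a grid-only config is inferred
    from the data (seed recorded as -1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SPECTRA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spectra CSV lacks columns {sorted(missing)}")
    first = df[
        (df["day"] == df["day"].iloc[0])
        & (df["sample_kind"] == df["sample_kind"].iloc[0])
        & (df["round"] == df["round"].iloc[0])
    ]
    g0 = first[first["glucose_mgdl"].fillna(-1) == first["glucose_mgdl"].fillna(-1).iloc[0]]
    freqs = g0["freq_khz"].to_numpy(dtype=float)
    if freqs.size < 2 or np.any(np.diff(freqs) <= 0):
        raise ValueError("non-monotone frequency grid in spectra CSV")
    grid = FrequencyGrid(float(freqs[0]), float(freqs[-1]), float(freqs[1] - freqs[0]))
    spectra = []
    for (day, kind, rnd, glu), grp in df.fillna({"glucose_mgdl": np.nan}).groupby(
        ["day", "sample_kind", "round", df["glucose_mgdl"].fillna(-1.0)], sort=False
    ):
        f = grp["freq_khz"].to_numpy(dtype=float)
        if f.size != grid.n_points or np.any(np.diff(f) <= 0):
            raise ValueError(
                f"spectrum (day={day}, kind={kind}, round={rnd}) has a malformed grid "
                f"({f.size} bins, expected {grid.n_points})"
            )
        spectra.append(
            AcousticSpectrum(
                grid=grid,
                amplitudes_uv=grp["amplitude_uv"].to_numpy(dtype=float),
                day=int(day),
                round_idx=int(rnd),
                glucose_mgdl=None if glu < 0 else float(glu),
                sample_kind=str(kind),
            )
        )
    if config is None:
        config = DatasetConfig(grid=grid)
        seed = -1
    else:
        seed = config.noise.seed
    return SpectrumDataset(spectra=spectra, config=config, seed=seed)


def write_features_csv(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# YAML configuration


def dump_config(config: DatasetConfig, path: str | Path | None = None) -> str:
    """Serialise a dataset config to YAML (returned; optionally written)."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_config(source: str | Path | dict) -> DatasetConfig:
    """Build a :class:`DatasetConfig` from YAML (path or text) or a dict."""
    if isinstance(source, dict):
        raw = source
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    kwargs: dict[str, Any] = {}
    if "grid" in raw:
        kwargs["grid"] = FrequencyGrid(**raw["grid"])
    if "resonator" in raw:
        kwargs["resonator"] = ResonatorModel(**raw["resonator"])
    if "response" in raw:
        kwargs["response"] = GlucoseResponseModel(**raw["response"])
    if "noise" in raw:
        noise = dict(raw["noise"])
        jit = noise.get("round_jitter_rel")
        if isinstance(jit, dict):
            noise["round_jitter_rel"] = {int(k): float(v) for k, v in jit.items()}
        kwargs["noise"] = NoiseModel(**noise)
    for key in ("days", "classes_mgdl"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    if "rounds" in raw:
        kwargs["rounds"] = int(raw["rounds"])
    return DatasetConfig(**kwargs)
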