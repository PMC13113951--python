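"""Glucose-response calibration statistics.

Fits the linear relation between the integrated peak-window signal and the
glucose concentration, and summarises the sensitivity (consecutive-class
percentage differences) and repeatability (round-to-round variability) of
the response, per measurement day and pooled across days.

The module follows a model/results split: :class:`GlucoseCalibration` is
built from a feature table (one row per sweep, as produced by
:func:`paglucose.prep.extract_features`), and :meth:`GlucoseCalibration.fit`
returns a :class:`GlucoseCalibrationResults` carrying the per-day statistics
with a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "interclass_differences",
    "pearson_correlation",
    "round_variability",
    "DayCalibration",
    "GlucoseCalibrationResults",
    "GlucoseCalibration",
]


def interclass_differences(integrals_desc: np.ndarray) -> np.ndarray:
    """Percentage signal drop between consecutive classes.

    ``integrals_desc`` must be ordered by *descending* glucose; each entry of
    the result is ``100 * (I_high - I_low) / I_high`` for an adjacent pair,
    so 12 classes give 11 values.  The higher-concentration integral is the
    denominator, matching the high-to-low pairing convention.
    """
    I = np.asarray(integrals_desc, dtype=float)
    if I.size < 2:
        raise ValueError("need at least two classes")
    if np.any(I <= 0):
        raise ValueError("integrals must be positive")
    high, low = I[:-1], I[1:]
    return 100.0 * (high - low) / high


def pearson_correlation(
    concentrations: np.ndarray, integrals: np.ndarray
) -> tuple[float, float, float]:
    """Product-moment correlation plus the least-squares line.

    Returns ``(r, slope, intercept)`` with slope in uV*kHz per mg/dL.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(integrals, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in concentrations or integrals")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept)


def round_variability(per_round: pd.DataFrame) -> float:
    """Mean within-sample round-to-round SD, percent of the sample mean.

    ``per_round`` needs columns ``glucose_mgdl`` and ``integral`` with one
    row per round; rows of one sample share a ``glucose_mgdl`` (and ``day``
    when present).  The SD uses the population convention (divisor n) since
    a sample's three rounds are the complete set, not a subsample.
    """
    keys = [c for c in ("day", "glucose_mgdl") if c in per_round.columns]
    rels = []
    for _, grp in per_round.groupby(keys):
        vals = grp["integral"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError("round variability needs >= 2 rounds per sample")
        rels.append(100.0 * vals.std(ddof=0) / vals.mean())
    return float(np.mean(rels))


@dataclass
class DayCalibration:
    """Calibration statistics of one measurement day (or the pooled set)."""

    day: int | str
    r: float
    slope: float
    intercept: float
    diffs_pct: np.ndarray
    mean_diff_pct: float
    mean_round_sd: float | None

    def to_dict(self) -> dict:
        return {
            "day": self.day,
            "r": self.r,
            "slope": self.slope,
            "intercept": self.intercept,
            "diffs_pct": list(map(float, self.diffs_pct)),
            "mean_diff_pct": self.mean_diff_pct,
            "mean_round_sd": self.mean_round_sd,
        }


@dataclass
class GlucoseCalibrationResults:
    """Per-day and pooled glucose-response statistics with ``summary()``."""

    days: dict[int, DayCalibration]
    pooled: DayCalibration
    sd_convention: str = "population (ddof=0), percent of sample mean"

    def to_dict(self) -> dict:
        return {
            "days": {str(k): v.to_dict() for k, v in self.days.items()},
            "pooled": self.pooled.to_dict(),
            "sd_convention": self.sd_convention,
        }

    def summary(self) -> str:
        lines = [
            "Glucose response calibration",
            "=" * 64,
            f"{'day':>8} {'r':>8} {'slope':>12} {'mean diff %':>12} {'round SD %':>11}",
        ]
        for cal in [*self.days.values(), self.pooled]:
            sd = f"{cal.mean_round_sd:.2f}" if cal.mean_round_sd is not None else "-"
            lines.append(
                f"{str(cal.day):>8} {cal.r:8.4f} {cal.slope:12.5f} "
                f"{cal.mean_diff_pct:12.2f} {sd:>11}"
            )
        lines.append("=" * 64)
        lines.append(f"round-SD convention: {self.sd_convention}")
        return "\n".join(lines)


class GlucoseCalibration:
    """Glucose-response calibration model over a peak-window feature table.

    Parameters
    ----------
    features : pandas.DataFrame
        One row per sweep with columns ``day``, ``round``, ``glucose_mgdl``
        and ``integral`` (``paglucose.prep.extract_features`` output).
    """

    def __init__(self, features: pd.DataFrame):
        required = {"day", "round", "glucose_mgdl", "integral"}
        missing = required - set(features.columns)
        if missing:
            raise ValueError(f"feature table lacks columns {sorted(missing)}")
        self.features = features

    @classmethod
    def from_features(cls, features: pd.DataFrame) -> "GlucoseCalibration":
        return cls(features)

    def _day_stats(self, df: pd.DataFrame, day: int) -> DayCalibration:
        per_class = (
            df.groupby("glucose_mgdl")["integral"].mean().sort_index()
        )
        conc = per_class.index.to_numpy(dtype=float)
        integ = per_class.to_numpy(dtype=float)
        r, slope, intercept = pearson_correlation(conc, integ)
        diffs = interclass_differences(integ[::-1])
        return DayCalibration(
            day=day,
            r=r,
            slope=slope,
            intercept=intercept,
            diffs_pct=diffs,
            mean_diff_pct=float(diffs.mean()),
            mean_round_sd=round_variability(df),
        )

    def fit(self) -> GlucoseCalibrationResults:
        """Compute per-day statistics and the pooled two-day correlation.

        Per day, the three rounds of each phantom are averaged before the
        correlation and difference statistics.  Pooling first normalises
        each day's class-mean integrals by that day's overall mean — the
        absolute gain of a session is arbitrary — then correlates the
        combined pairs.
        """
        days: dict[int, DayCalibration] = {}
        pooled_x, pooled_y = [], []
        for day, df in self.features.groupby("day"):
            days[int(day)] = self._day_stats(df, int(day))
            per_class = df.groupby("glucose_mgdl")["integral"].mean().sort_index()
            pooled_x.append(per_class.index.to_numpy(dtype=float))
            pooled_y.append(per_class.to_numpy(dtype=float) / per_class.mean())
        x = np.concatenate(pooled_x)
        y = np.concatenate(pooled_y)
        r, slope, intercept = pearson_correlation(x, y)
        per_class_all = (
            pd.DataFrame({"glucose_mgdl": x, "norm_integral": y})
            .groupby("glucose_mgdl")["norm_integral"]
            .mean()
            .sort_index()
        )
        diffs = interclass_differences(per_class_all.to_numpy(dtype=float)[::-1])
        pooled = DayCalibration(
            day="pooled",
            r=r,
            slope=slope,
            intercept=intercept,
            diffs_pct=diffs,
            mean_diff_pct=float(diffs.mean()),
            mean_round_sd=None,
        )
        return GlucoseCalibrationResults(days=days, pooled=pooled)
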