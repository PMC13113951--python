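"""Clarke error grid analysis (EGA).

The Clarke grid partitions (reference, predicted) blood-glucose pairs into
five clinical-accuracy zones: A (clinically accurate, within 20% of the
reference or both readings below 70 mg/dL), B (benign deviations), C
(overcorrection), D (dangerous failure to detect), and E (erroneous,
opposite treatment).  Regulators require at least 99% of a monitor's
readings to fall in zones A and B.

Published pseudo-code variants of the grid disagree on some C/D boundary
details; the rule set here is fixed and evaluated in the order A, E, C, D,
else B, so boundary points belong deterministically to the earlier zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EGAReport", "clarke_zone", "clarke_zones", "confusion_to_ega", "ZONES"]

ZONES = ("A", "B", "C", "D", "E")

#: Regulatory threshold: percent of readings required in zones A+B.
REGULATORY_AB_PCT = 99.0


def clarke_zone(reference_mgdl: float, predicted_mgdl: float) -> str:
    """Assign the Clarke zone of one (reference, predicted) pair in mg/dL."""
    r, p = float(reference_mgdl), float(predicted_mgdl)
    if r <= 0 or p <= 0:
        raise ValueError("glucose concentrations must be positive")
    if (r < 70 and p < 70) or abs(p - r) <= 0.2 * r:
        return "A"
    if (r <= 70 and p >= 180) or (r >= 180 and p <= 70):
        return "E"
    if (70 <= r <= 290 and p >= r + 110) or (130 <= r <= 180 and p <= 1.4 * r - 182):
        return "C"
    if 70 <= p <= 180 and (r <= 70 or r >= 240):
        return "D"
    return "B"


def clarke_zones(reference_mgdl: np.ndarray, predicted_mgdl: np.ndarray) -> np.ndarray:
    """Vectorised zone assignment; returns an array of zone labels."""
    r = np.asarray(reference_mgdl, dtype=float).ravel()
    p = np.asarray(predicted_mgdl, dtype=float).ravel()
    if r.shape != p.shape:
        raise ValueError("reference and predicted arrays must have equal length")
    return np.array([clarke_zone(ri, pi) for ri, pi in zip(r, p)])


@dataclass
class EGAReport:
    """Zone percentages of a set of prediction events."""

    pct: dict[str, float]
    n_pairs: int

    def __post_init__(self) -> None:
        total = sum(self.pct.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"zone percentages sum to {total}, not 100")

    @property
    def pass_regulatory(self) -> bool:
        return self.pct["A"] + self.pct["B"] >= REGULATORY_AB_PCT

    def to_dict(self) -> dict:
        return {
            "pct": dict(self.pct),
            "n_pairs": self.n_pairs,
            "pass_regulatory": self.pass_regulatory,
        }

    def summary(self) -> str:
        lines = ["Clarke error grid analysis", "=" * 40]
        for z in ZONES:
            lines.append(f"  zone {z}: {self.pct[z]:6.2f} %")
        lines.append("-" * 40)
        lines.append(
            f"  A+B = {self.pct['A'] + self.pct['B']:.2f} % "
            f"({'meets' if self.pass_regulatory else 'fails'} the >=99% criterion), "
            f"n = {self.n_pairs}"
        )
        return "\n".join(lines)


def confusion_to_ega(
    confusion: np.ndarray, class_centers_mgdl: np.ndarray
) -> EGAReport:
    """Convert a classifier confusion matrix into Clarke zone percentages.

    Cell (i, j) contributes ``count`` prediction events with class centre i
    as the reference and class centre j as the predicted concentration.
    """
    conf = np.asarray(confusion)
    centers = np.asarray(class_centers_mgdl, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    if centers.size != conf.shape[0]:
        raise ValueError("class_centers length must match the confusion dimension")
    total = int(conf.sum())
    if total == 0:
        raise ValueError("confusion matrix has no prediction events")
    counts = dict.fromkeys(ZONES, 0)
    for i in range(conf.shape[0]):
        for j in range(conf.shape[1]):
            c = int(conf[i, j])
            if c:
                counts[clarke_zone(centers[i], centers[j])] += c
    pct = {z: 100.0 * counts[z] / total for z in ZONES}
    return EGAReport(pct=pct, n_pairs=total)
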