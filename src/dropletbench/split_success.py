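"""Area-threshold classification of droplet splits.

After an array-generation run, each detected droplet is declared a
successful split iff its footprint area falls inside a band around the
nominal single-droplet area.  Oversized detections are merged or unsplit
droplets; the band's default ``[0.5, 1.5] x nominal`` separates 1x droplets
from 2x merges with maximal margin.  The array's success rate is the
percentage of in-band droplets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SuccessPolicy", "SuccessReport", "classify_split", "nominal_area_estimate"]


@dataclass(frozen=True)
class SuccessPolicy:
    """Success band ``[low_frac * nominal, high_frac * nominal]`` in pixel area.

    For the one-sided variant (only oversized droplets fail) use a
    ``low_frac`` close to zero via :meth:`one_sided`.
    """

    nominal_area_px: float
    low_frac: float = 0.5
    high_frac: float = 1.5

    def __post_init__(self) -> None:
        if self.nominal_area_px <= 0:
            raise ValueError("nominal_area_px must be positive")
        if not 0 < self.low_frac <= 1:
            raise ValueError("low_frac must lie in (0, 1]")
        if self.high_frac < self.low_frac:
            raise ValueError("high_frac must be >= low_frac")

    @classmethod
    def one_sided(cls, nominal_area_px: float, high_frac: float = 1.5) -> "SuccessPolicy":
        """Only larger-than-band areas fail (any positive area passes below)."""
        return cls(nominal_area_px=nominal_area_px, low_frac=1e-9, high_frac=high_frac)

    @property
    def band(self) -> tuple[float, float]:
        return (self.low_frac * self.nominal_area_px, self.high_frac * self.nominal_area_px)


@dataclass
class SuccessReport:
    n_success: int
    n_fail: int
    success_rate_percent: float
    per_droplet: list[tuple[int, float, str]]  # (droplet_id, area_px, verdict)

    @property
    def failure_rate_percent(self) -> float:
        return 100.0 - self.success_rate_percent


def classify_split(areas: Sequence[tuple[int, float]], policy: SuccessPolicy) -> SuccessReport:
    """Classify each (id, area) as a successful or failed split.

    Verdict is ``"success"`` iff the area lies inside the policy band
    (inclusive); the success rate is ``100 * n_success / n``.
    """
    if len(areas) == 0:
        raise ValueError("need at least one droplet to classify")
    lo, hi = policy.band
    per_droplet = []
    n_success = 0
    for did, area in areas:
        if area <= 0:
            raise ValueError(f"droplet {did} has non-positive area {area}")
        verdict = "success" if lo <= area <= hi else "fail"
        n_success += verdict == "success"
        per_droplet.append((did, float(area), verdict))
    n = len(per_droplet)
    return SuccessReport(
        n_success=n_success,
        n_fail=n - n_success,
        success_rate_percent=100.0 * n_success / n,
        per_droplet=per_droplet,
    )


def nominal_area_estimate(areas: Sequence[float]) -> float:
    """Median area: a robust nominal when a minority of droplets are merges."""
    if len(areas) == 0:
        raise ValueError("need at least one area")
    return float(np.median(np.asarray(areas, dtype=float)))
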