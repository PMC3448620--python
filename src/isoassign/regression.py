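"""Ring-recovery longitude regression with t-based prediction intervals.

Trans-Saharan ring recoveries link the longitude where a bird was ringed in
Europe to the longitude where it was recovered in Africa.  An ordinary
least-squares fit of recovery longitude on ringing longitude, evaluated at a
colony's longitude, predicts a wintering longitude; the 95% prediction
interval around it defines a longitudinal band that can be intersected with
the isotopic cluster map to narrow the assignment.

Longitudes are decimal degrees, east positive (Gaast = +5.4).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from isoassign.clustering import ClusterMap

__all__ = ["RecoveryRecord", "OlsFit", "IntervalPrediction",
           "fit_ols", "predict_interval", "clip_clusters_to_band",
           "read_recovery_csv"]


@dataclasses.dataclass(frozen=True)
class RecoveryRecord:
    """One ring recovery: ringing and recovery longitudes (°, east positive)."""

    ring_lon: float
    recovery_lon: float

    def __post_init__(self) -> None:
        for v in (self.ring_lon, self.recovery_lon):
            if not -180 <= v <= 180:
                raise ValueError(f"longitude {v} outside [-180, 180]")


@dataclasses.dataclass
class OlsFit:
    """Least-squares fit of recovery longitude on ringing longitude."""

    slope: float
    intercept: float
    residual_se: float
    n: int
    x_mean: float
    s_xx: float

    @property
    def df(self) -> int:
        return self.n - 2

    def predict(self, x0: float) -> float:
        return self.intercept + self.slope * x0


@dataclasses.dataclass
class IntervalPrediction:
    x0: float
    center: float
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not self.lower <= self.center <= self.upper:
            raise ValueError("interval must bracket its center")


def read_recovery_csv(path) -> list[RecoveryRecord]:
    df = pd.read_csv(path)
    return [RecoveryRecord(float(r.ring_lon), float(r.recovery_lon))
            for r in df.itertuples()]


def fit_ols(records: Sequence[RecoveryRecord]) -> OlsFit:
    """Ordinary least squares via the closed-form normal equations.

    residual_se² = RSS / (n − 2); requires n ≥ 3 and non-constant x.
    """
    x = np.array([r.ring_lon for r in records], dtype=float)
    y = np.array([r.recovery_lon for r in records], dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 recoveries")
    x_mean, y_mean = x.mean(), y.mean()
    s_xx = float(np.sum((x - x_mean) ** 2))
    if s_xx == 0:
        raise ValueError("ringing longitudes are constant")
    slope = float(np.sum((x - x_mean) * (y - y_mean)) / s_xx)
    intercept = float(y_mean - slope * x_mean)
    rss = float(np.sum((y - intercept - slope * x) ** 2))
    residual_se = float(np.sqrt(rss / (n - 2)))
    return OlsFit(slope=slope, intercept=intercept, residual_se=residual_se,
                  n=n, x_mean=float(x_mean), s_xx=s_xx)


def predict_interval(fit: OlsFit, x0: float,
                     level: float = 0.95) -> IntervalPrediction:
    """t-based prediction interval for a NEW recovery longitude at x0.

    half-width = t_{(1+level)/2, n−2} · s · sqrt(1 + 1/n + (x0 − x̄)²/S_xx);
    wider than the confidence interval for the mean response because it
    includes the residual variance of a single new observation.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if fit.df < 1:
        raise ValueError("prediction interval undefined for n < 3")
    center = fit.predict(x0)
    tcrit = stats.t.ppf((1 + level) / 2, fit.df)
    half = tcrit * fit.residual_se * np.sqrt(
        1 + 1 / fit.n + (x0 - fit.x_mean) ** 2 / fit.s_xx)
    return IntervalPrediction(x0=float(x0), center=center,
                              lower=center - half, upper=center + half,
                              level=level)


def clip_clusters_to_band(clusters: ClusterMap,
                          interval: IntervalPrediction) -> ClusterMap:
    """Zero out cluster cells whose cell-center longitude is off the band.

    Membership is judged at cell centers.  Returns a new ClusterMap; cluster
    areas inside the band are available via ``cell_counts()``.
    """
    lons = clusters.cell_center_lons()
    keep = (lons >= interval.lower) & (lons <= interval.upper)
    if not keep.any():
        import warnings

        warnings.warn("prediction band does not intersect the raster extent",
                      RuntimeWarning, stacklevel=2)
    labels = clusters.labels.copy()
    labels[:, ~keep] = 0
    return dataclasses.replace(clusters, labels=labels)
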