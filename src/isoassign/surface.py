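"""Single-isotope continuous assignment over a calibrated feather isoscape.

Instead of assigning to a handful of discrete clusters, the δ²H-only mode
spreads a normal likelihood over every raster cell: the likelihood that a
feather with value ``d2h_f`` was grown in a cell with expected feather value
``v`` is N(d2h_f; v, σ), and normalizing over all valid cells yields a
posterior origin surface.  σ expresses the combined calibration + individual
variation on the feather scale; a sensible choice is the residual SD of the
known-origin calibration birds.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from isoassign.grids import IsoscapeGrid

__all__ = ["ContinuousAssignment", "continuous_posterior", "odds_region"]


@dataclasses.dataclass
class ContinuousAssignment:
    """Normalized per-cell origin probabilities for one observation."""

    posterior: np.ndarray
    valid_mask: np.ndarray
    sigma: float
    observation: float
    origin: tuple[float, float]
    cell_size: float

    def map_cell(self) -> tuple[int, int]:
        """Row/col of the maximum a-posteriori cell."""
        masked = np.where(self.valid_mask, self.posterior, -np.inf)
        return tuple(np.unravel_index(np.argmax(masked), masked.shape))


def continuous_posterior(d2h_f: float, isoscape: IsoscapeGrid,
                         sigma: float) -> ContinuousAssignment:
    """Cell-wise normal likelihood of a feather value, normalized to 1.

    ``isoscape`` must already be on the feather scale (calibration applied).
    Computed in log space and normalized by log-sum-exp, so steep gradients
    cannot underflow the far tail to an all-zero surface.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    mask = isoscape.valid_mask
    if not mask.any():
        raise ValueError("isoscape has no valid cells")
    loglik = np.full(isoscape.shape, -np.inf)
    resid = (d2h_f - isoscape.values[mask]) / sigma
    loglik[mask] = -0.5 * resid ** 2
    peak = loglik[mask].max()
    post = np.zeros(isoscape.shape)
    post[mask] = np.exp(loglik[mask] - peak)
    post[mask] /= post[mask].sum()
    return ContinuousAssignment(posterior=post, valid_mask=mask,
                                sigma=float(sigma), observation=float(d2h_f),
                                origin=isoscape.origin,
                                cell_size=isoscape.cell_size)


def odds_region(assignment: ContinuousAssignment,
                odds_ratio: float = 2.0) -> np.ndarray:
    """Boolean raster of cells within ``odds_ratio`` of the MAP posterior.

    Cells with posterior ≥ max(posterior)/odds_ratio are retained; the MAP
    cell is always in the region, and the region grows monotonically with
    the ratio.
    """
    if odds_ratio < 1:
        raise ValueError("odds_ratio must be >= 1")
    peak = assignment.posterior[assignment.valid_mask].max()
    return assignment.valid_mask & (assignment.posterior >= peak / odds_ratio)
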