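"""Mortality quantification and the integrity-predicts-cytotoxicity fit.

Evans-blue dye exclusion yields dead/total counts per replicate.  Mortality
is expressed in percent; condition-level means are regressed on the
condition's mean microtubule integrity score (ordinary least squares), the
negative slope and R² quantifying how well early microtubule loss predicts
cell death three days later.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .synthetic import MortalityRecord

__all__ = [
    "RegressionResult",
    "mortality_fraction",
    "regress_mortality_on_integrity",
]


@dataclass
class RegressionResult:
    """OLS fit of mortality (%) on integrity score."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    slope_se: float
    intercept_se: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def summary(self) -> str:
        return (
            f"mortality[%] = {self.intercept:.2f} {self.slope:+.3f} * score  "
            f"(R^2 = {self.r_squared:.3f}, n = {self.n_points}; "
            f"slope SE = {self.slope_se:.3f})"
        )


def mortality_fraction(records: list[MortalityRecord]) -> tuple[float, float]:
    """Mean mortality percentage and its SE across replicates.

    The SE is the sample SD of the per-replicate percentages over sqrt(n);
    zero when only one replicate is available.
    """
    if not records:
        raise ValueError("no mortality records given")
    fractions = np.array([100.0 * r.dead / r.total for r in records])
    mean = float(fractions.mean())
    if fractions.size == 1:
        return mean, 0.0
    return mean, float(fractions.std(ddof=1) / np.sqrt(fractions.size))


def regress_mortality_on_integrity(
    pairs: list[tuple[float, float]] | np.ndarray,
) -> RegressionResult:
    """Unweighted OLS of mortality (%) on integrity score.

    ``pairs`` holds (score, mortality%) points, typically one per
    condition.  Requires at least three points and non-degenerate scores.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least three (score, mortality) pairs")
    scores, mortality = arr[:, 0], arr[:, 1]
    if np.ptp(scores) == 0:
        raise ValueError("score variance is zero; slope undefined")
    fit = sm.OLS(mortality, sm.add_constant(scores)).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(np.clip(fit.rsquared, 0.0, 1.0)),
        n_points=int(arr.shape[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
    )
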