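"""Restricted cubic (natural) spline bases for dose-response terms.

The dose term of every hazard model is expanded in a restricted cubic
spline: piecewise cubic between knots, constrained to be linear beyond the
boundary knots.  Knots are placed at empirical percentiles of the
(winsorized) exposure distribution — by default the 10th, 50th and 90th.

The parameterisation is the truncated-power form with the conventional
boundary-knot normalisation (dividing the cubic terms by the squared
boundary-knot span), so the nonlinear columns are on the same scale as the
dose itself.  With k knots the basis has k−1 columns: the dose, plus k−2
restricted cubic terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError, EstimationError

DEFAULT_KNOT_PERCENTILES = (10.0, 50.0, 90.0)


@dataclass(frozen=True)
class RCSBasis:
    """A restricted-cubic-spline knot set for one exposure.

    Parameters
    ----------
    knots
        Strictly increasing knot locations in minutes/day, at least 3.
    parameterisation
        Tag recording the basis convention; only ``"truncated-power-norm2"``
        (cubic terms divided by the squared boundary span) is implemented.
    """

    knots: tuple[float, ...]
    parameterisation: str = "truncated-power-norm2"

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        if knots.size < 3:
            raise ArgumentError(f"need at least 3 knots, got {knots.size}")
        if not np.all(np.isfinite(knots)):
            raise ArgumentError("knots must be finite")
        if not np.all(np.diff(knots) > 0):
            raise ArgumentError(f"knots must be strictly increasing: {self.knots}")

    @property
    def n_columns(self) -> int:
        """Number of basis columns (one linear + k−2 nonlinear)."""
        return len(self.knots) - 1

    @property
    def n_nonlinear(self) -> int:
        return len(self.knots) - 2


def compute_knots(
    doses: np.ndarray,
    percentiles: tuple[float, ...] = DEFAULT_KNOT_PERCENTILES,
) -> RCSBasis:
    """Place spline knots at empirical percentiles of a dose vector.

    Percentiles use the linear-interpolation definition (the numpy default).
    Winsorization, where requested, must be applied to ``doses`` *before*
    knot placement.

    Raises
    ------
    EstimationError
        If the requested percentiles collide (degenerate dose distribution);
        the remedy is fewer knots or a wider percentile spread.
    """
    doses = np.asarray(doses, dtype=float)
    doses = doses[np.isfinite(doses)]
    if np.unique(doses).size < 10:
        raise ArgumentError("need at least 10 distinct finite dose values")
    pct = np.asarray(percentiles, dtype=float)
    if pct.size < 3:
        raise ArgumentError("need at least 3 percentiles")
    if not (np.all(np.diff(pct) > 0) and pct[0] > 0 and pct[-1] < 100):
        raise ArgumentError("percentiles must be strictly increasing within (0, 100)")
    knots = np.percentile(doses, pct)
    if not np.all(np.diff(knots) > 0):
        raise EstimationError(
            f"knot collision at percentiles {tuple(pct)}: knots {tuple(knots)}; "
            "use fewer knots or check the dose distribution"
        )
    return RCSBasis(knots=tuple(float(k) for k in knots))


def rcs_design(x: np.ndarray, basis: RCSBasis) -> np.ndarray:
    """Evaluate the restricted-cubic-spline design matrix at doses ``x``.

    Column 0 is the dose itself; columns 1..k−2 are the restricted cubic
    terms

        R_j(x) = [ (x−t_j)⁺³ − (x−t_{k−1})⁺³·(t_k−t_j)/(t_k−t_{k−1})
                   + (x−t_k)⁺³·(t_{k−1}−t_j)/(t_k−t_{k−1}) ] / (t_k−t_1)²

    which are exactly zero below the first knot and linear above the last,
    with continuous second derivatives at the interior knots.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ArgumentError("dose vector contains non-finite values")
    t = np.asarray(basis.knots, dtype=float)
    k = t.size
    scale = (t[-1] - t[0]) ** 2
    cols = np.empty((x.size, k - 1), dtype=float)
    cols[:, 0] = x

    def pos3(v: np.ndarray) -> np.ndarray:
        return np.clip(v, 0.0, None) ** 3

    span = t[-1] - t[-2]
    for j in range(k - 2):
        cols[:, j + 1] = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / span
            + pos3(x - t[-1]) * (t[-2] - t[j]) / span
        ) / scale
    return cols
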