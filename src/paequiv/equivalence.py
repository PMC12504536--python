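"""Intensity-equivalence from matched risk-reduction levels.

For each risk-reduction level ℓ (in %, corresponding to HR = 1 − ℓ/100)
every intensity's dose-response curve is inverted for the smallest dose
reaching that HR.  Dividing the MPA and LPA doses by the VPA dose equates
their minutes to one minute of VPA; the median of these per-level ratios
over the risk band (default 5–35 %) is the headline equivalence figure.
Levels a curve never reaches are recorded as undefined and excluded from
the median, mirroring how light activity only attains modest reductions.

Under log-linear dose-response the per-level ratio is level-independent
and equals the slope ratio — the closed-form oracle used throughout the
test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve
from .errors import ArgumentError, PipelineError

DEFAULT_RR_BAND = (5.0, 35.0)  # % risk reduction
DEFAULT_RR_STEP = 0.1  # "continuous increments" mode
REPORTING_RR_STEP = 5.0  # supplementary-table mode


def invert_curve(curve: DoseResponseCurve, target_hr: float) -> float:
    """Smallest dose at which the curve first reaches HR <= target.

    Linear interpolation between the two grid points bracketing the first
    crossing; well-defined for non-monotone curves.  Returns NaN when the
    curve never reaches the target.
    """
    if not target_hr > 0:
        raise ArgumentError("target_hr must be > 0")
    if target_hr > 1:
        raise ArgumentError("target_hr must be <= 1 (a risk reduction)")
    hr = curve.hr
    below = hr <= target_hr
    if not below.any():
        return math.nan
    j = int(np.argmax(below))
    if j == 0:
        return float(curve.dose[0])
    d0, d1 = curve.dose[j - 1], curve.dose[j]
    h0, h1 = hr[j - 1], hr[j]
    if h1 == h0:
        return float(d1)
    return float(d0 + (target_hr - h0) / (h1 - h0) * (d1 - d0))


@dataclass
class EquivalenceTable:
    """Per-level inverted doses and ratios, plus median summaries."""

    outcome: str
    rr_levels: np.ndarray  # % risk reduction
    dose_vpa: np.ndarray
    dose_mpa: np.ndarray
    dose_lpa: np.ndarray
    ratio_mpa: np.ndarray  # minutes of MPA per minute of VPA, NaN if undefined
    ratio_lpa: np.ndarray
    median_ratio_mpa: float
    median_ratio_lpa: float
    mpa_lpa_ratio: float  # minutes of LPA per minute of MPA
    n_defined_mpa: int = 0
    n_defined_lpa: int = 0
    undefined_handling: str = "exclude"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "risk_reduction_pct": self.rr_levels,
                "target_hr": 1.0 - self.rr_levels / 100.0,
                "dose_vpa": self.dose_vpa,
                "dose_mpa": self.dose_mpa,
                "dose_lpa": self.dose_lpa,
                "mpa_per_vpa": self.ratio_mpa,
                "lpa_per_vpa": self.ratio_lpa,
            }
        )

    def summary(self) -> dict:
        return {
            "outcome": self.outcome,
            "median_mpa_per_vpa": _round_opt(self.median_ratio_mpa, 2),
            "median_lpa_per_vpa": _round_opt(self.median_ratio_lpa, 2),
            "lpa_per_mpa": _round_opt(self.mpa_lpa_ratio, 2),
            "median_mpa_per_vpa_1dp": _round_opt(self.median_ratio_mpa, 1),
            "median_lpa_per_vpa_1dp": _round_opt(self.median_ratio_lpa, 1),
            "levels_defined_mpa": self.n_defined_mpa,
            "levels_defined_lpa": self.n_defined_lpa,
            "levels_total": int(self.rr_levels.size),
        }


def _round_opt(x: float, nd: int) -> float:
    return float("nan") if math.isnan(x) else round(x, nd)


def _nanmedian(values: np.ndarray) -> float:
    defined = values[~np.isnan(values)]
    return float(np.median(defined)) if defined.size else math.nan


def equivalence_grid(
    curve_vpa: DoseResponseCurve,
    curve_mpa: DoseResponseCurve,
    curve_lpa: DoseResponseCurve,
    rr_min: float = DEFAULT_RR_BAND[0],
    rr_max: float = DEFAULT_RR_BAND[1],
    step: float = DEFAULT_RR_STEP,
    undefined: str = "exclude",
) -> EquivalenceTable:
    """Invert all three curves across the risk-reduction band.

    The VPA dose is measured from its referent (0), and MPA/LPA doses are
    likewise measured as minutes above their own referents, so the LPA
    ratio reads "additional LPA minutes per VPA minute".

    ``undefined`` governs levels some curve cannot reach: "exclude" (drop
    from the median, the default) or "cap" (impute the curve's maximum
    dose, flagged in the output).
    """
    if not rr_min < rr_max:
        raise ArgumentError("rr_min must be < rr_max")
    if undefined not in ("exclude", "cap"):
        raise ArgumentError("undefined must be 'exclude' or 'cap'")
    outcomes = {curve_vpa.outcome, curve_mpa.outcome, curve_lpa.outcome}
    if len(outcomes) != 1:
        raise ArgumentError(f"curves mix outcomes: {sorted(outcomes)}")

    levels = np.round(np.arange(rr_min, rr_max + step / 2, step), 10)
    targets = 1.0 - levels / 100.0
    doses = {}
    for name, curve in (("vpa", curve_vpa), ("mpa", curve_mpa), ("lpa", curve_lpa)):
        d = np.array([invert_curve(curve, t) for t in targets])
        d = d - curve.referent  # minutes above the intensity's referent
        if undefined == "cap":
            d = np.where(np.isnan(d), curve.dose[-1] - curve.referent, d)
        doses[name] = d

    if np.all(np.isnan(doses["vpa"])) or np.all(doses["vpa"][~np.isnan(doses["vpa"])] <= 0):
        raise PipelineError("VPA curve reaches no level in the band: no denominator")

    with np.errstate(invalid="ignore", divide="ignore"):
        r_m = doses["mpa"] / doses["vpa"]
        r_l = doses["lpa"] / doses["vpa"]
    r_m = np.where(doses["vpa"] > 0, r_m, math.nan)
    r_l = np.where(doses["vpa"] > 0, r_l, math.nan)

    med_m = _nanmedian(r_m)
    med_l = _nanmedian(r_l)
    return EquivalenceTable(
        outcome=curve_vpa.outcome,
        rr_levels=levels,
        dose_vpa=doses["vpa"],
        dose_mpa=doses["mpa"],
        dose_lpa=doses["lpa"],
        ratio_mpa=r_m,
        ratio_lpa=r_l,
        median_ratio_mpa=med_m,
        median_ratio_lpa=med_l,
        mpa_lpa_ratio=derive_secondary_ratio(med_l, med_m, ndigits=None),
        n_defined_mpa=int(np.sum(~np.isnan(r_m))),
        n_defined_lpa=int(np.sum(~np.isnan(r_l))),
        undefined_handling=undefined,
    )


def derive_secondary_ratio(
    median_r_lpa: float, median_r_mpa: float, ndigits: int | None = 2
) -> float:
    """Minutes of LPA per minute of MPA from the two VPA-anchored medians.

    This is the arithmetic identity behind the published summary table's
    last column: VPA:LPA divided by VPA:MPA, reported to 2 decimals.
    """
    if math.isnan(median_r_lpa) or math.isnan(median_r_mpa):
        return math.nan
    if median_r_lpa <= 0 or median_r_mpa <= 0:
        raise ArgumentError("medians must be positive")
    ratio = median_r_lpa / median_r_mpa
    return round(ratio, ndigits) if ndigits is not None else ratio


def cross_outcome_median(values: dict[str, float] | list[float]) -> float:
    """Empirical median of per-outcome medians (mean of the central pair)."""
    vals = list(values.values()) if isinstance(values, dict) else list(values)
    vals = [v for v in vals if not math.isnan(v)]
    if not vals:
        raise ArgumentError("no defined values")
    return float(np.median(vals))
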