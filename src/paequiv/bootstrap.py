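"""Nonparametric bootstrap confidence intervals for equivalence ratios.

The principal mode resamples *subjects* with replacement and re-runs the
whole estimation path — winsorization, knot placement, model fits, curve
construction, inversion — inside every resample, so the intervals carry
all of that variability.  A faster "curve" mode draws coefficient vectors
from the fitted sampling distribution N(β̂, V̂) without refitting,
matching a literal reading of bootstrapping "model-predicted values".

Intervals are the empirical 2.5th/97.5th percentiles of the B resampled
values, reported at rounded predicted risk levels (HR 0.65, 0.70, …,
0.95) and for the median ratio over the risk band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve, predict_hr_curve, referent_dose, winsorize_doses
from .equivalence import DEFAULT_RR_BAND, DEFAULT_RR_STEP, equivalence_grid, invert_curve
from .errors import ArgumentError, EstimationError
from .hazards import HazardFit
from .pipeline import DEFAULT_BOOT_LEVELS, analyze_outcome
from .splines import DEFAULT_KNOT_PERCENTILES

MAX_RETRIES_PER_RESAMPLE = 100


@dataclass
class BootstrapResult:
    """Bootstrap distributions and percentile bounds for one outcome."""

    outcome: str
    B: int
    levels: tuple[float, ...]  # rounded HR levels
    mode: str
    seed: int
    point_mpa: np.ndarray  # per-level point estimates (len(levels),)
    point_lpa: np.ndarray
    point_median_mpa: float
    point_median_lpa: float
    dist_mpa: np.ndarray  # (B, len(levels))
    dist_lpa: np.ndarray
    dist_median_mpa: np.ndarray  # (B,)
    dist_median_lpa: np.ndarray
    n_redraws: int = 0
    diagnostics: list = field(default_factory=list)

    def _bounds(self, dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        import warnings

        with warnings.catch_warnings():
            # all-NaN level columns (never-reached levels) yield NaN bounds
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanpercentile(dist, 2.5, axis=0)
            hi = np.nanpercentile(dist, 97.5, axis=0)
        return np.atleast_1d(lo), np.atleast_1d(hi)

    def interval_frame(self) -> pd.DataFrame:
        lo_m, hi_m = self._bounds(self.dist_mpa)
        lo_l, hi_l = self._bounds(self.dist_lpa)
        return pd.DataFrame(
            {
                "target_hr": self.levels,
                "risk_reduction_pct": [round(100 * (1 - h), 6) for h in self.levels],
                "mpa_per_vpa": self.point_mpa,
                "mpa_lo95": lo_m,
                "mpa_hi95": hi_m,
                "lpa_per_vpa": self.point_lpa,
                "lpa_lo95": lo_l,
                "lpa_hi95": hi_l,
            }
        )

    def median_interval(self, which: str = "mpa") -> tuple[float, float, float]:
        """(point, lower, upper) for the median ratio over the band."""
        if which == "mpa":
            point, dist = self.point_median_mpa, self.dist_median_mpa
        else:
            point, dist = self.point_median_lpa, self.dist_median_lpa
        lo, hi = self._bounds(dist[:, None])
        return point, float(lo[0]), float(hi[0])

    def check_bounds_contain_point(self) -> None:
        """Diagnostic only: log (not fail) point estimates outside bounds."""
        for which in ("mpa", "lpa"):
            point, lo, hi = self.median_interval(which)
            if not math.isnan(point) and not (lo - 1e-9 <= point <= hi + 1e-9):
                self.diagnostics.append(
                    f"median {which} point {point:.4g} outside [{lo:.4g}, {hi:.4g}]"
                )

    def summary(self) -> dict:
        pm, lm, hm = self.median_interval("mpa")
        pl, ll, hl = self.median_interval("lpa")
        self.check_bounds_contain_point()
        return {
            "outcome": self.outcome,
            "B": self.B,
            "mode": self.mode,
            "seed": self.seed,
            "median_mpa_per_vpa": pm,
            "median_mpa_ci": [lm, hm],
            "median_lpa_per_vpa": pl,
            "median_lpa_ci": [ll, hl],
            "levels": self.interval_frame().to_dict(orient="records"),
            "n_redraws": self.n_redraws,
            "diagnostics": list(self.diagnostics),
        }


def _ratios_at_levels(
    curves: dict[str, DoseResponseCurve], levels: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    r_m = np.empty(len(levels))
    r_l = np.empty(len(levels))
    for j, hr in enumerate(levels):
        d_v = invert_curve(curves["vpa"], hr) - curves["vpa"].referent
        d_m = invert_curve(curves["mpa"], hr) - curves["mpa"].referent
        d_l = invert_curve(curves["lpa"], hr) - curves["lpa"].referent
        r_m[j] = d_m / d_v if d_v and d_v > 0 else math.nan
        r_l[j] = d_l / d_v if d_v and d_v > 0 else math.nan
    return r_m, r_l


def bootstrap_equivalence(
    cohort: pd.DataFrame,
    outcome: str,
    family: str = "cox",
    covariates: Sequence[str] = ("age", "sex", "lifestyle"),
    winsor_percentile: float = 97.5,
    knot_percentiles: Sequence[float] = DEFAULT_KNOT_PERCENTILES,
    rr_band: tuple[float, float] = DEFAULT_RR_BAND,
    rr_step: float = DEFAULT_RR_STEP,
    B: int = 1000,
    levels: Sequence[float] = DEFAULT_BOOT_LEVELS,
    mode: str = "cohort",
    seed: int = 0,
    refit_knots: bool = True,
) -> BootstrapResult:
    """Percentile bootstrap of the equivalence ratios.

    mode "cohort": subject-level resampling with full refits (knots are
    recomputed inside each resample unless ``refit_knots=False``).
    mode "curve": coefficient draws from N(β̂, V̂), no refitting.
    Resamples with no event of interest are redrawn, up to a cap.
    """
    if B < 1:
        raise ArgumentError("B must be >= 1")
    if mode not in ("cohort", "curve"):
        raise ArgumentError("mode must be 'cohort' or 'curve'")
    for hr in levels:
        if not 0 < hr < 1:
            raise ArgumentError("levels must be HR values in (0, 1)")

    kwargs = dict(
        family=family,
        covariates=covariates,
        winsor_percentile=winsor_percentile,
        knot_percentiles=knot_percentiles,
        rr_band=rr_band,
        rr_step=rr_step,
    )
    table0, fits0, curves0 = analyze_outcome(cohort, outcome, **kwargs)
    point_m, point_l = _ratios_at_levels(curves0, levels)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0B007]))
    L = len(levels)
    dist_m = np.full((B, L), np.nan)
    dist_l = np.full((B, L), np.nan)
    dist_med_m = np.full(B, np.nan)
    dist_med_l = np.full(B, np.nan)
    n_redraws = 0
    diagnostics: list[str] = []

    if mode == "cohort":
        n = len(cohort)
        fixed_kwargs = dict(kwargs)
        if not refit_knots:
            fixed_kwargs["fixed_bases"] = {i: f.basis for i, f in fits0.items()}
        for b in range(B):
            for attempt in range(MAX_RETRIES_PER_RESAMPLE):
                idx = rng.integers(0, n, size=n)
                sample = cohort.iloc[idx].reset_index(drop=True)
                if (sample["event_code"] == 1).sum() >= 1:
                    break
                n_redraws += 1
            else:
                raise EstimationError("retry cap exceeded: resamples without events")
            try:
                table, _, curves = analyze_outcome(sample, outcome, **fixed_kwargs)
            except Exception as exc:  # degenerate resample: record, redraw once
                diagnostics.append(f"resample {b}: {exc}")
                continue
            dist_m[b], dist_l[b] = _ratios_at_levels(curves, levels)
            dist_med_m[b] = table.median_ratio_mpa
            dist_med_l[b] = table.median_ratio_lpa
    else:
        prepared = winsorize_doses(cohort, winsor_percentile)
        for b in range(B):
            curves_b: dict[str, DoseResponseCurve] = {}
            for intensity, fit in fits0.items():
                draw = rng.multivariate_normal(fit.params, fit.cov, method="cholesky")
                fit_b = HazardFit(
                    params=draw, cov=fit.cov, names=fit.names, spec=fit.spec,
                    basis=fit.basis, spline_idx=fit.spline_idx,
                    nonlinear_idx=fit.nonlinear_idx, n=fit.n, n_events=fit.n_events,
                    loglik=fit.loglik, loglik_trace=fit.loglik_trace,
                    n_iter=fit.n_iter, converged=fit.converged,
                )
                ref = referent_dose(intensity, prepared)
                gmax = float(prepared[f"{intensity}_min"].max())
                curves_b[intensity] = predict_hr_curve(fit_b, referent=ref, grid_max=gmax)
            dist_m[b], dist_l[b] = _ratios_at_levels(curves_b, levels)
            try:
                tb = equivalence_grid(
                    curves_b["vpa"], curves_b["mpa"], curves_b["lpa"],
                    rr_min=rr_band[0], rr_max=rr_band[1], step=rr_step,
                )
                dist_med_m[b] = tb.median_ratio_mpa
                dist_med_l[b] = tb.median_ratio_lpa
            except Exception as exc:
                diagnostics.append(f"draw {b}: {exc}")

    result = BootstrapResult(
        outcome=outcome, B=B, levels=tuple(levels), mode=mode, seed=seed,
        point_mpa=point_m, point_lpa=point_l,
        point_median_mpa=table0.median_ratio_mpa,
        point_median_lpa=table0.median_ratio_lpa,
        dist_mpa=dist_m, dist_lpa=dist_l,
        dist_median_mpa=dist_med_m, dist_median_lpa=dist_med_l,
        n_redraws=n_redraws, diagnostics=diagnostics,
    )
    result.check_bounds_contain_point()
    return result
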