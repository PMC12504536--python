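"""End-to-end orchestration: prepare → fit → curves → equivalence → report.

``analyze_outcome`` is the single-outcome workhorse (also re-run inside
every bootstrap resample): winsorize, place knots, fit one hazard model
per intensity with mutual volume adjustment, build referent-anchored HR
curves, and invert them into an equivalence table.

``run_pipeline`` drives the full analysis from an :class:`AnalysisConfig`
(loadable from YAML): simulate or load a cohort, apply the exclusion
rules per outcome, run every outcome, attach diagnostics (nonlinearity
and proportional-hazards p-values), bootstrap confidence intervals, and
write machine-readable results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from .cohort import TruthScenario, generate_cohort, read_cohort
from .dose_response import (
    DEFAULT_GRID_STEP,
    DEFAULT_WINSOR_PERCENTILE,
    DoseResponseCurve,
    apply_exclusions,
    predict_hr_curve,
    referent_dose,
    winsorize_doses,
)
from .equivalence import (
    DEFAULT_RR_BAND,
    DEFAULT_RR_STEP,
    EquivalenceTable,
    equivalence_grid,
)
from .errors import ArgumentError, ConfigurationError, PipelineError
from .hazards import (
    HazardFit,
    ModelSpec,
    fit_model,
    schoenfeld_ph_test,
    wald_nonlinearity_test,
)
from .splines import DEFAULT_KNOT_PERCENTILES, compute_knots

INTENSITIES = ("lpa", "mpa", "vpa")

#: Rounded HR levels at which bootstrap intervals are reported
#: (risk reductions 35%, 30%, ..., 5%).
DEFAULT_BOOT_LEVELS = (0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95)


@dataclass
class OutcomeResult:
    """Everything the pipeline computes for one outcome."""

    outcome: str
    fits: dict[str, HazardFit]
    curves: dict[str, DoseResponseCurve]
    table: EquivalenceTable
    diagnostics: pd.DataFrame
    exclusion_log: dict
    n: int
    events: int
    person_years: float


def analyze_outcome(
    cohort: pd.DataFrame,
    outcome: str,
    family: str = "cox",
    covariates: Sequence[str] = ("age", "sex", "lifestyle"),
    winsor_percentile: float = DEFAULT_WINSOR_PERCENTILE,
    knot_percentiles: Sequence[float] | None = DEFAULT_KNOT_PERCENTILES,
    rr_band: tuple[float, float] = DEFAULT_RR_BAND,
    rr_step: float = DEFAULT_RR_STEP,
    grid_step: float = DEFAULT_GRID_STEP,
    ties: str = "efron",
    undefined: str = "exclude",
    fixed_bases: Mapping[str, "object"] | None = None,
) -> tuple[EquivalenceTable, dict[str, HazardFit], dict[str, DoseResponseCurve]]:
    """Winsorize → knots → per-intensity fits → curves → equivalence.

    Assumes exclusions were already applied (they sit outside the
    bootstrap refit by construction of the resampling unit).  Pass
    ``fixed_bases`` (intensity → RCSBasis) to reuse pre-computed knots,
    e.g. when a bootstrap is configured not to refit them; pass
    ``knot_percentiles=None`` for log-linear (single linear dose term)
    models, the matched family for closed-form validation truths.
    """
    prepared = winsorize_doses(cohort, winsor_percentile)
    fits: dict[str, HazardFit] = {}
    curves: dict[str, DoseResponseCurve] = {}
    for intensity in INTENSITIES:
        doses = prepared[f"{intensity}_min"].to_numpy(dtype=float)
        if fixed_bases is not None:
            basis = fixed_bases[intensity]
        elif knot_percentiles is None:
            basis = None
        else:
            basis = compute_knots(doses, tuple(knot_percentiles))
        spec = ModelSpec(
            outcome=outcome,
            intensity=intensity,
            basis=basis,
            covariates=tuple(covariates),
            family=family,
            ties=ties,
        )
        fit = fit_model(prepared, spec)
        ref = referent_dose(intensity, prepared)
        curves[intensity] = predict_hr_curve(
            fit, referent=ref, grid_max=float(doses.max()), step=grid_step
        )
        fits[intensity] = fit
    table = equivalence_grid(
        curves["vpa"], curves["mpa"], curves["lpa"],
        rr_min=rr_band[0], rr_max=rr_band[1], step=rr_step, undefined=undefined,
    )
    return table, fits, curves


def diagnostics_table(fits: Mapping[str, HazardFit]) -> pd.DataFrame:
    """Nonlinearity Wald p and global Schoenfeld PH p per intensity model."""
    rows = []
    for intensity, fit in fits.items():
        ph = schoenfeld_ph_test(fit)
        rows.append(
            {
                "intensity": intensity,
                "n": fit.n,
                "events": fit.n_events,
                "nonlinearity_p": wald_nonlinearity_test(fit),
                "ph_global_p": ph["global_p"],
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def person_year_table(cohorts: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-outcome accounting: n analysed, events, person-years."""
    rows = []
    for outcome, frame in cohorts.items():
        rows.append(
            {
                "outcome": outcome,
                "n": len(frame),
                "events": int((frame["event_code"] == 1).sum()),
                "person_years": float(frame["follow_time"].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class AnalysisConfig:
    """Single source of truth for a full pipeline run."""

    cohort_path: str | None = None
    truth: TruthScenario | None = None
    n_subjects: int = 20000
    outcomes: Mapping[str, str] = field(
        default_factory=lambda: {"acm": "cox", "cvd": "finegray"}
    )
    covariates: tuple[str, ...] = ("age", "sex", "lifestyle")
    winsor_percentile: float = DEFAULT_WINSOR_PERCENTILE
    knot_percentiles: tuple[float, ...] = DEFAULT_KNOT_PERCENTILES
    rr_band: tuple[float, float] = DEFAULT_RR_BAND
    rr_step: float = DEFAULT_RR_STEP
    boot_levels: tuple[float, ...] = DEFAULT_BOOT_LEVELS
    n_boot: int = 1000
    boot_mode: str = "cohort"
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.cohort_path is None and self.truth is None:
            self.truth = TruthScenario(seed=self.seed)
        for fam in self.outcomes.values():
            if fam not in ("cox", "finegray"):
                raise ConfigurationError(f"unknown model family {fam!r}")
        lo, hi = self.rr_band
        if not 0 < lo < hi < 100:
            raise ConfigurationError("risk band must satisfy 0 < lo < hi < 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        truth = None
        if "truth" in raw:
            t = dict(raw.pop("truth"))
            effects = {}
            for name, spec in t.pop("dose_effects", {}).items():
                effects[name] = cohort_mod.DoseEffect(**spec)
            if effects:
                t["dose_effects"] = {
                    i: effects.get(i, cohort_mod.DoseEffect()) for i in INTENSITIES
                }
            truth = TruthScenario(**t)
        for key in ("outcomes",):
            if key in raw and raw[key] is not None:
                raw[key] = dict(raw[key])
        for key in ("covariates", "knot_percentiles", "rr_band", "boot_levels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(truth=truth, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if self.truth is not None:
            t = data["truth"]
            t["intensity_corr"] = np.asarray(self.truth.intensity_corr).tolist()
            t["dose_effects"] = {
                k: dataclasses.asdict(v) for k, v in self.truth.dose_effects.items()
            }
            t["intensity_log_means"] = dict(self.truth.intensity_log_means)
            t["intensity_log_sds"] = dict(self.truth.intensity_log_sds)
            t["covariate_effects"] = dict(self.truth.covariate_effects)
        data["outcomes"] = dict(self.outcomes)
        Path(path).write_text(yaml.safe_dump(_listify(data), sort_keys=False))


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _load_or_simulate(config: AnalysisConfig) -> pd.DataFrame:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    truth = config.truth.with_seed(config.seed) if config.truth.seed != config.seed else config.truth
    return generate_cohort(truth, config.n_subjects)


def run_pipeline(config: AnalysisConfig, with_bootstrap: bool = False) -> dict:
    """Execute the full analysis; returns (and writes) the report bundle."""
    from .bootstrap import bootstrap_equivalence  # lazy: avoids import cycle

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = _load_or_simulate(config)

    bundle: dict = {"config_seed": config.seed, "outcomes": {}}
    prepared_cohorts: dict[str, pd.DataFrame] = {}
    for outcome, family in config.outcomes.items():
        kept, log = apply_exclusions(cohort)
        prepared_cohorts[outcome] = kept
        try:
            table, fits, curves = analyze_outcome(
                kept,
                outcome,
                family=family,
                covariates=config.covariates,
                winsor_percentile=config.winsor_percentile,
                knot_percentiles=config.knot_percentiles,
                rr_band=config.rr_band,
                rr_step=config.rr_step,
            )
        except PipelineError as exc:
            bundle["outcomes"][outcome] = {
                "status": "no-equivalence",
                "reason": str(exc),
                "exclusions": log.to_dict(),
            }
            continue
        diag = diagnostics_table(fits)
        entry = {
            "status": "ok",
            "family": family,
            "exclusions": log.to_dict(),
            "summary": table.summary(),
            "diagnostics": diag.to_dict(orient="records"),
            "knots": {i: list(fits[i].basis.knots) for i in INTENSITIES},
            "referents": {i: curves[i].referent for i in INTENSITIES},
        }
        if with_bootstrap:
            boot = bootstrap_equivalence(
                kept,
                outcome=outcome,
                family=family,
                covariates=config.covariates,
                winsor_percentile=config.winsor_percentile,
                knot_percentiles=config.knot_percentiles,
                B=config.n_boot,
                levels=config.boot_levels,
                mode=config.boot_mode,
                seed=config.seed,
            )
            entry["bootstrap"] = boot.summary()
        bundle["outcomes"][outcome] = entry
        table.to_frame().to_csv(out_dir / f"equivalence_{outcome}.csv", index=False)
        for i, curve in curves.items():
            curve.to_frame().to_csv(out_dir / f"curve_{outcome}_{i}.csv", index=False)

    pyt = person_year_table(prepared_cohorts)
    pyt.to_csv(out_dir / "person_years.csv", index=False)
    bundle["person_years"] = pyt.to_dict(orient="records")
    (out_dir / "results.json").write_text(json.dumps(_listify(bundle), indent=2, allow_nan=True))
    return bundle
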