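"""Synthetic accelerometry-cohort generator.

Emulates the statistical structure of a wrist-accelerometer cohort with
linked time-to-event outcomes: right-skewed, correlated daily minutes of
light / moderate / vigorous physical activity (LPA/MPA/VPA), a small set of
confounders, cause-specific exponential event and competing-event hazards
scaled by ``exp(linear predictor)``, and administrative censoring with a
staggered entry so that follow-up has the familiar "horizon minus entry"
shape.

Ground truth is specified as a :class:`TruthScenario`: per-intensity
log-hazard dose-response functions (linear, piecewise-linear "spline", or
null), covariate effects, baseline hazards, censoring geometry and the
joint intensity distribution.  Everything is driven by one integer seed
through named substreams, so adding a draw stream never perturbs the
others.

Cohort tables are plain pandas DataFrames with the documented column set
(see :data:`COHORT_COLUMNS`) and round-trip through CSV.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConfigurationError

INTENSITIES = ("lpa", "mpa", "vpa")

#: Canonical cohort column order. One row per subject; ``event_code`` is
#: 0 = censored, 1 = event of interest, 2 = competing event.
COHORT_COLUMNS = (
    "id",
    "lpa_min",
    "mpa_min",
    "vpa_min",
    "age",
    "sex",
    "lifestyle",
    "follow_time",
    "event_code",
    "prevalent_flag",
    "entry_offset",
)

#: Centering constants applied to covariates inside the linear predictor so
#: the baseline hazard refers to a typical subject.
COVARIATE_CENTERS: Mapping[str, float] = {"age": 61.6, "sex": 0.0, "lifestyle": 0.0}


@dataclass(frozen=True)
class DoseEffect:
    """Ground-truth log-hazard contribution of one intensity.

    ``shape`` is one of

    - ``"null"``   — identically zero at every dose,
    - ``"linear"`` — ``slope`` log-HR per minute/day,
    - ``"spline"`` — piecewise-linear log-hazard through ``(knot, value)``
      pairs, constant beyond the end knots.
    """

    shape: str = "null"
    slope: float = 0.0
    knots: tuple[float, ...] = ()
    values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.shape not in ("null", "linear", "spline"):
            raise ConfigurationError(f"unknown dose-effect shape {self.shape!r}")
        if self.shape == "spline":
            if len(self.knots) != len(self.values) or len(self.knots) < 2:
                raise ConfigurationError("spline shape needs matching knots/values, >= 2")
            if not np.all(np.diff(self.knots) > 0):
                raise ConfigurationError("spline knots must be strictly increasing")

    def loghr(self, dose: np.ndarray) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        if self.shape == "null":
            return np.zeros_like(dose)
        if self.shape == "linear":
            return self.slope * dose
        return np.interp(dose, self.knots, self.values)


def _default_corr() -> np.ndarray:
    return np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.5], [0.2, 0.5, 1.0]])


@dataclass(frozen=True)
class TruthScenario:
    """Generative ground truth for one synthetic cohort.

    Intensity minutes are multivariate log-normal (order LPA, MPA, VPA in
    the correlation matrix) with an additive location offset for LPA, so
    the LPA marginal has a hard minimum like the empirical referent
    (37.9 min/day).  Event and competing times are cause-specific
    exponentials; censoring is administrative at ``horizon_years`` minus a
    uniform entry stagger.
    """

    dose_effects: Mapping[str, DoseEffect] = field(
        default_factory=lambda: {i: DoseEffect() for i in INTENSITIES}
    )
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.07, "sex": -0.35, "lifestyle": -0.10}
    )
    baseline_hazard: float = 0.0046  # events of interest per person-year
    competing_hazard: float = 0.005  # competing events per person-year
    horizon_years: float = 9.7
    entry_stagger_years: float = 3.4
    intensity_log_means: Mapping[str, float] = field(
        default_factory=lambda: {"lpa": np.log(120.0), "mpa": np.log(28.0), "vpa": np.log(4.0)}
    )
    intensity_log_sds: Mapping[str, float] = field(
        default_factory=lambda: {"lpa": 0.40, "mpa": 0.60, "vpa": 0.80}
    )
    intensity_corr: np.ndarray = field(default_factory=_default_corr)
    lpa_offset_min: float = 37.9
    prevalent_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.competing_hazard < 0:
            raise ConfigurationError("competing_hazard must be >= 0")
        if self.horizon_years <= self.entry_stagger_years:
            raise ConfigurationError("horizon must exceed the entry stagger")
        if not 0 <= self.prevalent_frac < 1:
            raise ConfigurationError("prevalent_frac must lie in [0, 1)")
        corr = np.asarray(self.intensity_corr, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ConfigurationError("correlation matrix must be symmetric 3x3")
        if np.min(np.linalg.eigvalsh(corr)) <= 0:
            raise ConfigurationError("correlation matrix must be positive definite")
        for i in INTENSITIES:
            if i not in self.dose_effects:
                raise ConfigurationError(f"missing dose effect for {i}")
        for name in self.covariate_effects:
            if name not in COVARIATE_CENTERS:
                raise ConfigurationError(f"unknown covariate {name!r}")

    def with_seed(self, seed: int) -> "TruthScenario":
        return replace(self, seed=seed)

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        """Ground-truth log-hazard of the event of interest, per subject."""
        lp = np.zeros(len(frame))
        for i in INTENSITIES:
            lp += self.dose_effects[i].loghr(frame[f"{i}_min"].to_numpy())
        for name, beta in self.covariate_effects.items():
            lp += beta * (frame[name].to_numpy(dtype=float) - COVARIATE_CENTERS[name])
        return lp


def stream(seed: int, name: str) -> np.random.Generator:
    """Named, seed-stable random substream.

    The stream key is a CRC32 of the name, so the draw sequence of one
    stream is invariant to which other streams exist.
    """
    key = zlib.crc32(name.encode("utf8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def generate_cohort(truth: TruthScenario, n: int) -> pd.DataFrame:
    """Draw ``n`` subjects under ``truth``; deterministic given (seed, n)."""
    if n < 2:
        raise ArgumentError(f"n must be >= 2, got {n}")

    rng_x = stream(truth.seed, "exposures")
    rng_c = stream(truth.seed, "covariates")
    rng_e = stream(truth.seed, "events")
    rng_z = stream(truth.seed, "censoring")
    rng_p = stream(truth.seed, "prevalent")

    corr = np.asarray(truth.intensity_corr, dtype=float)
    sds = np.array([truth.intensity_log_sds[i] for i in INTENSITIES])
    means = np.array([truth.intensity_log_means[i] for i in INTENSITIES])
    cov = corr * np.outer(sds, sds)
    logs = rng_x.multivariate_normal(means, cov, size=n, method="cholesky")
    minutes = np.exp(logs)
    minutes[:, 0] += truth.lpa_offset_min  # LPA location offset

    frame = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "lpa_min": minutes[:, 0],
            "mpa_min": minutes[:, 1],
            "vpa_min": minutes[:, 2],
            "age": rng_c.normal(61.6, 7.9, size=n),
            "sex": (rng_c.random(n) < 0.564).astype(int),
            "lifestyle": rng_c.normal(0.0, 1.0, size=n),
        }
    )

    lp = truth.linear_predictor(frame)
    t_event = rng_e.exponential(1.0, size=n) / (truth.baseline_hazard * np.exp(lp))
    if truth.competing_hazard > 0:
        t_comp = rng_e.exponential(1.0 / truth.competing_hazard, size=n)
    else:
        t_comp = np.full(n, np.inf)
    entry = rng_z.uniform(0.0, truth.entry_stagger_years, size=n)
    t_cens = truth.horizon_years - entry

    follow = np.minimum(np.minimum(t_event, t_comp), t_cens)
    code = np.where(t_event <= follow, 1, np.where(t_comp <= follow, 2, 0))
    frame["follow_time"] = np.maximum(follow, 1e-8)
    frame["event_code"] = code.astype(int)
    frame["prevalent_flag"] = rng_p.random(n) < truth.prevalent_frac
    frame["entry_offset"] = entry
    return frame[list(COHORT_COLUMNS)]


def empirical_event_rate(cohort: pd.DataFrame, event_code: int = 1) -> float:
    """Events of the given code per person-year of follow-up."""
    if len(cohort) == 0:
        raise ArgumentError("empty cohort")
    events = int((cohort["event_code"] == event_code).sum())
    person_years = float(cohort["follow_time"].sum())
    return events / person_years


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns and c != "entry_offset"]
    if missing:
        raise ArgumentError(f"cohort file missing columns: {missing}")
    frame["prevalent_flag"] = frame["prevalent_flag"].astype(bool)
    return frame


# ---------------------------------------------------------------------------
# Named scenarios


def null_scenario(seed: int = 0, **overrides) -> TruthScenario:
    """All intensities null: no dose-response signal anywhere."""
    return TruthScenario(seed=seed, **overrides)


def loglinear_scenario(
    beta_vpa: float = -0.04,
    beta_mpa: float = -0.01,
    beta_lpa: float = 0.0,
    seed: int = 0,
    baseline_hazard: float = 0.02,
    **overrides,
) -> TruthScenario:
    """Log-linear validation truth with a known equivalence ratio.

    Under log-linear dose-response the minutes-equivalence ratio between
    two intensities is level-independent and equals the slope ratio
    (default β_V/β_M = 4).  The baseline hazard is deliberately event-rich
    (0.02/py) so parameter-recovery checks at moderate n are informative.
    """
    effects = {
        "lpa": DoseEffect("linear", slope=beta_lpa) if beta_lpa else DoseEffect("null"),
        "mpa": DoseEffect("linear", slope=beta_mpa),
        "vpa": DoseEffect("linear", slope=beta_vpa),
    }
    return TruthScenario(
        dose_effects=effects, seed=seed, baseline_hazard=baseline_hazard, **overrides
    )


def generate_finegray_cohort(
    beta: float,
    p_event: float,
    n: int,
    seed: int,
    censor_max: float = 10.0,
) -> pd.DataFrame:
    """Simulate directly under a Fine–Gray truth for one binary covariate.

    The sub-distribution of the event of interest is
    ``F1(t|x) = 1 − (1 − p(1 − e^{−t}))^{exp(βx)}`` — a unit-exponential
    mixture whose sub-distribution log-hazard ratio for x is exactly
    ``beta``.  Competing times, given the complementary mass, are unit
    exponential; censoring is uniform on (0, censor_max).  Used to check
    that the IPCW-weighted fit recovers a known sub-distribution effect.
    """
    if not 0 < p_event < 1:
        raise ArgumentError("p_event must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x46475452]))
    x = (rng.random(n) < 0.5).astype(float)
    ehr = np.exp(beta * x)
    p1 = 1.0 - (1.0 - p_event) ** ehr  # P(cause 1 | x)
    u = rng.random(n)
    cause1 = u < p1
    # inverse transform: solve F1(t|x) = v*p1 for t on the cause-1 branch
    v = rng.random(n)
    tv = -np.log(1.0 - (1.0 - (1.0 - v * p1) ** (1.0 / ehr)) / p_event)
    t2 = rng.exponential(1.0, size=n)
    t = np.where(cause1, tv, t2)
    c = rng.uniform(0.0, censor_max, size=n)
    follow = np.minimum(t, c)
    code = np.where(t <= c, np.where(cause1, 1, 2), 0)
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "x": x,
            "follow_time": np.maximum(follow, 1e-10),
            "event_code": code.astype(int),
        }
    )
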