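"""Cox proportional-hazards and Fine–Gray sub-distribution fitting.

Both families share one counting-process partial-likelihood engine:
rows are (start, stop] intervals with a case weight, the log partial
likelihood is maximised by Newton–Raphson with step-halving, and ties are
handled by the Efron correction (Breslow available).  Convergence is
declared when the largest score component falls below ``SCORE_TOL``.

The Fine–Gray fit is the standard weighted-Cox estimator on expanded data:
subjects with competing events remain in later risk sets, carried forward
in intervals that break at the event-of-interest times, with
inverse-probability-of-censoring weights ``G(t−)/G(T_i−)`` taken from the
Kaplan–Meier estimate of the censoring distribution.  With no competing
events the expansion is the identity and the fit reduces to Cox exactly.

Model designs couple a restricted-cubic-spline term for the primary
intensity with linear energy-expenditure volume terms for the other two
intensities (mutual adjustment) and the named confounders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import ArgumentError, DesignError, EstimationError
from .splines import RCSBasis, rcs_design

SCORE_TOL = 1e-8
MAX_ITER = 50
INTENSITIES = ("lpa", "mpa", "vpa")

#: Default MET-style weights turning minutes into energy-expenditure volume
#: for the mutual-adjustment terms (light ≈ 2, moderate ≈ 4, vigorous ≈ 8
#: MET-min per minute).  Config, not doctrine: ``other_intensity_mode``
#: "minutes" uses unweighted minutes instead.
DEFAULT_MET_WEIGHTS: Mapping[str, float] = {"lpa": 2.0, "mpa": 4.0, "vpa": 8.0}


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one outcome × intensity hazard model."""

    outcome: str
    intensity: str
    basis: RCSBasis | None  # None fits a single linear dose term
    covariates: tuple[str, ...] = ("age", "sex", "lifestyle")
    family: str = "cox"
    ties: str = "efron"
    other_intensity_mode: str = "met"
    met_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MET_WEIGHTS))

    def __post_init__(self) -> None:
        if self.intensity not in INTENSITIES:
            raise ArgumentError(f"intensity must be one of {INTENSITIES}")
        if self.family not in ("cox", "finegray"):
            raise ArgumentError("family must be 'cox' or 'finegray'")
        if self.ties not in ("efron", "breslow"):
            raise ArgumentError("ties must be 'efron' or 'breslow'")
        if self.other_intensity_mode not in ("met", "minutes"):
            raise ArgumentError("other_intensity_mode must be 'met' or 'minutes'")
        if self.intensity in self.covariates or f"{self.intensity}_min" in self.covariates:
            raise ArgumentError("primary intensity cannot also be an adjustment covariate")


@dataclass
class HazardFit:
    """A converged hazard-model fit.

    ``params`` are log-hazard-ratio coefficients in the order of ``names``;
    ``cov`` is the inverse observed information.  ``spline_idx`` indexes the
    primary-intensity spline columns (first of which is the linear dose
    term); ``nonlinear_idx`` the restricted cubic columns only.
    """

    params: np.ndarray
    cov: np.ndarray
    names: tuple[str, ...]
    spec: ModelSpec
    basis: RCSBasis | None
    spline_idx: tuple[int, ...]
    nonlinear_idx: tuple[int, ...]
    n: int
    n_events: int
    loglik: float
    loglik_trace: tuple[float, ...]
    n_iter: int
    converged: bool
    _data: dict = field(default_factory=dict, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> pd.DataFrame:
        z = self.params / self.se
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "hr": np.exp(self.params),
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=list(self.names),
        )

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "intensity": self.spec.intensity,
            "family": self.spec.family,
            "names": list(self.names),
            "coef": self.params.tolist(),
            "cov": self.cov.tolist(),
            "knots": list(self.basis.knots) if self.basis is not None else None,
            "n": self.n,
            "events": self.n_events,
            "converged": self.converged,
            "loglik": self.loglik,
        }


# ---------------------------------------------------------------------------
# Design construction


def build_design(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, tuple[str, ...], tuple[int, ...]]:
    """Assemble the design matrix: spline dose, volume terms, covariates.

    Returns (X, column names, indices of spline columns).
    """
    dose = cohort[f"{spec.intensity}_min"].to_numpy(dtype=float)
    if spec.basis is None:
        spline = dose[:, None]
        names = [f"{spec.intensity}_min"]
    else:
        spline = rcs_design(dose, spec.basis)
        names = [f"{spec.intensity}_rcs{j}" for j in range(spline.shape[1])]
    cols = [spline]
    spline_idx = tuple(range(spline.shape[1]))

    for other in INTENSITIES:
        if other == spec.intensity:
            continue
        w = spec.met_weights[other] if spec.other_intensity_mode == "met" else 1.0
        cols.append(w * cohort[f"{other}_min"].to_numpy(dtype=float)[:, None])
        names.append(f"vol_{other}")

    for cov in spec.covariates:
        if cov not in cohort.columns:
            raise ArgumentError(f"covariate {cov!r} not in cohort")
        col = cohort[cov]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            cols.append(dummies.to_numpy())
            names.extend(dummies.columns.tolist())
        else:
            cols.append(col.to_numpy(dtype=float)[:, None])
            names.append(cov)

    X = np.hstack(cols)
    return X, tuple(names), spline_idx


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    Xc = X - X.mean(axis=0)
    scale = np.linalg.norm(Xc, axis=0)
    if np.any(scale == 0):
        bad = [names[i] for i in np.flatnonzero(scale == 0)]
        raise DesignError(f"constant (inestimable) columns: {bad}")
    from scipy.linalg import qr

    _, r, piv = qr(Xc / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag[0] * max(X.shape) * np.finfo(float).eps * 100
    deficient = np.flatnonzero(diag < tol)
    if deficient.size:
        bad = [names[piv[i]] for i in deficient]
        raise DesignError(f"collinear design columns: {bad}")


# ---------------------------------------------------------------------------
# Counting-process partial-likelihood engine


def _ll_grad_hess(beta, X, w, stop_order, start_order, stops_s, starts_s,
                  ev_rows, ev_stop, grp_start, grp_sizes, ties):
    """Log partial likelihood, score and information at ``beta``.

    Risk sums over {i : start_i < t <= stop_i} are suffix sums over stop
    minus suffix sums over start, evaluated at the event times by binary
    search; the Efron correction subtracts the within-tie fractions.
    """
    n, p = X.shape
    eta = X @ beta
    r = w * np.exp(eta)
    rX = r[:, None] * X
    # n x p(p+1)/2 packed outer products
    iu = np.triu_indices(p)
    rXX = rX[:, iu[0]] * X[:, iu[1]]

    def suffix(arr, order):
        s = np.cumsum(arr[order][::-1], axis=0)[::-1]
        return np.vstack([s, np.zeros((1, arr.shape[1]))]) if arr.ndim == 2 else np.append(s, 0.0)

    suf_stop_r = suffix(r, stop_order)
    suf_start_r = suffix(r, start_order)
    suf_stop_rX = suffix(rX, stop_order)
    suf_start_rX = suffix(rX, start_order)
    suf_stop_rXX = suffix(rXX, stop_order)
    suf_start_rXX = suffix(rXX, start_order)

    # unique event times = ev_stop at group starts
    t_grp = ev_stop[grp_start]
    i_stop = np.searchsorted(stops_s, t_grp, side="left")
    i_start = np.searchsorted(starts_s, t_grp, side="left")
    S0 = suf_stop_r[i_stop] - suf_start_r[i_start]
    S1 = suf_stop_rX[i_stop] - suf_start_rX[i_start]
    S2p = suf_stop_rXX[i_stop] - suf_start_rXX[i_start]

    # tie-group sums over event rows
    w_ev = w[ev_rows]
    r_ev = r[ev_rows]
    rX_ev = rX[ev_rows]
    rXX_ev = rXX[ev_rows]
    S0D = np.add.reduceat(r_ev, grp_start)
    S1D = np.add.reduceat(rX_ev, grp_start)
    S2Dp = np.add.reduceat(rXX_ev, grp_start)
    wbar = np.add.reduceat(w_ev, grp_start) / grp_sizes

    # expand one pseudo-term per tied event: fraction l/d, l = 0..d-1
    rep = np.repeat(np.arange(len(grp_start)), grp_sizes)
    l_in_grp = np.arange(len(ev_rows)) - np.repeat(grp_start, grp_sizes)
    frac = l_in_grp / np.repeat(grp_sizes, grp_sizes)
    if ties == "breslow":
        frac = np.zeros_like(frac)
        wb = w_ev
    else:
        wb = np.repeat(wbar, grp_sizes)

    S0a = S0[rep] - frac * S0D[rep]
    S1a = S1[rep] - frac[:, None] * S1D[rep]
    S2a = S2p[rep] - frac[:, None] * S2Dp[rep]

    ll = float(np.sum(w_ev * eta[ev_rows]) - np.sum(wb * np.log(S0a)))
    mean = S1a / S0a[:, None]
    grad = (w_ev[:, None] * X[ev_rows]).sum(axis=0) - (wb[:, None] * mean).sum(axis=0)

    # information: sum wb * (S2a/S0a - mean mean^T)
    info_p = (wb[:, None] * (S2a / S0a[:, None])).sum(axis=0)
    info = np.zeros((p, p))
    info[iu] = info_p
    info = info + info.T - np.diag(np.diag(info))
    info -= (wb[:, None, None] * mean[:, :, None] * mean[:, None, :]).sum(axis=0)
    return ll, grad, info


def _prepare(start, stop, status, X, w):
    stop_order = np.argsort(stop, kind="stable")
    start_order = np.argsort(start, kind="stable")
    stops_s = stop[stop_order]
    starts_s = start[start_order]
    ev = np.flatnonzero(status == 1)
    ev = ev[np.argsort(stop[ev], kind="stable")]
    ev_stop = stop[ev]
    grp_start = np.flatnonzero(np.concatenate([[True], np.diff(ev_stop) > 0]))
    grp_sizes = np.diff(np.append(grp_start, len(ev)))
    return stop_order, start_order, stops_s, starts_s, ev, ev_stop, grp_start, grp_sizes


def _newton_cox(start, stop, status, X, w, ties="efron",
                tol=SCORE_TOL, max_iter=MAX_ITER):
    """Maximise the (weighted) partial likelihood; returns fit internals."""
    n, p = X.shape
    mu = X.mean(axis=0)
    Xc = X - mu  # centering: invariant coefficients, better conditioning
    parts = _prepare(start, stop, status, Xc, w)
    beta = np.zeros(p)
    ll, grad, info = _ll_grad_hess(beta, Xc, w, *parts, ties)
    trace = [ll]
    n_iter = 0
    converged = False
    step_tol = 1e-9  # coefficient-scale floor once score hits summation noise
    while n_iter < max_iter:
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular information matrix at iteration {n_iter}") from exc
        if np.max(np.abs(delta)) < step_tol:
            converged = True
            break
        n_iter += 1
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, grad_new, info_new = _ll_grad_hess(cand, Xc, w, *parts, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
        else:
            raise EstimationError(
                f"step-halving failed at iteration {n_iter}; loglik trace {trace}"
            )
        improvement = ll_new - ll
        moved = np.max(np.abs(step * delta))
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        trace.append(ll)
        if improvement < 1e-12 * (1.0 + abs(ll)) and moved < 1e-6:
            # a tiny accepted Newton step with negligible gain: the next
            # iterate is quadratically accurate, call it converged
            converged = True
            break
    if not converged:
        raise EstimationError(
            f"no convergence in {max_iter} iterations; |score|={np.max(np.abs(grad)):.3g}; "
            f"loglik trace {trace}"
        )
    cov = np.linalg.inv(info)
    return beta, cov, ll, trace, n_iter


def _schoenfeld_residuals(start, stop, status, X, w, beta):
    """Plain Schoenfeld residuals x_j − x̄(t_j) at the event rows."""
    mu = X.mean(axis=0)
    Xc = X - mu
    parts = _prepare(start, stop, status, Xc, w)
    stop_order, start_order, stops_s, starts_s, ev, ev_stop, grp_start, grp_sizes = parts
    r = w * np.exp(Xc @ beta)
    rX = r[:, None] * Xc

    def suffix(arr, order):
        s = np.cumsum(arr[order][::-1], axis=0)[::-1]
        if arr.ndim == 2:
            return np.vstack([s, np.zeros((1, arr.shape[1]))])
        return np.append(s, 0.0)

    suf_stop_r = suffix(r, stop_order)
    suf_start_r = suffix(r, start_order)
    suf_stop_rX = suffix(rX, stop_order)
    suf_start_rX = suffix(rX, start_order)
    i_stop = np.searchsorted(stops_s, ev_stop, side="left")
    i_start = np.searchsorted(starts_s, ev_stop, side="left")
    S0 = suf_stop_r[i_stop] - suf_start_r[i_start]
    S1 = suf_stop_rX[i_stop] - suf_start_rX[i_start]
    resid = Xc[ev] - S1 / S0[:, None]
    return resid, ev_stop


# ---------------------------------------------------------------------------
# Public fitters


def _event_status(cohort: pd.DataFrame) -> np.ndarray:
    code = cohort["event_code"].to_numpy()
    if not np.isin(code, (0, 1, 2)).all():
        raise ArgumentError("event_code values must be in {0, 1, 2}")
    return (code == 1).astype(int)


def fit_cox(cohort: pd.DataFrame, spec: ModelSpec) -> HazardFit:
    """Cox proportional-hazards fit (competing events censored)."""
    status = _event_status(cohort)
    if status.sum() < 1:
        raise EstimationError("no events of interest in cohort")
    X, names, spline_idx = build_design(cohort, spec)
    _check_rank(X, names)
    stop = cohort["follow_time"].to_numpy(dtype=float)
    start = np.zeros_like(stop)
    w = np.ones_like(stop)
    beta, cov, ll, trace, n_iter = _newton_cox(start, stop, status, X, w, spec.ties)
    nonlin = tuple(i for i in spline_idx[1:])
    return HazardFit(
        params=beta, cov=cov, names=names, spec=spec, basis=spec.basis,
        spline_idx=spline_idx, nonlinear_idx=nonlin, n=len(cohort),
        n_events=int(status.sum()), loglik=ll, loglik_trace=tuple(trace),
        n_iter=n_iter, converged=True,
        _data={"start": start, "stop": stop, "status": status, "X": X, "w": w},
    )


def censoring_km(cohort: pd.DataFrame) -> KaplanMeierFitter:
    """Kaplan–Meier estimate of the censoring distribution G(t)."""
    kmf = KaplanMeierFitter()
    kmf.fit(cohort["follow_time"], event_observed=(cohort["event_code"] == 0))
    return kmf


def finegray_expand(cohort: pd.DataFrame) -> pd.DataFrame:
    """Expand a cohort into weighted counting-process rows for Fine–Gray.

    Subjects without a competing event contribute one row (0, T] with
    weight 1.  A competing-event subject additionally remains at risk after
    T: one row per later event-of-interest time t with weight
    G(t−)/G(T−), G the censoring-distribution Kaplan–Meier.  Weights only
    matter at event times, so intervals break exactly there.

    Returns a frame with columns start, stop, status, weight, row (index
    into the original cohort).
    """
    status = _event_status(cohort)
    time = cohort["follow_time"].to_numpy(dtype=float)
    code = cohort["event_code"].to_numpy()

    base = pd.DataFrame(
        {
            "start": 0.0,
            "stop": time,
            "status": status,
            "weight": 1.0,
            "row": np.arange(len(cohort)),
        }
    )
    comp = np.flatnonzero(code == 2)
    ev_times = np.unique(time[status == 1])
    if comp.size == 0 or ev_times.size == 0:
        return base

    kmf = censoring_km(cohort)
    km_t = kmf.survival_function_.index.to_numpy(dtype=float)
    km_s = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def g_minus(t: np.ndarray) -> np.ndarray:
        # left limit of the censoring survivor function
        idx = np.searchsorted(km_t, t, side="left") - 1
        out = np.ones_like(t, dtype=float)
        pos = idx >= 0
        out[pos] = km_s[idx[pos]]
        return out

    t_comp = time[comp]
    first = np.searchsorted(ev_times, t_comp, side="right")  # first event time > T_i
    counts = ev_times.size - first
    keep = counts > 0
    comp, t_comp, first, counts = comp[keep], t_comp[keep], first[keep], counts[keep]
    if comp.size == 0:
        return base

    total = int(counts.sum())
    rep = np.repeat(np.arange(comp.size), counts)
    offs = np.concatenate([[0], np.cumsum(counts)[:-1]])
    pos = np.arange(total) - np.repeat(offs, counts) + np.repeat(first, counts)
    stop_ext = ev_times[pos]
    at_first = pos == np.repeat(first, counts)
    start_ext = np.where(at_first, np.repeat(t_comp, counts), ev_times[np.maximum(pos - 1, 0)])
    g_ti = g_minus(np.repeat(t_comp, counts))
    weight = np.zeros(total)
    ok = g_ti > 0
    weight[ok] = g_minus(stop_ext[ok]) / g_ti[ok]
    ext = pd.DataFrame(
        {
            "start": start_ext,
            "stop": stop_ext,
            "status": 0,
            "weight": weight,
            "row": comp[rep],
        }
    )
    ext = ext[ext["weight"] > 0]
    return pd.concat([base, ext], ignore_index=True)


def fit_finegray(cohort: pd.DataFrame, spec: ModelSpec) -> HazardFit:
    """Fine–Gray sub-distribution hazards fit via IPCW-weighted Cox."""
    status = _event_status(cohort)
    if status.sum() < 1:
        raise EstimationError("no events of interest in cohort")
    if (cohort["event_code"] == 2).sum() == len(cohort):
        raise EstimationError("cohort contains only competing events")
    X, names, spline_idx = build_design(cohort, spec)
    _check_rank(X, names)
    expanded = finegray_expand(cohort)
    rows = expanded["row"].to_numpy()
    Xe = X[rows]
    beta, cov, ll, trace, n_iter = _newton_cox(
        expanded["start"].to_numpy(dtype=float),
        expanded["stop"].to_numpy(dtype=float),
        expanded["status"].to_numpy(),
        Xe,
        expanded["weight"].to_numpy(dtype=float),
        spec.ties,
    )
    nonlin = tuple(i for i in spline_idx[1:])
    return HazardFit(
        params=beta, cov=cov, names=names, spec=spec, basis=spec.basis,
        spline_idx=spline_idx, nonlinear_idx=nonlin, n=len(cohort),
        n_events=int(status.sum()), loglik=ll, loglik_trace=tuple(trace),
        n_iter=n_iter, converged=True,
        _data={
            "start": expanded["start"].to_numpy(dtype=float),
            "stop": expanded["stop"].to_numpy(dtype=float),
            "status": expanded["status"].to_numpy(),
            "X": Xe,
            "w": expanded["weight"].to_numpy(dtype=float),
        },
    )


def fit_model(cohort: pd.DataFrame, spec: ModelSpec) -> HazardFit:
    return fit_cox(cohort, spec) if spec.family == "cox" else fit_finegray(cohort, spec)


# ---------------------------------------------------------------------------
# Diagnostics


def wald_nonlinearity_test(fit: HazardFit, indices: Sequence[int] | None = None) -> float:
    """Joint Wald chi-square that the nonlinear spline coefficients vanish."""
    idx = list(fit.nonlinear_idx if indices is None else indices)
    if len(idx) == 0:
        raise ArgumentError("no nonlinear terms to test")
    b = fit.params[idx]
    V = fit.cov[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(stat, df=len(idx)))


def schoenfeld_ph_test(
    fit: HazardFit, transform: str = "km"
) -> dict:
    """Grambsch–Therneau proportional-hazards test from Schoenfeld residuals.

    Scaled residuals ``s* = d·s·V`` are regressed on a transform of event
    time (default: 1 − KM of the observed time distribution); the slope
    statistic per term is ``(Σ(g−ḡ)s*_k)² / (d·V_kk·Σ(g−ḡ)²)`` on 1 df,
    with a joint chi-square on p df as the global test.
    """
    d = fit.n_events
    if d < 3:
        raise EstimationError("need at least 3 events for the PH test")
    data = fit._data
    resid, ev_times = _schoenfeld_residuals(
        data["start"], data["stop"], data["status"], data["X"], data["w"], fit.params
    )
    V = fit.cov
    scaled = d * resid @ V

    if transform == "km":
        kmf = KaplanMeierFitter()
        kmf.fit(data["stop"], event_observed=data["status"])
        sf = kmf.survival_function_
        g = 1.0 - np.interp(ev_times, sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy())
    elif transform == "identity":
        g = ev_times.astype(float)
    elif transform == "rank":
        g = stats.rankdata(ev_times).astype(float)
    else:
        raise ArgumentError(f"unknown time transform {transform!r}")

    gc = g - g.mean()
    gss = float(np.sum(gc**2))
    U = gc @ scaled  # p-vector
    var_kk = np.diag(V)
    stat_k = U**2 / (d * var_kk * gss)
    p_k = stats.chi2.sf(stat_k, df=1)
    global_stat = float(U @ np.linalg.solve(d * gss * V, U))
    global_p = float(stats.chi2.sf(global_stat, df=len(U)))
    return {
        "p_values": pd.Series(p_k, index=list(fit.names)),
        "statistics": pd.Series(stat_k, index=list(fit.names)),
        "global_statistic": global_stat,
        "global_p": global_p,
        "transform": transform,
    }
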