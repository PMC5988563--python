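"""Residence-time estimation from the normalised survival correlation.

For an ensemble of lipids with continuous-contact intervals, the survival
time-correlation function counts, for every lag t on a 1 ns grid, the time
windows [nu, nu + t] over which some lipid interacts continuously:

    sigma(t) = (1/N_j) (1/(T - t)) sum_j sum_nu rho_j(nu, nu + t)

where rho_j(nu, nu+t) is 1 when lipid j interacts continuously over the
whole window, N_j is the number of lipids with non-zero interaction time
and T the total simulation time. sigma is normalised by sigma(0) so that it
starts at 1. On the discrete nu-grid we divide by the exact number of
admissible window start points, floor((T-t)/dt)+1, the discrete realisation
of 1/(T-t); windows extending past T contribute nothing.

The normalised curve decays as exp(-t/theta) for a single interacting
population, or as A exp(-t/theta1) + B exp(-t/theta2) when fast and slow
populations coexist; theta is the residence time, and for the two-population
model the long timescale theta2 is the one reported.

Numerical notes
---------------
* Fits are weighted least squares with per-lag uncertainty proportional to
  1/sqrt(window count): S(t) is a count, and early lags are supported by
  orders of magnitude more windows than the tail.
* The fit range drops lags supported by fewer than ``min_windows`` raw
  windows or fewer than ``min_contributors`` distinct intervals. The
  1/(T-t) normalisation amplifies tail variance, and lags covered by only
  a couple of very long intervals carry no trustworthy shape information.
* The two-population fit is *staged* (exponential peeling): the slow
  component is fitted on the tail (lags past the half-decay point), then
  the fast component is fitted on the early-lag residual together with a
  constant + linear nuisance term that absorbs the local leak of the slow
  fit. A joint 4-parameter multi-start fit is retained as a fallback; used
  alone it is not identifiable at realistic event counts, because sampling
  fluctuations of the slow tail masquerade as a (wrong) fast timescale.

Uncertainties come from resampling the lipid set with replacement (default
1500 times), recomputing sigma and refitting, and taking the corrected
(n-1 denominator) standard deviation of the fitted residence times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist

from .contacts import InteractionIntervalSet
from .errors import (BootstrapError, DegenerateFitError, EstimationError,
                     FitError, ParameterError)

__all__ = [
    "SurvivalCurve",
    "ResidenceFit",
    "BootstrapResult",
    "survival_correlation",
    "fit_single_exponential",
    "fit_double_exponential",
    "select_fit",
    "bootstrap_residence_time",
    "leaflet_average",
]

DEFAULT_LAG_STEP_NS = 1.0
DEFAULT_MIN_WINDOWS = 10
DEFAULT_MIN_CONTRIBUTORS = 10
DEFAULT_N_BOOT = 1500
_EPS = 1e-9


@dataclass
class SurvivalCurve:
    """Normalised survival correlation sigma(t) on a lag grid."""

    lags: np.ndarray          # ns
    sigma: np.ndarray         # normalised, sigma[0] == 1
    counts: np.ndarray        # raw window counts S(t) summed over lipids
    n_possible: np.ndarray    # admissible window start points per lag
    n_lipids: int             # N_j: lipids with non-zero interaction time
    T: float                  # total simulation time, ns
    dt_lag: float
    contributors: np.ndarray | None = None  # intervals long enough per lag
    normalized: bool = True


@dataclass
class ResidenceFit:
    """Exponential fit of a survival curve.

    ``theta`` is the reported residence time: the single-model timescale, or
    theta2 (the long population) for the two-population model.
    """

    model: str                # 'single' | 'double'
    theta: float              # ns
    rss: float                # residual sum of squares over the fit range
    n_points: int
    A: float | None = None
    theta1: float | None = None
    B: float | None = None
    theta2: float | None = None
    bootstrap_sd: float | None = None
    n_boot: int = 0
    converged: bool = True
    notes: list = field(default_factory=list)

    @property
    def residence_time(self) -> float:
        return self.theta


@dataclass
class BootstrapResult:
    sd: float
    samples: np.ndarray
    n_failed: int
    n_boot: int


# ---------------------------------------------------------------------------
# sigma(t)
# ---------------------------------------------------------------------------

def _as_continuous_intervals(interval_sets):
    """Normalise input to a list (per lipid) of [(start_ns, end_ns), ...]."""
    out = []
    for s in interval_sets:
        if isinstance(s, InteractionIntervalSet):
            out.append(s.continuous_intervals())
        else:
            out.append([(float(a), float(b)) for a, b in s])
    return out


def _window_counts(intervals, lags, dt, T):
    """Window counts per lag for one lipid's intervals (vectorised)."""
    counts = np.zeros(lags.size)
    if not intervals:
        return counts
    a = np.array([iv[0] for iv in intervals])
    b = np.minimum(np.array([iv[1] for iv in intervals]), T)
    keep = b > a
    a, b = a[keep], b[keep]
    if a.size == 0:
        return counts
    lo = np.ceil(a / dt - _EPS)
    for i0 in range(0, a.size, 512):
        i1 = min(a.size, i0 + 512)
        hi = np.floor((b[i0:i1, None] - lags[None, :]) / dt + _EPS)
        c = hi - lo[i0:i1, None] + 1
        np.maximum(c, 0, out=c)
        counts += c.sum(axis=0)
    return counts


def _contributor_counts(intervals, lags, T):
    """Number of intervals at least as long as each lag."""
    if not intervals:
        return np.zeros(lags.size)
    lens = np.array([min(b, T) - a for a, b in intervals])
    lens = np.sort(lens[lens > 0])
    return lens.size - np.searchsorted(lens, lags, side="left")


def _lag_grid(T, dt_lag, max_lag):
    if T <= 0:
        raise ParameterError("T must be > 0")
    if dt_lag <= 0:
        raise ParameterError("dt_lag must be > 0")
    top = T if max_lag is None else min(max_lag + dt_lag, T)
    lags = np.arange(0.0, top - _EPS, dt_lag)  # t = T dropped (1/(T-t) undefined)
    if lags.size == 0:
        raise ParameterError("lag grid is empty; decrease dt_lag")
    return lags


def per_lipid_window_counts(interval_sets, T, dt_lag=DEFAULT_LAG_STEP_NS,
                            max_lag=None):
    """Window-count and contributor matrices (n_lipids, n_lags) + lag grid."""
    sets = _as_continuous_intervals(interval_sets)
    lags = _lag_grid(T, dt_lag, max_lag)
    C = np.empty((len(sets), lags.size))
    K = np.empty((len(sets), lags.size))
    for j, ivs in enumerate(sets):
        C[j] = _window_counts(ivs, lags, dt_lag, T)
        K[j] = _contributor_counts(ivs, lags, T)
    return C, K, lags


def _curve_from_counts(S, lags, T, dt_lag, n_lipids, contributors=None):
    n_possible = np.floor((T - lags) / dt_lag + _EPS).astype(np.int64) + 1
    if n_lipids == 0 or S[0] <= 0:
        raise EstimationError("no interacting lipids: sigma(0) would be zero")
    sigma_u = S / (n_lipids * n_possible)
    sigma = sigma_u / sigma_u[0]
    return SurvivalCurve(lags, sigma, S, n_possible, n_lipids, T, dt_lag,
                         contributors=contributors)


def survival_correlation(interval_sets, T: float,
                         dt_lag: float = DEFAULT_LAG_STEP_NS,
                         max_lag: float | None = None) -> SurvivalCurve:
    """Normalised survival time-correlation function of an interval ensemble.

    Parameters
    ----------
    interval_sets
        One entry per lipid: an :class:`InteractionIntervalSet` or a sequence
        of ``(start_ns, end_ns)`` pairs in continuous time.
    T
        Total simulation time in ns.
    dt_lag
        Lag grid step in ns (default 1). The window start nu runs on the same
        grid; lag t = T is dropped.
    max_lag
        Optionally truncate the lag grid (the full grid extends to T).

    Lipids with no intervals are excluded from N_j.
    """
    C, K, lags = per_lipid_window_counts(interval_sets, T, dt_lag, max_lag)
    has_any = C[:, 0] > 0
    n_lipids = int(has_any.sum())
    return _curve_from_counts(C.sum(axis=0), lags, T, dt_lag, n_lipids,
                              contributors=K.sum(axis=0))


# ---------------------------------------------------------------------------
# exponential fits
# ---------------------------------------------------------------------------

def _fit_selection(curve, fit_range, min_windows, min_contributors,
                   n_required):
    sel = curve.counts >= min_windows
    if curve.contributors is not None and min_contributors > 0:
        sel &= curve.contributors >= min_contributors
        if not sel.any():  # tiny ensembles: fall back to the count rule
            sel = curve.counts >= min_windows
    if fit_range is not None:
        t0, t1 = fit_range
        sel &= (curve.lags >= t0) & (curve.lags <= t1)
    n = int(sel.sum())
    if n < n_required:
        raise FitError(
            f"only {n} lags available for fitting (need >= {n_required})",
            diagnostics={"n_lags": n, "min_windows": min_windows})
    return sel


def _check_degenerate(sigma):
    if np.all(sigma > 0.999):
        raise DegenerateFitError(
            "sigma(t) is indistinguishable from 1: the residence time "
            "exceeds the observable window")


def fit_single_exponential(curve: SurvivalCurve, fit_range=None,
                           min_windows: int = DEFAULT_MIN_WINDOWS,
                           min_contributors: int = DEFAULT_MIN_CONTRIBUTORS
                           ) -> ResidenceFit:
    """Weighted least-squares fit of sigma(t) ~ exp(-t/theta).

    The initial theta is the first lag where sigma drops below 1/e
    (fallback T/10).
    """
    sel = _fit_selection(curve, fit_range, min_windows, min_contributors, 3)
    t, y = curve.lags[sel], curve.sigma[sel]
    w = 1.0 / np.sqrt(np.maximum(curve.counts[sel], 1.0))
    _check_degenerate(y)
    below = np.flatnonzero(y < np.exp(-1.0))
    p0 = float(t[below[0]]) if below.size and t[below[0]] > 0 else curve.T / 10.0
    try:
        popt, _ = curve_fit(lambda tt, th: np.exp(-tt / th), t, y, p0=[p0],
                            sigma=w, bounds=(1e-12, np.inf), maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"single-exponential fit did not converge: {exc}",
                       diagnostics={"p0": p0, "n_points": t.size}) from exc
    theta = float(popt[0])
    rss = float(np.sum((y - np.exp(-t / theta)) ** 2))
    return ResidenceFit(model="single", theta=theta, rss=rss, n_points=t.size)


def _double_model(t, A, th1, B, th2):
    return A * np.exp(-t / th1) + B * np.exp(-t / th2)


def _staged_double(t, y, w, dt_lag, T):
    """Exponential peeling: tail fit for the slow component, then the fast
    component on the early residual with a constant+linear nuisance term.

    Returns (A, th1, B, th2) or None when no fast component is resolvable.
    """
    i_half = np.flatnonzero(y < 0.5 * y[0])
    t_half = t[i_half[0]] if i_half.size and t[i_half[0]] > 0 else t[-1] / 4.0
    g = lambda tt, B, th: B * np.exp(-tt / th)  # noqa: E731
    h = lambda tt, A, th, c, m: A * np.exp(-tt / th) + c + m * tt  # noqa: E731

    def one_pass(tail_start):
        tail = t >= tail_start
        if tail.sum() < 3:
            return None
        (B0, th2), _ = curve_fit(g, t[tail], y[tail],
                                 p0=[0.9, max(tail_start, dt_lag)],
                                 sigma=w[tail],
                                 bounds=([0.0, 1e-12], [2.0, np.inf]),
                                 maxfev=10000)
        resid = y - g(t, B0, th2)
        mid = (t >= th2 / 10.0) & (t <= th2 / 4.0)
        r_inf = float(np.median(resid[mid])) if mid.sum() > 3 else 0.0
        r0 = resid[0] - r_inf
        if r0 <= 1e-4:
            return None
        drop = np.flatnonzero(resid - r_inf < r0 / np.e)
        th1_g = max(t[drop[0]] if drop.size and t[drop[0]] > 0 else 5 * dt_lag,
                    dt_lag)
        early = t <= 8.0 * th1_g
        if early.sum() < 5:
            early = t <= max(8.0 * th1_g, t[min(5, t.size - 1)])
        (A1, th1, _c, _m), _ = curve_fit(
            h, t[early], resid[early], p0=[r0, th1_g, r_inf, 0.0],
            sigma=w[early], maxfev=20000)
        if not (0 < th1 < th2) or A1 <= 0:
            return None
        return float(A1), float(th1), float(B0), float(th2)

    candidates = []
    params = one_pass(t_half)
    if params is not None:
        candidates.append(params)
        # one refinement: restart the tail past the fast component, which
        # matters when the fast amplitude is large (half-decay in the fast
        # regime)
        try:
            refined = one_pass(max(t_half, 8.0 * params[1]))
        except RuntimeError:
            refined = None
        if refined is not None:
            candidates.append(refined)
    return candidates


def _joint_double(t, y, w, dt_lag, T):
    """Fallback: joint multi-start weighted LS over 5 timescale pairs."""
    grid = np.geomspace(max(dt_lag, 1e-6), T, 6)
    start_pairs = [(grid[0], grid[2]), (grid[0], grid[3]), (grid[1], grid[3]),
                   (grid[1], grid[4]), (grid[2], grid[5])]
    out = []
    for th1, th2 in start_pairs:
        try:
            popt, _ = curve_fit(
                _double_model, t, y, p0=[0.5, th1, 0.5, th2], sigma=w,
                bounds=([0.0, 1e-12, 0.0, 1e-12], [2.0, np.inf, 2.0, np.inf]),
                maxfev=20000)
        except RuntimeError:
            continue
        A, t1, B, t2 = (float(v) for v in popt)
        if t1 > t2:
            A, t1, B, t2 = B, t2, A, t1
        out.append((A, t1, B, t2))
    return out


def fit_double_exponential(curve: SurvivalCurve, fit_range=None,
                           min_windows: int = DEFAULT_MIN_WINDOWS,
                           min_contributors: int = DEFAULT_MIN_CONTRIBUTORS,
                           amplitude_tol: float = 1e-6,
                           separation: float = 2.0) -> ResidenceFit:
    """Fit sigma(t) ~ A exp(-t/theta1) + B exp(-t/theta2), theta1 < theta2.

    Staged least squares (see module docstring); a joint multi-start fit is
    the fallback. A candidate counts as a genuine two-population fit only if
    both amplitudes exceed ``amplitude_tol``, the timescales are separated
    by at least ``separation`` (closer pairs are an arbitrary split of one
    population), and theta2 does not exceed the observable window T (a
    slower component is indistinguishable from a constant). When no
    candidate qualifies, or when the best candidate does not beat the
    single-exponential fit in weighted residual terms, the curve carries a
    single population and the single fit is reported with a warning.
    """
    sel = _fit_selection(curve, fit_range, min_windows, min_contributors, 5)
    t, y = curve.lags[sel], curve.sigma[sel]
    w = 1.0 / np.sqrt(np.maximum(curve.counts[sel], 1.0))
    _check_degenerate(y)

    def valid(p):
        A, th1, B, th2 = p
        # a fast timescale below the lag grid, or a slow one beyond the
        # observable window, is unresolvable
        return (A >= amplitude_tol and B >= amplitude_tol
                and th1 >= curve.dt_lag
                and th1 * separation <= th2 <= curve.T)

    def refit_amplitudes(p):
        # timescales come from the staged fit; amplitudes are then the exact
        # (weighted) linear LS solution, so the assembled model is coherent
        # over the whole fit range
        _A, th1, _B, th2 = p
        X = np.column_stack([np.exp(-t / th1), np.exp(-t / th2)]) / w[:, None]
        coef, *_ = np.linalg.lstsq(X, y / w, rcond=None)
        if np.any(coef <= 0):
            return p
        return float(coef[0]), th1, float(coef[1]), th2

    try:
        candidates = _staged_double(t, y, w, curve.dt_lag, curve.T)
    except RuntimeError:
        candidates = []
    candidates = [refit_amplitudes(p) for p in candidates]
    candidates = [p for p in candidates if valid(p)]
    if not candidates:
        candidates = [p for p in _joint_double(t, y, w, curve.dt_lag, curve.T)
                      if valid(p)]
    best = None
    for p in candidates:
        rss = float(np.sum((y - _double_model(t, *p)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, p)
    if best is None:
        warnings.warn("double-exponential amplitude collapsed; reporting the "
                      "single-exponential fit")
        single = fit_single_exponential(curve, fit_range, min_windows,
                                        min_contributors)
        single.notes.append("double-fit amplitude collapse")
        return single
    rss, (A, th1, B, th2) = best
    fit = ResidenceFit(model="double", theta=th2, rss=rss,
                       n_points=t.size, A=A, theta1=th1, B=B, theta2=th2)
    single = fit_single_exponential(curve, fit_range, min_windows,
                                    min_contributors)
    if rss >= single.rss:
        fit.notes.append("does not improve on the single-exponential fit")
    return fit


def select_fit(curve: SurvivalCurve, model: str = "auto", alpha: float = 0.05,
               fit_range=None, min_windows: int = DEFAULT_MIN_WINDOWS,
               min_contributors: int = DEFAULT_MIN_CONTRIBUTORS
               ) -> ResidenceFit:
    """Fit sigma(t), choosing between one and two populations.

    ``model='auto'`` fits both and keeps the two-population model when an
    F-test at level ``alpha`` favours it (two extra parameters); otherwise
    the requested model is fitted directly.
    """
    if model == "single":
        return fit_single_exponential(curve, fit_range, min_windows,
                                      min_contributors)
    if model == "double":
        return fit_double_exponential(curve, fit_range, min_windows,
                                      min_contributors)
    if model != "auto":
        raise ParameterError(f"unknown model {model!r}")
    single = fit_single_exponential(curve, fit_range, min_windows,
                                    min_contributors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            double = fit_double_exponential(curve, fit_range, min_windows,
                                            min_contributors)
        except FitError:
            return single
    if double.model != "double" or double.rss >= single.rss:
        return single
    n = double.n_points
    if n <= 4 or double.rss <= 0:
        return double
    F = ((single.rss - double.rss) / 2.0) / (double.rss / (n - 4))
    p = float(f_dist.sf(F, 2, n - 4))
    return double if p < alpha else single


# ---------------------------------------------------------------------------
# bootstrap and leaflet averaging
# ---------------------------------------------------------------------------

def bootstrap_residence_time(interval_sets, T: float, model: str = "single",
                             n_boot: int = DEFAULT_N_BOOT,
                             seed=None, dt_lag: float = DEFAULT_LAG_STEP_NS,
                             max_lag: float | None = None,
                             min_windows: int = DEFAULT_MIN_WINDOWS
                             ) -> BootstrapResult:
    """Bootstrap SD of the residence time over lipid resampling.

    The lipid set is resampled with replacement ``n_boot`` times; for each
    resample sigma(t) is recomputed and refitted, and the corrected
    ((n-1)-denominator) standard deviation of the resulting residence times
    is returned. Failed refits are dropped and counted; more than 50%
    failures raises :class:`BootstrapError`.
    """
    sets = list(interval_sets)
    n = len(sets)
    if n < 2:
        raise EstimationError("bootstrap requires at least 2 lipids")
    C, K, lags = per_lipid_window_counts(sets, T, dt_lag, max_lag)
    has_any = C[:, 0] > 0
    rng = np.random.default_rng(seed)
    samples, n_failed = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        mult = np.bincount(idx, minlength=n).astype(float)
        S = mult @ C
        contrib = mult @ K
        n_lip = int(mult @ has_any)
        try:
            curve = _curve_from_counts(S, lags, T, dt_lag, n_lip,
                                       contributors=contrib)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = select_fit(curve, model=model, min_windows=min_windows)
            samples.append(fit.residence_time)
        except (EstimationError, FitError):
            n_failed += 1
    if n_failed > n_boot / 2:
        raise BootstrapError(f"{n_failed}/{n_boot} bootstrap refits failed")
    samples = np.asarray(samples)
    if samples.size > 1 and not np.all(samples == samples[0]):
        sd = float(np.std(samples, ddof=1))
    else:
        sd = 0.0
    return BootstrapResult(sd=sd, samples=samples, n_failed=n_failed,
                           n_boot=n_boot)


def leaflet_average(theta_inner, theta_outer) -> float:
    """Overall residence time for a lipid type: mean of the two leaflets.

    The protein surfaces exposed to the inner and outer leaflet are treated
    as two separate interaction sites; the overall residence time is the
    arithmetic mean of the per-leaflet values. A missing value propagates
    (with a warning).
    """
    vals = [theta_inner, theta_outer]
    if any(v is None or not np.isfinite(v) for v in vals):
        warnings.warn("missing per-leaflet residence time; propagating NaN")
        return float("nan")
    if any(v <= 0 for v in vals):
        raise ParameterError("residence times must be positive")
    return float((theta_inner + theta_outer) / 2.0)
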