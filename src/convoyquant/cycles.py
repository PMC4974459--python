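"""Detection and model fitting of isolated transcription cycles.

An isolated cycle is a TS intensity peak flanked by silent periods, which
can be attributed to a single polymerase convoy.  Each detected cycle is fit
with the deterministic convoy model over the four kinetic parameters (with
the first-initiation time as a nuisance parameter), pooled UP-ramp
regression recovers cohort-level elongation rate and spacing, and
inter-convoy statistics summarize ON durations and the gaps between
successive convoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .convoy import (
    ConvoyParams,
    GeneGeometry,
    IntensityTrace,
    analytic_durations,
    kbmin_to_nts,
    ts_intensity,
)

__all__ = [
    "TranscriptionCycle",
    "FittedConvoy",
    "find_isolated_cycles",
    "fit_convoy_cycle",
    "pooled_upramp_regression",
    "interconvoy_stats",
]


@dataclass
class TranscriptionCycle:
    """A contiguous above-threshold trace segment.

    ``start``/``end`` are frame indices (half-open) of the segment used for
    fitting, which includes up to ``min_off_frames`` of silent padding on
    each side; ``core_start``/``core_end`` bound the above-threshold run
    itself.  ``isolated`` is False when the run touches a trace boundary or
    lacks the required silent flanks.
    """

    times: np.ndarray
    values: np.ndarray
    start: int
    end: int
    core_start: int
    core_end: int
    isolated: bool

    def __post_init__(self) -> None:
        if not (self.start <= self.core_start < self.core_end <= self.end):
            raise ValueError("inconsistent cycle frame bounds")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


def find_isolated_cycles(
    trace: IntensityTrace,
    off_threshold: float = 0.5,
    min_off_frames: int = 3,
) -> list[TranscriptionCycle]:
    """Find maximal above-threshold segments in an RNA-equivalent trace.

    A segment is marked ``isolated`` when it is flanked on both sides by at
    least ``min_off_frames`` below-threshold frames; segments touching the
    trace boundaries are returned with ``isolated=False``.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    above = trace.values > off_threshold
    cycles: list[TranscriptionCycle] = []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += [int(e) + 1 for e in edges if above[e + 1]]
    ends = [int(e) + 1 for e in edges if above[e]]
    if above[-1]:
        ends.append(len(trace))
    for s, e in zip(starts, ends):
        left_ok = s >= min_off_frames and not above[s - min_off_frames:s].any()
        right_ok = (
            e + min_off_frames <= len(trace) and not above[e:e + min_off_frames].any()
        )
        pad_l = min(s, min_off_frames)
        pad_r = min(len(trace) - e, min_off_frames)
        cycles.append(
            TranscriptionCycle(
                times=trace.times[s - pad_l:e + pad_r],
                values=trace.values[s - pad_l:e + pad_r],
                start=s - pad_l,
                end=e + pad_r,
                core_start=s,
                core_end=e,
                isolated=bool(left_ok and right_ok),
            )
        )
    return cycles


@dataclass
class FittedConvoy:
    """Best-fit convoy parameters for one cycle.

    ``v_el_is_lower_bound`` is set when the residual profile is flat in
    ``v_el`` (noise hides the elongation-rate signature, typically on
    plateau-free cycles), in which case ``params.v_el`` is the smallest
    rate within 1% of the optimal residual.  ``uncertainty`` holds
    approximate 1-sigma errors for the continuous parameters from a
    finite-difference Jacobian at the optimum.
    """

    params: ConvoyParams
    t0: float
    residual_norm: float
    v_el_is_lower_bound: bool = False
    uncertainty: dict[str, float] = field(default_factory=dict)

    @property
    def up_ramp_s(self) -> float:
        return (self.params.n_pol - 1) * self.params.t_space


_BOUNDS_LO = np.array([1e-3, 0.1, 0.0, -np.inf])
_BOUNDS_HI = np.array([120.0, 30.0, 1000.0, np.inf])


def _residuals(theta: np.ndarray, n_pol: int, t: np.ndarray, y: np.ndarray,
               geom: GeneGeometry) -> np.ndarray:
    t_space, v_el, t_proc, t0 = theta
    params = ConvoyParams(n_pol, max(t_space, 0.0), max(v_el, 1e-6), max(t_proc, 0.0))
    return ts_intensity(t, params, geom, t0) - y


def _initial_guess(t: np.ndarray, y: np.ndarray, geom: GeneGeometry,
                   n_pol: int) -> np.ndarray:
    """Moment-style start: crossing times of the 25% and 85% intensity
    levels locate the linear ramps; rescaling by the level fractions gives
    full ramp durations, from which the model parameters follow in closed
    form."""
    peak = float(y.max())
    f_lo, f_hi = 0.25, 0.85
    lo = f_lo * peak
    hi = f_hi * peak
    t_lo_up = t[np.argmax(y > lo)]
    above_hi = y > hi
    t_hi_up = t[np.argmax(above_hi)]
    t_hi_down = t[len(y) - 1 - np.argmax(above_hi[::-1])]
    last_above = np.flatnonzero(y > lo)
    t_lo_down = t[last_above[-1]] if last_above.size else t[-1]
    span = f_hi - f_lo
    up_full = max((t_hi_up - t_lo_up) / span, 1e-3)
    down_full = max((t_lo_down - t_hi_down) / span, 1e-3)
    up_start = t_lo_up - f_lo * up_full
    down_start = t_hi_down - (1.0 - f_hi) * down_full
    # the DOWN ramp is exactly linear so down_full is reliable; the UP ramp
    # has quadratic shoulders, so seed several MS2 transit times: the
    # crossing-based estimate plus a coarse elongation-rate grid
    m_auto = max(up_full - down_full, 3.0)
    m_grid = [m_auto] + [geom.l_ms2 / kbmin_to_nts(v) for v in (1.0, 2.0, 4.0, 8.0)]
    return [
        np.array([up_start, m, down_full, down_start]) for m in m_grid
    ]


@dataclass
class _FitResult:
    x: np.ndarray  # (t_space, v_el, t_proc, t0)
    cost: float
    success: bool


def _phi_to_theta(phi: np.ndarray, n_pol: int, geom: GeneGeometry) -> np.ndarray:
    """Convert the internal fitting parameters to model parameters.

    The fit runs over near-orthogonal observables: ``a`` = UP-ramp start
    time, ``m`` = MS2-repeat transit time ``l_ms2 / v_el``, ``d`` =
    DOWN-ramp duration ``(n_pol - 1) * t_space``, ``r`` = first-release
    time.  In the (t_space, v_el, t_proc, t0) space the sum of squares has
    a long curved valley (v_el trades off against t0 and t_proc); in
    (a, m, d, r) each parameter moves one visible feature of the cycle.
    """
    a, m, d, r = phi
    m = max(m, 1e-3)
    v_nt = geom.l_ms2 / m
    t_space = max(d, 0.0) / max(n_pol - 1, 1)
    t0 = a - geom.l_pre / v_nt
    t_proc = max(r - a - m - geom.l_post / v_nt, 0.0)
    v_el = v_nt / kbmin_to_nts(1.0)
    return np.array([t_space, np.clip(v_el, 1e-2, 60.0), t_proc, t0])


def _theta_to_phi(theta: np.ndarray, n_pol: int, geom: GeneGeometry) -> np.ndarray:
    t_space, v_el, t_proc, t0 = theta
    v_nt = kbmin_to_nts(v_el)
    a = t0 + geom.l_pre / v_nt
    m = geom.l_ms2 / v_nt
    d = (n_pol - 1) * t_space
    r = t0 + geom.l_total / v_nt + t_proc
    return np.array([a, m, d, r])


def _fit_at_n(n_pol: int, phi0: np.ndarray, t: np.ndarray, y: np.ndarray,
              geom: GeneGeometry, free: np.ndarray | None = None,
              maxiter: int = 2000) -> _FitResult:
    """Minimize the sum of squared residuals over the continuous parameters.

    Transcript release is instantaneous, so the sampled model is a step
    function of the release-timing parameters and gradient-based solvers
    stall on the flat pieces; Nelder-Mead with a simplex wider than the
    sampling interval is robust to them.  ``free`` optionally fixes a subset
    of the (a, m, d, r) parameters (used by the elongation-rate profile
    scan, which pins the transit time ``m``).
    """
    if free is None:
        free = np.ones(4, dtype=bool)
    idx = np.flatnonzero(free)
    base = np.asarray(phi0, dtype=float).copy()

    def obj(sub: np.ndarray) -> float:
        phi = base.copy()
        phi[idx] = sub
        theta = _phi_to_theta(phi, n_pol, geom)
        r = _residuals(theta, n_pol, t, y, geom)
        return float(0.5 * np.dot(r, r))

    x0 = base[idx]
    steps = np.maximum(0.15 * np.abs(x0), 2.0)
    simplex = np.vstack([x0] + [x0 + steps[j] * np.eye(len(idx))[j]
                                for j in range(len(idx))])
    res = optimize.minimize(
        obj, x0, method="Nelder-Mead",
        options={"initial_simplex": simplex, "xatol": 1e-4, "fatol": 1e-12,
                 "maxiter": maxiter, "maxfev": maxiter},
    )
    phi = base.copy()
    phi[idx] = res.x
    return _FitResult(
        x=_phi_to_theta(phi, n_pol, geom), cost=float(res.fun), success=True
    )


def fit_convoy_cycle(
    cycle: TranscriptionCycle,
    geom: GeneGeometry,
    n_starts: int = 5,
    seed: int = 0,
) -> FittedConvoy:
    """Least-squares fit of the convoy model to one cycle.

    The polymerase number is optimized over an integer grid spanning +/-50%
    of the peak-intensity estimate (ties broken toward smaller values); the
    continuous parameters (t_space, v_el, t_proc, t0) are fit with bounded
    nonlinear least squares from an analytic start plus randomized restarts.
    """
    if cycle.n_frames < 8:
        raise ValueError("cycle must span at least 8 frames")
    t = cycle.times
    y = cycle.values
    rng = np.random.default_rng(seed)
    peak = float(y.max())
    n0 = max(1, int(round(peak)))
    n_grid = range(max(1, int(np.floor(0.5 * n0))), int(np.ceil(1.5 * n0)) + 1)

    # coarse pass: short optimizations from every analytic guess per n
    best = {}

    def scan(n_values):
        for n in n_values:
            if n in best:
                continue
            for phi0 in _initial_guess(t, y, geom, n):
                res = _fit_at_n(n, phi0, t, y, geom, maxiter=200)
                if n not in best or res.cost < best[n].cost:
                    best[n] = res

    scan(n_grid)
    # Peak intensity undercounts the polymerases of a strongly truncated
    # cycle (releases begin before the last initiation, capping the signal
    # at a dynamic steady state).  If the peak-based grid cannot reach the
    # noise floor, or prefers its own edge, extend toward the count implied
    # by total visible duration times the steady UP slope (1/t_space).
    # per-frame noise from second differences (zero for the piecewise-linear
    # noiseless signal, var = 6 sigma^2 under i.i.d. noise)
    d2 = np.diff(y, n=2)
    sigma_est = 1.4826 * float(np.median(np.abs(d2))) / np.sqrt(6.0)
    current = min(best, key=lambda n: (best[n].cost, n))
    resid_now = np.sqrt(2 * best[current].cost)
    n_frames = len(y)
    chi2_floor = sigma_est * np.sqrt(n_frames + 3 * np.sqrt(2.0 * n_frames))
    floor_norm = chi2_floor + 1e-2 * np.sqrt(np.sum(y**2))
    if resid_now > floor_norm or current == n_grid[-1]:
        from scipy.ndimage import uniform_filter1d

        dt_s = float(t[1] - t[0])
        slope = np.gradient(uniform_filter1d(y, size=5, mode="nearest"), dt_s)
        s_up = float(np.percentile(slope, 97))
        above = np.flatnonzero(y > 0.25 * peak)
        if s_up > 0 and above.size:
            t_span = t[above[-1]] - t[above[0]]
            n_t = int(np.ceil(1.2 * s_up * t_span)) + 1
            if n_t > n_grid[-1]:
                scan(range(n_grid[-1] + 1, min(n_t, 150) + 1))
    # full pass on the leading candidates, with randomized restarts
    order = sorted(best, key=lambda n: (best[n].cost, n))
    for n in order[:3]:
        base = _theta_to_phi(best[n].x, n, geom)
        res = _fit_at_n(n, base, t, y, geom)
        if res.cost < best[n].cost:
            best[n] = res
        for _ in range(max(n_starts - 1, 0)):
            phi0 = base + rng.normal(0.0, [4.0, 0.2 * base[1] + 1, 4.0, 4.0])
            res = _fit_at_n(n, phi0, t, y, geom, maxiter=600)
            if res.cost < best[n].cost:
                best[n] = res
    n_best = min(best, key=lambda n: (best[n].cost, n))
    fit = best[n_best]
    t_space, v_el, t_proc, t0 = fit.x
    cost_opt = fit.cost
    tss = float(np.sum(y**2))
    floor = 1e-9 * max(tss, 1.0)
    free_m_fixed = np.array([True, False, True, True])
    warm = {"phi": _theta_to_phi(fit.x, n_best, geom)}

    def cost_at_v(v: float) -> float:
        """Profile cost with the transit time pinned at l_ms2 / v; the
        nuisance parameters are re-optimized from a warm start plus
        perturbed restarts so the profile is a clean lower envelope."""
        phi0 = warm["phi"].copy()
        phi0[1] = geom.l_ms2 / kbmin_to_nts(v)
        res = _fit_at_n(n_best, phi0, t, y, geom, free=free_m_fixed)
        for k in range(2):
            phi_k = phi0 + rng.normal(0.0, [3.0, 0.0, 3.0, 3.0])
            phi_k[1] = phi0[1]
            alt = _fit_at_n(n_best, phi_k, t, y, geom, free=free_m_fixed,
                            maxiter=800)
            if alt.cost < res.cost:
                res = alt
        warm["phi"] = _theta_to_phi(res.x, n_best, geom)
        return res.cost

    rel_change = (cost_at_v(min(2 * v_el, _BOUNDS_HI[1])) - cost_opt) / (cost_opt + floor)
    v_lower_bound = bool(rel_change < 0.01)
    if v_lower_bound:
        # smallest v_el whose best profile residual stays within 1% of the
        # optimum
        v_small = v_el
        warm["phi"] = _theta_to_phi(fit.x, n_best, geom)
        for v in np.geomspace(v_el, _BOUNDS_LO[1], 12)[1:]:
            if (cost_at_v(v) - cost_opt) / (cost_opt + floor) < 0.01:
                v_small = v
            else:
                break
        v_el = v_small

    # approximate 1-sigma errors from a finite-difference Jacobian whose
    # steps exceed the flat cells of the release-time staircase
    unc: dict[str, float] = {}
    steps = np.array([0.2, 0.1, 1.0, 0.5])
    cols = []
    for i in range(4):
        hi_theta = fit.x.copy()
        lo_theta = fit.x.copy()
        hi_theta[i] += steps[i]
        lo_theta[i] -= steps[i]
        cols.append(
            (_residuals(hi_theta, n_best, t, y, geom)
             - _residuals(lo_theta, n_best, t, y, geom)) / (2 * steps[i])
        )
    jac = np.column_stack(cols)
    try:
        dof = max(len(y) - 5, 1)
        s2 = 2 * cost_opt / dof
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        for name, var in zip(("t_space", "v_el", "t_proc", "t0"), np.diag(cov)):
            unc[name] = float(np.sqrt(max(var, 0.0)))
    except np.linalg.LinAlgError:
        pass
    params = ConvoyParams(n_best, float(t_space), float(v_el), float(t_proc))
    return FittedConvoy(
        params=params,
        t0=float(t0),
        residual_norm=float(np.sqrt(2 * cost_opt)),
        v_el_is_lower_bound=v_lower_bound,
        uncertainty=unc,
    )


def pooled_upramp_regression(
    fits: list[FittedConvoy], geom: GeneGeometry
) -> dict[str, float]:
    """Cohort-level regression of UP-ramp duration on polymerase number.

    Under the convoy model the UP ramp lasts ``(n_pol - 1) * t_space +
    l_ms2 / v_el``, so an ordinary least-squares line through (n_pol,
    up_ramp) has slope ``t_space`` and intercept ``l_ms2 / v_el - t_space``;
    the pooled elongation rate is ``l_ms2 / (slope + intercept)``.  Also
    reports the Pearson correlation between fitted n_pol and t_space.
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 fitted cycles")
    n_pol = np.array([f.params.n_pol for f in fits], dtype=float)
    if np.unique(n_pol).size < 2:
        raise ValueError("degenerate regression: all n_pol identical")
    up = np.array(
        [analytic_durations(f.params, geom)["up_ramp"] for f in fits]
    )
    reg = stats.linregress(n_pol, up)
    t_space = np.array([f.params.t_space for f in fits])
    if np.unique(t_space).size < 2:
        corr = 0.0
    else:
        corr = float(stats.pearsonr(n_pol, t_space).statistic)
    ms2_time = reg.slope + reg.intercept  # = l_ms2 / v_el, seconds
    v_el = geom.l_ms2 / ms2_time / kbmin_to_nts(1.0) if ms2_time > 0 else np.nan
    return {
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "v_el_pooled": float(v_el),
        "npol_tspace_correlation": corr,
    }


def _up_ramp_window(fit: FittedConvoy, geom: GeneGeometry) -> tuple[float, float]:
    """Absolute start/end times of a fitted cycle's UP ramp: the ramp starts
    when the first polymerase enters the MS2 repeat and ends one full ramp
    duration later."""
    v = kbmin_to_nts(fit.params.v_el)
    start = fit.t0 + geom.l_pre / v
    up = analytic_durations(fit.params, geom)["up_ramp"]
    return start, start + up


def interconvoy_stats(
    per_trace_fits: list[list[FittedConvoy]],
    geom: GeneGeometry,
) -> dict[str, object]:
    """ON-duration and inter-convoy gap statistics across traces.

    A convoy's duration is ``n_pol * t_space`` (the time to initiate all its
    polymerases).  The gap between two successive convoys in the same trace
    is measured from the end of the UP ramp of one cycle to the beginning of
    the UP ramp of the next.  The exponential time constant of the gaps is
    their maximum-likelihood mean (undefined when no gaps exist).
    """
    durations: list[float] = []
    gaps: list[float] = []
    for fits in per_trace_fits:
        fits = sorted(fits, key=lambda f: f.t0)
        for f in fits:
            durations.append(f.params.n_pol * f.params.t_space)
        for prev, nxt in zip(fits, fits[1:]):
            _, up_end_prev = _up_ramp_window(prev, geom)
            up_start_next, _ = _up_ramp_window(nxt, geom)
            gaps.append(up_start_next - up_end_prev)
    gaps_arr = np.asarray(gaps)
    tau = float(gaps_arr.mean()) if gaps_arr.size else None
    return {
        "convoy_durations": np.asarray(durations),
        "gaps": gaps_arr,
        "exp_fit_tau": tau,
    }
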