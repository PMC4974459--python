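"""Threshold-based ON/OFF segmentation of TS traces and dwell-time fits.

Long, low-frame-rate movies do not need absolute nascent counts: a TS is
called active when its (moving-average smoothed) intensity exceeds a
threshold based on the mean single-molecule intensity, and silent otherwise.
Runs shorter than a minimum number of frames are merged into their flanking
state.  Dwell times of the resulting periods are fit with exponential or
bi-exponential models by maximum likelihood (expectation-maximization for
the mixture).  The same machinery serves short movies (ON/OFF between
convoys) and long movies (permissive/non-permissive periods) with different
configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .convoy import IntensityTrace

__all__ = [
    "OnOffConfig",
    "Period",
    "DwellFit",
    "segment_on_off",
    "fit_dwell",
]


@dataclass(frozen=True)
class OnOffConfig:
    """Segmentation configuration.

    ``threshold`` is in the trace's own units; the conventional choice is
    1.0x the mean single-molecule intensity.  ``smooth_window`` is an odd
    moving-average width in frames; runs shorter than ``min_state_frames``
    are merged into the flanking state.
    """

    threshold: float
    smooth_window: int = 3
    min_state_frames: int = 2

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if self.min_state_frames < 1:
            raise ValueError("min_state_frames must be >= 1")


@dataclass(frozen=True)
class Period:
    state: str  # "ON" or "OFF"
    start_s: float
    duration_s: float
    censored: bool


def _runs(states: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) half-open runs of constant value."""
    edges = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate([[0], edges, [states.size]])
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def segment_on_off(trace: IntensityTrace, cfg: OnOffConfig) -> list[Period]:
    """Segment a regular trace into ON and OFF periods.

    The trace is smoothed with a centered moving average, classified frame
    by frame against the threshold, and runs shorter than
    ``min_state_frames`` are merged into the flanking state (shortest run
    first; on equal length the earlier run merges first, i.e. into the
    preceding state).  The first and last periods are flagged censored since
    their true onset/offset lies outside the movie.
    """
    if len(trace) < cfg.smooth_window:
        raise ValueError("trace shorter than the smoothing window")
    smoothed = uniform_filter1d(
        trace.values, size=cfg.smooth_window, mode="nearest"
    )
    states = (smoothed > cfg.threshold).astype(np.int8)
    while True:
        runs = _runs(states)
        if len(runs) <= 1:
            break
        short = [
            (b - a, i) for i, (a, b) in enumerate(runs)
            if b - a < cfg.min_state_frames
        ]
        if not short:
            break
        _, i = min(short)  # shortest first; ties -> earliest
        a, b = runs[i]
        states[a:b] = 1 - states[a:b]  # flip into flanking state
    runs = _runs(states)
    dt = trace.dt
    periods = []
    for i, (a, b) in enumerate(runs):
        periods.append(
            Period(
                state="ON" if states[a] else "OFF",
                start_s=float(trace.times[a]),
                duration_s=(b - a) * dt,
                censored=(i == 0 or i == len(runs) - 1),
            )
        )
    return periods


@dataclass
class DwellFit:
    """Maximum-likelihood exponential or bi-exponential dwell fit.

    ``taus`` are sorted ascending; ``weights`` sum to 1.
    """

    model: str  # "mono" or "bi"
    taus: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_used: int

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.taus <= 0):
            raise ValueError("taus must be > 0")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")


def _mixture_loglik(d, cens, taus, weights):
    dens = (weights / taus) * np.exp(-d[:, None] / taus)
    surv = weights * np.exp(-d[:, None] / taus)
    per_obs = np.where(cens, surv.sum(axis=1), dens.sum(axis=1))
    return float(np.log(np.clip(per_obs, 1e-300, None)).sum())


def _em_biexp(d, cens, tau0, w0, max_iter=500, tol=1e-10):
    taus = np.asarray(tau0, dtype=float)
    w = np.asarray(w0, dtype=float)
    ll_old = -np.inf
    for _ in range(max_iter):
        dens = np.where(
            cens[:, None],
            w * np.exp(-d[:, None] / taus),
            (w / taus) * np.exp(-d[:, None] / taus),
        )
        tot = np.clip(dens.sum(axis=1, keepdims=True), 1e-300, None)
        r = dens / tot
        w = r.mean(axis=0)
        # censored observations contribute their expected residual life
        contrib = np.where(cens[:, None], d[:, None] + taus, d[:, None])
        events = (r * ~cens[:, None]).sum(axis=0)
        taus = (r * contrib).sum(axis=0) / np.clip(events, 1e-300, None)
        taus = np.clip(taus, 1e-9, None)
        ll = _mixture_loglik(d, cens, taus, w)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return taus, w, ll


def fit_dwell(
    durations: np.ndarray,
    model: str = "mono",
    censored: np.ndarray | None = None,
    censoring: str = "exclude",
    n_restarts: int = 10,
    seed: int = 0,
) -> DwellFit:
    """Maximum-likelihood dwell-time fit.

    ``mono`` fits a single exponential (MLE: the mean of uncensored
    durations, or total time over event count with survival handling).
    ``bi`` fits a two-component exponential mixture by EM with seeded
    restarts.  Censored durations are excluded by default
    (``censoring="exclude"``) or enter the likelihood through survival terms
    (``censoring="survival"``).
    """
    d = np.asarray(durations, dtype=float)
    cens = (
        np.zeros(d.size, dtype=bool)
        if censored is None
        else np.asarray(censored, dtype=bool)
    )
    if censoring not in ("exclude", "survival"):
        raise ValueError(f"unknown censoring mode {censoring!r}")
    if censoring == "exclude":
        d = d[~cens]
        cens = np.zeros(d.size, dtype=bool)
    if np.any(d < 0):
        raise ValueError("durations must be >= 0")
    n_events = int((~cens).sum())
    if model == "mono":
        if n_events < 1:
            raise ValueError("mono fit needs >= 1 uncensored duration")
        tau = float(d.sum() / n_events)
        ll = _mixture_loglik(d, cens, np.array([tau]), np.array([1.0]))
        return DwellFit("mono", [tau], [1.0], ll, int(d.size))
    if model != "bi":
        raise ValueError(f"unknown model {model!r}")
    if n_events < 10:
        raise ValueError("bi-exponential fit needs >= 10 uncensored durations")
    rng = np.random.default_rng(seed)
    best = None
    mean = d.mean()
    for k in range(n_restarts):
        if k == 0:
            q = np.quantile(d, [0.35, 0.85])
            tau0 = np.clip(q, 1e-6, None)
            w0 = np.array([0.6, 0.4])
        else:
            tau0 = mean * np.exp(rng.normal(0.0, 1.0, size=2))
            w0 = rng.dirichlet([1.0, 1.0])
        taus, w, ll = _em_biexp(d, cens, tau0, w0)
        if best is None or ll > best[2]:
            best = (taus, w, ll)
    taus, w, ll = best
    order = np.argsort(taus)
    return DwellFit("bi", taus[order], w[order], ll, int(d.size))
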