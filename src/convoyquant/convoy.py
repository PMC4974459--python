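"""Deterministic model of transcription-site (TS) intensity produced by a
polymerase convoy.

A convoy is a group of ``n_pol`` RNA polymerases initiating in rapid
succession (every ``t_space`` seconds) and elongating together at a common
speed ``v_el``.  The TS signal reported by an MS2/MCP reporter is the sum of
per-polymerase contributions: a polymerase is invisible while it transcribes
the leader upstream of the MS2 repeat, contributes linearly increasing signal
while it traverses the repeat (continuum approximation of the discrete
stem-loops), contributes one full RNA equivalent once past the repeat, and
drops to zero when its transcript is cleaved and released ``t_proc`` seconds
after it reaches the polyA site.

The superposition of ``n_pol`` such staircases is the tri-phasic cycle seen
in live-cell traces: a linear UP ramp, a plateau at ``n_pol`` and a linear
DOWN ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ConvoyParams",
    "GeneGeometry",
    "IntensityTrace",
    "ts_intensity",
    "intensity_from_initiations",
    "analytic_durations",
    "nucleotide_spacing",
]

#: nucleotides per second for a speed given in kb/min
NT_PER_S_PER_KB_MIN = 1000.0 / 60.0


def kbmin_to_nts(v_el: float) -> float:
    """Convert an elongation rate from kb/min to nt/s."""
    return v_el * NT_PER_S_PER_KB_MIN


@dataclass(frozen=True)
class ConvoyParams:
    """Kinetic parameters of a polymerase convoy.

    Parameters
    ----------
    n_pol : int
        Number of polymerases in the convoy (>= 1).
    t_space : float
        Time between successive initiations, seconds (>= 0).
    v_el : float
        Elongation rate, kb/min (> 0).
    t_proc : float
        3'-end processing/release time after the polymerase reaches the
        cleavage site, seconds (>= 0).
    """

    n_pol: int
    t_space: float
    v_el: float
    t_proc: float

    def __post_init__(self) -> None:
        if int(self.n_pol) != self.n_pol or self.n_pol < 1:
            raise ValueError(f"n_pol must be an integer >= 1, got {self.n_pol}")
        if self.t_space < 0:
            raise ValueError(f"t_space must be >= 0, got {self.t_space}")
        if not self.v_el > 0:
            raise ValueError(f"v_el must be > 0, got {self.v_el}")
        if self.t_proc < 0:
            raise ValueError(f"t_proc must be >= 0, got {self.t_proc}")

    @property
    def v_el_nt_s(self) -> float:
        return kbmin_to_nts(self.v_el)


@dataclass(frozen=True)
class GeneGeometry:
    """Reporter layout in nucleotides.

    Defaults describe an MS2x128 reporter: ~2 kb of leader before the repeat,
    a compact 128-stem-loop repeat (~22 nt per loop unit), and the distance
    from the repeat end to the cleavage/polyA site chosen so that, at typical
    fitted rates, post-repeat transit plus release takes on the order of
    three minutes.  All lengths are configuration, not ground truth.
    """

    l_pre: float = 2000.0
    l_ms2: float = 2800.0
    l_post: float = 4500.0

    def __post_init__(self) -> None:
        if self.l_pre < 0 or self.l_post < 0:
            raise ValueError("l_pre and l_post must be >= 0")
        if not self.l_ms2 > 0:
            raise ValueError(f"l_ms2 must be > 0, got {self.l_ms2}")

    @property
    def l_total(self) -> float:
        return self.l_pre + self.l_ms2 + self.l_post


@dataclass
class IntensityTrace:
    """Regularly sampled TS intensity versus time.

    ``units`` is ``"arbitrary"`` for raw fluorescence and
    ``"rna_equivalents"`` once calibrated to full-length RNA counts.
    """

    times: np.ndarray
    values: np.ndarray
    units: str = "arbitrary"
    meta: dict[str, Any] = field(default_factory=dict)

    _DT_RTOL = 1e-6

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have the same length")
        if self.units not in ("arbitrary", "rna_equivalents"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.times.size >= 2:
            diffs = np.diff(self.times)
            if np.any(diffs <= 0):
                raise ValueError("times must be strictly increasing")
            dt = diffs[0]
            if np.any(np.abs(diffs - dt) > self._DT_RTOL * max(dt, 1.0)):
                raise ValueError("times must be regularly spaced")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("dt undefined for traces with < 2 frames")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)


def intensity_from_initiations(
    t: np.ndarray | float,
    initiation_times: np.ndarray,
    v_el: float,
    geom: GeneGeometry,
    t_proc: float,
) -> np.ndarray | float:
    """TS intensity for an explicit list of polymerase initiation times.

    Each polymerase initiated at time ``ti`` sits at position
    ``v_el * (t - ti)`` nt.  Its signal is 0 before the MS2 repeat, ramps
    linearly to 1 across the repeat, stays at 1, and drops to 0 at its
    release time ``ti + l_total / v_el + t_proc``.

    ``v_el`` is in kb/min; ``t`` may be scalar or array (seconds).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    init = np.asarray(initiation_times, dtype=float)
    v = kbmin_to_nts(v_el)
    # position of every polymerase at every queried time, nt
    x = v * (t_arr[:, None] - init[None, :])
    s = np.clip((x - geom.l_pre) / geom.l_ms2, 0.0, 1.0)
    release = init[None, :] + geom.l_total / v + t_proc
    s[t_arr[:, None] >= release] = 0.0
    out = s.sum(axis=1)
    return out if np.ndim(t) else float(out[0])


def ts_intensity(
    t: np.ndarray | float,
    params: ConvoyParams,
    geom: GeneGeometry,
    t0: float = 0.0,
) -> np.ndarray | float:
    """TS intensity of a regularly spaced convoy, in RNA equivalents.

    Polymerase ``i`` (0-based) initiates at ``t0 + i * t_space``.  The result
    is non-negative and bounded by ``n_pol``.
    """
    init = t0 + np.arange(params.n_pol) * params.t_space
    return intensity_from_initiations(t, init, params.v_el, geom, params.t_proc)


def analytic_durations(params: ConvoyParams, geom: GeneGeometry) -> dict[str, float | bool]:
    """Closed-form phase durations of a regular convoy cycle.

    Returns up-ramp, plateau and down-ramp durations (s) plus the total
    visible time.  The plateau exists only while all transcripts are complete
    but none released, i.e. iff ``(n_pol - 1) * t_space <= l_post / v_el +
    t_proc``; otherwise it is clamped to 0 and ``truncated`` is set.
    """
    v = params.v_el_nt_s
    stagger = (params.n_pol - 1) * params.t_space
    up = stagger + geom.l_ms2 / v
    down = stagger
    plateau_raw = geom.l_post / v + params.t_proc - stagger
    truncated = plateau_raw < 0
    plateau = max(plateau_raw, 0.0)
    return {
        "up_ramp": up,
        "plateau": plateau,
        "down_ramp": down,
        "visible_total": up + plateau + down,
        "truncated": truncated,
    }


def nucleotide_spacing(t_space: float, v_el: float) -> float:
    """Physical distance between successive polymerases, nt.

    ``t_space`` in seconds, ``v_el`` in kb/min.
    """
    if t_space < 0 or v_el < 0:
        raise ValueError("t_space and v_el must be non-negative")
    return t_space * kbmin_to_nts(v_el)
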