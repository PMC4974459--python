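"""Seeded generators for every input the pipeline consumes.

The study's raw imaging data are not deposited, so synthetic stand-ins
emulate them: noisy convoy intensity traces (regular or stochastic polymerase
spacing), multi-scale promoter traces driven by the four-state promoter
model, 4D movie stacks with planted diffraction-limited spots and
tri-exponential photobleaching, calibration stacks, and dwell-time samples
from exponential mixtures.  Every generator is a pure function of its
arguments and a seed, and emits ground truth for downstream oracle checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .convoy import (
    ConvoyParams,
    GeneGeometry,
    IntensityTrace,
    analytic_durations,
    intensity_from_initiations,
)
from .promoter import PromoterModel, stationary_stats

__all__ = [
    "NoiseModel",
    "MovieSpec",
    "DwellMixture",
    "ElongationSpec",
    "simulate_convoy_trace",
    "simulate_promoter_trace",
    "simulate_movie_stack",
    "simulate_calibration_stack",
    "sample_dwell_times",
]


@dataclass(frozen=True)
class NoiseModel:
    """Per-frame measurement noise on an intensity trace.

    ``additive_sd`` is zero-mean Gaussian noise in trace units;
    ``multiplicative_sd`` is fractional intensity noise.  The default
    additive level of 0.5 RNA equivalents gives traces whose scatter
    resembles published single-TS recordings; it is a test parameter,
    not a measured quantity.
    """

    additive_sd: float = 0.5
    multiplicative_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise ValueError("noise sds must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(values, dtype=float).copy()
        if self.multiplicative_sd > 0:
            out *= 1.0 + rng.normal(0.0, self.multiplicative_sd, size=out.shape)
        if self.additive_sd > 0:
            out += rng.normal(0.0, self.additive_sd, size=out.shape)
        return out


@dataclass(frozen=True)
class MovieSpec:
    """Geometry, optics and noise of a synthetic time-lapse acquisition.

    Defaults mirror the live-cell acquisition: stacks of 11 planes with a
    0.6 um z-spacing, one stack every 3 s.  Bleaching is a global
    tri-exponential multiplier on all fluorescence (amplitudes sum to 1).
    """

    n_frames: int = 20
    n_z: int = 11
    z_step_um: float = 0.6
    frame_interval_s: float = 3.0
    xy_size_px: int = 64
    psf_sigma_xy_px: float = 1.3
    psf_sigma_z_planes: float = 1.0
    background_level: float = 100.0
    camera_noise_sd: float = 2.0
    bleach_amplitudes: tuple[float, float, float] = (0.5, 0.3, 0.2)
    bleach_rates: tuple[float, float, float] = (1 / 2000.0, 1 / 400.0, 1 / 80.0)
    saturation: float = math.inf

    def __post_init__(self) -> None:
        if self.n_z < 3:
            raise ValueError("n_z must be >= 3")
        if self.background_level < 0 or self.camera_noise_sd < 0:
            raise ValueError("levels and sds must be >= 0")
        if abs(sum(self.bleach_amplitudes) - 1.0) > 1e-9:
            raise ValueError("bleach amplitudes must sum to 1")

    def bleach_factor(self, t_s: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_s, dtype=float)
        amps = np.asarray(self.bleach_amplitudes)
        rates = np.asarray(self.bleach_rates)
        return (amps * np.exp(-np.multiply.outer(t, rates))).sum(axis=-1)


@dataclass(frozen=True)
class DwellMixture:
    """Mixture of exponential dwell times: taus in seconds, weights sum to 1."""

    taus: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.taus) != len(self.weights) or not self.taus:
            raise ValueError("taus and weights must be non-empty and equal length")
        if any(tau <= 0 for tau in self.taus):
            raise ValueError("taus must be > 0")
        if any(not (0 < w <= 1) for w in self.weights):
            raise ValueError("weights must lie in (0, 1]")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def mean(self) -> float:
        return float(sum(w * t for w, t in zip(self.weights, self.taus)))


@dataclass(frozen=True)
class ElongationSpec:
    """Elongation/release kinetics shared by all polymerases spawned by a
    promoter trace: speed in kb/min and 3'-processing time in seconds."""

    v_el: float = 4.1
    t_proc: float = 103.0


def simulate_convoy_trace(
    params: ConvoyParams,
    geom: GeneGeometry,
    dt: float,
    duration: float,
    spacing_mode: str = "regular",
    noise: NoiseModel | None = None,
    seed: int | None = None,
    t0: float = 0.0,
) -> IntensityTrace:
    """Sample a single convoy cycle at frame interval ``dt`` over ``duration``.

    In ``regular`` mode polymerase ``i`` initiates at ``t0 + i * t_space``;
    in ``exponential`` mode the inter-initiation gaps are i.i.d. exponential
    with mean ``t_space``.  Ground truth (initiation times, phase durations)
    is stored in ``trace.meta``.
    """
    if spacing_mode not in ("regular", "exponential"):
        raise ValueError(f"unknown spacing_mode {spacing_mode!r}")
    rng = np.random.default_rng(seed)
    if spacing_mode == "regular":
        init = t0 + np.arange(params.n_pol) * params.t_space
    else:
        gaps = rng.exponential(params.t_space, size=params.n_pol - 1)
        init = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
    times = np.arange(0.0, duration, dt)
    values = intensity_from_initiations(times, init, params.v_el, geom, params.t_proc)
    if noise is not None:
        values = noise.apply(values, rng)
    durations = analytic_durations(params, geom)
    last_release = float(init[-1]) + geom.l_total / params.v_el_nt_s + params.t_proc
    meta = {
        "initiation_times": init,
        "analytic_durations": durations,
        "last_release_s": last_release,
        "t0": t0,
        "duration_truncates_cycle": bool(duration < last_release),
    }
    return IntensityTrace(times, values, units="rna_equivalents", meta=meta)


def _gillespie_promoter_path(
    model: PromoterModel, duration: float, rng: np.random.Generator
) -> list[tuple[str, float, float]]:
    """Exact CTMC path of the promoter: list of (state, start_s, end_s)."""
    pi = stationary_stats(model).pi
    state = rng.choice(list(pi), p=list(pi.values()))
    t = 0.0
    path = []
    while t < duration:
        if state == "ON":
            moves = [("OFF1", model.k_off1)]
        elif state == "OFF1":
            moves = [
                ("ON", model.k_on1),
                ("OFF2a", model.f1 * model.k_off2),
                ("OFF2b", (1.0 - model.f1) * model.k_off2),
            ]
        elif state == "OFF2a":
            moves = [("OFF1", model.k_on2a)]
        else:
            moves = [("OFF1", model.k_on2b)]
        total = sum(rate for _, rate in moves)
        if total <= 0:  # absorbing state
            path.append((state, t, duration))
            break
        dwell = rng.exponential(1.0 / total)
        end = min(t + dwell, duration)
        path.append((state, t, end))
        if end >= duration:
            break
        u = rng.random() * total
        acc = 0.0
        for nxt, rate in moves:
            acc += rate
            if u <= acc:
                state = nxt
                break
        t = end
    return path


def simulate_promoter_trace(
    model: PromoterModel,
    geom: GeneGeometry,
    elongation: ElongationSpec,
    dt: float,
    duration: float,
    seed: int | None = None,
) -> tuple[np.ndarray, IntensityTrace]:
    """Simulate a promoter switching between ON/OFF1/OFF2a/OFF2b and the TS
    intensity trace it produces.

    While ON, polymerases initiate as a Poisson process at rate ``k_ini``;
    each is tracked through the reporter geometry exactly as in the convoy
    model.  Returns the per-frame promoter state path and the intensity
    trace (RNA equivalents); initiation times are stored in ``meta``.
    """
    rng = np.random.default_rng(seed)
    path = _gillespie_promoter_path(model, duration, rng)
    initiations: list[float] = []
    if model.k_ini > 0:
        for state, start, end in path:
            if state != "ON":
                continue
            n = rng.poisson(model.k_ini * (end - start))
            if n:
                initiations.extend(rng.uniform(start, end, size=n))
    init = np.sort(np.asarray(initiations))
    times = np.arange(0.0, duration, dt)
    if init.size:
        values = intensity_from_initiations(
            times, init, elongation.v_el, geom, elongation.t_proc
        )
    else:
        values = np.zeros_like(times)
    # per-frame state labels
    state_path = np.empty(times.size, dtype=object)
    for state, start, end in path:
        mask = (times >= start) & (times < end)
        state_path[mask] = state
    state_path[times >= path[-1][1]] = path[-1][0]
    trace = IntensityTrace(
        times,
        values,
        units="rna_equivalents",
        meta={"initiation_times": init, "state_intervals": path},
    )
    return state_path, trace


def _render_spot(
    frame: np.ndarray,
    z: float,
    y: float,
    x: float,
    integrated: float,
    sigma_xy: float,
    sigma_z: float,
) -> None:
    """Add a 3D Gaussian of given integrated intensity to ``frame`` in place."""
    n_z, n_y, n_x = frame.shape
    amp = integrated / ((2 * math.pi) ** 1.5 * sigma_xy**2 * sigma_z)
    rz = max(int(math.ceil(4 * sigma_z)), 2)
    rxy = max(int(math.ceil(4 * sigma_xy)), 2)
    z0, z1 = max(0, int(z) - rz), min(n_z, int(z) + rz + 1)
    y0, y1 = max(0, int(y) - rxy), min(n_y, int(y) + rxy + 1)
    x0, x1 = max(0, int(x) - rxy), min(n_x, int(x) + rxy + 1)
    zz = np.arange(z0, z1, dtype=float)[:, None, None]
    yy = np.arange(y0, y1, dtype=float)[None, :, None]
    xx = np.arange(x0, x1, dtype=float)[None, None, :]
    g = np.exp(
        -((zz - z) ** 2) / (2 * sigma_z**2)
        - ((yy - y) ** 2) / (2 * sigma_xy**2)
        - ((xx - x) ** 2) / (2 * sigma_xy**2)
    )
    frame[z0:z1, y0:y1, x0:x1] += amp * g


def _camera_noise(
    signal: np.ndarray, read_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson shot noise (Gaussian approximation with matched variance)
    plus additive Gaussian read noise."""
    var = np.clip(signal, 0.0, None) + read_sd**2
    return signal + rng.normal(0.0, 1.0, size=signal.shape) * np.sqrt(var)


def simulate_movie_stack(
    spec: MovieSpec,
    ts_trace: IntensityTrace | None,
    n_single_molecules: int,
    single_molecule_intensity: float,
    seed: int | None = None,
    ts_position: tuple[float, float, float] | None = None,
    margin_px: int = 6,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a 4D movie (t, z, y, x) with a fixed TS and diffusing single
    molecules, global tri-exponential bleaching and camera noise.

    The TS integrated intensity per frame is ``ts_trace`` (RNA equivalents)
    times ``single_molecule_intensity``.  Single molecules are static within
    a frame and repositioned uniformly at random between frames.  Returns the
    stack and a ground-truth table listing every spot's position and
    pre-bleach integrated intensity.
    """
    rng = np.random.default_rng(seed)
    shape = (spec.n_frames, spec.n_z, spec.xy_size_px, spec.xy_size_px)
    stack = np.zeros(shape, dtype=float)
    if ts_position is None:
        ts_position = (spec.n_z / 2.0, spec.xy_size_px / 2.0, spec.xy_size_px / 2.0)
    truth = []
    clipped = False
    t_s = np.arange(spec.n_frames) * spec.frame_interval_s
    bleach = np.asarray(spec.bleach_factor(t_s), dtype=float)
    for f in range(spec.n_frames):
        frame = np.full(shape[1:], float(spec.background_level))
        if ts_trace is not None:
            inten = float(ts_trace.values[f]) * single_molecule_intensity
            if inten > 0:
                _render_spot(
                    frame, *ts_position, inten, spec.psf_sigma_xy_px, spec.psf_sigma_z_planes
                )
            truth.append((f, "ts", *ts_position, inten))
        for _ in range(n_single_molecules):
            z = rng.uniform(1.0, spec.n_z - 2.0)
            y = rng.uniform(margin_px, spec.xy_size_px - 1 - margin_px)
            x = rng.uniform(margin_px, spec.xy_size_px - 1 - margin_px)
            _render_spot(
                frame, z, y, x, single_molecule_intensity,
                spec.psf_sigma_xy_px, spec.psf_sigma_z_planes,
            )
            truth.append((f, "molecule", z, y, x, single_molecule_intensity))
        frame *= bleach[f]
        if spec.camera_noise_sd > 0:
            frame = _camera_noise(frame, spec.camera_noise_sd, rng)
        if np.any(frame > spec.saturation):
            frame = np.minimum(frame, spec.saturation)
            clipped = True
        stack[f] = frame
    gt = pd.DataFrame(truth, columns=["frame", "kind", "z", "y", "x", "intensity"])
    gt.attrs["bleach_factors"] = bleach
    gt.attrs["clipped"] = clipped
    return stack, gt


def simulate_calibration_stack(
    spec: MovieSpec,
    n_single_molecules: int,
    single_molecule_intensity: float,
    illumination_gain: float = 50.0,
    n_z: int = 21,
    z_step_um: float = 0.3,
    seed: int | None = None,
    ts_intensity_equivalents: float = 0.0,
    ts_position_xy: tuple[float, float] | None = None,
    margin_px: int = 6,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the single high-power 3D calibration stack acquired at movie end.

    Finer z-sampling (21 planes every 0.3 um by default) and an illumination
    gain make individual molecules reliably detectable.  The physical PSF is
    unchanged, so the axial sigma in planes scales with the z-step.
    """
    rng = np.random.default_rng(seed)
    sigma_z_planes = spec.psf_sigma_z_planes * spec.z_step_um / z_step_um
    vol = np.full(
        (n_z, spec.xy_size_px, spec.xy_size_px),
        float(spec.background_level) * illumination_gain,
    )
    truth = []
    if ts_intensity_equivalents > 0:
        y, x = ts_position_xy or (spec.xy_size_px / 2.0, spec.xy_size_px / 2.0)
        inten = ts_intensity_equivalents * single_molecule_intensity * illumination_gain
        _render_spot(vol, n_z / 2.0, y, x, inten, spec.psf_sigma_xy_px, sigma_z_planes)
        truth.append(("ts", n_z / 2.0, y, x, inten))
    for _ in range(n_single_molecules):
        z = rng.uniform(2.0, n_z - 3.0)
        y = rng.uniform(margin_px, spec.xy_size_px - 1 - margin_px)
        x = rng.uniform(margin_px, spec.xy_size_px - 1 - margin_px)
        inten = single_molecule_intensity * illumination_gain
        _render_spot(vol, z, y, x, inten, spec.psf_sigma_xy_px, sigma_z_planes)
        truth.append(("molecule", z, y, x, inten))
    if spec.camera_noise_sd > 0:
        vol = _camera_noise(vol, spec.camera_noise_sd, rng)
    gt = pd.DataFrame(truth, columns=["kind", "z", "y", "x", "intensity"])
    gt.attrs["illumination_gain"] = illumination_gain
    gt.attrs["sigma_z_planes"] = sigma_z_planes
    return vol, gt


def sample_dwell_times(
    mix: DwellMixture, n: int, seed: int | None = None
) -> np.ndarray:
    """Draw ``n`` i.i.d. dwell times (s) from a mixture of exponentials."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    comps = rng.choice(len(mix.taus), size=n, p=np.asarray(mix.weights))
    return rng.exponential(np.asarray(mix.taus)[comps])
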