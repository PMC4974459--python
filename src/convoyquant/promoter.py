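"""Four-state promoter model of multi-scale transcriptional bursting.

The promoter switches between an active ON state (where polymerase convoys
form), a short-lived intermediate OFF1 state, and two long-lived OFF2
sub-states (OFF2a, OFF2b) that account for the two lifetimes of the long
non-permissive periods.  The chain is linear in the sense
OFF2 <-> OFF1 <-> ON; entry into OFF2 splits with probability ``f1`` into
OFF2a and ``1 - f1`` into OFF2b.  While ON, nascent RNAs are produced at
rate ``k_ini``; each nascent RNA is released from the transcription site
with first-order rate ``k_release`` and each released (mature) pre-mRNA
decays with rate ``k_deg``.

The module provides the analytic stationary distribution, the steady-state
rate constraints used to complete a partially specified model from observed
mean copy numbers, a fixed-step population Monte-Carlo (with an exact
event-driven cross-check), chi2/KS comparison against observed copy-number
distributions, and a grid-search fit with top-10 averaging.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PromoterModel",
    "CellCounts",
    "GridSpec",
    "PopulationSummary",
    "SimSettings",
    "StationaryStats",
    "stationary_stats",
    "solve_constrained_rates",
    "simulate_population",
    "compare_distributions",
    "grid_search_fit",
]

_STATE_INDEX = {"ON": 0, "OFF1": 1, "OFF2a": 2, "OFF2b": 3}


@dataclass(frozen=True)
class PromoterModel:
    """All rates in per second.

    ``k_on1``/``k_off1`` switch OFF1 <-> ON; ``k_off2`` leaves OFF1 for the
    long OFF2 states, entering OFF2a with probability ``f1``; ``k_on2a`` and
    ``k_on2b`` return to OFF1.  ``k_ini`` is the initiation rate while ON,
    ``k_release`` the per-molecule nascent release rate and ``k_deg`` the
    per-molecule mature decay rate.
    """

    k_on1: float
    k_off1: float
    k_off2: float
    f1: float
    k_on2a: float
    k_on2b: float
    k_ini: float
    k_release: float
    k_deg: float

    def __post_init__(self) -> None:
        for name in (
            "k_on1", "k_off1", "k_off2", "k_on2a", "k_on2b",
            "k_ini", "k_release", "k_deg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.f1 <= 1.0:
            raise ValueError(f"f1 must be in [0, 1], got {self.f1}")


@dataclass
class CellCounts:
    """Per-cell nascent and mature (released) pre-mRNA counts."""

    nascent: np.ndarray
    mature: np.ndarray

    def __post_init__(self) -> None:
        self.nascent = np.asarray(self.nascent)
        self.mature = np.asarray(self.mature)
        if self.nascent.shape != self.mature.shape or self.nascent.ndim != 1:
            raise ValueError("nascent and mature must be 1-D and equal length")
        if np.any(self.nascent < 0) or np.any(self.mature < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return int(self.nascent.size)

    def summary(self) -> "PopulationSummary":
        return PopulationSummary(
            mean_mature=float(self.mature.mean()),
            mean_nascent=float(self.nascent.mean()),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"cell_id": np.arange(len(self)), "nascent": self.nascent, "mature": self.mature}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CellCounts":
        df = pd.read_csv(path)
        return cls(df["nascent"].to_numpy(), df["mature"].to_numpy())


@dataclass(frozen=True)
class PopulationSummary:
    """Population means of mature and nascent pre-mRNA per cell."""

    mean_mature: float
    mean_nascent: float

    def __post_init__(self) -> None:
        if self.mean_mature < 0 or self.mean_nascent < 0:
            raise ValueError("means must be >= 0")


@dataclass(frozen=True)
class SimSettings:
    """Population simulation bookkeeping; defaults match a 10-hour run of
    1-second steps for 3,000 cells."""

    n_cells: int = 3000
    n_steps: int = 36000
    dt_s: float = 1.0
    scheme: str = "fixed_step"

    @property
    def total_time_s(self) -> float:
        return self.n_steps * self.dt_s

    @property
    def total_time_h(self) -> float:
        return self.total_time_s / 3600.0


@dataclass(frozen=True)
class StationaryStats:
    pi: dict[str, float]
    mean_nascent: float
    mean_mature: float


def stationary_stats(m: PromoterModel) -> StationaryStats:
    """Analytic stationary distribution of the promoter chain and the
    steady-state mean copy numbers.

    The chain is a tree, so detailed balance gives, relative to OFF1 weight 1:
    ``w_ON = k_on1/k_off1``, ``w_OFF2a = f1*k_off2/k_on2a``,
    ``w_OFF2b = (1-f1)*k_off2/k_on2b``.  Mean nascent and mature counts are
    ``k_ini*pi_ON/k_release`` and ``k_ini*pi_ON/k_deg``.
    """
    if m.k_off1 == 0 and m.k_on1 > 0:
        warnings.warn("k_off1 = 0 with k_on1 > 0: ON is absorbing, pi_ON = 1")
        pi = {"ON": 1.0, "OFF1": 0.0, "OFF2a": 0.0, "OFF2b": 0.0}
    else:
        w_on = m.k_on1 / m.k_off1 if m.k_off1 > 0 else 0.0
        w_2a = m.f1 * m.k_off2 / m.k_on2a if m.k_on2a > 0 else 0.0
        w_2b = (1.0 - m.f1) * m.k_off2 / m.k_on2b if m.k_on2b > 0 else 0.0
        if (m.f1 > 0 and m.k_off2 > 0 and m.k_on2a == 0) or (
            m.f1 < 1 and m.k_off2 > 0 and m.k_on2b == 0
        ):
            raise ValueError("an OFF2 state with entry but no exit is absorbing")
        total = 1.0 + w_on + w_2a + w_2b
        pi = {
            "ON": w_on / total,
            "OFF1": 1.0 / total,
            "OFF2a": w_2a / total,
            "OFF2b": w_2b / total,
        }
    flux = m.k_ini * pi["ON"]
    mean_nasc = flux / m.k_release if m.k_release > 0 else (0.0 if flux == 0 else np.inf)
    mean_mat = flux / m.k_deg if m.k_deg > 0 else (0.0 if flux == 0 else np.inf)
    return StationaryStats(pi=pi, mean_nascent=mean_nasc, mean_mature=mean_mat)


@dataclass(frozen=True)
class SolveResult:
    model: PromoterModel | None
    status: str  # "ok" or "infeasible"
    k_off2: float
    k_release: float


def solve_constrained_rates(
    partial: PromoterModel, target: PopulationSummary
) -> SolveResult:
    """Complete a model so that its stationary means match observed means.

    ``k_release`` follows from the steady-state identity
    ``k_release/k_deg = meanMat/meanNasc``; ``k_off2`` is then the unique
    solution of ``mean_mature(model) = meanMat`` (linear in ``k_off2``).
    Parameter combinations requiring ``k_off2 < 0`` are reported with status
    ``"infeasible"`` rather than raising.
    """
    if target.mean_mature <= 0 or target.mean_nascent <= 0:
        raise ValueError("target means must be > 0")
    if partial.k_off1 <= 0 or partial.k_on1 <= 0:
        raise ValueError("k_on1 and k_off1 must be > 0 to solve the constraints")
    k_release = partial.k_deg * target.mean_mature / target.mean_nascent
    w_on = partial.k_on1 / partial.k_off1
    c = partial.f1 / partial.k_on2a + (1.0 - partial.f1) / partial.k_on2b
    # meanMat = k_ini*w_on / (k_deg*(1 + w_on + c*k_off2))
    k_off2 = (
        partial.k_ini * w_on / (partial.k_deg * target.mean_mature) - 1.0 - w_on
    ) / c
    if k_off2 < 0 or not np.isfinite(k_off2):
        return SolveResult(None, "infeasible", float(k_off2), k_release)
    model = replace(partial, k_off2=float(k_off2), k_release=float(k_release))
    return SolveResult(model, "ok", float(k_off2), k_release)


def _check_dt_stability(m: PromoterModel, dt: float) -> None:
    exits = {
        "OFF1 exit (k_on1 + k_off2)": m.k_on1 + m.k_off2,
        "ON exit (k_off1)": m.k_off1,
        "OFF2a exit (k_on2a)": m.k_on2a,
        "OFF2b exit (k_on2b)": m.k_on2b,
        "k_release": m.k_release,
        "k_deg": m.k_deg,
    }
    for name, rate in exits.items():
        if rate * dt >= 0.1:
            raise ValueError(
                f"fixed-step instability: dt * {name} = {rate * dt:.3g} >= 0.1"
            )


def _initial_population(
    m: PromoterModel, n_cells: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Initial states from the analytic stationary distribution; counts from
    Poisson at the stationary means (runs are long relative to 1/k_deg, so
    results are insensitive to this choice)."""
    ss = stationary_stats(m)
    probs = [ss.pi[s] for s in ("ON", "OFF1", "OFF2a", "OFF2b")]
    states = rng.choice(4, size=n_cells, p=probs).astype(np.int64)
    mean_n = ss.mean_nascent if np.isfinite(ss.mean_nascent) else 0.0
    mean_m = ss.mean_mature if np.isfinite(ss.mean_mature) else 0.0
    nasc = rng.poisson(mean_n, size=n_cells).astype(np.int64)
    mat = rng.poisson(mean_m, size=n_cells).astype(np.int64)
    return states, nasc, mat


def _fixed_step_numpy(
    rates: tuple, states, nasc, mat, n_steps, dt, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k_on1, k_off1, k_off2, f1, k_on2a, k_on2b, k_ini, k_rel, k_deg = rates
    p_on1, p_off1 = k_on1 * dt, k_off1 * dt
    p_2a, p_2b = f1 * k_off2 * dt, (1 - f1) * k_off2 * dt
    p_on2a, p_on2b = k_on2a * dt, k_on2b * dt
    p_rel, p_deg = k_rel * dt, k_deg * dt
    for _ in range(n_steps):
        on = states == 0
        if k_ini > 0:
            nasc[on] += rng.poisson(k_ini * dt, size=int(on.sum()))
        rel = rng.binomial(nasc, p_rel)
        nasc -= rel
        mat += rel
        mat -= rng.binomial(mat, p_deg)
        u = rng.random(states.size)
        off1 = states == 1
        new = states.copy()
        new[on & (u < p_off1)] = 1
        new[off1 & (u < p_on1)] = 0
        new[off1 & (u >= p_on1) & (u < p_on1 + p_2a)] = 2
        new[off1 & (u >= p_on1 + p_2a) & (u < p_on1 + p_2a + p_2b)] = 3
        new[(states == 2) & (u < p_on2a)] = 1
        new[(states == 3) & (u < p_on2b)] = 1
        states = new
    return states, nasc, mat


try:  # pragma: no cover - exercised indirectly
    import numba

    @numba.njit(cache=True)
    def _fixed_step_kernel(
        k_on1, k_off1, k_off2, f1, k_on2a, k_on2b, k_ini, k_rel, k_deg,
        states, nasc, mat, n_steps, dt, seed,
    ):
        np.random.seed(seed)
        p_off1 = k_off1 * dt
        p_on1 = k_on1 * dt
        p_2a = f1 * k_off2 * dt
        p_2b = (1.0 - f1) * k_off2 * dt
        p_on2a = k_on2a * dt
        p_on2b = k_on2b * dt
        p_rel = k_rel * dt
        p_deg = k_deg * dt
        lam = k_ini * dt
        for c in range(states.size):
            s = states[c]
            n = nasc[c]
            m = mat[c]
            for _ in range(n_steps):
                if s == 0 and lam > 0.0:
                    n += np.random.poisson(lam)
                if n > 0 and p_rel > 0.0:
                    r = np.random.binomial(n, p_rel)
                    n -= r
                    m += r
                if m > 0 and p_deg > 0.0:
                    m -= np.random.binomial(m, p_deg)
                u = np.random.random()
                if s == 0:
                    if u < p_off1:
                        s = 1
                elif s == 1:
                    if u < p_on1:
                        s = 0
                    elif u < p_on1 + p_2a:
                        s = 2
                    elif u < p_on1 + p_2a + p_2b:
                        s = 3
                elif s == 2:
                    if u < p_on2a:
                        s = 1
                else:
                    if u < p_on2b:
                        s = 1
            states[c] = s
            nasc[c] = n
            mat[c] = m
        return states, nasc, mat

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _gillespie_cell(
    m: PromoterModel, t_end: float, state: int, nasc: int, mat: int,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """Exact event-driven simulation of one cell (cross-check scheme)."""
    t = 0.0
    while True:
        if state == 0:
            a = [m.k_off1, 0.0, 0.0, m.k_ini, m.k_release * nasc, m.k_deg * mat]
        elif state == 1:
            a = [
                m.k_on1, m.f1 * m.k_off2, (1 - m.f1) * m.k_off2,
                0.0, m.k_release * nasc, m.k_deg * mat,
            ]
        elif state == 2:
            a = [m.k_on2a, 0.0, 0.0, 0.0, m.k_release * nasc, m.k_deg * mat]
        else:
            a = [m.k_on2b, 0.0, 0.0, 0.0, m.k_release * nasc, m.k_deg * mat]
        total = sum(a)
        if total <= 0:
            return state, nasc, mat
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            return state, nasc, mat
        u = rng.random() * total
        acc = 0.0
        for idx, rate in enumerate(a):
            acc += rate
            if u <= acc:
                break
        if idx == 0:  # promoter switch
            if state == 0:
                state = 1
            elif state == 1:
                state = 0
            else:
                state = 1
        elif idx == 1:
            state = 2
        elif idx == 2:
            state = 3
        elif idx == 3:
            nasc += 1
        elif idx == 4:
            nasc -= 1
            mat += 1
        else:
            mat -= 1


def simulate_population(
    m: PromoterModel,
    n_cells: int,
    n_steps: int = 36000,
    dt: float = 1.0,
    seed: int | None = None,
    scheme: str = "fixed_step",
    return_states: bool = False,
):
    """Simulate a population of independent cells and return end-of-run
    per-cell counts.

    ``fixed_step`` advances every cell in steps of ``dt`` seconds: promoter
    transitions fire with probability ``rate * dt`` (valid only while all
    exit probabilities stay below 0.1, enforced), initiations are Poisson
    draws and per-molecule release/decay are binomial thinnings.  ``exact``
    is an event-driven Gillespie cross-check.
    """
    rng = np.random.default_rng(seed)
    states, nasc, mat = _initial_population(m, n_cells, rng)
    if scheme == "fixed_step":
        _check_dt_stability(m, dt)
        rates = (
            m.k_on1, m.k_off1, m.k_off2, m.f1, m.k_on2a, m.k_on2b,
            m.k_ini, m.k_release, m.k_deg,
        )
        if _HAVE_NUMBA:
            kernel_seed = int(rng.integers(0, 2**31 - 1))
            states, nasc, mat = _fixed_step_kernel(
                *[float(r) for r in rates], states, nasc, mat,
                int(n_steps), float(dt), kernel_seed,
            )
        else:
            states, nasc, mat = _fixed_step_numpy(
                rates, states, nasc, mat, int(n_steps), float(dt), rng
            )
    elif scheme == "exact":
        t_end = n_steps * dt
        for c in range(n_cells):
            states[c], nasc[c], mat[c] = _gillespie_cell(
                m, t_end, int(states[c]), int(nasc[c]), int(mat[c]), rng
            )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    counts = CellCounts(nasc, mat)
    if return_states:
        labels = np.array(["ON", "OFF1", "OFF2a", "OFF2b"])[states]
        return counts, labels
    return counts


def _chi2_nascent(sim: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    """Two-sample chi-square on integer count distributions, pooling
    adjacent bins until every expected cell is >= 5."""
    hi = int(max(sim.max(initial=0), obs.max(initial=0)))
    edges = np.arange(hi + 2)
    c_sim, _ = np.histogram(sim, bins=edges)
    c_obs, _ = np.histogram(obs, bins=edges)
    table = np.vstack([c_sim, c_obs]).astype(float)

    def expected(tab):
        row = tab.sum(axis=1, keepdims=True)
        col = tab.sum(axis=0, keepdims=True)
        return row * col / tab.sum()

    while table.shape[1] > 2:
        exp = expected(table)
        if exp.min() >= 5:
            break
        j = int(np.argmin(exp.min(axis=0)))
        k = j + 1 if j + 1 < table.shape[1] else j - 1
        table[:, min(j, k)] += table[:, max(j, k)]
        table = np.delete(table, max(j, k), axis=1)
    if table.shape[1] < 2:
        raise ValueError("chi-square undefined: fewer than 2 bins after pooling")
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(chi2), float(p)


def compare_distributions(sim: CellCounts, obs: CellCounts) -> dict[str, float]:
    """Score a simulated population against an observed one.

    Mature (released) counts are compared with a two-sample KS test; nascent
    counts with a chi-square test on pooled integer bins (nascent
    distributions contain many tied values, which invalidates KS).  The
    combined score is the product of the two p-values.
    """
    if len(sim) == 0 or len(obs) == 0:
        raise ValueError("both samples must be non-empty")
    ks = stats.ks_2samp(obs.mature, sim.mature, method="asymp")
    chi2, p_nasc = _chi2_nascent(sim.nascent, obs.nascent)
    return {
        "ks_stat": float(ks.statistic),
        "p_mature": float(ks.pvalue),
        "chi2_stat": chi2,
        "p_nascent": p_nasc,
        "p_product": float(ks.pvalue) * p_nasc,
    }


@dataclass(frozen=True)
class GridSpec:
    """Grid of candidate rate parameters for the population fit.

    Axis values follow the natural experimental parameterization: initiation
    intervals ``1/k_ini`` in seconds, OFF2a fraction ``f1``, long-OFF exit
    intervals ``1/k_on2b`` in minutes, ON exit rates ``k_off1`` in per
    second, and permissive-entry intervals ``1/k_on1`` in minutes.
    ``1/k_on2a`` is fixed at 5 min and ``k_deg`` at 1/75 per minute.
    """

    inv_k_ini_s: tuple[float, ...] = (2.3, 2.6, 3.0, 3.4, 3.7, 4.0, 4.3, 4.6)
    f1: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9)
    inv_k_on2b_min: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)
    k_off1_per_s: tuple[float, ...] = (1 / 90.0, 1 / 110.0, 1 / 130.0, 1 / 160.0)
    inv_k_on1_min: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0)
    inv_k_on2a_min: float = 5.0
    k_deg_per_min: float = 1 / 75.0

    def __post_init__(self) -> None:
        for name in ("inv_k_ini_s", "f1", "inv_k_on2b_min", "k_off1_per_s", "inv_k_on1_min"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")

    def combos(self):
        """Yield partially specified models (k_off2 and k_release zeroed)."""
        for inv_ki, f1, inv_k2b, koff1, inv_kon1 in itertools.product(
            self.inv_k_ini_s, self.f1, self.inv_k_on2b_min,
            self.k_off1_per_s, self.inv_k_on1_min,
        ):
            yield PromoterModel(
                k_on1=1.0 / (inv_kon1 * 60.0),
                k_off1=koff1,
                k_off2=0.0,
                f1=f1,
                k_on2a=1.0 / (self.inv_k_on2a_min * 60.0),
                k_on2b=1.0 / (inv_k2b * 60.0),
                k_ini=1.0 / inv_ki,
                k_release=0.0,
                k_deg=self.k_deg_per_min / 60.0,
            ), {
                "inv_k_ini_s": inv_ki,
                "f1": f1,
                "inv_k_on2b_min": inv_k2b,
                "k_off1_per_s": koff1,
                "inv_k_on1_min": inv_kon1,
            }

    def __len__(self) -> int:
        return (
            len(self.inv_k_ini_s) * len(self.f1) * len(self.inv_k_on2b_min)
            * len(self.k_off1_per_s) * len(self.inv_k_on1_min)
        )


_GRID_AXES = ["inv_k_ini_s", "f1", "inv_k_on2b_min", "k_off1_per_s", "inv_k_on1_min"]


def grid_search_fit(
    grid: GridSpec,
    obs: CellCounts,
    sim: SimSettings | None = None,
    seed: int | None = None,
    n_top: int = 10,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fit the promoter model to observed copy-number distributions.

    For every grid combination the constrained rates (``k_release``,
    ``k_off2``) are solved from the observed means, a population is
    simulated, and the simulated distributions are scored against the
    observed ones.  Rows are ranked by the product of p-values; the
    arithmetic mean of each grid axis (plus the solved rates) over the
    ``n_top`` best feasible combinations is returned alongside the table.
    """
    sim = sim or SimSettings()
    target = obs.summary()
    seeds = np.random.SeedSequence(seed).spawn(len(grid))
    rows = []
    for (partial, axes), ss in zip(grid.combos(), seeds):
        row = dict(axes)
        res = solve_constrained_rates(partial, target)
        row["k_off2_per_s"] = res.k_off2
        row["k_release_per_s"] = res.k_release
        row["status"] = res.status
        if res.status == "ok":
            counts = simulate_population(
                res.model, sim.n_cells, sim.n_steps, sim.dt_s,
                seed=int(ss.generate_state(1)[0] % (2**31 - 1)),
            )
            row.update(compare_distributions(counts, obs))
        else:
            row.update(
                ks_stat=np.nan, p_mature=np.nan, chi2_stat=np.nan,
                p_nascent=np.nan, p_product=-1.0,
            )
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        "p_product", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    feasible = table[table["status"] == "ok"]
    if feasible.empty:
        raise ValueError("all grid combinations are infeasible (k_off2 < 0)")
    top = feasible.head(n_top)
    averaged = {
        name: float(top[name].mean())
        for name in _GRID_AXES + ["k_off2_per_s", "k_release_per_s"]
    }
    averaged["n_averaged"] = float(len(top))
    table.loc[table["status"] != "ok", "p_product"] = np.nan
    return table, averaged
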