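"""Exact stochastic simulation of the promoter cycle and synthetic luminescence cohorts.

This is the synthetic-data generator of the package: it emulates single-allele
short-lived luciferase recordings in non-dividing fibroblasts — cohorts of
roughly 48-64 cells recorded for ~48 h at a 5-min sampling interval — by
simulating the coupled promoter/mRNA/protein birth-death process exactly
(Gillespie's direct method) and reading the protein copy number out through a
calibrated emission model mapping protein copies to gray-level signal.

Static cell-to-cell heterogeneity (kinetic parameters that differ between
cells but are constant within a recording) is modeled with per-parameter
log-normal variation, the mechanism behind extrinsic mRNA noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit

from .model import PromoterCycleModel, kinetic_summaries, stationary_promoter_distribution

__all__ = [
    "CalibrationModel",
    "Trajectory",
    "TraceDataset",
    "simulate_ssa",
    "sample_trace",
    "generate_cohort",
    "promoter_intervals",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Emission model mapping protein copies to measured gray-level signal.

    The probability of measuring signal ``s`` given ``p`` protein copies is
    Gaussian with mean ``gain * p + background`` and variance
    ``var_floor + var_slope * gain * p`` — a camera-like floor plus a
    shot-noise-like term growing with the expected photon flux.  Setting both
    variance parameters to zero gives a noiseless (deterministic) readout.
    """

    gain: float = 1.0
    background: float = 0.0
    var_floor: float = 0.0
    var_slope: float = 0.0

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        if self.var_floor < 0 or self.var_slope < 0:
            raise ValueError("emission variance parameters must be nonnegative")

    def mean(self, p):
        return self.gain * np.asarray(p, dtype=float) + self.background

    def variance(self, p):
        return self.var_floor + self.var_slope * self.gain * np.asarray(p, dtype=float)

    @property
    def noiseless(self) -> bool:
        return self.var_floor == 0.0 and self.var_slope == 0.0

    def log_emission(self, s: float, p_grid) -> np.ndarray:
        """log P_e(s | p) over a grid of protein copy numbers.

        For a noiseless calibration the emission is an indicator of the
        matching copy number (log 0 elsewhere).
        """
        mu = self.mean(p_grid)
        if self.noiseless:
            out = np.full(np.shape(mu), -np.inf)
            out[np.abs(mu - s) < 1e-9] = 0.0
            return out
        var = np.maximum(self.variance(p_grid), 1e-300)
        return -0.5 * np.log(2 * np.pi * var) - 0.5 * (s - mu) ** 2 / var

    def to_dict(self) -> dict:
        return {"gain": self.gain, "background": self.background,
                "var_floor": self.var_floor, "var_slope": self.var_slope}

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass
class Trajectory:
    """Piecewise-constant sample path of (promoter state g, mRNA m, protein p).

    ``times`` are event times in (0, duration]; ``g/m/p`` hold the state
    *after* each event.  The state on [0, times[0]) is (g0, m0, p0).
    Promoter state 0 is the active state.
    """

    times: np.ndarray
    g: np.ndarray
    m: np.ndarray
    p: np.ndarray
    g0: int
    m0: int
    p0: int
    duration: float

    def state_at(self, t):
        """Return (g, m, p) arrays at the query times ``t``."""
        t = np.asarray(t, dtype=float)
        if len(self.times) == 0:
            shape = np.shape(t)
            return (np.full(shape, self.g0), np.full(shape, self.m0),
                    np.full(shape, self.p0))
        idx = np.searchsorted(self.times, t, side="right") - 1
        g = np.where(idx < 0, self.g0, self.g[np.maximum(idx, 0)])
        m = np.where(idx < 0, self.m0, self.m[np.maximum(idx, 0)])
        p = np.where(idx < 0, self.p0, self.p[np.maximum(idx, 0)])
        return g, m, p

    def time_average_mrna(self) -> float:
        t = np.concatenate(([0.0], self.times, [self.duration]))
        m = np.concatenate(([self.m0], self.m))
        return float(np.sum(m * np.diff(t)) / self.duration)

    def mrna_moments(self):
        """Time-averaged mean and variance of the mRNA copy number."""
        t = np.concatenate(([0.0], self.times, [self.duration]))
        m = np.concatenate(([self.m0], self.m)).astype(float)
        w = np.diff(t) / self.duration
        mean = np.sum(w * m)
        var = np.sum(w * (m - mean) ** 2)
        return float(mean), float(var)

    def active_fraction(self) -> float:
        t = np.concatenate(([0.0], self.times, [self.duration]))
        g = np.concatenate(([self.g0], self.g))
        return float(np.sum((g == 0) * np.diff(t)) / self.duration)


@dataclass
class TraceDataset:
    """Cohort of uniformly sampled signal time series, one per cell.

    All cells share the sampling interval ``dt`` (min).  ``ground_truth``
    optionally retains the generating parameters (per cell) and trajectories.
    """

    signals: list
    dt: float
    cell_ids: list = None
    calibration: Optional[CalibrationModel] = None
    ground_truth: Optional[dict] = None

    def __post_init__(self):
        self.signals = [np.asarray(s, dtype=float) for s in self.signals]
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{i:03d}" for i in range(len(self.signals))]
        if len(self.cell_ids) != len(self.signals):
            raise ValueError("cell_ids and signals length mismatch")
        if self.dt <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.signals)

    def times(self, i: int) -> np.ndarray:
        return np.arange(len(self.signals[i])) * self.dt

    def subset(self, indices) -> "TraceDataset":
        return TraceDataset(signals=[self.signals[i] for i in indices], dt=self.dt,
                            cell_ids=[self.cell_ids[i] for i in indices],
                            calibration=self.calibration)


# ---------------------------------------------------------------------------
# Gillespie core.  Reactions: promoter advance (cycle), transcription (only in
# the active state g == 0), mRNA decay, translation, protein decay.
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gillespie_core(promoter_rates, k_m, k_p, gamma_m, gamma_p,
                    g0, m0, p0, duration, seed,
                    times, gs, ms, ps):
    np.random.seed(seed)
    n_states = promoter_rates.shape[0]  # N + 1; rate out of state i advances cycle
    g, m, p = g0, m0, p0
    t = 0.0
    cap = times.shape[0]
    n_ev = 0
    while True:
        a_prom = promoter_rates[g]
        a_tx = k_m if g == 0 else 0.0
        a_mdeg = gamma_m * m
        a_tl = k_p * m
        a_pdeg = gamma_p * p
        a_tot = a_prom + a_tx + a_mdeg + a_tl + a_pdeg
        t += -np.log(np.random.random()) / a_tot
        if t >= duration:
            break
        if n_ev >= cap:
            return -1, g, m, p
        r = np.random.random() * a_tot
        if r < a_prom:
            g = (g + 1) % n_states
        elif r < a_prom + a_tx:
            m += 1
        elif r < a_prom + a_tx + a_mdeg:
            m -= 1
        elif r < a_prom + a_tx + a_mdeg + a_tl:
            p += 1
        else:
            p -= 1
        times[n_ev] = t
        gs[n_ev] = g
        ms[n_ev] = m
        ps[n_ev] = p
        n_ev += 1
    return n_ev, g, m, p


def _event_rate_estimate(model: PromoterCycleModel) -> float:
    ks = kinetic_summaries(model)
    mean_m = max(ks["mean_mrna"], 1.0)
    mean_p = max(ks["mean_protein"], 1.0)
    pi_on = model.tau_a / (model.tau_a + model.silent_period)
    promoter = (model.n_inactive + 1) / (model.tau_a + model.silent_period)
    return (promoter + model.k_m * pi_on + 2 * model.gamma_m * mean_m
            + model.k_p * mean_m + 2 * model.gamma_p * mean_p)


def simulate_ssa(model: PromoterCycleModel, duration: float, seed: int,
                 burn_in: Optional[float] = None) -> Trajectory:
    """Statistically exact sample path of the coupled promoter/mRNA/protein process.

    The initial promoter state is drawn from the stationary promoter law and
    mRNA/protein start at their (rounded) stationary means; a burn-in of
    ``5 * max(tau_m, 1/gamma_p)`` (overridable) is simulated and discarded so
    that the recorded window is effectively stationary.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if burn_in is None:
        burn_in = 5.0 * max(model.tau_m, 1.0 / model.gamma_p)
    rng = np.random.default_rng(seed)
    pi = stationary_promoter_distribution(model)
    g0 = int(rng.choice(len(pi), p=pi))
    ks = kinetic_summaries(model)
    m0 = int(round(ks["mean_mrna"]))
    p0 = int(round(ks["mean_protein"]))

    # rates out of each promoter state, ordered (on, off_1 .. off_N)
    promoter_rates = np.concatenate(([model.off_rate], np.asarray(model.step_rates)))
    total = burn_in + duration
    core_seed = int(rng.integers(0, 2**31 - 1))
    cap = int(total * _event_rate_estimate(model) * 2) + 10_000
    while True:
        times = np.empty(cap)
        gs = np.empty(cap, dtype=np.int64)
        ms = np.empty(cap, dtype=np.int64)
        ps = np.empty(cap, dtype=np.int64)
        n_ev, _, _, _ = _gillespie_core(promoter_rates, model.k_m, model.k_p,
                                        model.gamma_m, model.gamma_p,
                                        g0, m0, p0, total, core_seed,
                                        times, gs, ms, ps)
        if n_ev >= 0:
            break
        cap *= 2  # same seed: the longer buffer replays the identical path

    times, gs, ms, ps = times[:n_ev], gs[:n_ev], ms[:n_ev], ps[:n_ev]
    # drop the burn-in window; the state at burn_in becomes the initial state
    keep = times > burn_in
    first = int(np.searchsorted(times, burn_in, side="right"))
    if first == 0:
        init = (g0, m0, p0)
    else:
        init = (int(gs[first - 1]), int(ms[first - 1]), int(ps[first - 1]))
    return Trajectory(times=times[keep] - burn_in, g=gs[keep], m=ms[keep], p=ps[keep],
                      g0=init[0], m0=init[1], p0=init[2], duration=duration)


def promoter_intervals(traj: Trajectory):
    """Continuous-time silent and active interval durations, censored ends excluded.

    Returns ``(silent, active)`` arrays of complete interval durations in
    minutes (intervals touching either trace boundary are dropped).
    """
    t = np.concatenate(([0.0], traj.times, [traj.duration]))
    g = np.concatenate(([traj.g0], traj.g))
    active = g == 0
    # collapse runs of equal activity
    change = np.nonzero(np.diff(active.astype(np.int8)))[0] + 1
    bounds = np.concatenate(([0], change, [len(active)]))
    silent_out, active_out = [], []
    for j in range(len(bounds) - 1):
        lo, hi = bounds[j], bounds[j + 1]
        if lo == 0 or hi == len(active):  # censored at a boundary
            continue
        dur = t[hi] - t[lo]
        (active_out if active[lo] else silent_out).append(dur)
    return np.asarray(silent_out), np.asarray(active_out)


def sample_trace(traj: Trajectory, dt: float, calibration: CalibrationModel,
                 seed: int) -> np.ndarray:
    """One cell's signal series: emission draws P_e(. | p(t)) on the uniform grid."""
    if dt <= 0:
        raise ValueError("sampling interval must be positive")
    rng = np.random.default_rng(seed)
    # samples at 0, dt, ..., < duration: a 48-h trace at 5-min sampling has 576
    t_grid = np.arange(0.0, traj.duration - 1e-9, dt)
    _, _, p = traj.state_at(t_grid)
    mu = calibration.mean(p)
    if calibration.noiseless:
        return mu
    sd = np.sqrt(calibration.variance(p))
    return rng.normal(mu, sd)


_HET_PARAMS = ("k_m", "k_p", "tau_a", "T", "gamma_m", "gamma_p")


def _perturb_model(model: PromoterCycleModel, het: dict, rng) -> PromoterCycleModel:
    """Draw one cell's parameters: mean-preserving log-normal variation."""
    def factor(cv):
        if cv <= 0:
            return 1.0
        s2 = np.log1p(cv**2)
        return float(np.exp(rng.normal(-0.5 * s2, np.sqrt(s2))))

    changes = {}
    step = np.asarray(model.step_rates)
    for name, cv in het.items():
        if name not in _HET_PARAMS:
            raise ValueError(f"unknown heterogeneity parameter {name!r}; "
                             f"allowed: {_HET_PARAMS}")
        fac = factor(cv)
        if name == "tau_a":
            changes["off_rate"] = model.off_rate / fac
        elif name == "T":
            step = step / fac  # scales every silent sub-step duration
        else:
            changes[name] = getattr(model, name) * fac
    return replace(model, step_rates=tuple(step), **changes)


def generate_cohort(model: PromoterCycleModel, n_cells: int = 56,
                    duration: float = 2880.0, dt: float = 5.0,
                    calibration: Optional[CalibrationModel] = None,
                    heterogeneity: Optional[dict] = None, seed: int = 0,
                    keep_trajectories: bool = False) -> TraceDataset:
    """Synthetic cohort emulating the time-lapse experiments.

    Defaults follow the experimental design: ~48-64 non-dividing cells (56 by
    default), 48 h recordings (2880 min) at a 5-min sampling interval.
    ``heterogeneity`` maps parameter names (k_m, k_p, tau_a, T, gamma_m,
    gamma_p) to cell-to-cell log-normal CVs; parameters are static within a
    cell.  Ground truth (per-cell parameters, and trajectories on request) is
    retained for validation.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    calibration = calibration or CalibrationModel()
    heterogeneity = heterogeneity or {}
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.spawn(n_cells)
    signals, cell_models, trajs = [], [], []
    for i in range(n_cells):
        rng = np.random.default_rng(cell_seeds[i])
        cell_model = _perturb_model(model, heterogeneity, rng) if heterogeneity else model
        s_traj, s_emit = rng.integers(0, 2**31 - 1, size=2)
        traj = simulate_ssa(cell_model, duration, int(s_traj))
        signals.append(sample_trace(traj, dt, calibration, int(s_emit)))
        cell_models.append(cell_model)
        if keep_trajectories:
            trajs.append(traj)
    truth = {"base_model": model, "cell_models": cell_models,
             "heterogeneity": dict(heterogeneity), "seed": seed}
    if keep_trajectories:
        truth["trajectories"] = trajs
    return TraceDataset(signals=signals, dt=dt, calibration=calibration,
                        ground_truth=truth)
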