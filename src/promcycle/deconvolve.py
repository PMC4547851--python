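"""Deconvolution of signal traces into hidden promoter-activity and mRNA paths.

Given the optimal model and its kinetic parameters, hidden trajectories are
drawn exactly from their conditional law given the data by forward filtering
followed by backward sampling (FFBS) on the observation grid, using the same
one-interval propagator as the likelihood — the filter and the sampler
therefore cannot disagree.  Sampled paths yield per-cell activity
probabilities per time point, empirical mRNA occupancy histograms, and
empirical distributions of silent/active interval durations.

Paths live on the sampling grid: events between observations are not
resolved, so interval durations are quantized in units of the sampling
interval (active periods shorter than one interval are invisible).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import PromoterCycleModel, silent_interval_density
from .likelihood import (LatticeTruncation, Propagator, build_propagator,
                         choose_truncation, stationary_lattice_distribution,
                         _emission_weights, ZeroForwardMassError)
from .simulate import CalibrationModel, TraceDataset

__all__ = [
    "TrajectoryPosterior",
    "ffbs_sample",
    "deconvolve_dataset",
    "interval_statistics",
]


@dataclass
class TrajectoryPosterior:
    """Posterior over hidden paths for a cohort, from conditional path samples.

    ``g_paths``/``m_paths`` are per-cell integer arrays of shape
    (n_samples, n_times); ``p_on`` the per-cell marginal activity
    probabilities per time point; ``mrna_histogram`` the pooled posterior
    mRNA occupancy (normalized).
    """

    g_paths: list
    m_paths: list
    p_paths: list
    p_on: list
    mrna_histograms: list
    dt: float
    n_samples: int
    model: PromoterCycleModel
    propagator: Propagator

    @property
    def n_cells(self) -> int:
        return len(self.g_paths)

    def pooled_mrna_histogram(self) -> np.ndarray:
        h = np.sum(self.mrna_histograms, axis=0)
        return h / h.sum()

    def activity_fraction(self) -> float:
        return float(np.mean([p.mean() for p in self.p_on]))


def _forward_pass(signal, calibration, propagator, stationary):
    E = _emission_weights(np.asarray(signal, float), calibration, propagator.p_of_state)
    T = len(signal)
    alphas = np.empty((T, propagator.n))
    alpha = stationary * E[0]
    for t in range(T):
        if t > 0:
            alpha = propagator.propagate(alpha) * E[t]
        c = alpha.sum()
        if c <= 0 or not np.isfinite(c):
            raise ZeroForwardMassError(f"forward mass vanished at time index {t}")
        alpha /= c
        alphas[t] = alpha
    return alphas


def _backward_sample(alphas, P, rng, n_draws=1):
    T, n = alphas.shape
    paths = np.empty((n_draws, T), dtype=np.int64)
    for d in range(n_draws):
        x = rng.choice(n, p=alphas[-1])
        paths[d, -1] = x
        for t in range(T - 2, -1, -1):
            w = alphas[t] * P[:, x]
            s = w.sum()
            if s <= 0:
                raise ZeroForwardMassError(f"backward mass vanished at time index {t}")
            x = rng.choice(n, p=w / s)
            paths[d, t] = x
    return paths


def ffbs_sample(signal, dt: float, model: PromoterCycleModel,
                calibration: CalibrationModel,
                truncation: Optional[LatticeTruncation] = None,
                seed: int = 0,
                propagator: Optional[Propagator] = None,
                stationary: Optional[np.ndarray] = None,
                n_draws: int = 1) -> tuple:
    """Exact draws from P(path | trace) on the sampling grid.

    Returns ``(g_paths, m_paths, p_paths)`` integer arrays of shape
    (n_draws, n_times).  Requires a dense propagator (backward sampling needs
    explicit transition columns).
    """
    if truncation is None:
        truncation = choose_truncation(model)
    if propagator is None:
        propagator = build_propagator(model, dt, truncation)
    if not propagator.dense:
        raise ValueError("FFBS needs a dense propagator; reduce the lattice "
                         "or raise dense_cap")
    if stationary is None:
        stationary = stationary_lattice_distribution(propagator)
    rng = np.random.default_rng(seed)
    alphas = _forward_pass(signal, calibration, propagator, stationary)
    paths = _backward_sample(alphas, propagator.P, rng, n_draws)
    g = propagator.g_of_state[paths]
    m = propagator.m_of_state[paths]
    p = propagator.p_of_state[paths]
    return g, m, p


def deconvolve_dataset(dataset: TraceDataset, model: PromoterCycleModel,
                       calibration: Optional[CalibrationModel] = None,
                       n_samples: int = 50, seed: int = 0,
                       truncation: Optional[LatticeTruncation] = None) -> TrajectoryPosterior:
    """Per-cell posterior path summaries for a whole cohort.

    One forward pass per cell, ``n_samples`` backward draws each; all cells
    share a single propagator (the same object the likelihood would use).
    """
    if n_samples < 1:
        raise ValueError("need at least one posterior sample per cell")
    calibration = calibration or dataset.calibration
    if truncation is None:
        truncation = choose_truncation(model)
    prop = build_propagator(model, dataset.dt, truncation)
    stationary = stationary_lattice_distribution(prop)
    ss = np.random.SeedSequence(seed)
    g_paths, m_paths, p_paths, p_on, hists = [], [], [], [], []
    n_m = truncation.m_max + 1
    for i, signal in enumerate(dataset.signals):
        rng = np.random.default_rng(ss.spawn(1)[0])
        alphas = _forward_pass(signal, calibration, prop, stationary)
        paths = _backward_sample(alphas, prop.P, rng, n_samples)
        g = prop.g_of_state[paths]
        m = prop.m_of_state[paths]
        g_paths.append(g)
        m_paths.append(m)
        p_paths.append(prop.p_of_state[paths])
        p_on.append((g == 0).mean(axis=0))
        hists.append(np.bincount(m.ravel(), minlength=n_m) / m.size)
    return TrajectoryPosterior(g_paths=g_paths, m_paths=m_paths, p_paths=p_paths,
                               p_on=p_on, mrna_histograms=hists, dt=dataset.dt,
                               n_samples=n_samples, model=model, propagator=prop)


def _grid_intervals(active: np.ndarray, dt: float):
    """Complete run lengths (in minutes) of an activity path on the grid."""
    change = np.nonzero(np.diff(active.astype(np.int8)))[0] + 1
    bounds = np.concatenate(([0], change, [len(active)]))
    silent, on = [], []
    censored = 0
    for j in range(len(bounds) - 1):
        lo, hi = bounds[j], bounds[j + 1]
        if lo == 0 or hi == len(active):
            censored += 1
            continue
        dur = (hi - lo) * dt
        (on if active[lo] else silent).append(dur)
    return silent, on, censored


def interval_statistics(posterior: TrajectoryPosterior,
                        density_grid: Optional[np.ndarray] = None) -> dict:
    """Empirical silent/active interval distributions from sampled paths.

    Durations are grid-quantized (units of the sampling interval); intervals
    touching trace boundaries are censored and excluded.  The model's
    phase-type silent-interval density is returned on ``density_grid`` for
    overlay (default: 0 to 5T).
    """
    silent, active = [], []
    n_censored = 0
    for g in posterior.g_paths:
        for path in g:
            s, a, c = _grid_intervals(path == 0, posterior.dt)
            silent.extend(s)
            active.extend(a)
            n_censored += c
    silent = np.asarray(silent)
    active = np.asarray(active)
    if density_grid is None:
        density_grid = np.linspace(0.0, 5.0 * posterior.model.silent_period, 200)
    out = {
        "empty": silent.size == 0 and active.size == 0,
        "n_censored": n_censored,
        "silent_durations": silent,
        "active_durations": active,
        "model_silent_grid": density_grid,
        "model_silent_density": silent_interval_density(posterior.model, density_grid),
    }
    for name, x in (("silent", silent), ("active", active)):
        if x.size:
            out[f"{name}_mean"] = float(x.mean())
            out[f"{name}_cv"] = float(x.std() / x.mean()) if x.mean() > 0 else np.nan
        else:
            out[f"{name}_mean"] = np.nan
            out[f"{name}_cv"] = np.nan
    return out
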