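"""Exact likelihood of luminescence traces under a promoter-cycle model.

The hidden state is the triple (promoter state g, mRNA m, protein p).  On a
finite copy-number lattice the master equation of the coupled process has a
sparse generator Q, and the transition operator over one sampling interval is
exp(Q * dt).  The likelihood of a signal trace is the forward-algorithm sum
over all hidden lattice trajectories:

    P(D) = sum_Lambda P_0(x_0) P_e(s_0|x_0) prod_t P_t(x_t|x_{t-1}) P_e(s_t|x_t)

with the stationary lattice law as initial prior, the emission model P_e
mapping protein copies to gray levels, and per-step renormalization
accumulated in log space (traces of ~576 samples underflow otherwise).

The lattice is truncated so that the stationary mass beyond the bounds is
below a tolerance; transitions leaving the lattice are treated as absorbing
(sub-stochastic propagator), so truncation can only remove probability, never
invent it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.linalg import expm
from scipy.stats import nbinom, poisson

from .model import PromoterCycleModel, kinetic_summaries, stationary_promoter_distribution
from .noise import model_intrinsic_noise
from .simulate import CalibrationModel, TraceDataset

__all__ = [
    "LatticeTruncation",
    "Propagator",
    "choose_truncation",
    "build_propagator",
    "stationary_lattice_distribution",
    "trace_loglikelihood",
    "dataset_loglikelihood",
    "InfeasibleLatticeError",
    "ZeroForwardMassError",
]


class InfeasibleLatticeError(ValueError):
    """Truncation bounds exceed the configured hard cap."""


class ZeroForwardMassError(RuntimeError):
    """The forward mass vanished at some time index (signal incompatible with lattice)."""


@dataclass(frozen=True)
class LatticeTruncation:
    """Inclusive copy-number bounds of the (g, m, p) lattice.

    Chosen so that the stationary probability mass beyond the bounds is below
    the leak tolerance ``eps``.
    """

    m_max: int
    p_max: int
    eps: float = 1e-4

    def n_states(self, model: PromoterCycleModel) -> int:
        return (model.n_inactive + 1) * (self.m_max + 1) * (self.p_max + 1)


def _tail_bound(mean: float, var: float, eps: float) -> int:
    """Upper quantile of a moment-matched counting distribution at level eps."""
    if mean <= 0:
        return 0
    if var <= mean * (1 + 1e-9):
        return int(poisson.isf(eps, mean))
    # negative binomial with matched mean/variance for over-dispersed marginals
    r = mean**2 / (var - mean)
    q = mean / var
    return int(nbinom.isf(eps, r, q))


def choose_truncation(model: PromoterCycleModel, eps: float = 1e-4,
                      m_cap: int = 500, p_cap: int = 2000) -> LatticeTruncation:
    """Copy-number bounds covering at least 1 - eps of the stationary mass.

    Marginal means and variances of mRNA and protein are computed from the
    model (promoter-noise contribution included via the cycle coefficient),
    and the bounds are upper tail quantiles of moment-matched Poisson /
    negative-binomial distributions at level ``eps/2`` per dimension.
    """
    if not (0 < eps <= 0.1):
        raise ValueError("eps must lie in (0, 0.1]")
    ks = kinetic_summaries(model)
    mean_m, mean_p = ks["mean_mrna"], ks["mean_protein"]
    if model.k_m == 0:
        return LatticeTruncation(m_max=0, p_max=0, eps=eps)
    nz = model_intrinsic_noise(model)
    var_m = mean_m + mean_m**2 * nz["eta_c2"]
    m_max = _tail_bound(mean_m, var_m, eps / 2)
    if model.k_p == 0 or mean_p == 0:
        p_max = 0
    else:
        # protein bursts of size k_p/(gamma_m + gamma_p) per transcript, plus
        # the (conservatively unfiltered) promoter-noise contribution
        b_p = model.k_p / (model.gamma_m + model.gamma_p)
        var_p = mean_p * (1 + b_p) + mean_p**2 * nz["eta_c2"]
        p_max = _tail_bound(mean_p, var_p, eps / 2)
    if m_max > m_cap:
        raise InfeasibleLatticeError(
            f"mRNA bound m_max={m_max} exceeds the hard cap {m_cap}")
    if p_max > p_cap:
        raise InfeasibleLatticeError(
            f"protein bound p_max={p_max} exceeds the hard cap {p_cap}")
    return LatticeTruncation(m_max=m_max, p_max=p_max, eps=eps)


def _lattice_shapes(model: PromoterCycleModel, trunc: LatticeTruncation):
    return model.n_inactive + 1, trunc.m_max + 1, trunc.p_max + 1


def lattice_generator(model: PromoterCycleModel, trunc: LatticeTruncation) -> sparse.csr_matrix:
    """Sparse (sub-stochastic) master-equation generator on the truncated lattice.

    State index = (g * (m_max+1) + m) * (p_max+1) + p.  Transitions that would
    leave the lattice keep their rate on the diagonal but have no destination,
    so exp(Q dt) row sums fall short of 1 by exactly the truncation leak.
    """
    nG, nM, nP = _lattice_shapes(model, trunc)
    G, M, P = np.meshgrid(np.arange(nG), np.arange(nM), np.arange(nP), indexing="ij")
    G, M, P = G.ravel(), M.ravel(), P.ravel()
    idx = (G * nM + M) * nP + P
    n = nG * nM * nP
    promoter_rates = np.concatenate(([model.off_rate], np.asarray(model.step_rates)))

    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    def add(mask, dest, rate):
        rate = np.broadcast_to(rate, idx.shape)
        active = mask & (rate > 0)
        rows.append(idx[active])
        cols.append(dest[active])
        vals.append(rate[active])
        np.add.at(diag, idx, np.where(mask, rate, 0.0))

    # promoter advance g -> g+1 (mod nG); always inside the lattice
    g_next = (G + 1) % nG
    add(np.ones_like(idx, bool), (g_next * nM + M) * nP + P, promoter_rates[G])
    # transcription (active state only); leaves lattice at m == m_max
    tx_rate = np.where(G == 0, model.k_m, 0.0)
    add(M + 1 < nM, (G * nM + (M + 1)) * nP + P, tx_rate)
    np.add.at(diag, idx, np.where((G == 0) & (M + 1 >= nM), model.k_m, 0.0))
    # mRNA decay
    add(M > 0, (G * nM + (M - 1)) * nP + P, model.gamma_m * M)
    # translation; leaves lattice at p == p_max
    add(P + 1 < nP, (G * nM + M) * nP + (P + 1), model.k_p * M)
    np.add.at(diag, idx, np.where(P + 1 >= nP, model.k_p * M, 0.0))
    # protein decay
    add(P > 0, (G * nM + M) * nP + (P - 1), model.gamma_p * P)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    Q = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    Q = Q + sparse.diags(-diag)
    return Q.tocsr()


class Propagator:
    """Transition operator exp(Q dt) over the truncated lattice.

    Lattices up to ``dense_cap`` states use a dense matrix exponential (which
    forward filtering and backward sampling then share); larger lattices fall
    back to uniformization, which applies the operator through a truncated
    Poisson-weighted series of sparse products and never materializes a dense
    matrix.
    """

    def __init__(self, model: PromoterCycleModel, dt: float, trunc: LatticeTruncation,
                 dense_cap: int = 2000, uniformization_tol: float = 1e-12):
        if dt < 0:
            raise ValueError("sampling interval must be nonnegative")
        self.model = model
        self.dt = float(dt)
        self.trunc = trunc
        self.n = trunc.n_states(model)
        self.shape_gmp = _lattice_shapes(model, trunc)
        self.Q = lattice_generator(model, trunc)
        self.dense = self.n <= dense_cap
        self._tol = uniformization_tol
        if self.dense:
            self.P = np.eye(self.n) if dt == 0 else expm(self.Q.toarray() * dt)
            np.clip(self.P, 0.0, None, out=self.P)  # expm can produce tiny negatives
        else:
            self.P = None
            lam = float(np.max(-self.Q.diagonal()))
            self._lam = lam
            self._B_T = (sparse.eye(self.n) + self.Q / lam).T.tocsr() if lam > 0 else None

    # protein copy number of each lattice state, for the emission model
    @property
    def p_of_state(self) -> np.ndarray:
        nG, nM, nP = self.shape_gmp
        return np.tile(np.arange(nP), nG * nM)

    @property
    def g_of_state(self) -> np.ndarray:
        nG, nM, nP = self.shape_gmp
        return np.repeat(np.arange(nG), nM * nP)

    @property
    def m_of_state(self) -> np.ndarray:
        nG, nM, nP = self.shape_gmp
        return np.tile(np.repeat(np.arange(nM), nP), nG)

    def propagate(self, v: np.ndarray, steps: int = 1) -> np.ndarray:
        """Evolve distribution column vector(s) ``v`` by ``steps`` sampling intervals."""
        v = np.asarray(v, dtype=float)
        for _ in range(steps):
            v = self._apply_T(v)
        return v

    def _apply_T(self, v):
        if self.dense:
            return self.P.T @ v
        if self.dt == 0 or self._B_T is None:
            return v.copy()
        lam_t = self._lam * self.dt
        k_max = int(poisson.isf(self._tol, lam_t)) + 2
        log_w0 = -lam_t
        term = v.copy()
        acc = np.exp(log_w0) * term
        log_fact = 0.0
        for k in range(1, k_max + 1):
            term = self._B_T @ term
            log_fact += np.log(k)
            w = np.exp(-lam_t + k * np.log(lam_t) - log_fact)
            acc += w * term
        return acc

    def stationary_leak(self, stationary: np.ndarray) -> float:
        """Probability mass lost through the truncation boundary in one interval,
        weighted by the stationary law (boundary rows individually leak much
        more, but carry almost no mass)."""
        return float(1.0 - self.propagate(np.asarray(stationary)).sum())

    def row_sum_deficit(self) -> float:
        """Largest truncation leak over lattice states for one interval."""
        ones = np.ones(self.n)
        if self.dense:
            return float(np.max(1.0 - self.P @ ones))
        # apply the non-transposed operator to the all-ones vector
        lam_t = self._lam * self.dt
        k_max = int(poisson.isf(self._tol, lam_t)) + 2
        B = (sparse.eye(self.n) + self.Q / self._lam).tocsr()
        term = ones.copy()
        acc = np.exp(-lam_t) * term
        log_fact = 0.0
        for k in range(1, k_max + 1):
            term = B @ term
            log_fact += np.log(k)
            acc += np.exp(-lam_t + k * np.log(lam_t) - log_fact) * term
        return float(np.max(1.0 - acc))


def build_propagator(model: PromoterCycleModel, dt: float,
                     truncation: LatticeTruncation, **kwargs) -> Propagator:
    """Construct the one-interval transition operator for the given lattice."""
    return Propagator(model, dt, truncation, **kwargs)


def stationary_lattice_distribution(prop: Propagator, tol: float = 1e-11,
                                    max_iter: int = 20000) -> np.ndarray:
    """Stationary law on the lattice, by long propagation of a product guess.

    The initial guess is promoter-stationary x Poisson marginals at the
    conditional means; each propagation step renormalizes (the sub-stochastic
    operator loses the truncation leak), and iteration stops when the L1
    change per step is below ``tol``.
    """
    model = prop.model
    ks = kinetic_summaries(model)
    nG, nM, nP = prop.shape_gmp
    pi_g = stationary_promoter_distribution(model)
    pm = poisson.pmf(np.arange(nM), max(ks["mean_mrna"], 1e-12))
    pp = poisson.pmf(np.arange(nP), max(ks["mean_protein"], 1e-12))
    if pm.sum() == 0:
        pm[0] = 1.0
    if pp.sum() == 0:
        pp[0] = 1.0
    v = (pi_g[:, None, None] * pm[None, :, None] * pp[None, None, :]).ravel()
    v /= v.sum()
    for _ in range(max_iter):
        w = prop.propagate(v)
        s = w.sum()
        if s <= 0:
            raise ZeroForwardMassError("stationary propagation lost all mass")
        w /= s
        if np.abs(w - v).sum() < tol:
            return w
        v = w
    return v


def _emission_weights(signal: np.ndarray, calibration: CalibrationModel,
                      p_of_state: np.ndarray) -> np.ndarray:
    """(T, n_states) matrix of emission probabilities P_e(s_t | p(state))."""
    nP = int(p_of_state.max()) + 1
    p_grid = np.arange(nP)
    logw = np.stack([calibration.log_emission(s, p_grid) for s in signal])
    with np.errstate(under="ignore"):
        w = np.exp(logw)
    return w[:, p_of_state]


def trace_loglikelihood(signal, dt: float, model: PromoterCycleModel,
                        calibration: CalibrationModel,
                        truncation: Optional[LatticeTruncation] = None,
                        propagator: Optional[Propagator] = None,
                        stationary: Optional[np.ndarray] = None) -> float:
    """Log-likelihood of one uniformly sampled signal trace.

    The forward recursion is initialized with the stationary lattice prior at
    the first observation and renormalized at every step, accumulating the
    normalizers in log space.
    """
    signal = np.asarray(signal, dtype=float)
    if truncation is None:
        truncation = choose_truncation(model)
    if propagator is None:
        propagator = build_propagator(model, dt, truncation)
    if stationary is None:
        stationary = stationary_lattice_distribution(propagator)
    E = _emission_weights(signal, calibration, propagator.p_of_state)
    alpha = stationary * E[0]
    loglik = 0.0
    for t in range(len(signal)):
        if t > 0:
            alpha = propagator.propagate(alpha) * E[t]
        c = alpha.sum()
        if c <= 0 or not np.isfinite(c):
            raise ZeroForwardMassError(
                f"forward mass vanished at time index {t} "
                f"(signal {signal[t]:.3g} incompatible with the lattice)")
        loglik += np.log(c)
        alpha = alpha / c
    return float(loglik)


def dataset_loglikelihood(dataset: TraceDataset, model: PromoterCycleModel,
                          calibration: Optional[CalibrationModel] = None,
                          truncation: Optional[LatticeTruncation] = None,
                          propagator: Optional[Propagator] = None,
                          stationary: Optional[np.ndarray] = None) -> float:
    """Sum of per-trace log-likelihoods under shared kinetic parameters.

    Equal-length traces are filtered as one batched forward pass (one matrix
    product per sampling step for the whole cohort).
    """
    calibration = calibration or dataset.calibration
    if calibration is None:
        raise ValueError("no calibration on the dataset; pass one explicitly")
    if truncation is None:
        truncation = choose_truncation(model)
    if propagator is None:
        propagator = build_propagator(model, dataset.dt, truncation)
    if stationary is None:
        stationary = stationary_lattice_distribution(propagator)

    lengths = {len(s) for s in dataset.signals}
    if len(lengths) != 1:
        return float(sum(
            trace_loglikelihood(s, dataset.dt, model, calibration, truncation,
                                propagator, stationary)
            for s in dataset.signals))

    T = lengths.pop()
    S = np.stack(dataset.signals)  # (cells, T)
    p_of_state = propagator.p_of_state
    nP = int(p_of_state.max()) + 1
    p_grid = np.arange(nP)
    # emission probabilities for the whole cohort in one vectorized shot
    mu = calibration.mean(p_grid)  # (nP,)
    if calibration.noiseless:
        E_all = (np.abs(S[:, :, None] - mu[None, None, :]) < 1e-9).astype(float)
    else:
        var = np.maximum(calibration.variance(p_grid), 1e-300)
        logE = (-0.5 * np.log(2 * np.pi * var)[None, None, :]
                - 0.5 * (S[:, :, None] - mu[None, None, :]) ** 2 / var[None, None, :])
        with np.errstate(under="ignore"):
            E_all = np.exp(logE)  # (cells, T, nP)
    loglik = 0.0
    alpha = None
    for t in range(T):
        E_t = E_all[:, t, :][:, p_of_state].T  # (n_states, cells)
        if t == 0:
            alpha = stationary[:, None] * E_t
        else:
            alpha = propagator.propagate(alpha) * E_t
        c = alpha.sum(axis=0)
        bad = ~(np.isfinite(c) & (c > 0))
        if np.any(bad):
            cell = dataset.cell_ids[int(np.nonzero(bad)[0][0])]
            raise ZeroForwardMassError(
                f"forward mass vanished at time index {t} for cell {cell}")
        loglik += np.log(c).sum()
        alpha = alpha / c
    return float(loglik)
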