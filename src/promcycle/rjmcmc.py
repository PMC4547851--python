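"""Reversible-jump MCMC over promoter cycles: how many silent steps, and how long.

The number of inactive states N defines a nested family of models.  The
sampler mixes multiplicative within-model updates of individual rates with
trans-model moves that add or remove one inactive step while holding the
total silent period T fixed: a birth draws a short step duration u on
(0, delta*T], shrinks the existing steps proportionally and inserts u at a
uniformly chosen position; a death removes the shortest step and
redistributes its duration proportionally.  Acceptance ratios include the
Jacobian of the proportional rescaling and the proposal density of u, so the
chain satisfies detailed balance on the joint space of (N, theta_N); a birth
whose inserted step would not be the shortest is rejected outright, since
the deterministic remove-the-shortest death could not reverse it.

Priors are log-uniform on every rate (scale-free over a broad bound) and
uniform on N; more complex cycles are penalized automatically through the
trans-dimensional acceptance ratio, so model selection needs no explicit
complexity term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .model import PromoterCycleModel
from .simulate import CalibrationModel, TraceDataset

__all__ = [
    "PriorSpec",
    "RJMCMCConfig",
    "CycleState",
    "PosteriorChain",
    "within_model_move",
    "birth_move",
    "death_move",
    "run_rjmcmc",
    "summarize_posterior",
]

MOVE_WITHIN, MOVE_BIRTH, MOVE_DEATH = 0, 1, 2
MOVE_NAMES = {MOVE_WITHIN: "within", MOVE_BIRTH: "birth", MOVE_DEATH: "death"}


@dataclass(frozen=True)
class PriorSpec:
    """Log-uniform rate priors over [rate_lo, rate_hi] per minute; N uniform on 1..n_max."""

    rate_lo: float = 1.0 / 600.0
    rate_hi: float = 60.0
    n_max: int = 12

    def __post_init__(self):
        if not (0 < self.rate_lo < self.rate_hi):
            raise ValueError("prior rate bounds must be positive and ordered")
        if self.n_max < 1:
            raise ValueError("n_max must be at least 1")

    @property
    def log_range(self) -> float:
        return np.log(self.rate_hi / self.rate_lo)

    def in_bounds(self, rate) -> bool:
        rate = np.asarray(rate)
        return bool(np.all((rate >= self.rate_lo) & (rate <= self.rate_hi)))

    def log_density_rate(self, rate) -> float:
        """Log prior density of one or more rates (density in rate space)."""
        rate = np.atleast_1d(np.asarray(rate, dtype=float))
        if not self.in_bounds(rate):
            return -np.inf
        return float(np.sum(-np.log(rate) - np.log(self.log_range)))


@dataclass
class CycleState:
    """Sampled parameters: step durations tau_1..tau_N (min), tau_a (min), k_m (/min)."""

    durations: np.ndarray
    tau_a: float
    k_m: float

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)

    @property
    def n(self) -> int:
        return len(self.durations)

    @property
    def T(self) -> float:
        return float(self.durations.sum())

    def copy(self) -> "CycleState":
        return CycleState(self.durations.copy(), self.tau_a, self.k_m)

    def to_model(self, base: PromoterCycleModel) -> PromoterCycleModel:
        """Combine sampled parameters with the measured rates of ``base``."""
        return PromoterCycleModel(
            n_inactive=self.n, step_rates=tuple(1.0 / self.durations),
            off_rate=1.0 / self.tau_a, k_m=self.k_m,
            k_p=base.k_p, gamma_m=base.gamma_m, gamma_p=base.gamma_p)


def log_prior(state: CycleState, priors: PriorSpec) -> float:
    """Joint log prior density in (durations, tau_a, k_m) coordinates.

    A log-uniform prior on a rate k is log-uniform on its duration 1/k, with
    density 1/(tau ln R) over the inverted bounds — this is the measure the
    trans-model Jacobians are written against.
    """
    if not (priors.in_bounds(1.0 / state.durations)
            and priors.in_bounds(1.0 / state.tau_a)
            and priors.in_bounds(state.k_m)):
        return -np.inf
    durs = np.concatenate((state.durations, [state.tau_a]))
    lp_dur = float(np.sum(-np.log(durs) - np.log(priors.log_range)))
    lp_km = -np.log(state.k_m) - np.log(priors.log_range)
    return lp_dur + lp_km


@dataclass
class RJMCMCConfig:
    n_iter: int = 2000
    burn_in: Optional[int] = None  # default: 20% of n_iter
    seed: int = 0
    n_max: int = 12
    within_scale: float = 0.1  # log-sd of multiplicative rate updates
    p_within: float = 0.8
    p_birth: float = 0.1
    birth_delta: float = 0.2  # new-step support (0, delta * T]
    lattice_eps: float = 1e-3  # truncation leak tolerance for likelihood lattices
    m_cap: int = 60  # lattice caps; proposals beyond them are infeasible
    p_cap: int = 60

    def __post_init__(self):
        if self.burn_in is None:
            self.burn_in = int(0.2 * self.n_iter)


def within_model_move(state: CycleState, scale: float, rng) -> tuple:
    """Multiplicative log-normal update of one randomly chosen rate.

    Symmetric in log space; in the natural-parameter coordinates the prior
    density is evaluated in, the proposal asymmetry contributes the Jacobian
    log(x'/x), returned as the extra log term (it cancels the log-uniform
    prior ratio, so the effective acceptance is the likelihood ratio).
    """
    if scale < 0:
        raise ValueError("proposal scale must be nonnegative")
    prop = state.copy()
    which = rng.integers(0, state.n + 2)
    fac = float(np.exp(scale * rng.standard_normal()))
    if which < state.n:
        prop.durations = prop.durations.copy()
        prop.durations[which] *= fac
    elif which == state.n:
        prop.tau_a *= fac
    else:
        prop.k_m *= fac
    return prop, float(np.log(fac))


def birth_move(state: CycleState, rng, delta: float = 0.2,
               priors: Optional[PriorSpec] = None) -> tuple:
    """Insert a short silent step, keeping the total silent period T fixed.

    Returns ``(proposal, log_extra)`` where ``log_extra`` collects proposal
    densities and the rescaling Jacobian (everything except the likelihood
    and prior terms, which ``run_rjmcmc`` adds); ``(None, -inf)`` marks an
    auto-rejected (irreversible) proposal.
    """
    T = state.T
    u = float(rng.uniform(0.0, delta * T))
    if u <= 0 or u >= T:
        return None, -np.inf
    s = (T - u) / T
    pos = int(rng.integers(0, state.n + 1))
    new = np.insert(state.durations * s, pos, u)
    if u >= np.min(np.delete(new, pos)):  # reverse death would remove a different step
        return None, -np.inf
    prop = CycleState(new, state.tau_a, state.k_m)
    # q_fwd = 1/(delta T) * 1/(N+1).  The Jacobian of (tau_1..tau_N, u) ->
    # (tau_1 s, .., u, .., tau_N s) with s = (T-u)/T is s^(N-1): s itself
    # depends on the tau's through T (at N=1 the map (tau,u) -> (u, tau-u)
    # is volume-preserving).  The prior ratio is evaluated via log_prior.
    log_extra = (np.log(delta * T) + np.log(state.n + 1)
                 + (state.n - 1) * np.log(s))
    return prop, float(log_extra)


def death_move(state: CycleState, rng, delta: float = 0.2,
               priors: Optional[PriorSpec] = None) -> tuple:
    """Remove the shortest silent step, redistributing its duration proportionally.

    Deterministic given the state (ties broken toward the lowest index); the
    reverse birth must be able to re-insert the removed step, so a death whose
    shortest step exceeds delta*T is auto-rejected.
    """
    if state.n < 2:
        return None, -np.inf
    T = state.T
    j = int(np.argmin(state.durations))
    u = float(state.durations[j])
    if u > delta * T:
        return None, -np.inf
    s = (T - u) / T
    new = np.delete(state.durations, j) / s
    prop = CycleState(new, state.tau_a, state.k_m)
    # exact inverse of the birth bookkeeping at the matching dimensions
    log_extra = -np.log(delta * T) - np.log(state.n) - (state.n - 2) * np.log(s)
    return prop, float(log_extra)


@dataclass
class PosteriorChain:
    """Iteration-indexed RJ-MCMC samples with move bookkeeping."""

    n: np.ndarray
    k_m: np.ndarray
    tau_a: np.ndarray
    T: np.ndarray
    durations: list
    loglik: np.ndarray
    logpost: np.ndarray
    move_type: np.ndarray
    accepted: np.ndarray
    seed: int
    burn_in: int

    def __len__(self) -> int:
        return len(self.n)

    def post_burn_in(self) -> "PosteriorChain":
        s = slice(self.burn_in, None)
        return PosteriorChain(self.n[s], self.k_m[s], self.tau_a[s], self.T[s],
                              self.durations[self.burn_in:], self.loglik[s],
                              self.logpost[s], self.move_type[s], self.accepted[s],
                              self.seed, 0)


def _moment_init(dataset: TraceDataset, base: PromoterCycleModel,
                 calibration: CalibrationModel, priors: PriorSpec) -> CycleState:
    """Cheap method-of-moments start: N=1, k_m from the mean signal level."""
    mean_s = float(np.mean([s.mean() for s in dataset.signals]))
    mean_p = max((mean_s - calibration.background) / calibration.gain, 0.1)
    mean_m = max(mean_p * base.gamma_p / base.k_p, 0.05) if base.k_p > 0 else 1.0
    tau_a, T = 8.0, 60.0
    k_m = mean_m * (tau_a + T) * base.gamma_m / tau_a
    k_m = float(np.clip(k_m, priors.rate_lo * 1.01, priors.rate_hi * 0.99))
    return CycleState(np.array([T]), tau_a, k_m)


def run_rjmcmc(dataset: Optional[TraceDataset], priors: PriorSpec,
               config: RJMCMCConfig, base_model: Optional[PromoterCycleModel] = None,
               calibration: Optional[CalibrationModel] = None,
               loglik_fn: Optional[Callable[[CycleState], float]] = None,
               init_state: Optional[CycleState] = None,
               progress: bool = False) -> PosteriorChain:
    """Sample P(N, theta_N | D) by reversible-jump Metropolis-Hastings.

    ``loglik_fn`` defaults to the exact dataset log-likelihood of the trace
    cohort under shared kinetic parameters (k_p, gamma_m, gamma_p fixed at the
    measured values carried by ``base_model``); any callable mapping a
    :class:`CycleState` to a log-likelihood may be substituted, e.g. for toy
    targets with enumerable posteriors.
    """
    rng = np.random.default_rng(config.seed)
    if loglik_fn is None:
        if dataset is None or base_model is None:
            raise ValueError("need a dataset and base_model (or a custom loglik_fn)")
        calibration = calibration or dataset.calibration
        from .likelihood import (InfeasibleLatticeError, choose_truncation,
                                 dataset_loglikelihood)

        def loglik_fn(state: CycleState) -> float:
            model = state.to_model(base_model)
            try:
                trunc = choose_truncation(model, config.lattice_eps,
                                          m_cap=config.m_cap, p_cap=config.p_cap)
            except InfeasibleLatticeError:
                # the exact likelihood is not computable there; treat the region
                # as excluded (a hard numerical bound on the sampled prior)
                return -np.inf
            return dataset_loglikelihood(dataset, model, calibration, trunc)

    if init_state is None:
        init_state = _moment_init(dataset, base_model, calibration, priors)
    state = init_state.copy()
    state_lp = log_prior(state, priors)
    state_ll = loglik_fn(state)
    if not np.isfinite(state_lp) or not np.isfinite(state_ll):
        bad = "prior" if not np.isfinite(state_lp) else "likelihood"
        raise ValueError(
            f"non-finite log-{bad} at initialization: N={state.n}, "
            f"k_m={state.k_m:.4g}, tau_a={state.tau_a:.4g}, T={state.T:.4g}")

    n_it = config.n_iter
    rec = {
        "n": np.empty(n_it + 1, dtype=int), "k_m": np.empty(n_it + 1),
        "tau_a": np.empty(n_it + 1), "T": np.empty(n_it + 1),
        "loglik": np.empty(n_it + 1), "logpost": np.empty(n_it + 1),
        "move": np.full(n_it + 1, -1, dtype=int),
        "acc": np.zeros(n_it + 1, dtype=bool),
    }
    durations = []

    def record(i, move=-1, acc=False):
        rec["n"][i] = state.n
        rec["k_m"][i] = state.k_m
        rec["tau_a"][i] = state.tau_a
        rec["T"][i] = state.T
        rec["loglik"][i] = state_ll
        rec["logpost"][i] = state_ll + state_lp
        rec["move"][i] = move
        rec["acc"][i] = acc
        durations.append(state.durations.copy())

    record(0)
    p_death = 1.0 - config.p_within - config.p_birth
    for i in range(1, n_it + 1):
        r = rng.random()
        if r < config.p_within:
            move = MOVE_WITHIN
            prop, log_extra = within_model_move(state, config.within_scale, rng)
        elif r < config.p_within + config.p_birth:
            move = MOVE_BIRTH
            if state.n >= config.n_max:
                prop, log_extra = None, -np.inf
            else:
                prop, log_extra = birth_move(state, rng, config.birth_delta)
                # asymmetric attempt probabilities would enter here; the move
                # mix is state-independent so log(p_death/p_birth) is constant
                if prop is not None:
                    log_extra += np.log(p_death / config.p_birth)
        else:
            move = MOVE_DEATH
            prop, log_extra = death_move(state, rng, config.birth_delta)
            if prop is not None:
                log_extra += np.log(config.p_birth / p_death)

        accepted = False
        if prop is not None:
            prop_lp = log_prior(prop, priors)
            if np.isfinite(prop_lp):
                prop_ll = loglik_fn(prop)
                log_alpha = (prop_ll + prop_lp) - (state_ll + state_lp) + log_extra
                if np.log(rng.random()) < log_alpha:
                    state, state_ll, state_lp = prop, prop_ll, prop_lp
                    accepted = True
        record(i, move, accepted)
        if progress and i % max(1, n_it // 20) == 0:
            print(f"  iter {i}/{n_it}  N={state.n}  loglik={state_ll:.1f}", flush=True)

    return PosteriorChain(
        n=rec["n"], k_m=rec["k_m"], tau_a=rec["tau_a"], T=rec["T"],
        durations=durations, loglik=rec["loglik"], logpost=rec["logpost"],
        move_type=rec["move"], accepted=rec["acc"], seed=config.seed,
        burn_in=config.burn_in)


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence autocovariance sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    s = 1.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else rho[2 * k - 1]
        if pair < 0:
            break
        s += 2 * pair if 2 * k < n else 2 * rho[2 * k - 1]
    return float(n / max(s, 1.0))


def summarize_posterior(chain: PosteriorChain) -> dict:
    """Marginal P(N|D), parameter summaries, MAP model, acceptance and ESS.

    Percentiles use linear interpolation; the MAP model is the argmax of
    P(N|D) with posterior-mean step durations conditional on that N.
    """
    if len(chain) <= chain.burn_in:
        raise ValueError("chain shorter than its burn-in")
    post = chain.post_burn_in()
    ns, counts = np.unique(post.n, return_counts=True)
    p_n = {int(n): float(c) / len(post.n) for n, c in zip(ns, counts)}
    map_n = int(ns[np.argmax(counts)])
    sel = post.n == map_n
    map_durations = np.mean([d for d, keep in zip(post.durations, sel) if keep], axis=0)

    def summary(x):
        return {"mean": float(np.mean(x)),
                "p5": float(np.percentile(x, 5)),
                "p95": float(np.percentile(x, 95))}

    acc = {}
    for code, name in MOVE_NAMES.items():
        mask = chain.move_type == code
        acc[name] = float(chain.accepted[mask].mean()) if mask.any() else np.nan
    result = {
        "p_n": p_n,
        "map_n": map_n,
        "map_durations": map_durations,
        "params": {"k_m": summary(post.k_m), "tau_a": summary(post.tau_a),
                   "T": summary(post.T)},
        "acceptance": acc,
        "ess": {"k_m": _ess(post.k_m), "tau_a": _ess(post.tau_a), "T": _ess(post.T)},
        "degenerate": False,
    }
    if not chain.accepted[1:].any():
        result["degenerate"] = True
        warnings.warn("degenerate chain: no accepted moves after initialization")
    return result
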