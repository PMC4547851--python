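"""The irreversible promoter-cycle gene expression model.

The promoter traverses an irreversible cycle of one transcriptionally active
state (``on``) and ``N`` sequential inactive states (``off_1 .. off_N``).
The gene exits the active state at rate ``1/tau_a`` into ``off_1``, advances
through the inactive states at per-step escape rates ``k_1 .. k_N``, and the
last step ``k_N`` (the reactivation rate, often written ``k_a``) returns it
to the active state.  While active, mRNA is transcribed at rate ``k_m``;
mRNA is translated at rate ``k_p`` per transcript and both species degrade
first-order (``gamma_m``, ``gamma_p``).

The total silent period ``T = sum_i 1/k_i`` is phase-type (hypoexponential)
distributed: exponential for N=1 and Gamma(N, T/N) for equal steps, i.e. a
peaked distribution expressing a refractory period in gene reactivation.

Units: minutes and per-minute rates throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PromoterCycleModel",
    "promoter_generator",
    "stationary_promoter_distribution",
    "silent_interval_density",
    "kinetic_summaries",
]

#: index of the transcriptionally active state in all promoter-state vectors
ON_STATE = 0


class InvalidModelError(ValueError):
    """Raised when model rates violate the cycle's invariants."""


@dataclass(frozen=True)
class PromoterCycleModel:
    """Parameters of the N+1-state promoter cycle with expression kinetics.

    Parameters
    ----------
    n_inactive
        Number N of sequential inactive states (N >= 1).
    step_rates
        Escape rates ``k_1 .. k_N`` (per minute) of the inactive states.  The
        last entry is the reactivation rate ``k_a``.
    off_rate
        Rate ``1/tau_a`` of leaving the active state (per minute).
    k_m
        Transcription rate while active (mRNA per minute); may be 0.
    k_p
        Translation rate (protein per mRNA per minute); may be 0.
    gamma_m, gamma_p
        First-order degradation rates of mRNA and protein (per minute).
    """

    n_inactive: int
    step_rates: tuple = ()
    off_rate: float = 1.0 / 8.0
    k_m: float = 5.0
    k_p: float = 1.0
    gamma_m: float = 1.0 / 20.0
    gamma_p: float = 1.0 / 30.0

    def __post_init__(self):
        object.__setattr__(self, "step_rates", tuple(float(k) for k in self.step_rates))
        if self.n_inactive < 1:
            raise InvalidModelError(f"need at least one inactive state, got N={self.n_inactive}")
        if len(self.step_rates) != self.n_inactive:
            raise InvalidModelError(
                f"{self.n_inactive} inactive states require {self.n_inactive} step rates, "
                f"got {len(self.step_rates)}")
        strictly_positive = {"off_rate": self.off_rate, "gamma_m": self.gamma_m,
                             "gamma_p": self.gamma_p}
        strictly_positive.update({f"k_{i+1}": k for i, k in enumerate(self.step_rates)})
        for name, value in strictly_positive.items():
            if not np.isfinite(value) or value <= 0:
                raise InvalidModelError(f"rate {name}={value} must be strictly positive and finite")
        for name, value in (("k_m", self.k_m), ("k_p", self.k_p)):
            if not np.isfinite(value) or value < 0:
                raise InvalidModelError(f"rate {name}={value} must be nonnegative and finite")

    # -- derived timescales ------------------------------------------------
    @property
    def tau_a(self) -> float:
        """Mean active-state duration (min)."""
        return 1.0 / self.off_rate

    @property
    def silent_period(self) -> float:
        """Mean total silent period T = sum_i 1/k_i (min)."""
        return float(np.sum(1.0 / np.asarray(self.step_rates)))

    @property
    def tau_m(self) -> float:
        """mRNA lifetime 1/gamma_m (min)."""
        return 1.0 / self.gamma_m

    @property
    def burst_size(self) -> float:
        """Mean transcripts per active period, b = k_m * tau_a."""
        return self.k_m * self.tau_a

    @property
    def cycle_fraction(self) -> float:
        """Cycle duration normalized by mRNA lifetime, f = (tau_a + T)/tau_m."""
        return (self.tau_a + self.silent_period) * self.gamma_m

    # -- convenience constructors / serialization --------------------------
    @classmethod
    def equal_steps(cls, n_inactive: int, silent_period: float, **kwargs) -> "PromoterCycleModel":
        """Cycle with the silent period T split into N steps of equal mean duration."""
        rates = (n_inactive / silent_period,) * n_inactive
        return cls(n_inactive=n_inactive, step_rates=rates, **kwargs)

    def with_step_durations(self, durations) -> "PromoterCycleModel":
        """Return a copy whose inactive steps have the given mean durations (min)."""
        durations = np.asarray(durations, dtype=float)
        return replace(self, n_inactive=len(durations), step_rates=tuple(1.0 / durations))

    def to_dict(self) -> dict:
        return {
            "n_inactive": self.n_inactive,
            "step_rates": list(self.step_rates),
            "off_rate": self.off_rate,
            "k_m": self.k_m,
            "k_p": self.k_p,
            "gamma_m": self.gamma_m,
            "gamma_p": self.gamma_p,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "PromoterCycleModel":
        return cls(n_inactive=int(d["n_inactive"]), step_rates=tuple(d["step_rates"]),
                   off_rate=d["off_rate"], k_m=d["k_m"], k_p=d["k_p"],
                   gamma_m=d["gamma_m"], gamma_p=d["gamma_p"])

    @classmethod
    def from_json(cls, path) -> "PromoterCycleModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def promoter_generator(model: PromoterCycleModel) -> np.ndarray:
    """Infinitesimal generator of the promoter cycle over its N+1 states.

    State 0 is ``on``; states ``1..N`` are ``off_1..off_N``.  Off-diagonal
    entries are the cycle rates (on -> off_1 at ``1/tau_a``, off_i -> off_{i+1}
    at ``k_i``, off_N -> on at ``k_N``); rows sum to zero.
    """
    n = model.n_inactive
    Q = np.zeros((n + 1, n + 1))
    Q[ON_STATE, 1] = model.off_rate
    for i in range(1, n):
        Q[i, i + 1] = model.step_rates[i - 1]
    Q[n, ON_STATE] = model.step_rates[n - 1]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_promoter_distribution(model: PromoterCycleModel) -> np.ndarray:
    """Stationary probabilities of the promoter states.

    By renewal-reward, the occupancy of each state is its mean sojourn time
    divided by the mean cycle duration: P(on) = tau_a/(tau_a + T) and
    P(off_i) = (1/k_i)/(tau_a + T).
    """
    sojourn = np.concatenate(([model.tau_a], 1.0 / np.asarray(model.step_rates)))
    return sojourn / sojourn.sum()


def silent_interval_density(model: PromoterCycleModel, t) -> np.ndarray:
    """Phase-type density of the total silent (off) interval at times ``t`` (min).

    The off-time is the sum of N independent exponential stage durations with
    rates ``k_1..k_N``; the density is evaluated through the matrix exponential
    of the sub-generator restricted to the inactive states, which is robust for
    repeated (near-equal) rates where partial fractions degenerate.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("silent-interval times must be nonnegative")
    rates = np.asarray(model.step_rates)
    n = model.n_inactive
    # sub-generator over off_1..off_N; exit vector feeds the return to `on`
    S = np.diag(-rates)
    for i in range(n - 1):
        S[i, i + 1] = rates[i]
    exit_rates = np.zeros(n)
    exit_rates[-1] = rates[-1]
    alpha = np.zeros(n)
    alpha[0] = 1.0
    # diagonalize when the rates are well separated (fast, vectorized over t);
    # near-equal rates make S defective, so fall back to per-time expm
    gaps = np.min(np.abs(np.subtract.outer(rates, rates))
                  + np.diag(np.full(n, np.inf))) if n > 1 else np.inf
    if n == 1:
        return rates[0] * np.exp(-rates[0] * t)
    if gaps > 1e-8 * rates.max():
        lam, V = np.linalg.eig(S)
        a = alpha @ V
        b = np.linalg.solve(V, exit_rates)
        out = np.real(np.exp(np.outer(t, lam)) @ (a * b))
        return np.clip(out, 0.0, None)
    out = np.empty_like(t)
    for j, tj in enumerate(t):
        out[j] = alpha @ expm(S * tj) @ exit_rates
    return out


def kinetic_summaries(model: PromoterCycleModel) -> dict:
    """Derived kinetic quantities of the cycle.

    Returns burst size ``b = k_m tau_a``, silent period ``T``, active time
    ``tau_a``, normalized cycle duration ``f = (tau_a + T)/tau_m``, the mean
    mRNA number ``<m> = b/f`` and the mean protein number ``<m> k_p/gamma_p``.
    """
    b = model.burst_size
    f = model.cycle_fraction
    mean_m = b / f
    return {
        "burst_size": b,
        "silent_period": model.silent_period,
        "tau_a": model.tau_a,
        "cycle_fraction": f,
        "mean_mrna": mean_m,
        "mean_protein": mean_m * model.k_p / model.gamma_p,
    }
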