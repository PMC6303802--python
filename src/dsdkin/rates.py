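"""Bayesian estimation of first-step-model rate constants from trajectories.

Each stochastic trajectory record carries an outcome label, a collision
rate constant ``k_coll`` (bimolecular only, per molar per second) and the
unimolecular completion time ``tau2`` (seconds).  Success counts are
binomial, so with a uniform prior the outcome probability has posterior
mean ``(N_i+1)/(N+2)`` and standard deviation
``sqrt(p_hat (1-p_hat) / (N+3))`` -- never exactly 0 or 1, which keeps the
error estimates usable even before the first success is observed.

The bimolecular ``k1`` combines the outcome probability with the mean
collision rate of successful trajectories:

    k1_hat = sum over outcome-i records of k_coll / (N + 2)

Its posterior standard deviation treats the outcome probability (Beta
posterior) and the collision-rate scale (inverse-gamma posterior from a
``1/k^3`` prior) as independent; the exact product-posterior second moment
gives

    sigma_k1 = k1_hat * sqrt( (2 (N+2) - N_i) / (N_i (N+3)) )

``k2`` is the collision-rate-weighted inverse mean completion time, with an
effective sample size correcting for unequal weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "TrajectoryRecord",
    "RateEstimate",
    "UnimolecularPolicy",
    "estimate_probability",
    "estimate_k1_bimolecular",
    "estimate_k2_bimolecular",
    "estimate_unimolecular_rates",
    "run_adaptive_estimation",
]

#: outcome labels that are not a reaction index
NO_INITIAL_STEP = "no-initial-step"
UNPRODUCTIVE = "unproductive"
SPURIOUS = "spurious"
UNRESOLVED = "unresolved"

Outcome = Union[int, str]


@dataclass(frozen=True)
class TrajectoryRecord:
    """One stochastic trajectory: outcome, collision rate, completion time."""

    outcome: Outcome
    k_coll: Optional[float] = None  # /M/s; None for unimolecular trajectories
    tau2: Optional[float] = None  # seconds; None when no initial step occurred
    seed: Optional[int] = None
    mode: str = "ordered-complex"

    def __post_init__(self) -> None:
        if self.tau2 is not None and self.tau2 <= 0:
            raise ValueError("tau2 must be positive when an initial step occurred")

    def to_json(self) -> dict:
        return {
            "outcome": self.outcome,
            "k_coll": self.k_coll,
            "tau2": self.tau2,
            "seed": self.seed,
            "mode": self.mode,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TrajectoryRecord":
        return cls(
            outcome=obj["outcome"],
            k_coll=obj.get("k_coll"),
            tau2=obj.get("tau2"),
            seed=obj.get("seed"),
            mode=obj.get("mode", "ordered-complex"),
        )


@dataclass
class RateEstimate:
    """Point estimates and posterior standard deviations for one reaction."""

    k1_hat: float
    sigma_k1: Optional[float]
    k2_hat: Optional[float]
    sigma_k2: Optional[float]
    N: int
    N_i: int
    N_eff: Optional[float] = None
    zero_success: bool = False
    precision_met: bool = True
    k1_upper_bound: Optional[float] = None  # companion value when N_i == 0

    def relative_error(self) -> float:
        if self.k1_hat <= 0 or self.sigma_k1 is None:
            return math.inf
        return self.sigma_k1 / self.k1_hat


@dataclass(frozen=True)
class UnimolecularPolicy:
    """Scale separation for unimolecular two-step rates.

    ``k_fast = k_scale * max_i k2_i`` makes the first step negligible while
    preserving the relative values of all ``k1`` in the model.
    """

    k_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.k_scale < 10:
            raise ValueError("k_scale must be >= 10 for a usable scale separation")


def estimate_probability(N_i: int, N: int) -> tuple[float, float]:
    """Posterior mean and sd of a binomial probability under a uniform prior.

    Equals the mean and standard deviation of the Beta(N_i+1, N-N_i+1)
    posterior: ``p_hat = (N_i+1)/(N+2)``, ``sigma = sqrt(p(1-p)/(N+3))``.
    """
    if N_i < 0 or N < 0 or N_i > N:
        raise ValueError(f"need 0 <= N_i <= N, got N_i={N_i}, N={N}")
    p_hat = (N_i + 1) / (N + 2)
    sigma = math.sqrt(p_hat * (1.0 - p_hat) / (N + 3))
    return p_hat, sigma


def _success_records(records: Sequence[TrajectoryRecord], i: Outcome) -> list[TrajectoryRecord]:
    return [r for r in records if r.outcome == i]


def estimate_k1_bimolecular(
    records: Sequence[TrajectoryRecord], i: Outcome
) -> tuple[float, Optional[float]]:
    """Bimolecular ``k1`` for outcome ``i`` with its posterior sd.

    Records with no initial step count toward ``N`` only.  When no success
    was observed the point estimate is 0 and the sd is unavailable; callers
    should use the Bayesian upper-bound companion (see
    :func:`k1_zero_success_bound`).
    """
    if not records:
        raise ValueError("empty record set")
    N = len(records)
    succ = _success_records(records, i)
    N_i = len(succ)
    S = sum(r.k_coll for r in succ)  # type: ignore[misc]
    k1_hat = S / (N + 2)
    if N_i == 0:
        return 0.0, None
    rel_var = (2.0 * (N + 2) - N_i) / (N_i * (N + 3))
    return k1_hat, k1_hat * math.sqrt(rel_var)


def k1_zero_success_bound(records: Sequence[TrajectoryRecord]) -> float:
    """Bayesian upper-bound companion for ``k1`` when no success was seen.

    The posterior success probability is at most ``1/(N+2)`` in expectation;
    scaled by the mean observed collision rate this bounds how fast the
    unobserved channel could plausibly be.
    """
    kcolls = [r.k_coll for r in records if r.k_coll is not None]
    if not kcolls:
        return 0.0
    return (sum(kcolls) / len(kcolls)) / (len(records) + 2)


def estimate_k2_bimolecular(
    records: Sequence[TrajectoryRecord], i: Outcome
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Bimolecular ``k2`` for outcome ``i``: ``(k2_hat, sigma_k2, N_eff)``.

    ``k2_hat = sum k_coll / sum (k_coll * tau2)`` over outcome-``i`` records;
    with constant ``k_coll`` this reduces to ``N_i / sum(tau2)``.  The sd
    uses the effective sample size ``N_eff = (sum k)^2 / sum k^2`` and is
    unavailable when ``N_eff <= 1``.
    """
    succ = _success_records(records, i)
    if not succ:
        return None, None, None
    k = np.array([r.k_coll for r in succ], dtype=float)
    tau = np.array([r.tau2 for r in succ], dtype=float)
    k2_hat = float(k.sum() / (k * tau).sum())
    n_eff = float(k.sum() ** 2 / (k**2).sum())
    if n_eff <= 1.0:
        return k2_hat, None, n_eff
    resid = (tau - 1.0 / k2_hat) ** 2
    sigma = k2_hat**2 * math.sqrt(float((k * resid).sum() / ((n_eff - 1.0) * k.sum())))
    return k2_hat, sigma, n_eff


def estimate_unimolecular_rates(
    records: Sequence[TrajectoryRecord],
    i: Outcome,
    policy: Optional[UnimolecularPolicy] = None,
    outcomes: Optional[Sequence[Outcome]] = None,
) -> RateEstimate:
    """Unimolecular two-step rates for outcome ``i``.

    ``k2`` is the inverse mean completion time of outcome-``i`` trajectories;
    ``k1 = k_fast * P_A(i)`` with ``k_fast = k_scale * max_j k2_j`` taken
    over ``outcomes`` (default: all reaction outcomes present).  The Markov
    chain then reproduces ``P_A(i) = k1_i / sum_j k1_j`` exactly.
    """
    if not records:
        raise ValueError("empty record set")
    policy = policy or UnimolecularPolicy()
    N = len(records)
    if outcomes is None:
        outcomes = sorted(
            {r.outcome for r in records if not isinstance(r.outcome, str)},
            key=str,
        )
        outcomes += sorted({r.outcome for r in records if r.outcome == SPURIOUS})

    def k2_of(j: Outcome) -> Optional[float]:
        taus = [r.tau2 for r in _success_records(records, j) if r.tau2 is not None]
        if not taus:
            return None
        return 1.0 / (sum(taus) / len(taus))

    k2s = [k2 for j in outcomes if (k2 := k2_of(j)) is not None]
    if not k2s:
        raise ValueError("no resolved trajectories to set the fast timescale")
    k_fast = policy.k_scale * max(k2s)

    succ = _success_records(records, i)
    N_i = len(succ)
    P_hat, sigma_P = estimate_probability(N_i, N)
    k1_hat = k_fast * P_hat
    sigma_k1 = k_fast * sigma_P
    k2_hat = k2_of(i)
    sigma_k2 = None
    if k2_hat is not None and N_i >= 2:
        taus = np.array([r.tau2 for r in succ], dtype=float)
        sigma_k2 = k2_hat**2 * math.sqrt(
            float(((taus - 1.0 / k2_hat) ** 2).sum() / (N_i * (N_i - 1)))
        )
    return RateEstimate(
        k1_hat=k1_hat,
        sigma_k1=sigma_k1,
        k2_hat=k2_hat,
        sigma_k2=sigma_k2,
        N=N,
        N_i=N_i,
        N_eff=float(N_i) if N_i else None,
        zero_success=(N_i == 0),
    )


def estimate_bimolecular_rates(records: Sequence[TrajectoryRecord], i: Outcome) -> RateEstimate:
    """Convenience bundle of the bimolecular ``k1``/``k2`` estimators."""
    k1_hat, sigma_k1 = estimate_k1_bimolecular(records, i)
    k2_hat, sigma_k2, n_eff = estimate_k2_bimolecular(records, i)
    N = len(records)
    N_i = len(_success_records(records, i))
    return RateEstimate(
        k1_hat=k1_hat,
        sigma_k1=sigma_k1,
        k2_hat=k2_hat,
        sigma_k2=sigma_k2,
        N=N,
        N_i=N_i,
        N_eff=n_eff,
        zero_success=(N_i == 0),
        k1_upper_bound=k1_zero_success_bound(records) if N_i == 0 else None,
    )


def run_adaptive_estimation(
    sampler: Callable[[int, np.random.Generator], Sequence[TrajectoryRecord]],
    i: Outcome,
    precision: float = 0.10,
    batch: int = 100,
    max_trajectories: int = 100_000,
    seed: int = 0,
    policy: Optional[UnimolecularPolicy] = None,
) -> RateEstimate:
    """Simulate in batches until the relative error on ``k1`` meets ``precision``.

    ``sampler(n, rng)`` yields ``n`` fresh :class:`TrajectoryRecord` objects.
    Bimolecular records (those carrying ``k_coll``) use the FSM estimators;
    otherwise the unimolecular estimators apply.  Error estimates are usable
    at every stage, including before the first success.
    """
    rng = np.random.default_rng(seed)
    records: list[TrajectoryRecord] = []
    estimate: Optional[RateEstimate] = None
    while len(records) < max_trajectories:
        n = min(batch, max_trajectories - len(records))
        records.extend(sampler(n, rng))
        bimolecular = any(r.k_coll is not None for r in records)
        if bimolecular:
            estimate = estimate_bimolecular_rates(records, i)
        else:
            try:
                estimate = estimate_unimolecular_rates(records, i, policy=policy)
            except ValueError:
                continue
        if estimate.relative_error() <= precision:
            estimate.precision_met = True
            return estimate
    if estimate is None:
        raise ValueError("sampler produced no records")
    estimate.precision_met = False
    return estimate
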