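"""First-step CRN assembly, mass-action simulation, and depletion scores.

Each first-step reaction contributes two mass-action reactions,
``A -> (k1) -> A_i`` and ``A_i -> (k2) -> P_i``; spurious products are
routed to an absorbing sink species (they are treated as permanently
unusable).  Reactions with no observed trajectories are omitted by default
because their rate estimates are informed only by the number of attempts
and may be extreme overestimates.

Depletion scores under a user-provided maximum concentration per macrostate:

* temporary depletion (unproductive sequestration), for partners A,B with
  association constant ``K_AB = k1_0 / k2_0``::

      alpha_AB = K_AB c_B / (1 + sum_A' K_AA' c_A')
      alpha_A  = sum_A' K_AA' c_A' / (1 + sum_A' K_AA' c_A')
      alpha    = max_A alpha_A

* permanent depletion (spurious loss rate, per second)::

      beta_A = sum_A' c_A' k1s(A, A')        beta = max_A beta_A
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MassActionReaction",
    "FirstStepCRN",
    "ConcentrationContext",
    "DepletionReport",
    "SPURIOUS_SINK",
    "assemble_first_step_crn",
    "simulate_mass_action",
    "simulate_stochastic",
    "compute_temporary_depletion",
    "compute_permanent_depletion",
]

AVOGADRO = 6.02214076e23
SPURIOUS_SINK = "SPURIOUS_PRODUCTS"


@dataclass(frozen=True)
class MassActionReaction:
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: float  # /M/s for bimolecular, /s for unimolecular

    def __repr__(self) -> str:
        return (
            " + ".join(self.reactants)
            + " -> "
            + (" + ".join(self.products) if self.products else "0")
            + f" @ {self.rate:g}"
        )


@dataclass
class FirstStepCRN:
    """A mass-action CRN assembled from estimated first-step reactions."""

    species: list[str]
    reactions: list[MassActionReaction]
    skipped: list[str] = field(default_factory=list)

    def export_text(self) -> str:
        """Plain-text reaction list consumable by external CRN simulators."""
        return "\n".join(repr(r) for r in self.reactions) + "\n"


def assemble_first_step_crn(
    first_step_reactions: Sequence,
    include_unobserved: bool = False,
) -> FirstStepCRN:
    """Two mass-action reactions per estimated first-step reaction.

    ``first_step_reactions`` carry :class:`~dsdkin.rates.RateEstimate`
    objects on their ``estimate`` attribute; reactions with a missing
    estimate are skipped with a warning, and zero-success reactions are
    omitted unless ``include_unobserved`` (then the Bayesian upper bound is
    used for ``k1``).
    """
    species: list[str] = []
    reactions: list[MassActionReaction] = []
    skipped: list[str] = []

    def add_species(name: str) -> None:
        if name not in species:
            species.append(name)

    for r in first_step_reactions:
        est = getattr(r, "estimate", None)
        label = repr(r)
        if est is None:
            warnings.warn(f"no rate estimate for {label}; skipped", stacklevel=2)
            skipped.append(label)
            continue
        if est.zero_success:
            if not include_unobserved:
                skipped.append(label)
                continue
            k1 = est.k1_upper_bound or 0.0
        else:
            k1 = est.k1_hat
        k2 = est.k2_hat
        if k1 is None or k2 is None or k1 <= 0 or k2 <= 0:
            skipped.append(label)
            continue
        reactant_names = tuple(m.name for m in r.reactants)
        inter = "I_" + "_".join(reactant_names) + f"_{r.index}"
        if isinstance(r.products, str):  # spurious sentinel
            product_names: tuple[str, ...] = (SPURIOUS_SINK,)
        else:
            product_names = tuple(m.name for m in r.products)
        for s in reactant_names + (inter,) + product_names:
            add_species(s)
        reactions.append(MassActionReaction(reactant_names, (inter,), k1))
        reactions.append(MassActionReaction((inter,), product_names, k2))
    return FirstStepCRN(species=species, reactions=reactions, skipped=skipped)


def _as_crn(crn_or_reactions) -> FirstStepCRN:
    if isinstance(crn_or_reactions, FirstStepCRN):
        return crn_or_reactions
    species: list[str] = []
    for r in crn_or_reactions:
        for s in r.reactants + r.products:
            if s not in species:
                species.append(s)
    return FirstStepCRN(species=species, reactions=list(crn_or_reactions))


def simulate_mass_action(
    crn,
    initial: Mapping[str, float],
    t_final: float,
    n_points: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Deterministic mass-action ODE solution.

    Concentrations in molar, time in seconds.  A stiff failure is retried
    once with tightened tolerances before raising.
    """
    crn = _as_crn(crn)
    idx = {s: i for i, s in enumerate(crn.species)}
    for s in initial:
        if s not in idx:
            idx[s] = len(idx)
    names = [s for s, _ in sorted(idx.items(), key=lambda kv: kv[1])]
    y0 = np.zeros(len(idx))
    for s, c in initial.items():
        if c < 0:
            raise ValueError(f"negative initial concentration for {s!r}")
        y0[idx[s]] = c
    compiled = [
        (
            [idx[s] for s in r.reactants],
            [idx[s] for s in r.products],
            r.rate,
        )
        for r in crn.reactions
    ]

    def rhs(_t, y):
        dy = np.zeros_like(y)
        for reac, prod, k in compiled:
            flux = k
            for i in reac:
                flux *= y[i]
            for i in reac:
                dy[i] -= flux
            for i in prod:
                dy[i] += flux
        return dy

    t_eval = np.linspace(0.0, t_final, n_points)
    sol = solve_ivp(rhs, (0.0, t_final), y0, method=method, t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        sol = solve_ivp(
            rhs, (0.0, t_final), y0, method="BDF", t_eval=t_eval,
            rtol=rtol * 1e-2, atol=atol * 1e-2,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
    series = {name: sol.y[i] for name, i in ((n, idx[n]) for n in names)}
    return sol.t, series


def simulate_stochastic(
    crn,
    initial_counts: Mapping[str, int],
    volume: float,
    t_final: float,
    seed: Optional[Union[int, np.random.Generator]] = None,
    max_events: int = 10_000_000,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Gillespie SSA trajectory of the CRN in a volume (litres).

    Deterministic rate constants are converted to stochastic propensities
    with ``c = k / (N_A V)`` per bimolecular reaction (halved for identical
    reactants).
    """
    crn = _as_crn(crn)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(crn.species)}
    for s in initial_counts:
        if s not in idx:
            idx[s] = len(idx)
    n_sp = len(idx)
    x = np.zeros(n_sp, dtype=np.int64)
    for s, c in initial_counts.items():
        x[idx[s]] = int(c)
    compiled = []
    for r in crn.reactions:
        reac = [idx[s] for s in r.reactants]
        prod = [idx[s] for s in r.products]
        if len(reac) == 1:
            c = r.rate
        elif len(reac) == 2:
            c = r.rate / (AVOGADRO * volume)
        else:
            raise ValueError("only uni- and bimolecular reactions supported")
        compiled.append((reac, prod, c))
    times = [0.0]
    states = [x.copy()]
    t = 0.0
    for _ in range(max_events):
        props = np.empty(len(compiled))
        for ri, (reac, _, c) in enumerate(compiled):
            if len(reac) == 1:
                props[ri] = c * x[reac[0]]
            else:
                a, b = reac
                props[ri] = c * (x[a] * (x[a] - 1) / 2.0 if a == b else x[a] * x[b])
        total = props.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_final:
            break
        ri = rng.choice(len(compiled), p=props / total)
        reac, prod, _ = compiled[ri]
        for i in reac:
            x[i] -= 1
        for i in prod:
            x[i] += 1
        times.append(t)
        states.append(x.copy())
    times.append(t_final)
    states.append(x.copy())
    arr = np.array(states)
    names = sorted(idx, key=lambda s: idx[s])
    return np.array(times), {s: arr[:, idx[s]] for s in names}


@dataclass(frozen=True)
class ConcentrationContext:
    """Maximum concentration (molar) per resting macrostate."""

    c: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for name, v in self.c:
            if v < 0:
                raise ValueError(f"negative concentration for {name!r}")

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ConcentrationContext":
        return cls(tuple(sorted(d.items())))

    def get(self, name: str) -> float:
        return dict(self.c).get(name, 0.0)

    def names(self) -> list[str]:
        return [n for n, _ in self.c]


@dataclass
class DepletionReport:
    """Temporary (alpha) and permanent (beta) depletion bounds."""

    alpha_AB: dict[tuple[str, str], float] = field(default_factory=dict)
    alpha_A: dict[str, float] = field(default_factory=dict)
    alpha: float = 0.0
    beta_A: dict[str, float] = field(default_factory=dict)
    beta: float = 0.0
    K_AB: dict[tuple[str, str], float] = field(default_factory=dict)
    flagged_upper_bound: bool = False


def compute_temporary_depletion(
    K_AB: Mapping[tuple[str, str], float],
    context: Union[ConcentrationContext, Mapping[str, float]],
) -> DepletionReport:
    """Bounds on sequestration by unproductive reactions.

    ``K_AB`` maps ordered pairs (A, B) to the association constant
    ``k1_0 / k2_0`` (per molar) of their unproductive reaction; supply both
    orientations when concentrations differ (the matrix need not be
    symmetric).  All alpha quantities lie in [0, 1].
    """
    ctx = (
        context
        if isinstance(context, ConcentrationContext)
        else ConcentrationContext.from_dict(context)
    )
    for pair, k in K_AB.items():
        if k < 0:
            raise ValueError(f"negative association constant for {pair}")
    partners: dict[str, dict[str, float]] = {}
    for (a, b), k in K_AB.items():
        partners.setdefault(a, {})[b] = k
    report = DepletionReport(K_AB=dict(K_AB))
    for a, ks in partners.items():
        denom = 1.0 + sum(k * ctx.get(b) for b, k in ks.items())
        for b, k in ks.items():
            report.alpha_AB[(a, b)] = k * ctx.get(b) / denom
        report.alpha_A[a] = sum(k * ctx.get(b) for b, k in ks.items()) / denom
    report.alpha = max(report.alpha_A.values(), default=0.0)
    return report


def compute_permanent_depletion(
    k1s: Mapping[tuple[str, str], float],
    context: Union[ConcentrationContext, Mapping[str, float]],
    upper_bound: bool = False,
) -> DepletionReport:
    """Bounds on the loss rate (per second) to spurious reactions.

    ``k1s`` maps ordered pairs (A, A') to the bimolecular spurious rate
    constant between them (upper-bound estimates allowed; set
    ``upper_bound`` to flag the report).
    """
    ctx = (
        context
        if isinstance(context, ConcentrationContext)
        else ConcentrationContext.from_dict(context)
    )
    report = DepletionReport(flagged_upper_bound=upper_bound)
    per_a: dict[str, float] = {}
    for (a, b), k in k1s.items():
        per_a[a] = per_a.get(a, 0.0) + ctx.get(b) * k
    report.beta_A = per_a
    report.beta = max(per_a.values(), default=0.0)
    return report
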