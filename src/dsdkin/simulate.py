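"""Desk-scale stochastic backends for thermodynamic and kinetic sampling.

These generators replace the heavyweight sequence-level machinery a
production analysis would use (an equilibrium structure sampler and an
elementary-step kinetic simulator) with exactly solvable toy counterparts:

* a Boltzmann sampler over exhaustively enumerated sequence-structure
  ensembles (:func:`sample_boltzmann_structures`);
* a continuous-time Markov chain over *domain-level* moves producing
  first-step-style trajectory records (collision rate ``k_coll``, completion
  time ``tau2``, outcome label);
* an exact solver for the same chain (:func:`exact_first_step_solution`),
  giving ground-truth branching probabilities and mean completion times;
* a synthetic record generator with known parameters for estimator tests.

Operating at domain resolution keeps every state space enumerable while
preserving all the interfaces and statistics of the framework; sequence
structures for p-approximation work come from the Boltzmann sampler,
decoupled from kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .core import BoxState, DomainStructure, SequenceStructure
from .enumeration import RestingMacrostate, bimolecular_binds, unimolecular_moves
from .firststep import FirstStepReaction, StopStateSet, box_state_of
from .macrostates import exact_boltzmann_distribution
from .rates import (
    NO_INITIAL_STEP,
    SPURIOUS,
    UNRESOLVED,
    TrajectoryRecord,
)

__all__ = [
    "ToyEnergyModel",
    "ToyKineticModel",
    "GroundTruthSpec",
    "sample_boltzmann_structures",
    "simulate_first_step_trajectories",
    "exact_first_step_solution",
    "generate_synthetic_records",
]

R_KCAL = 0.0019872  # kcal / mol / K


@dataclass(frozen=True)
class ToyEnergyModel:
    """Additive pair-counting energy: ``E = bp_energy * n_paired_nt + loop_penalty * n_unpaired_nt``.

    ``bp_energy`` (kcal/mol, negative) is the free energy per formed base
    pair; at domain resolution a bound domain pair contributes its full
    length.  Deliberately sequence-independent: it stands in for a
    nearest-neighbour model at toy scale.
    """

    bp_energy: float = -1.0
    loop_penalty: float = 0.0
    temperature: float = 298.15
    R: float = R_KCAL

    @property
    def RT(self) -> float:
        return self.R * self.temperature

    def energy(self, structure) -> float:
        if isinstance(structure, DomainStructure):
            paired_nt = sum(
                structure.domain_at(p).length
                for p, q in structure.pairing.items()
                if p < q
            )
            total_nt = sum(s.length for s in structure.strands)
        else:
            paired_nt = sum(1 for p, q in structure.pairing.items() if p < q)
            total_nt = sum(structure.unit_counts)
        unpaired = total_nt - 2 * paired_nt
        return self.bp_energy * paired_nt + self.loop_penalty * unpaired


@dataclass(frozen=True)
class ToyKineticModel:
    """Elementary domain-level move rates for the toy kinetic Monte Carlo.

    Unbinding slows exponentially with domain length
    (``unbind_base * exp(bp_energy * L / RT)``), which reproduces
    toehold-length dependence; with ``intra_bind_rate == unbind_base`` the
    bind/unbind pair satisfies detailed balance against
    :class:`ToyEnergyModel` with the same ``bp_energy``.  Branch migration
    of an L-nt domain scales as ``migration_base / L**2`` (an unbiased
    random walk over L steps).
    """

    nucleation_rate: float = 3e6  # /M/s per feasible first domain contact
    intra_bind_rate: float = 1e5  # /s, also used for re-binds after dissociation
    unbind_base: float = 1e5  # /s
    migration_base: float = 1e6  # /s
    bp_energy: float = -1.7  # kcal/mol per nt, kinetic weighting
    RT: float = 0.593  # kcal/mol at 25 C

    def __post_init__(self) -> None:
        for name in ("nucleation_rate", "intra_bind_rate", "unbind_base", "migration_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rate_for(self, move_type: str, domain_length: int) -> float:
        if move_type == "bind":
            return self.intra_bind_rate
        if move_type == "unbind":
            return self.unbind_base * math.exp(self.bp_energy * domain_length / self.RT)
        if move_type in ("branch_3way", "branch_4way"):
            return self.migration_base / max(domain_length, 1) ** 2
        raise ValueError(f"unknown move type {move_type!r}")


# ---------------------------------------------------------------------------
# Boltzmann structure sampling


def sample_boltzmann_structures(
    strands_or_complex,
    energy_model: ToyEnergyModel,
    n: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
    condition: Optional[Callable[[SequenceStructure], bool]] = None,
    min_loop: int = 3,
    wobble: bool = True,
    max_structures: int = 100_000,
    rejection_cap: int = 100_000,
) -> list[SequenceStructure]:
    """``n`` i.i.d. samples from the exact Boltzmann distribution.

    With ``condition`` the distribution is restricted by rejection sampling
    (e.g. to p-approximations of a conformation, for conditioned initial
    states); exceeding ``rejection_cap`` raises with the acceptance rate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = exact_boltzmann_distribution(
        strands_or_complex,
        energy_model,
        min_loop=min_loop,
        wobble=wobble,
        max_structures=max_structures,
    )
    structures = list(dist.keys())
    probs = np.array(list(dist.values()))
    if n == 0:
        return []
    if condition is None:
        idx = rng.choice(len(structures), size=n, p=probs)
        return [structures[i] for i in idx]
    out: list[SequenceStructure] = []
    attempts = 0
    while len(out) < n:
        budget = min(max(4 * (n - len(out)), 64), rejection_cap - attempts)
        if budget <= 0:
            rate = len(out) / max(attempts, 1)
            raise RuntimeError(
                f"rejection cap {rejection_cap} exceeded; acceptance rate {rate:.2e}"
            )
        idx = rng.choice(len(structures), size=budget, p=probs)
        attempts += budget
        for i in idx:
            if condition(structures[i]):
                out.append(structures[i])
                if len(out) == n:
                    break
    return out


# ---------------------------------------------------------------------------
# domain-level kinetic Monte Carlo in first-step style


def _box_moves(box: tuple[DomainStructure, ...], kinetic: ToyKineticModel):
    """All moves available in a box of conformations, with rates."""
    moves = []  # (rate, new_box)
    for ci, cplx in enumerate(box):
        rest = box[:ci] + box[ci + 1 :]
        for move_type, products, dlen in unimolecular_moves(cplx):
            rate = kinetic.rate_for(move_type, dlen)
            moves.append((rate, rest + tuple(products)))
    # re-binds between separated complexes (post-dissociation, single-molecule
    # scale): treated as unimolecular events at the intra-complex bind rate
    for ci in range(len(box)):
        for cj in range(ci + 1, len(box)):
            rest = tuple(c for k, c in enumerate(box) if k not in (ci, cj))
            for joined, _, _ in bimolecular_binds(box[ci], box[cj], dedupe=False):
                moves.append((kinetic.intra_bind_rate, rest + (joined,)))
    return moves


def _strand_box(box: Sequence[DomainStructure]) -> BoxState:
    return BoxState([c.strand_complex() for c in box])


def _sample_conformation(
    macrostate: RestingMacrostate,
    rng: np.random.Generator,
    energy_model: Optional[ToyEnergyModel],
) -> DomainStructure:
    from .macrostates import sorted_conformations

    confs = sorted_conformations(macrostate)
    if len(confs) == 1:
        return confs[0]
    if energy_model is None:
        weights = np.ones(len(confs))
    else:
        e = np.array([energy_model.energy(c) for c in confs])
        weights = np.exp(-(e - e.min()) / energy_model.RT)
    weights = weights / weights.sum()
    return confs[rng.choice(len(confs), p=weights)]


def _classify_box(
    sbox: BoxState, stop_states: StopStateSet, initial: BoxState
) -> Optional[Union[int, str]]:
    if sbox in stop_states.spurious:
        return SPURIOUS
    return stop_states.compatible.get(sbox)


def simulate_first_step_trajectories(
    A: Sequence[RestingMacrostate],
    kinetic_model: ToyKineticModel,
    stop_states: StopStateSet,
    n: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
    mode: str = "ordered-complex",
    energy_model: Optional[ToyEnergyModel] = None,
    max_steps: int = 1_000_000,
) -> list[TrajectoryRecord]:
    """First-step-mode trajectories for reactant multiset ``A``.

    Bimolecular ``A``: each trajectory samples one conformation per
    macrostate, reports ``k_coll = nucleation_rate x (number of feasible
    first domain contacts)``, takes one uniformly chosen contact as the
    forced initial bind, then runs the domain-level chain until a stop
    state; ``tau2`` is the post-collision time.  Unimolecular ``A`` skips
    the collision stage.  This generator works in ordered-complex mode (the
    domain-level chain carries no sequence structures).
    """
    if mode != "ordered-complex":
        raise ValueError(
            "the domain-level trajectory generator supports ordered-complex mode only"
        )
    if len(A) not in (1, 2):
        raise ValueError("A must contain one or two resting macrostates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    initial_sbox = box_state_of(A)
    records: list[TrajectoryRecord] = []
    for _ in range(n):
        if len(A) == 2:
            c1 = _sample_conformation(A[0], rng, energy_model)
            c2 = _sample_conformation(A[1], rng, energy_model)
            contacts = bimolecular_binds(c1, c2, dedupe=False)
            k_coll = kinetic_model.nucleation_rate * len(contacts)
            if not contacts:
                records.append(
                    TrajectoryRecord(outcome=NO_INITIAL_STEP, k_coll=None, tau2=None)
                )
                continue
            joined, _, _ = contacts[rng.integers(len(contacts))]
            box: tuple[DomainStructure, ...] = (joined,)
        else:
            k_coll = None
            box = (_sample_conformation(A[0], rng, energy_model),)
        t = 0.0
        outcome: Union[int, str] = UNRESOLVED
        for _step in range(max_steps):
            label = _classify_box(_strand_box(box), stop_states, initial_sbox)
            if label is not None:
                outcome = label
                if t == 0.0:
                    # the collision completes the reaction directly (no
                    # dissociation step): the unimolecular stage is a single
                    # zippering event at the helix-closing timescale
                    t = float(rng.exponential(1.0 / kinetic_model.intra_bind_rate))
                break
            moves = _box_moves(box, kinetic_model)
            if not moves:
                break  # absorbing non-stop state; leave unresolved
            rates = np.array([m[0] for m in moves])
            total = rates.sum()
            t += rng.exponential(1.0 / total)
            box = moves[rng.choice(len(moves), p=rates / total)][1]
        records.append(
            TrajectoryRecord(
                outcome=outcome,
                k_coll=k_coll,
                tau2=t if t > 0 else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# exact CTMC solution (ground truth for the same chain)


def exact_first_step_solution(
    A: Sequence[RestingMacrostate],
    kinetic_model: ToyKineticModel,
    stop_states: StopStateSet,
    energy_model: Optional[ToyEnergyModel] = None,
    max_states: int = 20_000,
) -> dict:
    """Solve the toy first-step chain exactly.

    Returns, per outcome label, the trajectory probability ``p`` (over the
    first-step sampling distribution), the conditional mean completion time
    ``mean_tau2``, the implied ``k1 = E[S * k_coll]`` (bimolecular) and
    ``k2 = 1 / mean_tau2``.
    """
    from .macrostates import sorted_conformations

    initial_sbox = box_state_of(A)

    def key_of(box: tuple[DomainStructure, ...]):
        return tuple(sorted(c.canonical_key() for c in box))

    # initial distribution over post-collision boxes
    entries = []  # (weight, k_coll, start_box)
    if len(A) == 2:
        confs1 = sorted_conformations(A[0])
        confs2 = sorted_conformations(A[1])

        def weights(confs):
            if energy_model is None or len(confs) == 1:
                return np.ones(len(confs)) / len(confs)
            e = np.array([energy_model.energy(c) for c in confs])
            w = np.exp(-(e - e.min()) / energy_model.RT)
            return w / w.sum()

        w1, w2 = weights(confs1), weights(confs2)
        for i, c1 in enumerate(confs1):
            for j, c2 in enumerate(confs2):
                contacts = bimolecular_binds(c1, c2, dedupe=False)
                if not contacts:
                    entries.append((w1[i] * w2[j], 0.0, None))
                    continue
                k_coll = kinetic_model.nucleation_rate * len(contacts)
                for joined, _, _ in contacts:
                    entries.append((w1[i] * w2[j] / len(contacts), k_coll, (joined,)))
    else:
        confs = sorted_conformations(A[0])
        if energy_model is None or len(confs) == 1:
            w = np.ones(len(confs)) / len(confs)
        else:
            e = np.array([energy_model.energy(c) for c in confs])
            w = np.exp(-(e - e.min()) / energy_model.RT)
            w = w / w.sum()
        entries = [(wi, None, (c,)) for wi, c in zip(w, confs)]

    # build the transient state space
    index: dict = {}
    transient: list[tuple[DomainStructure, ...]] = []
    absorb_labels: list[Union[int, str]] = []
    absorb_index: dict = {}
    edges: list[tuple[int, float, Union[int, tuple]]] = []

    def label_of(box) -> Optional[Union[int, str]]:
        return _classify_box(_strand_box(box), stop_states, initial_sbox)

    frontier = []
    for _, _, box in entries:
        if box is None:
            continue
        if label_of(box) is None and key_of(box) not in index:
            index[key_of(box)] = len(transient)
            transient.append(box)
            frontier.append(box)
    while frontier:
        box = frontier.pop()
        si = index[key_of(box)]
        for rate, nxt in _box_moves(box, kinetic_model):
            lab = label_of(nxt)
            if lab is not None:
                if lab not in absorb_index:
                    absorb_index[lab] = len(absorb_labels)
                    absorb_labels.append(lab)
                edges.append((si, rate, ("absorb", absorb_index[lab])))
            else:
                k = key_of(nxt)
                if k not in index:
                    if len(transient) >= max_states:
                        raise RuntimeError("CTMC state space exceeded max_states")
                    index[k] = len(transient)
                    transient.append(nxt)
                    frontier.append(nxt)
                edges.append((si, rate, index[k]))

    nt = len(transient)
    na = len(absorb_labels)
    Q = np.zeros((nt, nt))
    B = np.zeros((nt, na))
    for si, rate, dest in edges:
        Q[si, si] -= rate
        if isinstance(dest, tuple):
            B[si, dest[1]] += rate
        else:
            Q[si, dest] += rate
    H = np.linalg.solve(-Q, B) if nt else np.zeros((0, na))  # absorption probs
    U = np.zeros((nt, na))
    for j in range(na):
        U[:, j] = np.linalg.solve(-Q, H[:, j]) if nt else 0.0  # E[T ; absorb j]

    out: dict = {}
    total_weight = sum(w for w, _, _ in entries)
    # labels reached only by immediate absorption (no transient step)
    for _, _, box in entries:
        if box is None:
            continue
        lab0 = label_of(box)
        if lab0 is not None and lab0 not in absorb_index:
            absorb_index[lab0] = len(absorb_labels)
            absorb_labels.append(lab0)
            H = np.hstack([H, np.zeros((nt, 1))])
            U = np.hstack([U, np.zeros((nt, 1))])
            na += 1
    for j, lab in enumerate(absorb_labels):
        p = 0.0
        k1 = 0.0
        et = 0.0
        for w, k_coll, box in entries:
            if box is None:
                continue
            lab0 = label_of(box)
            if lab0 is not None:
                if lab0 == lab:
                    p += w
                    # immediate stop: one zippering event's mean duration
                    et += w / kinetic_model.intra_bind_rate
                    if k_coll:
                        k1 += w * k_coll
                continue
            si = index[key_of(box)]
            p += w * H[si, j]
            et += w * U[si, j]
            if k_coll:
                k1 += w * k_coll * H[si, j]
        mean_tau2 = et / p if p > 0 else None
        out[lab] = {
            "p": p / total_weight,
            "k1": k1 / total_weight if len(A) == 2 else None,
            "mean_tau2": mean_tau2,
            "k2": (1.0 / mean_tau2) if mean_tau2 else None,
        }
    return out


# ---------------------------------------------------------------------------
# synthetic records with known ground truth


@dataclass(frozen=True)
class DistSpec:
    """Distribution specification: constant, exponential or lognormal."""

    kind: str
    value: float = 0.0  # constant value / exponential mean / lognormal median
    spread: float = 1.0  # lognormal sigma (log-space)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, self.value)
        if self.kind == "exponential":
            return rng.exponential(self.value, size=n)
        if self.kind == "lognormal":
            return self.value * rng.lognormal(0.0, self.spread, size=n)
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def mean(self) -> float:
        if self.kind in ("constant", "exponential"):
            return self.value
        return self.value * math.exp(self.spread**2 / 2.0)


@dataclass(frozen=True)
class GroundTruthSpec:
    """Known-parameter description of a first-step trajectory ensemble.

    ``outcome_probs`` maps outcome labels to probabilities (the remainder is
    assigned to no-initial-step trajectories); ``k_coll`` is shared across
    outcomes, ``tau2`` may be given per outcome.
    """

    outcome_probs: tuple[tuple[Union[int, str], float], ...]
    k_coll: Optional[DistSpec] = None
    tau2: tuple[tuple[Union[int, str], DistSpec], ...] = ()
    default_tau2: DistSpec = DistSpec("constant", 1.0)

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.outcome_probs)
        if total > 1.0 + 1e-12:
            raise ValueError("outcome probabilities exceed 1")


def generate_synthetic_records(
    spec: GroundTruthSpec,
    n: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> list[TrajectoryRecord]:
    """Draw ``n`` trajectory records exactly from the specified distributions."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [lab for lab, _ in spec.outcome_probs]
    probs = np.array([p for _, p in spec.outcome_probs])
    p_none = max(0.0, 1.0 - probs.sum())
    all_labels = labels + [NO_INITIAL_STEP]
    all_probs = np.append(probs, p_none)
    all_probs = all_probs / all_probs.sum()
    draws = rng.choice(len(all_labels), size=n, p=all_probs)
    kcolls = spec.k_coll.sample(n, rng) if spec.k_coll is not None else None
    tau_by_label = dict(spec.tau2)
    taus = np.empty(n)
    for li, lab in enumerate(all_labels):
        mask = draws == li
        m = int(mask.sum())
        if m == 0 or lab == NO_INITIAL_STEP:
            continue
        dist = tau_by_label.get(lab, spec.default_tau2)
        taus[mask] = np.maximum(dist.sample(m, rng), 1e-300)
    records = []
    for idx in range(n):
        lab = all_labels[draws[idx]]
        if lab == NO_INITIAL_STEP:
            records.append(TrajectoryRecord(outcome=NO_INITIAL_STEP))
            continue
        records.append(
            TrajectoryRecord(
                outcome=lab,
                k_coll=None if kcolls is None else float(kcolls[idx]),
                tau2=float(taus[idx]),
            )
        )
    return records
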