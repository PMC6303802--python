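"""The first-step model: two-step reactions, stop states, trajectory labels.

Every macrostate-level reaction beginning with reactant multiset ``A`` is
modelled as a pair ``A -> (k1) -> A_i -> (k2) -> P_i``.  Productive
reactions are the condensed fates of ``A``; when ``A`` has two reactants an
*unproductive* reaction (products equal to the reactants) is always
included, and a single *spurious* reaction collects every trajectory that
leaves the strand-level reaction subnetwork.

Stop states for the stochastic simulator are derived at strand level: a
reachable box state whose dissociation (any contiguous bipartition of a
complex's circular strand order) would produce a box state that is not
reachable in the subnetwork marks that product as a spurious stop state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .core import BoxState, SequenceStructure, StrandComplex, canonicalize_strand_order
from .enumeration import CondensedReaction, RestingMacrostate, StrandReaction, Subnetwork
from .macrostates import (
    ApproximationPolicy,
    complex_match_fraction,
    domain_match_fractions,
    sorted_conformations,
)
from .rates import RateEstimate, SPURIOUS, UNPRODUCTIVE, UNRESOLVED

__all__ = [
    "FirstStepReaction",
    "StopStateSet",
    "MODES",
    "build_first_step_model",
    "reachable_box_states",
    "derive_stop_states",
    "classify_trajectory",
    "box_state_of",
]

MODES = ("ordered-complex", "count-by-complex", "count-by-domain")

SPURIOUS_SENTINEL = "spurious"


@dataclass
class FirstStepReaction:
    """One reaction pair of the first-step model for reactants ``A``."""

    reactants: tuple[RestingMacrostate, ...]
    products: Union[tuple[RestingMacrostate, ...], str]  # or the spurious sentinel
    kind: str  # productive | unproductive | spurious
    index: Union[int, str]  # reaction label: int for productive, else kind
    estimate: Optional[RateEstimate] = None

    def __post_init__(self) -> None:
        if self.kind not in ("productive", "unproductive", "spurious"):
            raise ValueError(f"unknown reaction kind {self.kind!r}")

    def product_box(self) -> Optional[BoxState]:
        if isinstance(self.products, str):
            return None
        return BoxState([m.strand_complex for m in self.products])

    def __repr__(self) -> str:
        lhs = " + ".join(m.name for m in self.reactants)
        rhs = (
            self.products
            if isinstance(self.products, str)
            else " + ".join(m.name for m in self.products)
        )
        return f"<R[{self.index}] {self.kind}: {lhs} -> {rhs}>"


def box_state_of(A: Sequence[RestingMacrostate]) -> BoxState:
    return BoxState([m.strand_complex for m in A])


def build_first_step_model(
    A: Sequence[RestingMacrostate],
    condensed_reactions: Sequence[CondensedReaction],
) -> list[FirstStepReaction]:
    """All first-step reactions for reactant multiset ``A``.

    One productive reaction per condensed fate of ``A``; the unproductive
    reaction is included iff ``A`` has two or more reactants; exactly one
    spurious reaction is always included.
    """
    if len(A) not in (1, 2):
        raise ValueError("A must contain one or two resting macrostates")
    A_sorted = tuple(sorted(A, key=lambda m: m.name))
    reactions: list[FirstStepReaction] = []
    if len(A_sorted) >= 2:
        reactions.append(
            FirstStepReaction(A_sorted, A_sorted, "unproductive", UNPRODUCTIVE)
        )
    idx = 0
    seen = set()
    for r in condensed_reactions:
        if tuple(sorted(r.reactants, key=lambda m: m.name)) != A_sorted:
            continue
        if r.products == A_sorted:
            continue  # the unproductive channel, already present
        if r.products in seen:
            continue
        seen.add(r.products)
        idx += 1
        reactions.append(FirstStepReaction(A_sorted, r.products, "productive", idx))
    reactions.append(FirstStepReaction(A_sorted, SPURIOUS_SENTINEL, "spurious", SPURIOUS))
    return reactions


def reachable_box_states(
    A: Sequence[RestingMacrostate],
    strand_reactions: Sequence[StrandReaction],
    max_states: int = 100_000,
) -> set[BoxState]:
    """BFS closure of box states from ``A`` under strand-level reactions."""
    start = box_state_of(A)
    seen = {start}
    frontier = [start]
    while frontier:
        box = frontier.pop()
        for r in strand_reactions:
            if not box.contains(r.reactants):
                continue
            nxt = box.remove(r.reactants).add(r.products)
            if nxt not in seen:
                if len(seen) >= max_states:
                    raise RuntimeError("box-state search exceeded max_states")
                seen.add(nxt)
                frontier.append(nxt)
    return seen


@dataclass
class StopStateSet:
    """Compatible (product) and spurious stop states for a first-step model."""

    initial: BoxState
    compatible: dict[BoxState, Union[int, str]]  # box -> reaction index
    spurious: set[BoxState] = field(default_factory=set)
    reachable: set[BoxState] = field(default_factory=set)

    def to_json(self) -> dict:
        return {
            "initial": repr(self.initial),
            "compatible": {repr(b): i for b, i in self.compatible.items()},
            "spurious": sorted(repr(b) for b in self.spurious),
        }


def _contiguous_bipartitions(cplx: StrandComplex):
    """All splits of a circular strand order into two contiguous non-empty arcs.

    A single dissociation event in an unpseudoknotted complex separates the
    circular strand order into two contiguous arcs, so only these splits are
    candidate dissociation products.
    """
    strands = cplx.strands
    n = len(strands)
    if n < 2:
        return
    seen = set()
    for start in range(n):
        for size in range(1, n):
            arc = tuple((start + k) % n for k in range(size))
            rest = tuple((start + size + k) % n for k in range(n - size))
            a = canonicalize_strand_order(StrandComplex(tuple(strands[i] for i in arc)))
            b = canonicalize_strand_order(StrandComplex(tuple(strands[i] for i in rest)))
            key = frozenset([a._canonical_names(), b._canonical_names()])
            if key in seen:
                continue
            seen.add(key)
            yield a, b


def derive_stop_states(
    A: Sequence[RestingMacrostate],
    strand_subnetwork: Union[Subnetwork, Sequence[StrandReaction]],
    first_step_reactions: Optional[Sequence[FirstStepReaction]] = None,
) -> StopStateSet:
    """Compatible and spurious stop states for the first-step model of ``A``.

    Compatible stop states are the strand-level product multisets of the
    model's non-spurious reactions.  Spurious stop states arise from
    improper dissociation: for every reachable post-binding box state, every
    contiguous bipartition of a complex whose outcome is not itself
    reachable is a spurious stop state.  Dissociation back into reachable
    states (e.g. the original reactants) is not spurious.
    """
    strand_reactions = (
        strand_subnetwork.strand_level
        if isinstance(strand_subnetwork, Subnetwork)
        else list(strand_subnetwork)
    )
    initial = box_state_of(A)
    reachable = reachable_box_states(A, strand_reactions)
    compatible: dict[BoxState, Union[int, str]] = {}
    if first_step_reactions is not None:
        for r in first_step_reactions:
            pb = r.product_box()
            if pb is not None:
                compatible.setdefault(pb, r.index)
    else:
        compatible[initial] = UNPRODUCTIVE
    bimolecular = len(A) == 2
    spurious: set[BoxState] = set()
    for box in reachable:
        if bimolecular and box == initial:
            continue  # pre-binding state: no dissociation has yet occurred
        for cplx in box:
            if len(cplx) < 2:
                continue
            for a, b in _contiguous_bipartitions(cplx):
                nxt = box.remove([cplx]).add([a, b])
                if nxt not in reachable:
                    spurious.add(nxt)
    spurious -= set(compatible)
    return StopStateSet(
        initial=initial, compatible=compatible, spurious=spurious, reachable=reachable
    )


def _accept_products(
    box: BoxState,
    structures,
    products: tuple[RestingMacrostate, ...],
    mode: str,
    policy: ApproximationPolicy,
) -> bool:
    """Mode-dependent acceptance of a candidate product box state.

    ``structures`` maps each complex of ``box`` (by position) to its
    sequence-level structure, or is None (only valid in ordered-complex
    mode, where strand-level identity suffices).
    """
    if mode == "ordered-complex":
        return True
    if structures is None:
        raise ValueError(f"mode {mode!r} requires sequence-level product structures")
    remaining = list(products)
    for cplx, Ts in zip(box.complexes, structures):
        match = None
        for m in remaining:
            if m.strand_complex != cplx:
                continue
            ok = False
            for Td in sorted_conformations(m):
                if mode == "count-by-domain":
                    try:
                        rep = domain_match_fractions(Ts, Td, policy.match_rule)
                    except Exception:
                        continue
                    ok = all(f >= policy.p_prime for f in rep.fractions.values())
                else:  # count-by-complex
                    try:
                        frac = complex_match_fraction(Ts, Td, policy.match_rule)
                    except Exception:
                        continue
                    ok = frac >= policy.p_prime
                if ok:
                    break
            if ok:
                match = m
                break
        if match is None:
            return False
        remaining.remove(match)
    return True


def classify_trajectory(
    trajectory: Sequence,
    stop_states: StopStateSet,
    first_step_reactions: Sequence[FirstStepReaction],
    mode: str = "ordered-complex",
    policy: Optional[ApproximationPolicy] = None,
) -> Union[int, str]:
    """Label a trajectory with the first-step reaction it corresponds to.

    ``trajectory`` is a sequence of box states (optionally ``(BoxState,
    structures)`` pairs carrying per-complex sequence structures) starting
    from the model's initial state.  The first stop state hit decides the
    label; spurious stop states are always tested in ordered-complex mode.
    A trajectory ending without reaching any stop state is ``"unresolved"``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    policy = policy or ApproximationPolicy()
    by_index = {r.index: r for r in first_step_reactions}
    steps = list(trajectory)
    for step_no, step in enumerate(steps):
        if isinstance(step, tuple):
            box, structures = step
        else:
            box, structures = step, None
        if box in stop_states.spurious:
            return SPURIOUS
        if step_no == 0:
            continue  # the starting state is not a stop state
        label = stop_states.compatible.get(box)
        if label is None:
            continue
        reaction = by_index.get(label)
        products = (
            reaction.reactants if label == UNPRODUCTIVE else reaction.products
        )
        if _accept_products(box, structures, products, mode, policy):  # type: ignore[arg-type]
            return label
    return UNRESOLVED
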