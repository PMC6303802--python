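"""Domain-level reaction enumeration, timescale separation and condensation.

Starting from the complexes declared in a system, the enumerator closes the
set of complexes under four elementary domain-level move types:

* ``bind``         -- two unbound complementary domains pair, within one
                      complex or joining two complexes;
* ``unbind``       -- a bound domain pair opens, possibly splitting the
                      complex in two;
* ``branch_3way``  -- an unbound domain displaces an identical bound domain
                      held at an adjacent branch point;
* ``branch_4way``  -- two bound domain pairs at a junction exchange partners.

Reactions are classified *fast* or *slow* by a :class:`TimescalePolicy`
(default: unimolecular moves fast, except unbinding of domains longer than a
toehold threshold; bimolecular moves always slow).  Strongly connected sets
of conformations with no outgoing fast reaction form *resting macrostates*;
condensation folds the fast follow-ups of each slow reaction into reactions
between resting macrostates.
"""

from __future__ import annotations

import itertools
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .core import (
    DomainStructure,
    Pos,
    StrandComplex,
    ValidityError,
    _is_connected,
    _is_unpseudoknotted,
    canonicalize_strand_order,
)

__all__ = [
    "TimescalePolicy",
    "DetailedReaction",
    "StrandReaction",
    "RestingMacrostate",
    "CondensedReaction",
    "ReactionNetwork",
    "Subnetwork",
    "EnumerationLimitError",
    "enumerate_detailed_reactions",
    "find_resting_macrostates",
    "condense_reactions",
    "project_to_strand_level",
    "build_reaction_subnetwork",
    "load_network_from_spec",
]

MOVE_TYPES = ("bind", "unbind", "branch_3way", "branch_4way")


class EnumerationLimitError(RuntimeError):
    """An enumeration cap (complex count / size) was exceeded."""


@dataclass(frozen=True)
class TimescalePolicy:
    """Fast/slow classification of enumerated reactions.

    ``toehold_threshold`` is the longest domain (nt) whose spontaneous
    unbinding still counts as fast; it is a policy knob, not a physical
    constant.  ``overrides`` maps a move type to a forced speed for
    unimolecular reactions.
    """

    toehold_threshold: int = 7
    overrides: tuple[tuple[str, str], ...] = ()

    def speed(self, move_type: str, bimolecular: bool, domain_length: int = 0) -> str:
        if bimolecular:
            return "slow"
        for mt, sp in self.overrides:
            if mt == move_type:
                return sp
        if move_type == "unbind" and domain_length > self.toehold_threshold:
            return "slow"
        return "fast"


def _sorted_structs(structs: Sequence[DomainStructure]) -> tuple[DomainStructure, ...]:
    return tuple(sorted(structs, key=lambda s: s.canonical_key()))


@dataclass(frozen=True)
class DetailedReaction:
    """One enumerated reaction between domain-level conformations."""

    reactants: tuple[DomainStructure, ...]
    products: tuple[DomainStructure, ...]
    move_type: str
    speed: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", _sorted_structs(self.reactants))
        object.__setattr__(self, "products", _sorted_structs(self.products))
        r = sorted(s.name for x in self.reactants for s in x.strands)
        p = sorted(s.name for x in self.products for s in x.strands)
        if r != p:
            raise ValidityError("reaction does not conserve the strand multiset")
        if len(self.reactants) == 2 and self.speed != "slow":
            raise ValidityError("bimolecular reactions must be slow")

    @property
    def is_bimolecular(self) -> bool:
        return len(self.reactants) == 2

    def __repr__(self) -> str:
        fmt = lambda xs: " + ".join(  # noqa: E731
            "/".join(s.name for s in x.strands) for x in xs
        )
        return f"<{self.speed} {self.move_type}: {fmt(self.reactants)} -> {fmt(self.products)}>"


@dataclass(frozen=True)
class StrandReaction:
    """A reaction projected to strand level (secondary structure erased)."""

    reactants: tuple[StrandComplex, ...]
    products: tuple[StrandComplex, ...]

    def __post_init__(self) -> None:
        key = lambda c: c._canonical_names()  # noqa: E731
        object.__setattr__(
            self, "reactants", tuple(sorted((canonicalize_strand_order(c) for c in self.reactants), key=key))
        )
        object.__setattr__(
            self, "products", tuple(sorted((canonicalize_strand_order(c) for c in self.products), key=key))
        )

    def __repr__(self) -> str:
        fmt = lambda xs: " + ".join("+".join(c.strand_names) for c in xs)  # noqa: E731
        return f"<strand rxn: {fmt(self.reactants)} -> {fmt(self.products)}>"


@dataclass(frozen=True)
class RestingMacrostate:
    """Conformations strongly connected by fast reactions, with no fast exit."""

    name: str
    conformations: frozenset[DomainStructure]

    def __post_init__(self) -> None:
        object.__setattr__(self, "conformations", frozenset(self.conformations))
        cplxs = {c.strand_complex() for c in self.conformations}
        if len(cplxs) != 1:
            raise ValidityError(
                f"macrostate {self.name!r}: conformations span multiple strand-level complexes"
            )

    @property
    def strand_complex(self) -> StrandComplex:
        return next(iter(self.conformations)).strand_complex()

    def __repr__(self) -> str:
        return f"<RestingMacrostate {self.name} ({len(self.conformations)} conf)>"


@dataclass(frozen=True)
class CondensedReaction:
    """A reaction between resting macrostates (one fate of a slow reaction)."""

    reactants: tuple[RestingMacrostate, ...]
    products: tuple[RestingMacrostate, ...]

    def __post_init__(self) -> None:
        key = lambda m: m.name  # noqa: E731
        object.__setattr__(self, "reactants", tuple(sorted(self.reactants, key=key)))
        object.__setattr__(self, "products", tuple(sorted(self.products, key=key)))

    @property
    def is_unproductive(self) -> bool:
        return self.reactants == self.products

    def __repr__(self) -> str:
        fmt = lambda xs: " + ".join(m.name for m in xs)  # noqa: E731
        return f"<condensed: {fmt(self.reactants)} -> {fmt(self.products)}>"


@dataclass
class ReactionNetwork:
    """Detailed + condensed view of an enumerated reaction network."""

    initial_complexes: list[DomainStructure]
    complexes: list[DomainStructure]
    reactions: list[DetailedReaction]
    policy: TimescalePolicy
    complete: bool = True
    resting_macrostates: Optional[list[RestingMacrostate]] = None
    transient_complexes: Optional[set[DomainStructure]] = None
    condensed_reactions: Optional[list[CondensedReaction]] = None
    names: dict = field(default_factory=dict)  # DomainStructure -> preferred name

    def macrostate_of(self, conformation: DomainStructure) -> RestingMacrostate:
        if self.resting_macrostates is None:
            raise RuntimeError("resting macrostates not computed yet")
        for m in self.resting_macrostates:
            if conformation in m.conformations:
                return m
        raise KeyError(f"{conformation!r} is not a resting conformation")

    def to_json(self) -> dict:
        from .core import write_structure

        def cname(c: DomainStructure) -> str:
            return self.names.get(c, "+".join(s.name for s in c.strands))

        out = {
            "complexes": [
                {
                    "name": cname(c),
                    "strands": [s.name for s in c.strands],
                    "structure": write_structure(c),
                }
                for c in self.complexes
            ],
            "reactions": [
                {
                    "move_type": r.move_type,
                    "speed": r.speed,
                    "reactants": [cname(x) for x in r.reactants],
                    "products": [cname(x) for x in r.products],
                }
                for r in self.reactions
            ],
            "complete": self.complete,
        }
        if self.resting_macrostates is not None:
            out["resting_macrostates"] = [
                {"name": m.name, "conformations": [cname(c) for c in m.conformations]}
                for m in self.resting_macrostates
            ]
        if self.condensed_reactions is not None:
            out["condensed_reactions"] = [
                {
                    "reactants": [m.name for m in r.reactants],
                    "products": [m.name for m in r.products],
                }
                for r in self.condensed_reactions
            ]
        return out


# ---------------------------------------------------------------------------
# move generation


def _try_structure(strands, pairing, allow_permutation=False) -> Optional[DomainStructure]:
    """Build a structure, trying strand rotations until one is unpseudoknotted.

    With ``allow_permutation`` (needed after four-way partner exchange, which
    can change the planar strand interleaving) arbitrary strand orders are
    tried as a fallback.
    """
    counts = [len(s.domains) for s in strands]
    if not _is_connected(pairing, len(strands)):
        return None
    n = len(strands)
    orders = [tuple((r + k) % n for k in range(n)) for r in range(n)]
    if allow_permutation:
        orders += [p for p in itertools.permutations(range(n)) if p not in orders]
    for order in orders:
        rot_strands = tuple(strands[i] for i in order)
        index = {old: new for new, old in enumerate(order)}
        remap = {(si, ui): (index[si], ui) for (si, ui) in pairing}
        rot_pairing = {remap[p]: remap[q] for p, q in pairing.items()}
        rot_counts = [counts[i] for i in order]
        if _is_unpseudoknotted(rot_pairing, rot_counts):
            return DomainStructure(rot_strands, rot_pairing)
    return None


def _arc_order(indices: set[int], n: int) -> list[int]:
    starts = [i for i in indices if (i - 1) % n not in indices]
    if len(starts) != 1:
        raise ValidityError("component strands do not form a contiguous circular arc")
    start = starts[0]
    out = []
    i = start
    while len(out) < len(indices):
        if i in indices:
            out.append(i)
        i = (i + 1) % n
    return out


def _split_components(structure: DomainStructure, pairing: dict) -> Optional[list[DomainStructure]]:
    """Split a disconnected pairing into its connected sub-complexes."""
    n = len(structure.strands)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for (si, _), (sj, _) in pairing.items():
        adj[si].add(sj)
        adj[sj].add(si)
    unseen = set(range(n))
    comps: list[set[int]] = []
    while unseen:
        root = min(unseen)
        comp = {root}
        stack = [root]
        while stack:
            for j in adj[stack.pop()]:
                if j not in comp:
                    comp.add(j)
                    stack.append(j)
        comps.append(comp)
        unseen -= comp
    parts = []
    for comp in comps:
        order = _arc_order(comp, n)
        index = {old: new for new, old in enumerate(order)}
        strands = tuple(structure.strands[i] for i in order)
        sub_pairing = {
            (index[p[0]], p[1]): (index[q[0]], q[1])
            for p, q in pairing.items()
            if p[0] in comp
        }
        part = _try_structure(strands, sub_pairing)
        if part is None:
            return None
        parts.append(part)
    return parts


def _apply_pairing(
    structure: DomainStructure, pairing: dict, allow_permutation: bool = False
) -> Optional[tuple[DomainStructure, ...]]:
    """Turn a modified pairing into one complex or a split pair of complexes."""
    counts = structure.unit_counts
    if _is_connected(pairing, len(structure.strands)):
        if _is_unpseudoknotted(pairing, counts):
            return (DomainStructure(structure.strands, pairing),)
        one = _try_structure(structure.strands, pairing, allow_permutation)
        return (one,) if one is not None else None
    try:
        parts = _split_components(structure, pairing)
    except ValidityError:
        return None
    return tuple(parts) if parts else None


def _positions(structure: DomainStructure) -> list[Pos]:
    return [
        (si, di)
        for si, s in enumerate(structure.strands)
        for di in range(len(s.domains))
    ]


def unimolecular_moves(structure: DomainStructure) -> list[tuple[str, tuple[DomainStructure, ...], int]]:
    """All single-complex moves: ``(move_type, products, domain_length)``."""
    moves: list[tuple[str, tuple[DomainStructure, ...], int]] = []
    positions = _positions(structure)
    unbound = [p for p in positions if not structure.is_paired(p)]

    # intra-complex bind
    for p, q in itertools.combinations(unbound, 2):
        if not structure.domain_at(p).is_complementary_to(structure.domain_at(q)):
            continue
        pairing = dict(structure.pairing)
        pairing[p] = q
        pairing[q] = p
        if _is_unpseudoknotted(pairing, structure.unit_counts):
            moves.append(
                (
                    "bind",
                    (DomainStructure(structure.strands, pairing),),
                    structure.domain_at(p).length,
                )
            )

    # unbind
    seen_pairs = set()
    for p, q in structure.pairing.items():
        if (q, p) in seen_pairs:
            continue
        seen_pairs.add((p, q))
        pairing = dict(structure.pairing)
        del pairing[p]
        del pairing[q]
        products = _apply_pairing(structure, pairing)
        if products:
            moves.append(("unbind", products, structure.domain_at(p).length))

    # three-way branch migration: unbound invader p held next to the branch
    # point displaces an identical incumbent j from template k.
    for p in unbound:
        for dn in (-1, 1):
            n_pos = (p[0], p[1] + dn)
            if n_pos[1] < 0 or n_pos[1] >= len(structure.strands[p[0]].domains):
                continue
            m = structure.partner(n_pos)
            if m is None:
                continue
            k = (m[0], m[1] + dn)  # helix continuation is antiparallel
            if k[1] < 0 or k[1] >= len(structure.strands[k[0]].domains):
                continue
            j = structure.partner(k)
            if j is None or j == p:
                continue
            if structure.domain_at(j).name != structure.domain_at(p).name:
                continue
            pairing = dict(structure.pairing)
            del pairing[k]
            del pairing[j]
            pairing[p] = k
            pairing[k] = p
            products = _apply_pairing(structure, pairing)
            if products:
                moves.append(("branch_3way", products, structure.domain_at(p).length))

    # four-way branch migration: adjacent paired domains with identical
    # partners exchange partners at the junction.
    for a in positions:
        c = (a[0], a[1] + 1)
        if c[1] >= len(structure.strands[a[0]].domains):
            continue
        b = structure.partner(a)
        d = structure.partner(c)
        if b is None or d is None:
            continue
        if b in (c,) or d in (a,):
            continue
        if structure.domain_at(b).name != structure.domain_at(d).name or b == d:
            continue
        pairing = dict(structure.pairing)
        pairing[a] = d
        pairing[d] = a
        pairing[c] = b
        pairing[b] = c
        products = _apply_pairing(structure, pairing, allow_permutation=True)
        if products:
            moves.append(("branch_4way", products, structure.domain_at(a).length))

    return moves


def bimolecular_binds(
    x: DomainStructure, y: DomainStructure, dedupe: bool = True
) -> list[tuple[DomainStructure, Pos, Pos]]:
    """All joined complexes from pairing an unbound domain of ``x`` with one of ``y``.

    Returns ``(joined, p, q)`` with ``p`` in ``x`` and ``q`` in ``y``.  With
    ``dedupe`` (the default) structurally identical joins are merged; without
    it one entry per feasible domain contact is returned, which is what the
    collision-rate bookkeeping of first-step sampling needs.
    """
    out = []
    seen = set()
    ny = len(y.strands)
    x_unbound = [p for p in _positions(x) if not x.is_paired(p)]
    y_unbound = [q for q in _positions(y) if not y.is_paired(q)]
    for p in x_unbound:
        for q in y_unbound:
            if not x.domain_at(p).is_complementary_to(y.domain_at(q)):
                continue
            joined = None
            for r in range(ny):  # rotation of y inserted after p's strand
                strands = (
                    x.strands[: p[0] + 1]
                    + y.strands[r:]
                    + y.strands[:r]
                    + x.strands[p[0] + 1 :]
                )
                xmap = lambda s: s if s <= p[0] else s + ny  # noqa: E731
                ymap = lambda s: p[0] + 1 + (s - r) % ny  # noqa: E731
                pairing: dict[Pos, Pos] = {}
                for a, b in x.pairing.items():
                    pairing[(xmap(a[0]), a[1])] = (xmap(b[0]), b[1])
                for a, b in y.pairing.items():
                    pairing[(ymap(a[0]), a[1])] = (ymap(b[0]), b[1])
                pp = (p[0], p[1])
                qq = (ymap(q[0]), q[1])
                pairing[pp] = qq
                pairing[qq] = pp
                counts = [len(s.domains) for s in strands]
                if _is_unpseudoknotted(pairing, counts):
                    joined = DomainStructure(strands, pairing)
                    break
            if joined is None:
                continue
            if dedupe:
                key = joined.canonical_key()
                if key in seen:
                    continue
                seen.add(key)
            out.append((joined, p, q))
    return out


# ---------------------------------------------------------------------------
# network enumeration


def enumerate_detailed_reactions(
    spec,
    policy: Optional[TimescalePolicy] = None,
    max_strands: int = 6,
    max_complexes: int = 1000,
    on_limit: str = "raise",
) -> ReactionNetwork:
    """Close the spec's complexes under the four move types.

    ``max_strands`` bounds complex size (binds beyond it are not taken and
    the network is flagged incomplete); exceeding ``max_complexes`` raises
    :class:`EnumerationLimitError` unless ``on_limit='flag'``.
    """
    policy = policy or TimescalePolicy()
    initial = list(spec.complexes.values()) if hasattr(spec, "complexes") else list(spec)
    names = (
        {c: n for n, c in spec.complexes.items()} if hasattr(spec, "complexes") else {}
    )
    seen: dict = {}
    queue: deque[DomainStructure] = deque()
    complete = True

    def admit(c: DomainStructure) -> DomainStructure:
        nonlocal complete
        key = c.canonical_key()
        if key in seen:
            return seen[key]
        if len(seen) >= max_complexes:
            if on_limit == "raise":
                raise EnumerationLimitError(
                    f"complex count exceeded max_complexes={max_complexes}"
                )
            complete = False
            return c
        seen[key] = c
        queue.append(c)
        return c

    for c in initial:
        admit(c)

    reactions: set[DetailedReaction] = set()
    processed: list[DomainStructure] = []

    def record(reactants, products, move_type, domain_length=0) -> None:
        products = tuple(admit(p) for p in products)
        speed = policy.speed(move_type, len(reactants) == 2, domain_length)
        reactions.add(DetailedReaction(tuple(reactants), products, move_type, speed))

    while queue:
        c = queue.popleft()
        for move_type, products, dlen in unimolecular_moves(c):
            record((c,), products, move_type, dlen)
        for d in processed + [c]:
            if len(c.strands) + len(d.strands) > max_strands:
                complete = False
                continue
            for joined, _, _ in bimolecular_binds(c, d):
                record((c, d), (joined,), "bind")
        processed.append(c)

    return ReactionNetwork(
        initial_complexes=initial,
        complexes=list(seen.values()),
        reactions=sorted(reactions, key=repr),
        policy=policy,
        complete=complete,
        names=dict(names),
    )


# ---------------------------------------------------------------------------
# resting macrostates and condensation


def _fast_digraph(network: ReactionNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(network.complexes)
    for r in network.reactions:
        if r.speed != "fast":
            continue
        for prod in r.products:
            g.add_edge(r.reactants[0], prod)
    return g


def find_resting_macrostates(
    network: ReactionNetwork,
) -> tuple[list[RestingMacrostate], set[DomainStructure]]:
    """SCCs of the fast digraph with no outgoing fast edge; rest are transient."""
    g = _fast_digraph(network)
    cond = nx.condensation(g)
    macrostates: list[RestingMacrostate] = []
    transient: set[DomainStructure] = set()
    by_cplx: dict[StrandComplex, list[str]] = {}
    counter = itertools.count(1)
    for scc_id in cond.nodes:
        members = cond.nodes[scc_id]["members"]
        if cond.out_degree(scc_id) == 0:
            named = [network.names[m] for m in members if m in network.names]
            name = sorted(named)[0] if named else None
            if name is None:
                base = "+".join(
                    next(iter(members)).strand_complex()._canonical_names()
                )
                name = f"RM{next(counter)}_{base}"
            ms = RestingMacrostate(name, frozenset(members))
            macrostates.append(ms)
            by_cplx.setdefault(ms.strand_complex, []).append(ms.name)
        else:
            transient.update(members)
    for cplx, ms_names in by_cplx.items():
        if len(ms_names) > 1:
            warnings.warn(
                f"distinct resting macrostates {ms_names} share strand-level "
                f"complex {cplx!r}; this framework assumes at most one",
                stacklevel=2,
            )
    macrostates.sort(key=lambda m: m.name)
    network.resting_macrostates = macrostates
    network.transient_complexes = transient
    return macrostates, transient


def _complex_fates(network: ReactionNetwork) -> dict[DomainStructure, frozenset]:
    """For each complex, the reachable multisets of resting macrostates."""
    if network.resting_macrostates is None:
        find_resting_macrostates(network)
    macro_of: dict[DomainStructure, RestingMacrostate] = {}
    for m in network.resting_macrostates:  # type: ignore[union-attr]
        for c in m.conformations:
            macro_of[c] = m
    fates: dict[DomainStructure, set[tuple]] = {c: set() for c in network.complexes}
    for c, m in macro_of.items():
        fates[c] = {(m,)}
    fast_by_reactant: dict[DomainStructure, list[DetailedReaction]] = {}
    for r in network.reactions:
        if r.speed == "fast":
            fast_by_reactant.setdefault(r.reactants[0], []).append(r)
    changed = True
    while changed:
        changed = False
        for c in network.complexes:
            if c in macro_of:
                continue
            new: set[tuple] = set(fates[c])
            for r in fast_by_reactant.get(c, []):
                prod_fates = [fates.get(p, set()) for p in r.products]
                if any(not f for f in prod_fates):
                    continue
                for combo in itertools.product(*prod_fates):
                    merged = tuple(
                        sorted((m for fate in combo for m in fate), key=lambda m: m.name)
                    )
                    new.add(merged)
            if new != fates[c]:
                fates[c] = new
                changed = True
    return {c: frozenset(f) for c, f in fates.items()}


def condense_reactions(network: ReactionNetwork) -> list[CondensedReaction]:
    """Fold fast follow-ups of each slow reaction into macrostate reactions.

    One condensed reaction is produced per (reactant macrostates, fate);
    the self-loop fate (products == reactants) is retained as the marker of
    the unproductive channel.
    """
    fates = _complex_fates(network)
    macro_of: dict[DomainStructure, RestingMacrostate] = {}
    for m in network.resting_macrostates:  # type: ignore[union-attr]
        for c in m.conformations:
            macro_of[c] = m
    condensed: set[CondensedReaction] = set()
    for r in network.reactions:
        if r.speed != "slow":
            continue
        if any(x not in macro_of for x in r.reactants):
            continue  # slow reaction from a transient conformation
        reactant_ms = tuple(sorted((macro_of[x] for x in r.reactants), key=lambda m: m.name))
        prod_fates = [fates[p] for p in r.products]
        if any(not f for f in prod_fates):
            raise EnumerationLimitError(
                "fate search reached the boundary of an incomplete network"
            )
        for combo in itertools.product(*prod_fates):
            merged = tuple(
                sorted((m for fate in combo for m in fate), key=lambda m: m.name)
            )
            condensed.add(CondensedReaction(reactant_ms, merged))
    out = sorted(condensed, key=repr)
    network.condensed_reactions = out
    return out


def project_to_strand_level(reactions: Sequence[DetailedReaction]) -> list[StrandReaction]:
    """Erase secondary structure; drop identity reactions; merge duplicates."""
    out: set[StrandReaction] = set()
    for r in reactions:
        sr = StrandReaction(
            tuple(x.strand_complex() for x in r.reactants),
            tuple(x.strand_complex() for x in r.products),
        )
        if sr.reactants == sr.products:
            continue
        out.add(sr)
    return sorted(out, key=repr)


@dataclass
class Subnetwork:
    """Reaction subnetwork for a multiset of resting macrostates."""

    macrostates: tuple[RestingMacrostate, ...]
    initiating: list[DetailedReaction]
    detailed: list[DetailedReaction]
    strand_level: list[StrandReaction]


def build_reaction_subnetwork(
    A: Sequence[RestingMacrostate], network: ReactionNetwork
) -> Subnetwork:
    """Slow reactions possible with the members of ``A`` plus their fast closure."""
    if len(A) not in (1, 2):
        raise ValueError("A must contain one or two resting macrostates")
    if network.resting_macrostates is None:
        find_resting_macrostates(network)
    for m in A:
        if m not in network.resting_macrostates:  # type: ignore[operator]
            raise KeyError(f"unknown macrostate {m.name!r}")
    conf_pool = [m.conformations for m in A]
    initiating = []
    for r in network.reactions:
        if r.speed != "slow" or len(r.reactants) != len(A):
            continue
        if len(A) == 1:
            if r.reactants[0] in conf_pool[0]:
                initiating.append(r)
        else:
            a, b = r.reactants
            if (a in conf_pool[0] and b in conf_pool[1]) or (
                a in conf_pool[1] and b in conf_pool[0]
            ):
                initiating.append(r)
    fast_by_reactant: dict[DomainStructure, list[DetailedReaction]] = {}
    for r in network.reactions:
        if r.speed == "fast":
            fast_by_reactant.setdefault(r.reactants[0], []).append(r)
    detailed = list(initiating)
    visited: set[DomainStructure] = set()
    frontier = [p for r in initiating for p in r.products]
    while frontier:
        c = frontier.pop()
        if c in visited:
            continue
        visited.add(c)
        for r in fast_by_reactant.get(c, []):
            detailed.append(r)
            frontier.extend(r.products)
    detailed = sorted(set(detailed), key=repr)
    return Subnetwork(
        macrostates=tuple(A),
        initiating=initiating,
        detailed=detailed,
        strand_level=project_to_strand_level(detailed),
    )


def load_network_from_spec(spec, policy: Optional[TimescalePolicy] = None) -> ReactionNetwork:
    """Build a network from ``reaction`` lines of a pre-enumerated system file."""
    policy = policy or TimescalePolicy()
    reactions = []
    for speed, reactant_names, product_names in spec.reactions:
        reactants = tuple(spec.complexes[n] for n in reactant_names)
        products = tuple(spec.complexes[n] for n in product_names)
        if speed is None:
            speed = "slow" if len(reactants) == 2 else "fast"
        reactions.append(DetailedReaction(reactants, products, "imported", speed))
    complexes = list(spec.complexes.values())
    return ReactionNetwork(
        initial_complexes=complexes,
        complexes=complexes,
        reactions=reactions,
        policy=policy,
        names={c: n for n, c in spec.complexes.items()},
    )
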