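"""Relating sequence-level secondary structures to domain-level conformations.

A sampled sequence-level structure ``Ts`` is a *p-approximation* of a
domain-level conformation ``Td`` when, domain by domain, the fraction of
correctly configured nucleotides is at least ``p``; a structure matching no
conformation of a resting macrostate is *p-spurious*.  Conformation
probabilities are estimated from Boltzmann samples with Bayesian error bars
(posterior mean and standard deviation under a uniform prior), so usable
uncertainties exist even before the first success is observed.

Two match rules are provided:

* ``defect`` (default) -- a nucleotide is correct iff its pairing state in
  ``Ts`` equals the state implied by ``Td`` exactly (unbound matches unbound,
  bound matches the same partner nucleotide).  With ``p > 0.5`` this makes a
  structure match at most one conformation.
* ``literal`` -- any unbound nucleotide counts as correct, in addition to
  nucleotides bound to the implied partner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .core import (
    DomainStructure,
    Pos,
    SequenceStructure,
    Strand,
    ValidityError,
    bases_pair,
)
from .rates import estimate_probability

__all__ = [
    "ApproximationPolicy",
    "ApproximationReport",
    "ConformationEstimates",
    "NotComparableError",
    "EnsembleTooLargeError",
    "domain_match_fractions",
    "complex_match_fraction",
    "classify_structure",
    "estimate_conformation_probabilities",
    "enumerate_sequence_structures",
    "exact_boltzmann_distribution",
    "sorted_conformations",
]


class NotComparableError(ValueError):
    """Structures do not share an ordered strand list up to rotation."""


class EnsembleTooLargeError(RuntimeError):
    """The secondary-structure ensemble exceeds the enumeration bound."""


@dataclass(frozen=True)
class ApproximationPolicy:
    """Thresholds for thermodynamic (``p``) and kinetic (``p_prime``) matching.

    ``p > 0.5`` is recommended so a structure approximates at most one
    conformation; the default 0.51 tolerates partial branch migration.
    """

    p: float = 0.51
    p_prime: float = 0.51
    match_rule: str = "defect"

    def __post_init__(self) -> None:
        for name, v in (("p", self.p), ("p_prime", self.p_prime)):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.match_rule not in ("defect", "literal"):
            raise ValueError(f"unknown match_rule {self.match_rule!r}")


@dataclass
class ApproximationReport:
    """Per-domain correct fractions and the matched conformation, if any."""

    fractions: dict[Pos, float]
    matched: Union[int, str, None] = None  # conformation index or "spurious"

    def min_fraction(self) -> float:
        return min(self.fractions.values())


def _align_rotation(Ts: SequenceStructure, Td: DomainStructure) -> tuple[SequenceStructure, DomainStructure]:
    """Rotate both structures to the canonical rotation of their strand names."""
    ts_names = tuple(s.name for s in Ts.strands)
    td_names = tuple(s.name for s in Td.strands)
    n = len(td_names)
    if len(ts_names) != n or sorted(ts_names) != sorted(td_names):
        raise NotComparableError(
            f"strand lists differ: {ts_names} vs {td_names}"
        )
    rot = lambda names, r: names[r:] + names[:r]  # noqa: E731
    rs = min(range(n), key=lambda r: rot(ts_names, r))
    rd = min(range(n), key=lambda r: rot(td_names, r))
    if rot(ts_names, rs) != rot(td_names, rd):
        raise NotComparableError(
            f"strand lists are not rotations of each other: {ts_names} vs {td_names}"
        )
    return Ts.rotate(rs), Td.rotate(rd)


def _nucleotide_correctness(
    Ts: SequenceStructure, Td: DomainStructure, match_rule: str
) -> tuple[DomainStructure, list[list[bool]]]:
    Ts, Td = _align_rotation(Ts, Td)
    implied = Td.implied_sequence_pairing()
    correct: list[list[bool]] = []
    for si, strand in enumerate(Td.strands):
        flags = []
        for ni in range(strand.length):
            pos = (si, ni)
            actual = Ts.pairing.get(pos)
            target = implied.get(pos)
            if match_rule == "defect":
                flags.append(actual == target)
            else:  # literal: unbound always counts as correct
                flags.append(actual is None or actual == target)
        correct.append(flags)
    return Td, correct


def domain_match_fractions(
    Ts: SequenceStructure, Td: DomainStructure, match_rule: str = "defect"
) -> ApproximationReport:
    """Fraction of correctly configured nucleotides for every domain of ``Td``."""
    Td_rot, correct = _nucleotide_correctness(Ts, Td, match_rule)
    fractions: dict[Pos, float] = {}
    for si, strand in enumerate(Td_rot.strands):
        offset = 0
        for di, dom in enumerate(strand.domains):
            flags = correct[si][offset : offset + dom.length]
            fractions[(si, di)] = sum(flags) / dom.length
            offset += dom.length
    return ApproximationReport(fractions=fractions)


def complex_match_fraction(
    Ts: SequenceStructure, Td: DomainStructure, match_rule: str = "defect"
) -> float:
    """Correct fraction computed over the entire complex (count-by-complex)."""
    _, correct = _nucleotide_correctness(Ts, Td, match_rule)
    flat = [f for row in correct for f in row]
    return sum(flat) / len(flat)


def sorted_conformations(macrostate) -> list[DomainStructure]:
    """Deterministic conformation order for a macrostate or conformation set."""
    confs = getattr(macrostate, "conformations", macrostate)
    return sorted(confs, key=lambda c: c.canonical_key())


def classify_structure(
    Ts: SequenceStructure,
    macrostate,
    policy: Optional[ApproximationPolicy] = None,
) -> Union[int, str]:
    """Index of the first conformation ``Ts`` p-approximates, else ``"spurious"``.

    With the defect rule and ``p > 0.5`` at most one conformation can match,
    so the returned index is independent of conformation order.
    """
    policy = policy or ApproximationPolicy()
    for i, Td in enumerate(sorted_conformations(macrostate)):
        try:
            report = domain_match_fractions(Ts, Td, policy.match_rule)
        except NotComparableError:
            continue
        if all(f >= policy.p for f in report.fractions.values()):
            return i
    return "spurious"


@dataclass
class ConformationEstimates:
    """Bayesian conformation-probability estimates for one macrostate."""

    conformations: list[DomainStructure]
    N: int
    counts: list[int]  # per conformation; spurious tally is counts[-1]
    p_hat: list[float]
    sigma: list[float]
    precision_met: bool
    seed: Optional[int] = None

    @property
    def spurious_index(self) -> int:
        return len(self.conformations)

    @property
    def p_spurious(self) -> float:
        return self.p_hat[self.spurious_index]


def estimate_conformation_probabilities(
    sampler: Callable[[int, np.random.Generator], Sequence[SequenceStructure]],
    macrostate,
    policy: Optional[ApproximationPolicy] = None,
    precision: float = 0.10,
    max_samples: int = 100_000,
    batch: int = 100,
    seed: int = 0,
) -> ConformationEstimates:
    """Adaptively sample Boltzmann structures and classify them.

    ``sampler(n, rng)`` must yield ``n`` i.i.d. equilibrium samples for the
    macrostate's strand-level complex.  Sampling continues in batches until
    every conformation's relative posterior error ``sigma/p_hat`` drops to
    ``precision``, or ``max_samples`` is reached (flagged).
    """
    policy = policy or ApproximationPolicy()
    confs = sorted_conformations(macrostate)
    rng = np.random.default_rng(seed)
    counts = [0] * (len(confs) + 1)
    N = 0
    precision_met = False
    while N < max_samples:
        n = min(batch, max_samples - N)
        for Ts in sampler(n, rng):
            label = classify_structure(Ts, confs, policy)
            idx = len(confs) if label == "spurious" else int(label)
            counts[idx] += 1
            N += 1
        stats = [estimate_probability(c, N) for c in counts]
        if all(s / p <= precision for p, s in stats):
            precision_met = True
            break
    stats = [estimate_probability(c, N) for c in counts]
    return ConformationEstimates(
        conformations=confs,
        N=N,
        counts=counts,
        p_hat=[p for p, _ in stats],
        sigma=[s for _, s in stats],
        precision_met=precision_met,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# exact ensembles for desk-scale complexes


def _strand_breaks(strands: Sequence[Strand]) -> tuple[list[int], list[Pos]]:
    """Linear positions and the set of indices that begin a new strand."""
    positions: list[Pos] = []
    starts = []
    for si, s in enumerate(strands):
        starts.append(len(positions))
        positions.extend((si, ni) for ni in range(s.length))
    return starts, positions


def enumerate_sequence_structures(
    strands: Sequence[Strand],
    min_loop: int = 3,
    wobble: bool = True,
    max_structures: int = 100_000,
) -> list[SequenceStructure]:
    """All unpseudoknotted sequence-level structures over an ordered strand list.

    Multi-stranded structures must be connected.  ``min_loop`` is the minimum
    number of unpaired nucleotides closing a hairpin on a single strand.
    Raises :class:`EnsembleTooLargeError` when the (unconnected) count of
    structures exceeds ``max_structures``.
    """
    starts, positions = _strand_breaks(strands)
    n = len(positions)
    seq = "".join(s.sequence for s in strands)  # raises TypeError if unsequenced
    strand_of = [p[0] for p in positions]

    def allowed(i: int, j: int) -> bool:
        if not bases_pair(seq[i], seq[j], wobble=wobble):
            return False
        if strand_of[i] == strand_of[j] and j - i - 1 < min_loop:
            return False
        return True

    # count first so oversized ensembles are refused before enumeration
    count: dict[tuple[int, int], int] = {}

    def n_structs(i: int, j: int) -> int:
        if j - i <= 0:
            return 1
        if (i, j) in count:
            return count[(i, j)]
        total = n_structs(i + 1, j)
        for k in range(i + 1, j):
            if allowed(i, k):
                total += n_structs(i + 1, k) * n_structs(k + 1, j)
        count[(i, j)] = total
        return total

    if n_structs(0, n) > max_structures:
        raise EnsembleTooLargeError(
            f"{n_structs(0, n)} structures exceed the bound {max_structures}"
        )

    memo: dict[tuple[int, int], list[frozenset]] = {}

    def enum(i: int, j: int) -> list[frozenset]:
        if j - i <= 0:
            return [frozenset()]
        if (i, j) in memo:
            return memo[(i, j)]
        out = list(enum(i + 1, j))
        for k in range(i + 1, j):
            if allowed(i, k):
                for inner in enum(i + 1, k):
                    for outer in enum(k + 1, j):
                        out.append(inner | outer | {(i, k)})
        memo[(i, j)] = out
        return out

    structures = []
    for pairset in enum(0, n):
        pairing: dict[Pos, Pos] = {}
        for i, j in pairset:
            pairing[positions[i]] = positions[j]
            pairing[positions[j]] = positions[i]
        try:
            structures.append(SequenceStructure(strands, pairing, wobble=wobble))
        except ValidityError:
            continue  # disconnected multi-stranded arrangement
    return structures


def exact_boltzmann_distribution(
    strands_or_complex,
    energy_model,
    min_loop: int = 3,
    wobble: bool = True,
    max_structures: int = 100_000,
) -> dict[SequenceStructure, float]:
    """Exhaustive Boltzmann distribution ``exp(-E/RT)/Z`` over an ensemble.

    ``energy_model`` needs an ``energy(structure) -> float`` method (units
    consistent with its ``RT`` attribute).  Works only for desk-scale
    ensembles; oversized ones are refused explicitly.
    """
    strands = getattr(strands_or_complex, "strands", strands_or_complex)
    structures = enumerate_sequence_structures(
        strands, min_loop=min_loop, wobble=wobble, max_structures=max_structures
    )
    RT = energy_model.RT
    weights = np.array([math.exp(-energy_model.energy(s) / RT) for s in structures])
    Z = weights.sum()
    if not np.isfinite(Z) or Z <= 0:
        raise ValidityError("partition function is not finite and positive")
    probs = weights / Z
    return {s: float(p) for s, p in zip(structures, probs)}
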