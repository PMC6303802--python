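"""Core data model for domain-level DNA strand-displacement systems.

A *domain* is a functionally distinct contiguous section of a DNA strand,
identified by name and length (in nucleotides); a trailing ``*`` marks the
Watson-Crick complement of the undecorated domain.  Strands are ordered
domain lists (5' to 3'), and complexes are ordered strand lists carrying a
secondary structure.  Structures exist at two resolutions:

* :class:`DomainStructure` -- each domain is completely unbound or completely
  bound to one complementary domain;
* :class:`SequenceStructure` -- each nucleotide is unbound or paired to a
  complementary nucleotide (Watson-Crick or G-T wobble).

Both are restricted to non-pseudoknotted pairings, i.e. a valid
dot-parens-plus string exists for the given strand order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Domain",
    "Strand",
    "DomainStructure",
    "SequenceStructure",
    "StrandComplex",
    "BoxState",
    "SystemSpec",
    "ParseError",
    "ValidityError",
    "complement_name",
    "reverse_complement",
    "parse_structure",
    "write_structure",
    "canonicalize_strand_order",
    "read_system_spec",
]

WC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ParseError(ValueError):
    """Malformed dot-parens-plus text or system file."""


class ValidityError(ValueError):
    """Structurally well-formed input violating a model invariant."""


def complement_name(name: str) -> str:
    """Name of the complement domain; ``d`` <-> ``d*``, with ``d**`` == ``d``."""
    base = name.rstrip("*")
    stars = len(name) - len(base)
    return base if stars % 2 == 1 else base + "*"


def _normalize_name(name: str) -> str:
    base = name.rstrip("*")
    stars = len(name) - len(base)
    return base + ("*" if stars % 2 == 1 else "")


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def bases_pair(a: str, b: str, wobble: bool = True) -> bool:
    return (a, b) in WC_PAIRS or (wobble and (a, b) in WOBBLE_PAIRS)


@dataclass(frozen=True)
class Domain:
    """A named domain with a length in nucleotides and optional sequence."""

    name: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidityError(f"domain {self.name!r}: length must be >= 1")
        object.__setattr__(self, "name", _normalize_name(self.name))
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValidityError(
                    f"domain {self.name!r}: sequence length {len(self.sequence)} "
                    f"!= declared length {self.length}"
                )
            bad = set(self.sequence) - set("ATCG")
            if bad:
                raise ValidityError(f"domain {self.name!r}: illegal bases {sorted(bad)}")

    @property
    def is_complement(self) -> bool:
        return self.name.endswith("*")

    def complement(self) -> "Domain":
        seq = None if self.sequence is None else reverse_complement(self.sequence)
        return Domain(complement_name(self.name), self.length, seq)

    def is_complementary_to(self, other: "Domain") -> bool:
        return complement_name(self.name) == other.name and self.length == other.length


@dataclass(frozen=True)
class Strand:
    """An ordered (5' to 3') list of domains with a name."""

    name: str
    domains: tuple[Domain, ...]

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValidityError(f"strand {self.name!r}: empty domain list")
        object.__setattr__(self, "domains", tuple(self.domains))

    @property
    def length(self) -> int:
        return sum(d.length for d in self.domains)

    @property
    def sequence(self) -> Optional[str]:
        if any(d.sequence is None for d in self.domains):
            return None
        return "".join(d.sequence for d in self.domains)  # type: ignore[misc]


Pos = tuple[int, int]  # (strand index, unit index) -- unit is a domain or a nucleotide


def _check_involution(pairing: Mapping[Pos, Pos]) -> None:
    for p, q in pairing.items():
        if p == q:
            raise ValidityError(f"position {p} paired with itself")
        if pairing.get(q) != p:
            raise ValidityError(f"pairing is not an involution at {p}<->{q}")


def _linear_positions(unit_counts: Sequence[int]) -> list[Pos]:
    return [(si, ui) for si, n in enumerate(unit_counts) for ui in range(n)]


def _is_unpseudoknotted(pairing: Mapping[Pos, Pos], unit_counts: Sequence[int]) -> bool:
    """True iff the pairing nests in the given linear strand order."""
    order = {p: i for i, p in enumerate(_linear_positions(unit_counts))}
    stack: list[Pos] = []
    for p in _linear_positions(unit_counts):
        q = pairing.get(p)
        if q is None:
            continue
        if order[q] > order[p]:
            stack.append(p)
        else:
            if not stack or stack[-1] != q:
                return False
            stack.pop()
    return not stack


def _is_connected(pairing: Mapping[Pos, Pos], n_strands: int) -> bool:
    if n_strands <= 1:
        return True
    adj: dict[int, set[int]] = {i: set() for i in range(n_strands)}
    for (si, _), (sj, _) in pairing.items():
        adj[si].add(sj)
        adj[sj].add(si)
    seen = {0}
    stack = [0]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == n_strands


class _Structure:
    """Shared machinery for domain- and sequence-level structures."""

    #: subclasses set this: number of pairing units on a strand
    level: str = ""

    def __init__(self, strands: Sequence[Strand], pairing: Mapping[Pos, Pos]):
        self.strands: tuple[Strand, ...] = tuple(strands)
        if not self.strands:
            raise ValidityError("structure with no strands")
        self.pairing: dict[Pos, Pos] = dict(pairing)
        self._validate()

    # -- subclass hooks -------------------------------------------------
    def _unit_count(self, strand: Strand) -> int:
        raise NotImplementedError

    def _check_pair(self, p: Pos, q: Pos) -> None:
        raise NotImplementedError

    # -------------------------------------------------------------------
    @property
    def unit_counts(self) -> tuple[int, ...]:
        return tuple(self._unit_count(s) for s in self.strands)

    def _validate(self) -> None:
        counts = self.unit_counts
        for p in list(self.pairing) + list(self.pairing.values()):
            si, ui = p
            if not (0 <= si < len(self.strands)) or not (0 <= ui < counts[si]):
                raise ValidityError(f"position {p} out of range")
        _check_involution(self.pairing)
        for p, q in self.pairing.items():
            if p < q:
                self._check_pair(p, q)
        if not _is_unpseudoknotted(self.pairing, counts):
            raise ValidityError("structure is pseudoknotted in the given strand order")
        if not _is_connected(self.pairing, len(self.strands)):
            raise ValidityError("structure is not connected")

    def partner(self, p: Pos) -> Optional[Pos]:
        return self.pairing.get(p)

    def is_paired(self, p: Pos) -> bool:
        return p in self.pairing

    def rotate(self, r: int):
        """Circularly permute the strand order by ``r`` (new first strand = old r-th)."""
        n = len(self.strands)
        r %= n
        strands = self.strands[r:] + self.strands[:r]
        remap = lambda p: ((p[0] - r) % n, p[1])  # noqa: E731
        pairing = {remap(p): remap(q) for p, q in self.pairing.items()}
        return _rotated_copy(self, strands, pairing)

    def canonical_key(self):
        """Rotation-invariant identity key (strand names + remapped pairing)."""
        best = None
        n = len(self.strands)
        for r in range(n):
            names = tuple(s.name for s in self.strands[r:] + self.strands[:r])
            pairing = tuple(
                sorted(
                    (((p[0] - r) % n, p[1]), ((q[0] - r) % n, q[1]))
                    for p, q in self.pairing.items()
                    if (((p[0] - r) % n, p[1]) < ((q[0] - r) % n, q[1]))
                )
            )
            key = (names, pairing)
            if best is None or key < best:
                best = key
        return (self.level,) + best  # type: ignore[operator]

    def __eq__(self, other) -> bool:
        return isinstance(other, _Structure) and self.canonical_key() == other.canonical_key()

    def __hash__(self) -> int:
        return hash(self.canonical_key())

    def __repr__(self) -> str:
        names = ",".join(s.name for s in self.strands)
        return f"<{type(self).__name__} [{names}] {write_structure(self)!r}>"


def _rotated_copy(proto: _Structure, strands, pairing):
    cls = type(proto)
    obj = cls.__new__(cls)
    obj.strands = tuple(strands)
    obj.pairing = dict(pairing)
    # rotation of a valid structure may transiently break nesting for the
    # written form but never identity; re-validate only the cheap invariants
    _check_involution(obj.pairing)
    return obj


class DomainStructure(_Structure):
    """Secondary structure at domain resolution over an ordered strand list."""

    level = "domain"

    def _unit_count(self, strand: Strand) -> int:
        return len(strand.domains)

    def domain_at(self, p: Pos) -> Domain:
        return self.strands[p[0]].domains[p[1]]

    def _check_pair(self, p: Pos, q: Pos) -> None:
        a, b = self.domain_at(p), self.domain_at(q)
        if not a.is_complementary_to(b):
            raise ValidityError(
                f"domains {a.name!r} and {b.name!r} paired but not complementary"
            )

    def strand_complex(self) -> "StrandComplex":
        return canonicalize_strand_order(StrandComplex(self.strands))

    def implied_sequence_pairing(self) -> dict[Pos, Pos]:
        """Nucleotide pairing implied by the domain pairing.

        A domain bound to its partner pairs antiparallel nucleotide-wise:
        the i-th base of the domain pairs the (L-1-i)-th base of the partner.
        """
        offsets = [
            [sum(d.length for d in s.domains[:i]) for i in range(len(s.domains) + 1)]
            for s in self.strands
        ]
        seq_pairing: dict[Pos, Pos] = {}
        for p, q in self.pairing.items():
            if p > q:
                continue
            (si, di), (sj, dj) = p, q
            L = self.domain_at(p).length
            for i in range(L):
                a = (si, offsets[si][di] + i)
                b = (sj, offsets[sj][dj] + L - 1 - i)
                seq_pairing[a] = b
                seq_pairing[b] = a
        return seq_pairing


class SequenceStructure(_Structure):
    """Secondary structure at nucleotide resolution over sequenced strands."""

    level = "sequence"

    def __init__(self, strands, pairing, wobble: bool = True):
        self.wobble = wobble
        super().__init__(strands, pairing)

    def _unit_count(self, strand: Strand) -> int:
        if strand.sequence is None:
            raise ValidityError(f"strand {strand.name!r} has no sequence")
        return strand.length

    def base_at(self, p: Pos) -> str:
        return self.strands[p[0]].sequence[p[1]]  # type: ignore[index]

    def _check_pair(self, p: Pos, q: Pos) -> None:
        a, b = self.base_at(p), self.base_at(q)
        if not bases_pair(a, b, wobble=self.wobble):
            raise ValidityError(f"bases {a}{p} and {b}{q} cannot pair")


@dataclass(frozen=True)
class StrandComplex:
    """A strand-level complex: an ordered strand list up to circular permutation."""

    strands: tuple[Strand, ...]
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.strands:
            raise ValidityError("empty complex")
        object.__setattr__(self, "strands", tuple(self.strands))

    @property
    def strand_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.strands)

    def _canonical_names(self) -> tuple[str, ...]:
        names = self.strand_names
        n = len(names)
        return min(names[r:] + names[:r] for r in range(n))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StrandComplex)
            and self._canonical_names() == other._canonical_names()
        )

    def __hash__(self) -> int:
        return hash(self._canonical_names())

    def __len__(self) -> int:
        return len(self.strands)

    def __repr__(self) -> str:
        label = self.name or "+".join(self.strand_names)
        return f"<StrandComplex {label}>"


def canonicalize_strand_order(cplx: StrandComplex) -> StrandComplex:
    """Lexicographically minimal rotation of the strand-name list.

    Idempotent, and all rotations of a strand list canonicalize identically,
    so equal complexes map to identical canonical forms.
    """
    names = cplx.strand_names
    n = len(names)
    best_r = min(range(n), key=lambda r: names[r:] + names[:r])
    return StrandComplex(cplx.strands[best_r:] + cplx.strands[:best_r], cplx.name)


class BoxState:
    """A multiset of strand-level complexes: the state of the simulation box."""

    __slots__ = ("complexes", "_key")

    def __init__(self, complexes: Iterable[StrandComplex]):
        cplxs = [canonicalize_strand_order(c) for c in complexes]
        cplxs.sort(key=lambda c: c._canonical_names())
        self.complexes: tuple[StrandComplex, ...] = tuple(cplxs)
        self._key = tuple(c._canonical_names() for c in self.complexes)

    def strand_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(n for c in self.complexes for n in c.strand_names))

    def remove(self, sub: Sequence[StrandComplex]) -> "BoxState":
        remaining = list(self.complexes)
        for c in sub:
            remaining.remove(canonicalize_strand_order(c))
        return BoxState(remaining)

    def add(self, extra: Sequence[StrandComplex]) -> "BoxState":
        return BoxState(list(self.complexes) + list(extra))

    def contains(self, sub: Sequence[StrandComplex]) -> bool:
        remaining = list(self.complexes)
        for c in sub:
            cc = canonicalize_strand_order(c)
            if cc in remaining:
                remaining.remove(cc)
            else:
                return False
        return True

    def __eq__(self, other) -> bool:
        return isinstance(other, BoxState) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def __repr__(self) -> str:
        return "{" + ", ".join("+".join(k) for k in self._key) + "}"


# ---------------------------------------------------------------------------
# dot-parens-plus


def parse_structure(text: str, strands: Sequence[Strand], level: str = "domain"):
    """Parse a dot-parens-plus string over an ordered strand list.

    ``level`` selects domain resolution (one character per domain) or
    sequence resolution (one character per nucleotide).  Exactly one ``+``
    must separate consecutive strands; whitespace is ignored.
    """
    if level not in ("domain", "sequence"):
        raise ValueError(f"unknown level {level!r}")
    compact = "".join(text.split())
    bad = set(compact) - set(".()+")
    if bad:
        raise ParseError(f"illegal characters {sorted(bad)} in structure")
    segments = compact.split("+")
    if len(segments) != len(strands):
        raise ParseError(
            f"{len(segments)} strand segments but {len(strands)} strands"
        )
    counts = [
        len(s.domains) if level == "domain" else s.length for s in strands
    ]
    for seg, n, s in zip(segments, counts, strands):
        if len(seg) != n:
            raise ParseError(
                f"strand {s.name!r}: {len(seg)} structure characters for {n} units"
            )
    pairing: dict[Pos, Pos] = {}
    stack: list[Pos] = []
    for si, seg in enumerate(segments):
        for ui, ch in enumerate(seg):
            if ch == "(":
                stack.append((si, ui))
            elif ch == ")":
                if not stack:
                    raise ParseError("unbalanced parentheses: unmatched ')'")
                p = stack.pop()
                pairing[p] = (si, ui)
                pairing[(si, ui)] = p
    if stack:
        raise ParseError("unbalanced parentheses: unmatched '('")
    cls = DomainStructure if level == "domain" else SequenceStructure
    return cls(strands, pairing)


def write_structure(structure: _Structure) -> str:
    """Dot-parens-plus string for a structure; inverse of :func:`parse_structure`."""
    counts = structure.unit_counts
    order = {p: i for i, p in enumerate(_linear_positions(counts))}
    segments = []
    for si, n in enumerate(counts):
        chars = []
        for ui in range(n):
            q = structure.partner((si, ui))
            if q is None:
                chars.append(".")
            else:
                chars.append("(" if order[q] > order[(si, ui)] else ")")
        segments.append("".join(chars))
    return "+".join(segments)


# ---------------------------------------------------------------------------
# system specification files


@dataclass
class SystemSpec:
    """A fully resolved system: domains, strands, named complexes, concentrations."""

    domains: dict[str, Domain] = field(default_factory=dict)
    strands: dict[str, Strand] = field(default_factory=dict)
    complexes: dict[str, DomainStructure] = field(default_factory=dict)
    concentrations: dict[str, float] = field(default_factory=dict)
    #: optional pre-enumerated reactions: (speed or None, reactant names, product names)
    reactions: list[tuple[Optional[str], tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=list
    )


def _spec_error(lineno: int, msg: str) -> ParseError:
    return ParseError(f"line {lineno}: {msg}")


def read_system_spec(path_or_text) -> SystemSpec:
    """Read a PIL-style system file.

    Grammar (line oriented, ``#`` comments)::

        length <name> = <int>
        sequence <name> = <ACGT...>
        strand <name> = <dom> <dom> ...
        complex <name> = <strand> <strand> ... : <dot-parens-plus>
        conc <name> = <float> M
        reaction [fast|slow] A + B -> C + D

    Complement domains (``d*``) are generated automatically.  Accepts a
    filesystem path or the file content itself (anything containing a
    newline is treated as content).
    """
    s = str(path_or_text)
    if "\n" in s:
        text = s
    else:
        with open(s) as fh:
            text = fh.read()
    spec = SystemSpec()

    def add_domain(dom: Domain) -> None:
        spec.domains[dom.name] = dom
        comp = dom.complement()
        spec.domains.setdefault(comp.name, comp)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        kw = tokens[0]
        try:
            if kw == "length":
                name, eq, val = tokens[1], tokens[2], tokens[3]
                if eq != "=":
                    raise _spec_error(lineno, "expected '='")
                if _normalize_name(name) in spec.domains:
                    raise _spec_error(lineno, f"duplicate domain {name!r}")
                add_domain(Domain(name, int(val)))
            elif kw == "sequence":
                name, eq, val = tokens[1], tokens[2], tokens[3]
                if eq != "=":
                    raise _spec_error(lineno, "expected '='")
                if _normalize_name(name) in spec.domains:
                    raise _spec_error(lineno, f"duplicate domain {name!r}")
                add_domain(Domain(name, len(val), val))
            elif kw == "strand":
                name = tokens[1]
                if tokens[2] != "=":
                    raise _spec_error(lineno, "expected '='")
                if name in spec.strands:
                    raise _spec_error(lineno, f"duplicate strand {name!r}")
                doms = []
                for dn in tokens[3:]:
                    dn = _normalize_name(dn)
                    if dn not in spec.domains:
                        raise _spec_error(lineno, f"unknown domain {dn!r}")
                    doms.append(spec.domains[dn])
                if not doms:
                    raise _spec_error(lineno, f"strand {name!r} has no domains")
                spec.strands[name] = Strand(name, tuple(doms))
            elif kw == "complex":
                name = tokens[1]
                if tokens[2] != "=":
                    raise _spec_error(lineno, "expected '='")
                if name in spec.complexes:
                    raise _spec_error(lineno, f"duplicate complex {name!r}")
                rest = " ".join(tokens[3:])
                if ":" not in rest:
                    raise _spec_error(lineno, "expected ':' before structure")
                strand_part, struct_part = rest.split(":", 1)
                strand_names = strand_part.split()
                strands = []
                for sn in strand_names:
                    if sn not in spec.strands:
                        raise _spec_error(lineno, f"unknown strand {sn!r}")
                    strands.append(spec.strands[sn])
                try:
                    structure = parse_structure(struct_part, strands, level="domain")
                except (ParseError, ValidityError) as exc:
                    raise _spec_error(lineno, f"complex {name!r}: {exc}")
                spec.complexes[name] = structure
            elif kw == "conc":
                name = tokens[1]
                if tokens[2] != "=":
                    raise _spec_error(lineno, "expected '='")
                spec.concentrations[name] = float(tokens[3])
            elif kw == "reaction":
                rest = tokens[1:]
                speed: Optional[str] = None
                if rest and rest[0] in ("fast", "slow"):
                    speed = rest[0]
                    rest = rest[1:]
                joined = " ".join(rest)
                if "->" not in joined:
                    raise _spec_error(lineno, "expected '->' in reaction")
                lhs, rhs = joined.split("->", 1)
                reactants = tuple(t.strip() for t in lhs.split("+") if t.strip())
                products = tuple(t.strip() for t in rhs.split("+") if t.strip())
                for cn in reactants + products:
                    if cn not in spec.complexes:
                        raise _spec_error(lineno, f"unknown complex {cn!r}")
                spec.reactions.append((speed, reactants, products))
            else:
                raise _spec_error(lineno, f"unknown keyword {kw!r}")
        except IndexError:
            raise _spec_error(lineno, "malformed line") from None
    return spec
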