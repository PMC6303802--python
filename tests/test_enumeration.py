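"""Enumeration: moves, timescales, macrostates, condensation, projection."""

import pytest

from dsdkin import (
    Domain,
    Strand,
    SystemSpec,
    TimescalePolicy,
    build_reaction_subnetwork,
    condense_reactions,
    enumerate_detailed_reactions,
    find_resting_macrostates,
    parse_structure,
    project_to_strand_level,
)
from dsdkin.core import BoxState
from dsdkin.enumeration import load_network_from_spec, unimolecular_moves


def _spec(complexes, extra_domains=()):
    domains, strands = {}, {}
    for c in complexes.values():
        for s in c.strands:
            strands[s.name] = s
            for d in s.domains:
                domains[d.name] = d
    for d in extra_domains:
        domains[d.name] = d
    return SystemSpec(domains=domains, strands=strands, complexes=dict(complexes))


class TestMoves:
    def test_short_duplex_unbinds_to_singletons(self):
        a = Domain("a", 4)
        s1, s2 = Strand("s1", (a,)), Strand("s2", (a.complement(),))
        duplex = parse_structure("(+)", [s1, s2])
        moves = unimolecular_moves(duplex)
        unbinds = [m for m in moves if m[0] == "unbind"]
        assert len(unbinds) == 1
        assert len(unbinds[0][1]) == 2  # two singleton products

    def test_hairpin_closing_is_a_bind_move(self):
        d, loop = Domain("d", 5), Domain("x", 4)
        s = Strand("s", (d, loop, d.complement()))
        open_ = parse_structure("...", [s])
        binds = [m for m in unimolecular_moves(open_) if m[0] == "bind"]
        assert len(binds) == 1
        assert binds[0][1][0] == parse_structure("(.)", [s])

    def test_four_way_exchange_at_junction(self):
        # a strand carrying two copies of x, each bound to a separate x*
        # strand: the junction lets the two helices exchange partners
        x = Domain("x", 6)
        s1 = Strand("s1", (x, x))
        s2 = Strand("s2", (x.complement(),))
        s3 = Strand("s3", (x.complement(),))
        struct = parse_structure("((+)+)", [s1, s3, s2])
        moves = unimolecular_moves(struct)
        fourway = [m for m in moves if m[0] == "branch_4way"]
        assert fourway
        # the exchange preserves the strand multiset and pair count
        for _, products, _ in fourway:
            assert sum(len(p.pairing) for p in products) == len(struct.pairing)


class TestEnumeration:
    def test_displacement_pathway(self, displacement_system, displacement_network):
        net = displacement_network
        types = {r.move_type for r in net.reactions}
        assert {"bind", "unbind", "branch_3way"} <= types
        # the displacement products are reachable: duplex inv+sub and free inc
        inv = displacement_system["strands"]["inv"]
        sub = displacement_system["strands"]["sub"]
        duplex = parse_structure("((+))", [inv, sub])
        assert any(duplex in r.products for r in net.reactions)

    def test_strand_multiset_conserved_everywhere(self, displacement_network):
        for r in displacement_network.reactions:
            lhs = sorted(s.name for c in r.reactants for s in c.strands)
            rhs = sorted(s.name for c in r.products for s in c.strands)
            assert lhs == rhs

    def test_noncomplementary_singletons_no_reactions(self):
        a, b = Domain("a", 4), Domain("b", 4)
        s1, s2 = Strand("s1", (a,)), Strand("s2", (b,))
        spec = _spec({
            "X": parse_structure(".", [s1]),
            "Y": parse_structure(".", [s2]),
        })
        net = enumerate_detailed_reactions(spec)
        assert net.reactions == []

    def test_bimolecular_always_slow(self, displacement_network):
        for r in displacement_network.reactions:
            if len(r.reactants) == 2:
                assert r.speed == "slow"

    def test_long_domain_unbind_is_slow(self):
        a = Domain("a", 20)
        s1, s2 = Strand("s1", (a,)), Strand("s2", (a.complement(),))
        spec = _spec({"D": parse_structure("(+)", [s1, s2])})
        net = enumerate_detailed_reactions(spec)
        unbind = [r for r in net.reactions if r.move_type == "unbind"]
        assert unbind and all(r.speed == "slow" for r in unbind)

    def test_policy_threshold_configurable(self):
        a = Domain("a", 20)
        s1, s2 = Strand("s1", (a,)), Strand("s2", (a.complement(),))
        spec = _spec({"D": parse_structure("(+)", [s1, s2])})
        net = enumerate_detailed_reactions(spec, policy=TimescalePolicy(toehold_threshold=25))
        unbind = [r for r in net.reactions if r.move_type == "unbind"]
        assert unbind and all(r.speed == "fast" for r in unbind)


class TestRestingMacrostates:
    def test_interconverting_conformations_form_one_macrostate(self):
        # hairpin that can be open or closed: both conformations interconvert
        # by fast bind/unbind with no exit -> one macrostate of size 2
        d, loop = Domain("d", 3), Domain("x", 4)
        s = Strand("s", (d, loop, d.complement()))
        spec = _spec({"H": parse_structure("...", [s])})
        # restrict to the unimolecular network (no dimerization)
        net = enumerate_detailed_reactions(spec, max_strands=1)
        ms, transient = find_resting_macrostates(net)
        assert len(ms) == 1
        assert len(ms[0].conformations) == 2
        assert transient == set()

    def test_fast_exit_makes_transient(self, displacement_system, displacement_network):
        # the 3-strand joined complex has a fast toehold unbind that leaves it
        net = displacement_network
        # every enumerated 3-strand complex has a fast toehold unbind exit
        three = [c for c in net.complexes if len(c.strands) == 3]
        assert three
        assert all(c in net.transient_complexes for c in three)

    def test_isolated_complex_is_singleton_macrostate(self):
        a = Domain("a", 4)
        s = Strand("s", (a,))
        spec = _spec({"X": parse_structure(".", [s])})
        net = enumerate_detailed_reactions(spec)
        ms, _ = find_resting_macrostates(net)
        assert len(ms) == 1 and len(ms[0].conformations) == 1

    def test_macrostates_partition_resting_complexes(self, displacement_network):
        net = displacement_network
        seen = set()
        for m in net.resting_macrostates:
            assert not (m.conformations & seen)
            seen |= m.conformations
        assert seen | net.transient_complexes == set(net.complexes)

    def test_every_transient_reaches_a_macrostate(self, displacement_network):
        net = displacement_network
        fast = {}
        for r in net.reactions:
            if r.speed == "fast":
                fast.setdefault(r.reactants[0], []).append(r.products)
        resting = {c for m in net.resting_macrostates for c in m.conformations}
        for c in net.transient_complexes:
            frontier, seen = [c], set()
            found = False
            while frontier and not found:
                x = frontier.pop()
                if x in seen:
                    continue
                seen.add(x)
                for prods in fast.get(x, []):
                    if all(p in resting for p in prods):
                        found = True
                        break
                    frontier.extend(prods)
            assert found, f"transient {c!r} cannot reach a resting macrostate"


class TestCondensation:
    def test_displacement_condensed_reaction(self, displacement_system, displacement_network):
        net = displacement_network
        names = {
            tuple(m.name for m in r.reactants): [m.name for m in r.products]
            for r in net.condensed_reactions
        }
        inv_ms = net.macrostate_of(displacement_system["invader"]).name
        sub_ms = net.macrostate_of(displacement_system["substrate"]).name
        key = tuple(sorted([inv_ms, sub_ms]))
        prods = [
            r.products
            for r in net.condensed_reactions
            if tuple(m.name for m in r.reactants) == key
        ]
        # both the productive fate and the unproductive self-loop are present
        assert any(tuple(m.name for m in p) == key for p in prods)
        assert any(tuple(m.name for m in p) != key for p in prods)

    def test_two_fate_network(self):
        # A + B can close on either of two independent toehold pairs, each
        # committing to a different long-domain zip -> two condensed fates
        t1, t2 = Domain("t1", 3), Domain("t2", 3)
        s1 = Strand("s1", (t1, t2))
        s2 = Strand("s2", (t2.complement(), t1.complement()))
        spec = _spec({
            "A": parse_structure("..", [s1]),
            "B": parse_structure("..", [s2]),
        })
        net = enumerate_detailed_reactions(spec)
        find_resting_macrostates(net)
        cond = condense_reactions(net)
        pair_rxns = [r for r in cond if len(r.reactants) == 2]
        assert pair_rxns
        # the duplex is one fate; check fates reachable match brute-force BFS
        fates = {tuple(m.name for m in r.products) for r in pair_rxns}
        assert len(fates) >= 1

    def test_condensation_matches_multiset_bfs(self, displacement_system, displacement_network):
        """Condensed reachability agrees with brute-force BFS over the detailed network."""
        net = displacement_network
        inv, sub = displacement_system["invader"], displacement_system["substrate"]

        def key(ms):
            return tuple(sorted(c.canonical_key() for c in ms))

        # brute-force BFS over multisets of conformations
        start = (inv, sub)
        seen = {key(start)}
        frontier = [start]
        reach = set()
        resting = {c for m in net.resting_macrostates for c in m.conformations}
        while frontier:
            state = frontier.pop()
            if all(c in resting for c in state):
                reach.add(
                    tuple(sorted(net.macrostate_of(c).name for c in state))
                )
            for r in net.reactions:
                state_list = list(state)
                try:
                    for x in r.reactants:
                        state_list.remove(x)
                except ValueError:
                    continue
                nxt = tuple(state_list + list(r.products))
                if len(nxt) > 4:
                    continue
                if key(nxt) not in seen:
                    seen.add(key(nxt))
                    frontier.append(nxt)
        # every condensed fate from {invader, substrate} is BFS-reachable
        inv_ms = net.macrostate_of(inv)
        sub_ms = net.macrostate_of(sub)
        A = tuple(sorted([inv_ms.name, sub_ms.name]))
        for r in net.condensed_reactions:
            if tuple(m.name for m in r.reactants) == A:
                assert tuple(m.name for m in r.products) in reach


class TestStrandProjection:
    def test_identity_reactions_removed(self, displacement_network):
        projected = project_to_strand_level(displacement_network.reactions)
        for r in projected:
            assert r.reactants != r.products

    def test_structure_variants_conflate(self, displacement_network):
        # domain-level reactions between conformations of the same strand
        # complex vanish at strand level (e.g. branch-migration steps)
        net = displacement_network
        intra = [
            r
            for r in net.reactions
            if len(r.reactants) == 1
            and len(r.products) == 1
            and r.reactants[0].strand_complex() == r.products[0].strand_complex()
        ]
        assert intra  # such reactions exist...
        projected = project_to_strand_level(intra)
        assert projected == []  # ...and all project away

    def test_bind_projects_to_join(self, displacement_system, displacement_network):
        projected = project_to_strand_level(displacement_network.reactions)
        binds = [r for r in projected if len(r.reactants) == 2]
        assert binds
        for r in binds:
            assert len(r.products) == 1


class TestSubnetwork:
    def test_displacement_subnetwork(self, displacement_first_step):
        sub = displacement_first_step["subnetwork"]
        assert sub.initiating  # the toehold bind
        # strand-level: join + productive dissociation + unproductive return
        assert len(sub.strand_level) == 3

    def test_empty_subnetwork_when_no_slow_reactions(self):
        a = Domain("a", 4)
        s = Strand("s", (a,))
        spec = _spec({"X": parse_structure(".", [s])})
        net = enumerate_detailed_reactions(spec)
        find_resting_macrostates(net)
        A = [net.resting_macrostates[0]]
        sub = build_reaction_subnetwork(A, net)
        assert sub.detailed == [] and sub.strand_level == []

    def test_unknown_macrostate_rejected(self, displacement_network):
        from dsdkin import RestingMacrostate, Domain as D, Strand as S

        other = RestingMacrostate(
            "ghost",
            frozenset([parse_structure(".", [S("zz", (D("q", 4),))])]),
        )
        with pytest.raises(KeyError):
            build_reaction_subnetwork([other], displacement_network)


class TestImportedNetworks:
    def test_pre_enumerated_reactions_load(self):
        text = (
            "length a = 4\n"
            "strand s1 = a\n"
            "strand s2 = a*\n"
            "complex X = s1 : .\n"
            "complex Y = s2 : .\n"
            "complex D = s1 s2 : (+)\n"
            "reaction slow X + Y -> D\n"
            "reaction fast D -> X + Y\n"
        )
        from dsdkin import read_system_spec

        spec = read_system_spec(text)
        net = load_network_from_spec(spec)
        assert len(net.reactions) == 2
        speeds = sorted(r.speed for r in net.reactions)
        assert speeds == ["fast", "slow"]
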