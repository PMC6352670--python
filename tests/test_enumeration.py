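"""Census reproduction, building-block library, and dual-route equivalence."""

import itertools

import pytest

from kporph import (
    TautomerName,
    canonical_form,
    classify_motifs,
    derive_block_library,
    enumerate_by_block_composition,
    enumerate_closed_shell,
    enumerate_open_shell,
    is_closed_shell,
    parse_name,
)
from kporph.enumeration import UNIT_STATES
from kporph.valence import has_kekule_structure

CENSUS_SIZES = {0: 1, 2: 7, 4: 49, 6: 74, 8: 24}


class TestClosedShellCensus:
    @pytest.mark.parametrize("level, expected", sorted(CENSUS_SIZES.items()))
    def test_census_sizes(self, level, expected):
        census = enumerate_closed_shell(level, with_motifs=False)
        assert len(census) == expected

    def test_level_zero_is_fully_reduced_only(self):
        census = enumerate_closed_shell(0)
        assert census.names == {parse_name("a0_b0_c0_d0")}

    def test_level_two_motif_composition(self):
        """KP-2e: three single-ring-localized plus four inter-ring tautomers."""
        census = enumerate_closed_shell(2)
        assert census.counts_by_motif == {"single-ring-localized": 3, "interring-pair": 4}
        singles = {canonical_form(parse_name(f"a{d}_b0_c0_d0")) for d in ("15", "16", "56")}
        pairs = {
            canonical_form(parse_name(f"a{x}_b{y}_c0_d0"))
            for x, y in (("1", "1"), ("1", "6"), ("6", "1"), ("6", "6"))
        }
        assert census.names == singles | pairs

    @pytest.mark.parametrize("level", [10, 12])
    def test_highest_levels_empty_even_with_three_electron_blocks(self, level):
        census = enumerate_closed_shell(
            level, include_three_electron_blocks=True, with_motifs=False
        )
        assert len(census) == 0

    @pytest.mark.parametrize("level", [1, 3, 5, 7])
    def test_odd_level_is_a_parity_error(self, level):
        with pytest.raises(ValueError, match="open-shell by parity"):
            enumerate_closed_shell(level)

    def test_out_of_range_level(self):
        with pytest.raises(ValueError):
            enumerate_closed_shell(14)

    def test_members_are_canonical_and_closed_shell(self):
        census = enumerate_closed_shell(4, with_motifs=False)
        for name in census.names:
            assert canonical_form(name) == name
            assert is_closed_shell(name)
            for k in range(4):
                assert canonical_form(name.rotate(k)) in census.names

    def test_kp4e_all_one_electron_sublist_has_six_members(self):
        """The six names with every ring one-electron oxidized match the
        macrocyclic KP-4e list: a1_b1_c1_d1 ... a6_b6_c6_d6."""
        census = enumerate_closed_shell(4, with_motifs=False)
        sub = {n for n in census.names if all(len(s) == 1 for s in n.removed)}
        listed = {
            canonical_form(parse_name(t))
            for t in (
                "a1_b1_c1_d1", "a1_b1_c1_d6", "a1_b1_c6_d6",
                "a1_b6_c1_d6", "a1_b6_c6_d6", "a6_b6_c6_d6",
            )
        }
        assert sub == listed

    @pytest.mark.parametrize("level, expected", sorted(CENSUS_SIZES.items()))
    def test_burnside_count_matches_direct_dedup(self, level, expected):
        """Orbit count via Burnside's lemma over the 4 rotations equals the
        census size at every level."""
        feasible_cache = {}

        def feasible(assign):
            rep = canonical_form(TautomerName(assign)).removed
            if rep not in feasible_cache:
                feasible_cache[rep] = has_kekule_structure(TautomerName(rep))
            return feasible_cache[rep]

        fixed = [0, 0, 0, 0]
        for assign in itertools.product(UNIT_STATES, repeat=4):
            if sum(len(s) for s in assign) != level:
                continue
            if any(len(s) > 2 for s in assign):
                continue
            if not feasible(assign):
                continue
            for k in range(4):
                if tuple(assign[-k:] + assign[:-k] if k else assign) == assign:
                    fixed[k] += 1
        assert sum(fixed) % 4 == 0
        assert sum(fixed) // 4 == expected


class TestOpenShellCensus:
    @pytest.mark.parametrize("level, expected", [(0, 1), (1, 3), (12, 1)])
    def test_counts(self, level, expected):
        assert len(enumerate_open_shell(level)) == expected

    def test_level_one_orbits(self):
        expected = {
            canonical_form(parse_name(t))
            for t in ("a1_b0_c0_d0", "a5_b0_c0_d0", "a6_b0_c0_d0")
        }
        assert enumerate_open_shell(1) == expected


class TestClosedShellPredicate:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("a6_b6_c0_d0", True),
            ("a1_b0_c0_d0", False),  # odd removed-H count
            ("a6_b0_c6_d0", False),  # two opposite one-electron rings cannot pair
            ("a0_b0_c0_d0", True),
            ("a16_b56_c16_d56", True),
        ],
    )
    def test_examples(self, text, expected):
        assert is_closed_shell(parse_name(text)) is expected


class TestBlockLibrary:
    def test_standard_library_type_counts(self):
        """1 reduced / 4 one-electron / 3 two-electron (s,s) / 1 (d,d)."""
        library = derive_block_library()
        assert len(library) == 9
        by_ox = {}
        for block in library:
            by_ox.setdefault(block.unit_oxidation, []).append(block)
        assert len(by_ox[0]) == 1 and by_ox[0][0].dangling_2 == by_ox[0][0].dangling_7 == "single"
        assert len(by_ox[1]) == 4
        assert {frozenset(b.state) for b in by_ox[1]} == {
            frozenset({"N1"}),
            frozenset({"O6"}),
        }  # never {O5}
        two_ss = [b for b in by_ox[2] if b.dangling_2 == b.dangling_7 == "single"]
        two_dd = [b for b in by_ox[2] if b.dangling_2 == b.dangling_7 == "double"]
        assert len(two_ss) == 3
        assert {frozenset(b.state) for b in two_ss} == {
            frozenset({"O5", "O6"}),
            frozenset({"N1", "O6"}),
            frozenset({"N1", "O5"}),
        }
        assert len(two_dd) == 1 and two_dd[0].state == frozenset({"N1", "O6"})

    def test_parity_invariant(self):
        for block in derive_block_library(include_three_electron_blocks=True):
            n_dangling_double = [block.dangling_2, block.dangling_7].count("double")
            assert (block.unit_oxidation + n_dangling_double) % 2 == 0

    def test_unique_three_electron_block_dangles_at_seven(self):
        extra = derive_block_library(True) - derive_block_library(False)
        assert len(extra) == 1
        (block,) = extra
        assert block.state == frozenset({"N1", "O5", "O6"})
        assert (block.dangling_2, block.dangling_7) == ("single", "double")


class TestDualRouteEquivalence:
    @pytest.mark.parametrize("level", [0, 2, 4, 6, 8, 10, 12])
    def test_block_composition_census_matches_matching_census(self, level):
        whole = enumerate_closed_shell(level, with_motifs=False).names
        blocks = enumerate_by_block_composition(level)
        assert whole == blocks

    def test_composability_equals_feasibility_on_all_assignments(self):
        """Block composability and whole-graph matching feasibility agree on
        every one of the 4096 ring-state assignments (3e blocks admitted)."""
        library = derive_block_library(include_three_electron_blocks=True)
        keys = {(b.state, b.dangling_2, b.dangling_7) for b in library}
        cache = {}
        for assign in itertools.product(UNIT_STATES, repeat=4):
            composable = any(
                all(
                    (assign[i], orders[i], orders[(i - 1) % 4]) in keys
                    for i in range(4)
                )
                for orders in itertools.product(("single", "double"), repeat=4)
            )
            rep = canonical_form(TautomerName(assign)).removed
            if rep not in cache:
                cache[rep] = has_kekule_structure(TautomerName(rep))
            assert composable == cache[rep], assign


class TestMotifs:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("a6_b6_c0_d0", {"interring-pair"}),
            ("a6_b16_c6_d0", {"three-ring-chain"}),
            ("a16_b56_c16_d56", {"alternating-localized-quinonoid"}),
            ("a16_b6_c16_d6", {"macrocyclic-conjugated"}),
            ("a16_b0_c0_d0", {"single-ring-localized"}),
            ("a0_b0_c0_d0", set()),
        ],
    )
    def test_examples(self, text, expected):
        assert classify_motifs(parse_name(text)) == expected

    def test_open_shell_input_rejected(self):
        with pytest.raises(ValueError, match="open-shell"):
            classify_motifs(parse_name("a1_b0_c0_d0"))
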