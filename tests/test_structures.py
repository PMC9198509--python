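"""Parsing, loop decomposition, structural features, compatible counts."""

import math

import pytest

from rnaneutralset.enumeration import StructureConstraints, enumerate_structures
from rnaneutralset.structures import (
    HairpinTooShortError,
    InvalidCharacterError,
    LonelyPairError,
    UnbalancedBracketsError,
    compatible_sequence_count,
    compute_features,
    log10_compatible_sequence_count,
    loop_decomposition,
    parse_structure,
)


class TestParsing:
    def test_simple_hairpin(self):
        s = parse_structure("((...))")
        assert s.pairs == ((0, 6), (1, 5))
        assert s.length == 7

    def test_eleven_base_hairpin(self):
        s = parse_structure("((...........))")
        assert s.length == 15
        assert s.n_bp == 2

    @pytest.mark.parametrize(
        "bad, err",
        [
            ("(..)", HairpinTooShortError),
            ("((..))", HairpinTooShortError),
            ("((...)", UnbalancedBracketsError),
            ("(...))", UnbalancedBracketsError),
            ("((..x))", InvalidCharacterError),
        ],
    )
    def test_rejects_invalid(self, bad, err):
        with pytest.raises(err):
            parse_structure(bad)

    def test_lonely_pair_flag(self):
        parse_structure("(...)")  # fine without the flag
        with pytest.raises(LonelyPairError):
            parse_structure("(...)", no_lonely_pairs=True)
        with pytest.raises(LonelyPairError):
            parse_structure("((...))(...)", no_lonely_pairs=True)

    def test_open_structure_is_valid(self):
        s = parse_structure(".....", no_lonely_pairs=True)
        assert s.n_bp == 0

    def test_round_trip_over_enumeration(self):
        for s in enumerate_structures(StructureConstraints(L=9, no_lonely_pairs=False)):
            assert str(parse_structure(s.dotbracket)) == s.dotbracket


class TestLoopDecomposition:
    def test_hairpin_only(self):
        inv = loop_decomposition(parse_structure("((...))"))
        kinds = sorted(lp.kind for lp in inv.loops)
        assert kinds == ["exterior", "hairpin"]
        assert inv.by_kind("exterior")[0].size == 0
        assert inv.by_kind("hairpin")[0].unpaired_sizes == (3,)

    def test_internal_loop(self):
        inv = loop_decomposition(parse_structure("((..((...))..))"))
        assert inv.by_kind("internal")[0].unpaired_sizes == (2, 2)
        assert inv.by_kind("hairpin")[0].size == 3

    def test_multiloop_three_branches(self):
        inv = loop_decomposition(parse_structure("(((...))((...)))"))
        multi = inv.by_kind("multi")
        assert len(multi) == 1
        assert multi[0].branch_count == 3

    def test_matches_bruteforce_on_enumeration(self):
        """Loop assignment agrees with an independent pair-table classifier."""
        for nlp in (True, False):
            for s in enumerate_structures(
                StructureConstraints(L=12, no_lonely_pairs=nlp)
            ):
                inv = loop_decomposition(s)
                assert _brute_loop_multiset(s) == sorted(
                    (lp.kind, tuple(sorted(lp.unpaired_sizes)), lp.branch_count)
                    for lp in inv.loops
                )
                # every unpaired position in exactly one loop
                assert inv.total_unpaired + 2 * s.n_bp == s.length


def _brute_loop_multiset(s):
    """Independent loop classifier: walks the pair-table interval tree."""
    partner = s.partner
    L = s.length

    def kids_of(i, j):
        out, k = [], i + 1
        while k < j:
            if partner[k] > k:
                out.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return out

    loops = []

    def gaps(i, j, kids):
        edges = [i] + [x for p in kids for x in p] + [j]
        return [edges[m + 1] - edges[m] - 1 for m in range(0, len(edges), 2)]

    def visit(i, j):
        kids = kids_of(i, j)
        if not kids:
            loops.append(("hairpin", (j - i - 1,), 0))
        elif len(kids) == 1:
            g = gaps(i, j, kids)
            if sum(g) > 0:
                kind = "bulge" if 0 in g else "internal"
                sizes = tuple(sorted(x for x in g if kind == "internal" or x > 0))
                loops.append((kind, sizes, 2))
        else:
            loops.append(("multi", tuple(sorted(gaps(i, j, kids))), len(kids) + 1))
        for k, l in kids:
            visit(k, l)

    top = kids_of(-1, L)
    loops.append(("exterior", tuple(sorted(gaps(-1, L, top))), len(top)))
    for k, l in top:
        visit(k, l)
    return sorted(loops)


class TestFeatures:
    @pytest.mark.parametrize(
        "db, n_bp, n_regions, n_stack, n_eos",
        [
            ("((...........))", 2, 1, 1, 2),
            ("((..((...))..))", 4, 2, 2, 1),
            ("((.((...))))", 4, 2, 3, 1),
            ("((...))", 2, 1, 1, 1),          # hairpin of 3 gives no eos term
            ("((....))", 2, 1, 1, 2),         # hairpin of 4 does
            ("((..((...))...))", 4, 2, 2, 3),  # 2x3 internal loop: one per end
        ],
    )
    def test_examples(self, db, n_bp, n_regions, n_stack, n_eos):
        f = compute_features(parse_structure(db))
        assert (f.n_bp, f.n_stack_regions, f.n_stack, f.n_eos) == (
            n_bp, n_regions, n_stack, n_eos,
        )

    def test_invariants_over_enumeration(self):
        for s in enumerate_structures(StructureConstraints(L=12, no_lonely_pairs=False)):
            f = compute_features(s)
            assert f.n_stack >= f.n_bp - f.n_stack_regions
            assert f.n_eos <= 2 * f.n_stack_regions
            assert f.loop_inventory.total_unpaired + 2 * f.n_bp == s.length


class TestCompatibleCount:
    def test_no_pairs(self):
        assert compatible_sequence_count(35, 0) == 4**35

    def test_small(self):
        assert compatible_sequence_count(7, 2) == 2304

    def test_exact_big_integer(self):
        # independent arbitrary-precision oracle: repeated multiplication
        expected = 1
        for _ in range(17):
            expected *= 4
        for _ in range(9):
            expected *= 6
        assert compatible_sequence_count(35, 9) == expected

    def test_non_increasing_in_n_bp(self):
        counts = [compatible_sequence_count(35, k) for k in range(0, 18)]
        assert all(a > b for a, b in zip(counts, counts[1:]))

    def test_log10_matches(self):
        assert log10_compatible_sequence_count(35, 9) == pytest.approx(
            math.log10(compatible_sequence_count(35, 9))
        )

    def test_rejects_bad_n_bp(self):
        with pytest.raises(ValueError):
            compatible_sequence_count(7, 4)
        with pytest.raises(ValueError):
            compatible_sequence_count(7, -1)
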