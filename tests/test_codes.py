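import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from difftree.codes import (
    BinaryCode,
    apply_ordering_overrides,
    assign_codes,
    decode,
    hamming_bin_label,
    hamming_distance,
    hamming_table,
    isometric_coordinates,
    order_differentiation,
    random_code_null,
    spatial_hamming_export,
)
from difftree.lineage import CellNode, LineageTree, LineageValidationError
from difftree.simulate import SimulationConfig, simulate_code_shuffle, simulate_tree

from conftest import make_tree


class TestOrderDifferentiation:
    def test_smaller_moves_left(self):
        tree = make_tree([("P0", None, 1.0), ("AB", "P0", 0.51), ("P1", "P0", 0.49)])
        out = order_differentiation(tree)
        assert out.children["P0"] == ["P1", "AB"]
        assert out.ordering_kind == "differentiation"

    def test_all_symmetric_keeps_order_and_flags(self):
        tree = make_tree(
            [
                ("P0", None, 1.0),
                ("AB", "P0", 0.5),
                ("P1", "P0", 0.5),
                ("ABa", "AB", 0.25),
                ("ABp", "AB", 0.25),
                ("P2", "P1", 0.25),
                ("EMS", "P1", 0.25),
            ]
        )
        out = order_differentiation(tree)
        assert out.children == tree.children
        assert out.tie_flags == {"P0", "AB", "P1"}

    def test_idempotent_on_ordered_tree(self, depth3_tree):
        once = order_differentiation(depth3_tree)
        twice = order_differentiation(once)
        assert twice.children == once.children

    def test_missing_volume_falls_back_flagged(self):
        tree = make_tree([("P0", None, 1.0), ("AB", "P0", None), ("P1", "P0", 0.45)])
        out = order_differentiation(tree)
        assert out.children["P0"] == ["AB", "P1"]
        assert out.unknown_flags == {"P0"}

    def test_name_tie_policy(self):
        tree = make_tree([("P0", None, 1.0), ("Zb", "P0", 0.5), ("Aa", "P0", 0.5)])
        out = order_differentiation(tree, tie_policy="name")
        assert out.children["P0"] == ["Aa", "Zb"]

    def test_epsilon_widens_ties(self):
        tree = make_tree([("P0", None, 1.0), ("AB", "P0", 0.51), ("P1", "P0", 0.49)])
        out = order_differentiation(tree, tie_epsilon=0.05)
        assert out.tie_flags == {"P0"}
        assert out.children["P0"] == ["AB", "P1"]

    def test_topology_preserved(self, sim_tree):
        out = order_differentiation(sim_tree)
        assert {(m, frozenset(k)) for m, k in out.children.items()} == {
            (m, frozenset(k)) for m, k in sim_tree.children.items()
        }


class TestOverrides:
    def test_override_fixes_stated_division(self):
        tree = make_tree([("P0", None, 1.0), ("AB", "P0", 0.55), ("P1", "P0", 0.45)])
        ordered = order_differentiation(tree)
        assert ordered.children["P0"] == ["P1", "AB"]
        out = apply_ordering_overrides(ordered, {"P0": ("AB", "P1")})
        assert out.children["P0"] == ["AB", "P1"]
        assert out.ordering_kind == "composite"

    def test_empty_overrides_equal_differentiation(self, depth3_tree):
        ordered = order_differentiation(depth3_tree)
        out = apply_ordering_overrides(ordered, {})
        assert out.children == ordered.children

    def test_non_sibling_pair_rejected(self, depth3_tree):
        ordered = order_differentiation(depth3_tree)
        with pytest.raises(LineageValidationError):
            apply_ordering_overrides(ordered, {"Ra": ("Raa", "Rba")})

    def test_unknown_mother_rejected(self, depth3_tree):
        ordered = order_differentiation(depth3_tree)
        with pytest.raises(LineageValidationError, match="unknown cell"):
            apply_ordering_overrides(ordered, {"nope": ("Raa", "Rab")})


class TestAssignCodes:
    def test_root_and_children(self, three_cell_tree):
        codes = assign_codes(three_cell_tree)
        assert codes["P0"].bits == ()
        assert codes["AB"].bits == (0,)
        assert codes["P1"].bits == (1,)

    def test_path_concatenation(self, depth3_tree):
        codes = assign_codes(depth3_tree)
        assert codes["Raab"].bits == (0, 0, 1)

    def test_child_extends_parent_by_one_bit(self, sim_tree):
        codes = assign_codes(sim_tree)
        for name, node in sim_tree.nodes.items():
            if node.parent_name is not None:
                parent_bits = codes[node.parent_name].bits
                assert codes[name].bits[:-1] == parent_bits

    def test_codes_unique_and_length_equals_depth(self, sim_tree):
        codes = assign_codes(sim_tree)
        assert len({c.bits for c in codes.values()}) == len(sim_tree)
        for name, code in codes.items():
            assert len(code) == sim_tree.depth(name)

    def test_sorted_codes_enumerate_left_to_right_order(self):
        # oracle: explicit tree traversal on a 16-leaf simulated tree
        tree = simulate_tree(SimulationConfig(max_depth=4, seed=3))
        codes = assign_codes(tree)
        for m in range(5):
            level = tree.cells_at_depth(m)
            by_code = sorted(level, key=lambda c: codes[c].bits)
            assert by_code == level

    def test_decode_inverts_codes(self, sim_tree):
        codes = assign_codes(sim_tree)
        for name, code in codes.items():
            assert decode(sim_tree, code.bits) == name


class TestHamming:
    def test_identity(self):
        assert hamming_distance([0, 1, 0, 1], [0, 1, 0, 1]) == 0

    def test_complement(self):
        assert hamming_distance([0, 0, 0], [1, 1, 1]) == 3

    def test_hand_counted(self):
        assert hamming_distance([0, 1, 1, 0], [1, 1, 0, 0]) == 2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            hamming_distance([0, 1], [0, 1, 0])

    @given(
        st.lists(st.integers(0, 1), min_size=0, max_size=12),
        st.lists(st.integers(0, 1), min_size=0, max_size=12),
    )
    def test_symmetric_and_bounded(self, a, b):
        if len(a) != len(b):
            with pytest.raises(ValueError):
                hamming_distance(a, b)
            return
        d = hamming_distance(a, b)
        assert d == hamming_distance(b, a)
        assert 0 <= d <= len(a)


class TestHammingTable:
    def test_volume_ordered_layout_gives_all_zero(self):
        tree = make_tree(
            [
                ("P0", None, 1.0),
                ("P1", "P0", 0.45),
                ("AB", "P0", 0.55),
                ("P2", "P1", 0.2),
                ("EMS", "P1", 0.25),
            ]
        )
        table = hamming_table(tree)
        assert (table["hamming"] == 0).all()

    def test_root_swap_flips_leading_bit_everywhere(self):
        # exhaustive oracle on a complete depth-3 tree: swapping the root's
        # children changes bit 1 of every non-root cell
        rows = [("R", None, 1.0), ("Ra", "R", 0.6), ("Rb", "R", 0.4)]
        for name, vol in [("Ra", 0.3), ("Rb", 0.2)]:
            rows += [(name + "a", name, vol / 2 - 0.02), (name + "b", name, vol / 2 + 0.02)]
        for name in ["Raa", "Rab", "Rba", "Rbb"]:
            rows += [(name + "a", name, 0.04), (name + "b", name, 0.06)]
        tree = make_tree(rows)
        table = hamming_table(tree).set_index("cell")
        assert (table.loc[table["depth"] > 0, "hamming"] >= 1).all()

    def test_swap_affects_only_subtree(self, sim_tree):
        ordered = order_differentiation(sim_tree)
        mother = next(m for m, _, _ in sim_tree.divisions() if sim_tree.depth(m) == 2)
        swapped_children = {m: list(k) for m, k in ordered.children.items()}
        swapped_children[mother] = list(reversed(swapped_children[mother]))
        swapped = ordered.with_children(swapped_children, "differentiation")
        before = hamming_table(sim_tree, ordered).set_index("cell")["hamming"]
        after = hamming_table(sim_tree, swapped).set_index("cell")["hamming"]
        subtree = set()
        stack = [mother]
        while stack:
            n = stack.pop()
            subtree.add(n)
            stack.extend(sim_tree.children.get(n, ()))
        changed = set(before.index[before != after])
        assert changed <= subtree - {mother}

    def test_hamming_bounded_by_depth(self, sim_tree):
        table = hamming_table(sim_tree)
        assert (table["hamming"] <= table["depth"]).all()

    def test_requires_lineage_ordering(self, sim_tree):
        with pytest.raises(LineageValidationError):
            hamming_table(order_differentiation(sim_tree))


class TestIsometric:
    def test_root_at_origin(self, sim_tree):
        iso = isometric_coordinates(sim_tree)
        root = iso[iso["m"] == 0].iloc[0]
        assert (root["x"], root["y"]) == (0, 0)

    def test_complete_depth5_crosses_axes_at_31(self):
        tree = simulate_tree(SimulationConfig(max_depth=5, seed=0))
        iso = isometric_coordinates(tree)
        level = iso[iso["m"] == 5]
        assert len(level) == 32
        assert level["x"].min() == 0 and level["x"].max() == 31
        assert level["y"].min() == 0 and level["y"].max() == 31

    def test_xy_sum_invariant(self, sim_tree):
        iso = isometric_coordinates(sim_tree)
        counts = iso.groupby("m")["cell"].transform("size")
        assert ((iso["x"] + iso["y"]) == counts - 1).all()

    def test_points_per_isoline_match_depth_counts(self, sim_tree):
        iso = isometric_coordinates(sim_tree)
        for m, group in iso.groupby("m"):
            assert len(group) == len(sim_tree.cells_at_depth(m))

    def test_bin_labels(self):
        assert hamming_bin_label(0) == "0"
        assert hamming_bin_label(2) == "1-3"
        assert hamming_bin_label(5) == "4-6"
        assert hamming_bin_label(11) == "7+"


class TestRandomNull:
    def test_deterministic_by_seed(self, sim_tree):
        a = random_code_null(sim_tree, 3, seed=9)
        b = random_code_null(sim_tree, 3, seed=9)
        assert a.equals(b)

    def test_depth1_equal_frequencies(self):
        tree = make_tree([("P0", None, 1.0), ("A", "P0", 0.5), ("B", "P0", 0.5)])
        null = random_code_null(tree, 10_000, seed=11)
        per_rep = null[null["depth"] == 1].groupby("replicate")["hamming"].sum()
        # each replicate flips the single division w.p. 1/2 -> DH sums to 0 or 2
        frac_flipped = (per_rep == 2).mean()
        assert abs(frac_flipped - 0.5) < 0.02  # ~4 sigma at n=10,000

    def test_mean_hamming_half_depth(self):
        # complete tree: each of the d bits flips independently w.p. 1/2,
        # so E[DH at depth d] = d/2 (exhaustively true at small depth)
        tree = simulate_tree(SimulationConfig(max_depth=4, seed=5))
        null = random_code_null(tree, 400, seed=12)
        means = null.groupby("depth")["hamming"].mean()
        for d in range(5):
            assert means[d] == pytest.approx(d / 2, abs=0.15)


class TestSpatialExport:
    def test_no_positions_gives_empty_table(self, sim_tree, caplog):
        with caplog.at_level("WARNING"):
            out = spatial_hamming_export(sim_tree)
        assert out.empty
        assert "dropped" in caplog.text

    def test_join_consistency(self):
        nodes = [
            CellNode("P0", None, 1.0, position=(0.0, 0.0, 0.0)),
            CellNode("AB", "P0", 0.55, position=(1.0, 0.0, 0.0)),
            CellNode("P1", "P0", 0.45, position=(-1.0, 0.0, 0.0)),
        ]
        tree = LineageTree(nodes)
        out = spatial_hamming_export(tree).set_index("cell")
        ham = hamming_table(tree).set_index("cell")
        assert len(out) == 3
        for cell in out.index:
            assert out.loc[cell, "hamming"] == ham.loc[cell, "hamming"]


class TestShuffle:
    def test_volumes_topology_unchanged(self, sim_tree):
        shuffled = simulate_code_shuffle(sim_tree, seed=4)
        assert {(m, frozenset(k)) for m, k in shuffled.children.items()} == {
            (m, frozenset(k)) for m, k in sim_tree.children.items()
        }
        for name in sim_tree.nodes:
            assert shuffled.nodes[name].volume == sim_tree.nodes[name].volume

    def test_deterministic(self, sim_tree):
        a = simulate_code_shuffle(sim_tree, seed=4)
        b = simulate_code_shuffle(sim_tree, seed=4)
        assert a.children == b.children

    def test_swap_fraction_near_half(self):
        tree = simulate_tree(SimulationConfig(max_depth=9, seed=2))
        shuffled = simulate_code_shuffle(tree, seed=13)
        swapped = sum(
            shuffled.children[m] != tree.children[m] for m in tree.children
        )
        frac = swapped / len(tree.children)
        assert abs(frac - 0.5) < 0.05  # binomial, n=511
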