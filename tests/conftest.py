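import pandas as pd
import pytest

from difftree.lineage import CellNode, LineageTree
from difftree.simulate import SimulationConfig, simulate_tree


def make_tree(rows, units="relative"):
    """rows: (name, parent, volume[, birth, division]) tuples, in child order."""
    nodes = []
    for row in rows:
        name, parent, volume = row[:3]
        birth = row[3] if len(row) > 3 else None
        division = row[4] if len(row) > 4 else None
        nodes.append(
            CellNode(
                name=name,
                parent_name=parent,
                volume=volume,
                birth_time=birth,
                division_time=division,
            )
        )
    return LineageTree(nodes, volume_units=units)


@pytest.fixture
def three_cell_tree():
    return make_tree(
        [
            ("P0", None, 1.0, 0.0, 10.0),
            ("AB", "P0", 0.55, 10.0, 28.0),
            ("P1", "P0", 0.45, 10.0, 32.0),
        ]
    )


@pytest.fixture
def depth3_tree():
    """Complete depth-3 tree; lineage order deliberately disagrees with
    volume order at the root and at one depth-2 division."""
    rows = [
        ("R", None, 1.0),
        ("Ra", "R", 0.6),  # larger on the left: root disagrees
        ("Rb", "R", 0.4),
        ("Raa", "Ra", 0.25),
        ("Rab", "Ra", 0.35),
        ("Rba", "Rb", 0.3),  # larger on the left: disagrees
        ("Rbb", "Rb", 0.1),
        ("Raaa", "Raa", 0.1),
        ("Raab", "Raa", 0.15),
        ("Raba", "Rab", 0.15),
        ("Rabb", "Rab", 0.2),
        ("Rbaa", "Rba", 0.1),
        ("Rbab", "Rba", 0.2),
        ("Rbba", "Rbb", 0.04),
        ("Rbbb", "Rbb", 0.06),
    ]
    return make_tree(rows)


@pytest.fixture
def sim_tree():
    return simulate_tree(SimulationConfig(max_depth=6, seed=42, asym_fraction=0.3))


@pytest.fixture
def timed_sim_tree():
    return simulate_tree(
        SimulationConfig(
            max_depth=6,
            seed=7,
            asym_fraction=0.25,
            lifetime_exponent=-0.6,
            lifetime_noise_cv=0.05,
        )
    )
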