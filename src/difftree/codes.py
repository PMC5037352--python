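"""Binary tree codes: orderings, addresses, Hamming distances, isometric maps.

Every cell in a rooted ordered binary tree gets an address: the string of
0 (left branch) / 1 (right branch) choices along its root path.  Reordering
the tree by a different criterion (anatomy vs relative volume) changes the
addresses but not the topology, and the per-cell Hamming distance between
the two address systems measures how much the criteria disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from difftree.lineage import LineageTree, LineageValidationError

logger = logging.getLogger(__name__)

#: display bins for Hamming distances: {0}, {1-3}, {4-6}, {7+}
DEFAULT_HAMMING_BINS: Tuple[int, ...] = (0, 1, 4, 7)

TIE_POLICIES = ("lineage", "name", "flag-only")


@dataclass(frozen=True)
class BinaryCode:
    """Address of one cell under a given tree ordering.

    ``bits[i]`` is 0 if the path from the root takes the left branch at
    depth ``i``, 1 for the right branch; ``len(bits)`` equals the cell's
    depth, so the root carries the empty code.
    """

    cell: str
    ordering: str
    bits: Tuple[int, ...]

    def __str__(self) -> str:
        return "".join(map(str, self.bits))

    def __len__(self) -> int:
        return len(self.bits)


# ---------------------------------------------------------------------------
# Orderings
# ---------------------------------------------------------------------------


def order_differentiation(
    tree: LineageTree,
    tie_policy: str = "lineage",
    tie_epsilon: float = 0.0,
) -> LineageTree:
    """Reorder every division so the smaller daughter is on the left.

    Topology is untouched; only left/right order changes.  Sibling pairs
    whose relative volume difference ``|v_i - v_j| / (v_i + v_j)`` does not
    exceed ``tie_epsilon`` (default: strict equality only) are ties and are
    resolved by ``tie_policy``:

    - ``lineage`` / ``flag-only``: keep the incoming order;
    - ``name``: sort by cell name.

    Divisions with a missing sibling volume fall back to the incoming
    order as well.  Both kinds of fallback are flagged on the result
    (``tie_flags`` / ``unknown_flags``).
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    children: Dict[str, List[str]] = {}
    ties: set[str] = set()
    unknown: set[str] = set()
    for mother, left, right in tree.divisions():
        vl = tree.nodes[left].volume
        vr = tree.nodes[right].volume
        if vl is None or vr is None:
            children[mother] = [left, right]
            unknown.add(mother)
            continue
        total = vl + vr
        if total == 0 or abs(vl - vr) / total <= tie_epsilon:
            pair = sorted((left, right)) if tie_policy == "name" else [left, right]
            children[mother] = list(pair)
            ties.add(mother)
        elif vl <= vr:
            children[mother] = [left, right]
        else:
            children[mother] = [right, left]
    out = tree.with_children(children, "differentiation")
    out.tie_flags = ties
    out.unknown_flags = unknown
    return out


def apply_ordering_overrides(
    tree: LineageTree, overrides: Mapping[str, Sequence[str]]
) -> LineageTree:
    """Fix the child order of stated divisions, volume order elsewhere.

    Used to build a composite ordering when external knowledge (e.g. cell
    polarity at the earliest stages) overrides measured volumes.  ``tree``
    should already carry a differentiation ordering; each override maps a
    mother to the desired ordered pair of exactly its two children.
    """
    if tree.ordering_kind == "lineage":
        tree = order_differentiation(tree)
    children = {m: list(k) for m, k in tree.children.items()}
    for mother, pair in overrides.items():
        if mother not in tree.nodes:
            raise LineageValidationError(f"override names unknown cell {mother!r}")
        pair = list(pair)
        if sorted(pair) != sorted(children.get(mother, [])):
            raise LineageValidationError(
                f"override for {mother!r} does not list exactly its two "
                f"children {children.get(mother)}"
            )
        children[mother] = pair
    out = tree.with_children(children, "composite")
    out.tie_flags = set(tree.tie_flags) - set(overrides)
    out.unknown_flags = set(tree.unknown_flags) - set(overrides)
    return out


# ---------------------------------------------------------------------------
# Codes
# ---------------------------------------------------------------------------


def assign_codes(tree: LineageTree) -> Dict[str, BinaryCode]:
    """Assign every cell its 0/1 root-path address under the active ordering."""
    kind = tree.ordering_kind
    codes: Dict[str, BinaryCode] = {
        tree.root: BinaryCode(tree.root, kind, ())
    }
    stack = [tree.root]
    while stack:
        name = stack.pop()
        for bit, kid in enumerate(tree.children.get(name, ())):
            codes[kid] = BinaryCode(kid, kind, codes[name].bits + (bit,))
            stack.append(kid)
    return codes


def decode(tree: LineageTree, bits: Sequence[int]) -> str:
    """Walk a code from the root back down to the cell it addresses."""
    name = tree.root
    for bit in bits:
        kids = tree.children.get(name)
        if not kids:
            raise KeyError(f"code {list(bits)} walks past terminal cell {name!r}")
        name = kids[bit]
    return name


def hamming_distance(
    x: BinaryCode | Sequence[int], y: BinaryCode | Sequence[int]
) -> int:
    """Number of differing bit positions between two equal-length codes."""
    xb = x.bits if isinstance(x, BinaryCode) else tuple(x)
    yb = y.bits if isinstance(y, BinaryCode) else tuple(y)
    if len(xb) != len(yb):
        raise ValueError(
            f"codes differ in length ({len(xb)} vs {len(yb)}); the Hamming "
            "distance is defined for cells at the same depth"
        )
    return sum(a != b for a, b in zip(xb, yb))


def hamming_table(
    tree: LineageTree,
    ordered_tree: Optional[LineageTree] = None,
    tie_policy: str = "lineage",
) -> pd.DataFrame:
    """Per-cell comparison of lineage vs differentiation addresses.

    ``tree`` supplies the lineage ordering; ``ordered_tree`` the
    differentiation (or composite) ordering, computed from ``tree``'s
    volumes when not given.  Returns one row per cell with columns
    ``cell, depth, lineage_code, differentiation_code, hamming``.
    """
    if tree.ordering_kind != "lineage":
        raise LineageValidationError(
            "hamming_table needs the tree in its lineage ordering"
        )
    if ordered_tree is None:
        ordered_tree = order_differentiation(tree, tie_policy=tie_policy)
    lin = assign_codes(tree)
    diff = assign_codes(ordered_tree)
    rows = []
    for name in tree.preorder():
        rows.append(
            {
                "cell": name,
                "depth": tree.depth(name),
                "lineage_code": str(lin[name]),
                "differentiation_code": str(diff[name]),
                "hamming": hamming_distance(lin[name], diff[name]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Isometric graph coordinates
# ---------------------------------------------------------------------------


def hamming_bin_label(h: int, edges: Sequence[int] = DEFAULT_HAMMING_BINS) -> str:
    """Display bin for a Hamming distance, default {0}, {1-3}, {4-6}, {7+}."""
    edges = sorted(edges)
    for lo, hi in zip(edges, edges[1:]):
        if lo <= h < hi:
            return str(lo) if hi - lo == 1 else f"{lo}-{hi - 1}"
    return f"{edges[-1]}+"


def isometric_coordinates(
    tree: LineageTree,
    reference_ordering: str = "differentiation",
    ordered_tree: Optional[LineageTree] = None,
    bin_edges: Sequence[int] = DEFAULT_HAMMING_BINS,
) -> pd.DataFrame:
    """Project the depth-layered tree onto isometric (x, y) grid lines.

    Each cell at depth ``m`` with left-to-right order ``n`` (0-based, in
    the reference ordering) among the ``N_m`` cells of that depth maps to
    ``x = n``, ``y = N_m - 1 - n``, so every depth lies on the diagonal
    ``x + y = N_m - 1`` and the root sits at (0, 0).  ``N_m`` is counted
    from the actual tree, which may be incomplete.
    """
    if reference_ordering not in ("lineage", "differentiation"):
        raise ValueError(f"unknown reference ordering {reference_ordering!r}")
    if ordered_tree is None:
        ordered_tree = order_differentiation(tree)
    ham = hamming_table(tree, ordered_tree).set_index("cell")["hamming"]
    ref = tree if reference_ordering == "lineage" else ordered_tree
    rows = []
    for m in range(ref.max_depth + 1):
        level = ref.cells_at_depth(m)
        n_m = len(level)
        for n, cell in enumerate(level):
            h = int(ham[cell])
            rows.append(
                {
                    "cell": cell,
                    "m": m,
                    "n": n,
                    "x": n,
                    "y": n_m - 1 - n,
                    "hamming": h,
                    "hamming_bin": hamming_bin_label(h, bin_edges),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Random-ordering null
# ---------------------------------------------------------------------------


def random_code_null(
    shape_tree: LineageTree, n_replicates: int, seed: int
) -> pd.DataFrame:
    """Null distribution of per-cell Hamming distances under random ordering.

    For each replicate the left/right order of every division is redrawn
    uniformly at random and each cell's address is compared with its
    address in ``shape_tree``'s own ordering.  Returns a long table with
    columns ``replicate, cell, depth, hamming``; reproducible by seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    base = assign_codes(shape_tree)
    mothers = [m for m, _, _ in shape_tree.divisions()]
    rows = []
    for rep in range(n_replicates):
        flips = dict(zip(mothers, rng.integers(0, 2, size=len(mothers))))
        children = {
            m: (list(reversed(k)) if flips[m] else list(k))
            for m, k in shape_tree.children.items()
        }
        shuffled = shape_tree.with_children(children, shape_tree.ordering_kind)
        codes = assign_codes(shuffled)
        for name in shape_tree.preorder():
            rows.append(
                {
                    "replicate": rep,
                    "cell": name,
                    "depth": shape_tree.depth(name),
                    "hamming": hamming_distance(base[name], codes[name]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spatial join
# ---------------------------------------------------------------------------


def spatial_hamming_export(
    tree: LineageTree, ordered_tree: Optional[LineageTree] = None
) -> pd.DataFrame:
    """Join nucleus positions with per-cell Hamming distances.

    Cells without a recorded position are dropped (count logged); the
    result (columns ``cell, x, y, z, hamming``) is ready for 3D scatter
    plotting.
    """
    ham = hamming_table(tree, ordered_tree)
    rows = []
    dropped = 0
    for _, row in ham.iterrows():
        pos = tree.nodes[row["cell"]].position
        if pos is None:
            dropped += 1
            continue
        rows.append(
            {
                "cell": row["cell"],
                "x": pos[0],
                "y": pos[1],
                "z": pos[2],
                "hamming": row["hamming"],
            }
        )
    if dropped:
        logger.warning("spatial export dropped %d cell(s) without positions", dropped)
    return pd.DataFrame(rows, columns=["cell", "x", "y", "z", "hamming"])
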