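"""Rooted binary cell-lineage trees: data model, table/Newick I/O, validation.

A lineage tree is a rooted, planar, ordered binary tree whose nodes are
named cells.  Every internal node has exactly two ordered children; the
left/right order carries meaning (anatomical position for a lineage
ordering, relative daughter volume for a differentiation ordering) and is
the only thing downstream re-orderings are allowed to change.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column names of the lineage-table dialect
TABLE_COLUMNS = (
    "cell",
    "parent",
    "volume",
    "birth_time",
    "division_time",
    "x",
    "y",
    "z",
    "side",
)

ORDERING_KINDS = ("lineage", "differentiation", "composite")


class LineageValidationError(ValueError):
    """Raised when a table or tree violates the binary-lineage invariants."""


@dataclass
class CellNode:
    """One cell: identity, parentage, volume, timing and nucleus position.

    ``volume`` may be a relative fraction of the embryo or an absolute
    volume; the owning tree records the units and all downstream
    statistics use only ratios/differences of sibling volumes.
    """

    name: str
    parent_name: Optional[str]
    volume: Optional[float] = None
    birth_time: Optional[float] = None
    division_time: Optional[float] = None
    position: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.volume is not None and self.volume < 0:
            raise LineageValidationError(
                f"negative volume for cell {self.name!r}: {self.volume}"
            )
        if (
            self.birth_time is not None
            and self.division_time is not None
            and self.division_time < self.birth_time
        ):
            raise LineageValidationError(
                f"cell {self.name!r} divides before it is born "
                f"({self.division_time} < {self.birth_time})"
            )


class LineageTree:
    """Rooted binary tree of :class:`CellNode` with an active child ordering.

    Parameters
    ----------
    nodes:
        The cells, keyed or listed; parent links must describe a single
        rooted tree in which every internal node has exactly two children.
    children:
        Optional explicit ordered-children map (name -> ordered names).
        When omitted it is derived from parent links in node order.
    ordering_kind:
        Which convention the current left/right order follows; one of
        ``lineage``, ``differentiation``, ``composite``.
    volume_units:
        Free-text unit tag (e.g. ``"relative"`` or ``"um^3"``).
    """

    def __init__(
        self,
        nodes: Sequence[CellNode] | Mapping[str, CellNode],
        children: Optional[Mapping[str, Sequence[str]]] = None,
        ordering_kind: str = "lineage",
        volume_units: str = "relative",
    ) -> None:
        if isinstance(nodes, Mapping):
            node_list = list(nodes.values())
        else:
            node_list = list(nodes)
        self.nodes: Dict[str, CellNode] = {}
        for node in node_list:
            if node.name in self.nodes:
                raise LineageValidationError(f"duplicate cell name {node.name!r}")
            self.nodes[node.name] = node

        if children is None:
            derived: Dict[str, List[str]] = {}
            for node in node_list:
                if node.parent_name is not None:
                    derived.setdefault(node.parent_name, []).append(node.name)
            children = derived
        self.children: Dict[str, List[str]] = {
            name: list(kids) for name, kids in children.items() if kids
        }
        if ordering_kind not in ORDERING_KINDS:
            raise LineageValidationError(f"unknown ordering kind {ordering_kind!r}")
        self.ordering_kind = ordering_kind
        self.volume_units = volume_units
        #: mothers whose child order could not be decided by volume
        self.tie_flags: set[str] = set()
        #: mothers excluded from volume ordering for lack of sibling volumes
        self.unknown_flags: set[str] = set()
        self._validate()
        self._depths = self._compute_depths()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        roots = [n.name for n in self.nodes.values() if n.parent_name is None]
        if len(roots) != 1:
            raise LineageValidationError(
                f"expected exactly one root, found {len(roots)}: {roots}"
            )
        self._root = roots[0]
        for node in self.nodes.values():
            if node.parent_name is not None and node.parent_name not in self.nodes:
                raise LineageValidationError(
                    f"cell {node.name!r} references unknown parent "
                    f"{node.parent_name!r}"
                )
        for mother, kids in self.children.items():
            if mother not in self.nodes:
                raise LineageValidationError(f"unknown mother {mother!r}")
            if len(kids) == 1:
                raise LineageValidationError(
                    f"non-binary division: {mother!r} has a single recorded "
                    f"child {kids[0]!r} (missing sibling)"
                )
            if len(kids) > 2:
                raise LineageValidationError(
                    f"non-binary division: {mother!r} has {len(kids)} children"
                )
            for kid in kids:
                if self.nodes[kid].parent_name != mother:
                    raise LineageValidationError(
                        f"child map lists {kid!r} under {mother!r} but its "
                        f"parent is {self.nodes[kid].parent_name!r}"
                    )
        # reachability from the root doubles as the cycle check: parent
        # links always form a functional graph, and with one root plus
        # full reachability that graph is a tree.
        seen = set()
        stack = [self._root]
        while stack:
            name = stack.pop()
            if name in seen:
                raise LineageValidationError(f"cycle detected at {name!r}")
            seen.add(name)
            stack.extend(self.children.get(name, ()))
        if seen != set(self.nodes):
            orphans = sorted(set(self.nodes) - seen)
            raise LineageValidationError(
                f"cells unreachable from root {self._root!r}: {orphans}"
            )
        for node in self.nodes.values():
            if node.parent_name is None:
                continue
            mother = self.nodes[node.parent_name]
            if (
                node.birth_time is not None
                and mother.division_time is not None
                and not math.isclose(
                    node.birth_time, mother.division_time, rel_tol=1e-6, abs_tol=1e-6
                )
            ):
                warnings.warn(
                    f"birth time of {node.name!r} ({node.birth_time}) differs "
                    f"from division time of its mother {mother.name!r} "
                    f"({mother.division_time})",
                    stacklevel=2,
                )

    def _compute_depths(self) -> Dict[str, int]:
        depths = {self._root: 0}
        stack = [self._root]
        while stack:
            name = stack.pop()
            for kid in self.children.get(name, ()):
                depths[kid] = depths[name] + 1
                stack.append(kid)
        return depths

    # -- queries --------------------------------------------------------

    @property
    def root(self) -> str:
        return self._root

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def depth(self, name: str) -> int:
        """Number of tree edges from the root to ``name``."""
        return self._depths[name]

    @property
    def max_depth(self) -> int:
        return max(self._depths.values())

    def cells_at_depth(self, m: int) -> List[str]:
        """Cells at exactly depth ``m`` in left-to-right tree order."""
        out: List[str] = []

        def walk(name: str) -> None:
            if self._depths[name] == m:
                out.append(name)
                return
            for kid in self.children.get(name, ()):
                walk(kid)

        walk(self._root)
        return out

    def is_terminal(self, name: str) -> bool:
        return name not in self.children

    def divisions(self) -> Iterator[Tuple[str, str, str]]:
        """Yield (mother, left child, right child) in preorder."""
        stack = [self._root]
        while stack:
            name = stack.pop()
            kids = self.children.get(name)
            if kids:
                yield name, kids[0], kids[1]
                stack.extend(reversed(kids))

    def preorder(self) -> Iterator[str]:
        stack = [self._root]
        while stack:
            name = stack.pop()
            yield name
            stack.extend(reversed(self.children.get(name, ())))

    def check_volume_conservation(self, rel_tol: float = 0.10) -> List[str]:
        """Warn about divisions whose daughter volumes do not sum to the mother.

        Returns the offending mother names.  Nucleus-derived volumes are not
        expected to conserve volume, so this is diagnostic only.
        """
        bad: List[str] = []
        for mother, left, right in self.divisions():
            vm = self.nodes[mother].volume
            vl = self.nodes[left].volume
            vr = self.nodes[right].volume
            if vm in (None, 0) or vl is None or vr is None:
                continue
            if abs((vl + vr) - vm) / vm > rel_tol:
                bad.append(mother)
        if bad:
            logger.warning(
                "daughter volumes deviate from mother volume by more than "
                "%.0f%% at %d division(s): %s",
                rel_tol * 100,
                len(bad),
                ", ".join(bad[:10]),
            )
        return bad

    # -- copies / reorderings ------------------------------------------

    def with_children(
        self, children: Mapping[str, Sequence[str]], ordering_kind: str
    ) -> "LineageTree":
        """Same nodes, new child order (topology must be preserved)."""
        new = LineageTree(
            [replace(n) for n in self.nodes.values()],
            children=children,
            ordering_kind=ordering_kind,
            volume_units=self.volume_units,
        )
        if {(m, frozenset(k)) for m, k in new.children.items()} != {
            (m, frozenset(k)) for m, k in self.children.items()
        }:
            raise LineageValidationError("reordering changed tree topology")
        return new

    def copy(self) -> "LineageTree":
        out = self.with_children(self.children, self.ordering_kind)
        out.tie_flags = set(self.tie_flags)
        out.unknown_flags = set(self.unknown_flags)
        return out


def cell_lifetime(tree: LineageTree, cell: str) -> Optional[float]:
    """Time from a cell's birth by division to its own division, in minutes.

    Returns ``None`` when either timestamp is missing (e.g. terminal cells
    that never divide).
    """
    if cell not in tree.nodes:
        raise KeyError(f"unknown cell {cell!r}")
    node = tree.nodes[cell]
    if node.birth_time is None or node.division_time is None:
        return None
    return node.division_time - node.birth_time


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def _sulston_parent(name: str, names: set[str]) -> Optional[str]:
    # Sulston-style nomenclature: child name = mother name + one character
    if len(name) > 1 and name[:-1] in names:
        return name[:-1]
    return None


def read_lineage_table(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    units: str = "relative",
    sep: Optional[str] = None,
) -> LineageTree:
    """Read a per-cell lineage table (CSV/TSV) into a :class:`LineageTree`.

    Expected columns (renameable via ``column_map``, mapping canonical ->
    actual): ``cell`` and ``parent`` (required; ``parent`` empty for the
    root), plus optional ``volume``, ``birth_time``, ``division_time``,
    ``x``, ``y``, ``z`` and ``side`` (``L``/``R``).  Child order is the row
    order unless ``side`` is given.  If the ``parent`` column is absent
    entirely, Sulston-style nomenclature (child = mother name + one
    character) is used as a fallback.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return lineage_table_to_tree(df, units=units)


def lineage_table_to_tree(df: pd.DataFrame, units: str = "relative") -> LineageTree:
    """Build a validated tree from an in-memory lineage table."""
    if "cell" not in df.columns:
        raise LineageValidationError("lineage table lacks a 'cell' column")
    names = [str(c) for c in df["cell"]]
    name_set = set(names)
    if len(name_set) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise LineageValidationError(f"duplicate cell names: {dupes}")

    have_parent_col = "parent" in df.columns

    def opt(row: pd.Series, col: str) -> Optional[float]:
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    nodes: List[CellNode] = []
    order: Dict[str, List[Tuple[int, str, str]]] = {}
    for i, (_, row) in enumerate(df.iterrows()):
        name = str(row["cell"])
        parent: Optional[str] = None
        if have_parent_col and not pd.isna(row["parent"]) and str(row["parent"]):
            parent = str(row["parent"])
        elif _sulston_parent(name, name_set):
            parent = _sulston_parent(name, name_set)
        pos = None
        if all(opt(row, c) is not None for c in ("x", "y", "z")):
            pos = (float(row["x"]), float(row["y"]), float(row["z"]))
        nodes.append(
            CellNode(
                name=name,
                parent_name=parent,
                volume=opt(row, "volume"),
                birth_time=opt(row, "birth_time"),
                division_time=opt(row, "division_time"),
                position=pos,
            )
        )
        if parent is not None:
            side = ""
            if "side" in row and not pd.isna(row["side"]):
                side = str(row["side"]).strip().upper()
            order.setdefault(parent, []).append((i, side, name))

    children: Dict[str, List[str]] = {}
    for mother, entries in order.items():
        sides = {s for _, s, _ in entries if s}
        if sides == {"L", "R"} and len(entries) == 2:
            entries = sorted(entries, key=lambda t: t[1] != "L")
        else:
            entries = sorted(entries)
        children[mother] = [n for _, _, n in entries]

    return LineageTree(nodes, children=children, volume_units=units)


def write_lineage_table(tree: LineageTree, path: str | Path) -> None:
    """Write the standard lineage-table CSV/TSV (inverse of the reader)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    rows = []
    for name in tree.preorder():
        node = tree.nodes[name]
        side = ""
        if node.parent_name is not None:
            kids = tree.children[node.parent_name]
            side = "L" if kids[0] == name else "R"
        x, y, z = node.position if node.position is not None else (None, None, None)
        rows.append(
            {
                "cell": node.name,
                "parent": node.parent_name or "",
                "volume": node.volume,
                "birth_time": node.birth_time,
                "division_time": node.division_time,
                "x": x,
                "y": y,
                "z": z,
                "side": side,
            }
        )
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def to_newick(tree: LineageTree, annotations: bool = True) -> str:
    """Serialize to Newick; child order follows the tree's active ordering.

    Volume and division time are written as ``[&volume=...,t_div=...]``
    comment annotations after each label.
    """

    def annot(node: CellNode) -> str:
        if not annotations:
            return ""
        parts = []
        if node.volume is not None:
            parts.append(f"volume={node.volume:.10g}")
        if node.division_time is not None:
            parts.append(f"t_div={node.division_time:.10g}")
        return f"[&{','.join(parts)}]" if parts else ""

    def render(name: str) -> str:
        node = tree.nodes[name]
        kids = tree.children.get(name)
        if not kids:
            return f"{name}{annot(node)}"
        inner = ",".join(render(k) for k in kids)
        return f"({inner}){name}{annot(node)}"

    return render(tree.root) + ";"


def from_newick(text: str, volume_units: str = "relative") -> LineageTree:
    """Parse an annotated Newick string back into a :class:`LineageTree`."""
    import dendropy

    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=False,
        preserve_underscores=True,
        extract_comment_metadata=True,
    )
    nodes: List[CellNode] = []
    children: Dict[str, List[str]] = {}

    def label(nd) -> str:
        lbl = nd.taxon.label if nd.taxon is not None else nd.label
        if lbl is None:
            raise LineageValidationError("newick node without a label")
        return lbl

    for nd in dtree.preorder_node_iter():
        meta = {a.name: a.value for a in nd.annotations}
        name = label(nd)
        parent = label(nd.parent_node) if nd.parent_node is not None else None
        nodes.append(
            CellNode(
                name=name,
                parent_name=parent,
                volume=float(meta["volume"]) if "volume" in meta else None,
                division_time=float(meta["t_div"]) if "t_div" in meta else None,
            )
        )
        kids = [label(c) for c in nd.child_nodes()]
        if kids:
            children[name] = kids
    return LineageTree(nodes, children=children, volume_units=volume_units)


# ---------------------------------------------------------------------------
# Optional workbook ingestion
# ---------------------------------------------------------------------------


def read_workbook_table(
    path: str | Path,
    sheet: str | int = 0,
    column_map: Optional[Mapping[str, str]] = None,
    units: str = "relative",
) -> LineageTree:
    """Read a lineage table from an XLSX workbook sheet.

    ``column_map`` maps canonical column names to the sheet's headers,
    e.g. ``{"cell": "Cell name", "volume": "% embryo volume"}``.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return lineage_table_to_tree(df, units=units)
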