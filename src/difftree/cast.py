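"""CAST codes: depth-prefixed C/E cell tokens and their global alignment.

A cell's differentiation code (bits b1..bD) serializes as the token
"D.letters" with C = 0 (smaller daughter / contraction) and E = 1 (larger
daughter / expansion), e.g. bits (0, 1, 0) -> "3.CEC".  Two trees are
compared by globally aligning their token sequences with a
Needleman-Wunsch dynamic program scoring +1 for an identical-token match
and -1 for a gap; mismatched tokens cannot be paired by default.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

from difftree.codes import BinaryCode, assign_codes
from difftree.lineage import LineageTree

GAP = "-"

_TOKEN_RE = re.compile(r"^(\d+)\.([CE]+)$")


@dataclass(frozen=True, order=True)
class CastCode:
    """One cell's depth-prefixed C/E token."""

    depth: int
    letters: str

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("CAST token depth must be >= 1")
        if not self.letters or set(self.letters) - {"C", "E"}:
            raise ValueError(f"letters must be over {{C, E}}, got {self.letters!r}")
        if len(self.letters) != self.depth:
            raise ValueError(
                f"depth prefix {self.depth} does not match letter count "
                f"{len(self.letters)} in {self.depth}.{self.letters}"
            )

    @classmethod
    def from_bits(cls, bits: Sequence[int]) -> "CastCode":
        letters = "".join("E" if b else "C" for b in bits)
        return cls(depth=len(letters), letters=letters)

    @classmethod
    def parse(cls, text: str) -> "CastCode":
        m = _TOKEN_RE.match(text.strip())
        if not m:
            raise ValueError(f"malformed CAST token {text!r}")
        return cls(depth=int(m.group(1)), letters=m.group(2))

    def __str__(self) -> str:
        return f"{self.depth}.{self.letters}"


@dataclass
class CastSequence:
    """Ordered token sequence for one tree."""

    tokens: List[CastCode]
    source: str = ""
    canonical: bool = False

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def canonicalized(self) -> "CastSequence":
        """Sorted ascending by depth, then letters (C before E)."""
        return CastSequence(
            tokens=sorted(self.tokens), source=self.source, canonical=True
        )

    def truncated(self, max_depth: int) -> "CastSequence":
        """Keep only tokens with depth prefix <= ``max_depth``."""
        return CastSequence(
            tokens=[t for t in self.tokens if t.depth <= max_depth],
            source=self.source,
            canonical=self.canonical,
        )


def cast_encode(tree: LineageTree, max_depth: Optional[int] = None) -> CastSequence:
    """Encode a volume-ordered tree's differentiation codes as CAST tokens.

    One token per non-root cell (the root's code is empty), canonically
    ordered; ``max_depth`` truncates to the first depths when given.
    """
    if tree.ordering_kind not in ("differentiation", "composite"):
        raise ValueError(
            "cast_encode needs a differentiation or composite ordering; "
            "call order_differentiation first"
        )
    codes = assign_codes(tree)
    tokens = [
        CastCode.from_bits(code.bits)
        for cell, code in codes.items()
        if code.bits and (max_depth is None or len(code.bits) <= max_depth)
    ]
    return CastSequence(tokens=tokens, source=tree.root).canonicalized()


def cast_parse(
    path: str | Path, source: str = "", canonical: bool = False
) -> CastSequence:
    """Read a CAST token file: one "D.LETTERS" token per line or delimited.

    ``#``-prefixed comments and blank lines are ignored.  By default the
    file's own token order is preserved; pass ``canonical=True`` to sort.
    """
    text = Path(path).read_text(encoding="utf-8")
    tokens: List[CastCode] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        for part in re.split(r"[\s,;]+", line):
            if part:
                tokens.append(CastCode.parse(part))
    seq = CastSequence(tokens=tokens, source=source or str(path))
    return seq.canonicalized() if canonical else seq


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentResult:
    """Global alignment of two token sequences (gap = ``None`` slot)."""

    aligned_a: List[Optional[CastCode]]
    aligned_b: List[Optional[CastCode]]
    score: int
    matches: int = field(init=False)
    gaps: int = field(init=False)
    substitutions: int = field(init=False)

    def __post_init__(self) -> None:
        matches = gaps = subs = 0
        for ta, tb in zip(self.aligned_a, self.aligned_b):
            if ta is None or tb is None:
                gaps += 1
            elif ta == tb:
                matches += 1
            else:
                subs += 1
        self.matches = matches
        self.gaps = gaps
        self.substitutions = subs

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    def pairs(self) -> List[Tuple[str, str]]:
        return [
            (str(a) if a else GAP, str(b) if b else GAP)
            for a, b in zip(self.aligned_a, self.aligned_b)
        ]


def cast_align(
    a: CastSequence,
    b: CastSequence,
    match: int = 1,
    gap: int = -1,
    substitution: Optional[int] = None,
    canonicalize: bool = True,
) -> AlignmentResult:
    """Needleman-Wunsch global alignment over whole tokens.

    A token pairs only with an identical token (same depth and letters);
    matches score ``match`` (+1) and gaps ``gap`` (-1).  Substitutions are
    disallowed unless a penalty is supplied.  Traceback ties resolve
    deterministically as match > gap-in-``a`` > gap-in-``b``; the optimal
    score is tie-invariant.
    """
    if canonicalize:
        a = a if a.canonical else a.canonicalized()
        b = b if b.canonical else b.canonicalized()
    ta, tb = list(a.tokens), list(b.tokens)
    n, m = len(ta), len(tb)
    neg_inf = float("-inf")

    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        row, prev = score[i], score[i - 1]
        for j in range(1, m + 1):
            if ta[i - 1] == tb[j - 1]:
                diag = prev[j - 1] + match
            elif substitution is not None:
                diag = prev[j - 1] + substitution
            else:
                diag = neg_inf
            row[j] = max(diag, prev[j] + gap, row[j - 1] + gap)

    aligned_a: List[Optional[CastCode]] = []
    aligned_b: List[Optional[CastCode]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            if ta[i - 1] == tb[j - 1]:
                diag = score[i - 1][j - 1] + match
            elif substitution is not None:
                diag = score[i - 1][j - 1] + substitution
            else:
                diag = neg_inf
            if score[i][j] == diag:
                aligned_a.append(ta[i - 1])
                aligned_b.append(tb[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i][j] == score[i - 1][j] + gap:
            aligned_a.append(ta[i - 1])
            aligned_b.append(None)
            i -= 1
        else:
            aligned_a.append(None)
            aligned_b.append(tb[j - 1])
            j -= 1
    aligned_a.reverse()
    aligned_b.reverse()
    return AlignmentResult(
        aligned_a=aligned_a, aligned_b=aligned_b, score=int(score[n][m])
    )


def match_gap_oracle(a: Iterable[CastCode], b: Iterable[CastCode]) -> Tuple[int, int, int]:
    """Closed form for the no-substitution alignment: (matches, gaps, score).

    With substitutions disallowed and both sequences canonically ordered,
    matches = multiset-intersection size and every unmatched token costs a
    gap, so score = matches - gaps with gaps = |a| + |b| - 2*matches.
    """
    ca, cb = Counter(a), Counter(b)
    matches = sum((ca & cb).values())
    gaps = sum(ca.values()) + sum(cb.values()) - 2 * matches
    return matches, gaps, matches - gaps


def cast_align_report(result: AlignmentResult) -> str:
    """Human-readable alignment summary with score as percent of length."""
    pct = round(100 * result.score / result.length) if result.length else 0
    matched = [str(a) for a, b in zip(result.aligned_a, result.aligned_b) if a and b and a == b]
    only_a = [str(a) for a, b in zip(result.aligned_a, result.aligned_b) if a and b is None]
    only_b = [str(b) for a, b in zip(result.aligned_a, result.aligned_b) if b and a is None]
    lines = [
        f"alignment length: {result.length}",
        f"score: {result.score} ({pct}% of the length)",
        f"matches: {result.matches}",
        f"gaps: {result.gaps}",
        f"matched tokens: {' '.join(matched) if matched else '(none)'}",
        f"unmatched in first: {' '.join(only_a) if only_a else '(none)'}",
        f"unmatched in second: {' '.join(only_b) if only_b else '(none)'}",
    ]
    return "\n".join(lines)
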