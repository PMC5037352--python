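"""Loaders for the published supplementary data files.

The cross-species reproduction targets (threshold tables; CAST alignment
scores) are deterministic given the published supplementary workbooks,
which are not redistributable with this package.  To run those analyses,
place plain-text exports under ``data/supplementary/`` at the repository
root (or point ``DIFFTREE_SUPPLEMENTARY`` at another directory):

- ``ciona_confidence_intervals.csv`` -- one row per division with columns
  ``volume_a,volume_b`` (daughter volumes, any consistent units; 117 rows);
- ``celegans_confidence_intervals.csv`` -- same layout (257 rows);
- ``ciona.cast``, ``celegans.cast``, ``celegans_composite.cast``,
  ``axolotl.cast`` -- CAST token files, one ``D.LETTERS`` token per line,
  ``#`` comments allowed.

An XLSX sheet with two volume columns can be converted with
:func:`workbook_to_pairs_csv`.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import List, Optional, Tuple

import pandas as pd

from difftree.asymmetry import DivisionRecord, divisions_from_pairs
from difftree.cast import CastSequence, cast_parse

ENV_VAR = "DIFFTREE_SUPPLEMENTARY"

CONFIDENCE_FILES = {
    "ciona": "ciona_confidence_intervals.csv",
    "celegans": "celegans_confidence_intervals.csv",
}
CAST_FILES = {
    "ciona": "ciona.cast",
    "celegans": "celegans.cast",
    "celegans_composite": "celegans_composite.cast",
    "axolotl": "axolotl.cast",
}


class SupplementaryDataMissing(FileNotFoundError):
    """A needed supplementary fixture is not present."""


def data_dir(root: Optional[Path] = None) -> Path:
    if ENV_VAR in os.environ:
        return Path(os.environ[ENV_VAR])
    base = root if root is not None else Path.cwd()
    return base / "data" / "supplementary"


def _resolve(filename: str, root: Optional[Path]) -> Path:
    path = data_dir(root) / filename
    if not path.exists():
        raise SupplementaryDataMissing(
            f"supplementary fixture {path} not found; see "
            "difftree.supplementary for the expected layout"
        )
    return path


def load_confidence_pairs(
    species: str, root: Optional[Path] = None
) -> List[DivisionRecord]:
    """Daughter-volume pairs for one species' division set."""
    path = _resolve(CONFIDENCE_FILES[species], root)
    df = pd.read_csv(path)
    missing = {"volume_a", "volume_b"} - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks column(s) {sorted(missing)}")
    pairs = list(zip(df["volume_a"].astype(float), df["volume_b"].astype(float)))
    return divisions_from_pairs(pairs)


def load_cast_sequence(name: str, root: Optional[Path] = None) -> CastSequence:
    """One species' CAST token sequence, in the file's own order."""
    path = _resolve(CAST_FILES[name], root)
    return cast_parse(path, source=name)


def workbook_to_pairs_csv(
    xlsx_path: str | Path,
    out_csv: str | Path,
    sheet: str | int = 0,
    column_a: str = "volume_a",
    column_b: str = "volume_b",
) -> int:
    """Convert a two-volume-column workbook sheet to the pairs CSV layout.

    Returns the number of rows written.
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    out = pd.DataFrame(
        {"volume_a": df[column_a].astype(float), "volume_b": df[column_b].astype(float)}
    ).dropna()
    out.to_csv(out_csv, index=False)
    return len(out)
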