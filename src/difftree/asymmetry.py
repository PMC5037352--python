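"""Division-asymmetry statistics and volume scaling-law fits.

The central quantity is the relative volume difference of a daughter pair,
A = |C_i - C_j| / (C_i + C_j), tested against a confidence threshold h
(asymmetric iff A > h).  A and the smaller/larger size ratio r = C_S / C_L
are linked by the exact identity A = (1 - r) / (1 + r).  Scaling analyses
use ordinary least squares, on the log-log scale for power laws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from difftree.lineage import LineageTree

#: statistic variants, all dimensionless in the sibling volumes.
#: "relative" is the calibrated default; "half" is its halved form; the
#: literal "printed" form multiplies the halved form by the threshold h
#: itself (kept for reference -- it can never exceed h for positive
#: volumes, so it classifies nothing as asymmetric).
STATISTIC_VARIANTS = ("relative", "half", "printed")


def asymmetry_statistic(
    c_i: float, c_j: float, variant: str = "relative", h: float = 1.0
) -> float:
    """Dimensionless size asymmetry of an unordered daughter-volume pair.

    Default variant: ``A = |C_i - C_j| / (C_i + C_j)``, symmetric in its
    arguments, 0 for equal volumes and approaching 1 only as one volume
    vanishes.  Scale-invariant: multiplying both volumes by c > 0 changes
    nothing.
    """
    if c_i < 0 or c_j < 0:
        raise ValueError("volumes must be non-negative")
    total = c_i + c_j
    if total == 0:
        raise ValueError("both daughter volumes are zero")
    a = abs(c_i - c_j) / total
    if variant == "relative":
        return a
    if variant == "half":
        return a / 2.0
    if variant == "printed":
        return (a / 2.0) * h
    raise ValueError(f"unknown statistic variant {variant!r}")


def classify_division(
    c_i: float, c_j: float, h: float, variant: str = "relative"
) -> int:
    """1 if the pair's asymmetry statistic strictly exceeds threshold h, else 0."""
    if h <= 0:
        raise ValueError("threshold h must be positive")
    return int(asymmetry_statistic(c_i, c_j, variant=variant, h=h) > h)


def size_ratio(c_s: float, c_l: float) -> float:
    """Smaller/larger daughter volume ratio, 1 for a symmetric pair.

    The caller must order the pair (``c_s <= c_l``); larger asymmetries
    give values decreasing asymptotically toward 0.
    """
    if c_l <= 0:
        raise ValueError("larger daughter volume must be positive")
    if c_s > c_l:
        raise ValueError("size_ratio expects c_s <= c_l; order the pair first")
    return c_s / c_l


@dataclass
class DivisionRecord:
    """One binary division summarized by its ordered daughter volumes."""

    mother: str
    c_l: float
    c_s: float
    depth: int
    statistic: float = field(init=False)
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if self.c_s > self.c_l:
            self.c_s, self.c_l = self.c_l, self.c_s
        self.statistic = asymmetry_statistic(self.c_s, self.c_l)
        self.ratio = size_ratio(self.c_s, self.c_l)

    def passes(self, h: float, variant: str = "relative") -> int:
        return classify_division(self.c_s, self.c_l, h, variant=variant)


def division_records(tree: LineageTree) -> List[DivisionRecord]:
    """Extract every division with both daughter volumes known.

    Divisions with a missing sibling volume are excluded (they cannot
    enter asymmetry statistics).  ``depth`` is the daughters' depth.
    """
    out: List[DivisionRecord] = []
    for mother, left, right in tree.divisions():
        vl = tree.nodes[left].volume
        vr = tree.nodes[right].volume
        if vl is None or vr is None:
            continue
        out.append(
            DivisionRecord(
                mother=mother,
                c_l=max(vl, vr),
                c_s=min(vl, vr),
                depth=tree.depth(left),
            )
        )
    return out


def divisions_from_pairs(
    pairs: Iterable[Tuple[float, float]], depth: int = 0
) -> List[DivisionRecord]:
    """Wrap raw (volume, volume) pairs as :class:`DivisionRecord` objects."""
    return [
        DivisionRecord(mother=f"d{i}", c_l=max(a, b), c_s=min(a, b), depth=depth)
        for i, (a, b) in enumerate(pairs)
    ]


def threshold_table(
    divisions: Sequence[DivisionRecord],
    thresholds: Sequence[float],
    variant: str = "relative",
) -> pd.DataFrame:
    """Counts and proportions of divisions above each confidence threshold.

    One row per threshold h with columns ``h, count, proportion, total``;
    the count is non-increasing in h.
    """
    if not divisions:
        raise ValueError("empty division set")
    total = len(divisions)
    rows = []
    for h in thresholds:
        count = sum(d.passes(h, variant=variant) for d in divisions)
        rows.append(
            {"h": h, "count": count, "proportion": count / total, "total": total}
        )
    return pd.DataFrame(rows)


def ratio_depth_summary(tree: LineageTree) -> pd.DataFrame:
    """Min / mean / max smaller-to-larger volume ratio at each lineage depth.

    Depths are those of the daughter cells; only depths with at least one
    complete division appear.
    """
    records = division_records(tree)
    if not records:
        return pd.DataFrame(columns=["depth", "min", "mean", "max", "n"])
    df = pd.DataFrame(
        {"depth": [r.depth for r in records], "ratio": [r.ratio for r in records]}
    )
    out = (
        df.groupby("depth")["ratio"]
        .agg(["min", "mean", "max", "count"])
        .rename(columns={"count": "n"})
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit summary for ``y = m + b x`` (linear) or ``y = m x^b`` (power)."""

    model: str
    m: float
    b: float
    r_squared: float
    n: int
    p_value: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "power":
            return self.m * x**self.b
        return self.m + self.b * x


def fit_linear(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares line with slope p-value (t on n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x (all values equal)")
    res = stats.linregress(x, y)
    return RegressionFit(
        model="linear",
        m=float(res.intercept),
        b=float(res.slope),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
        p_value=float(res.pvalue),
    )

def fit_power(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Power-law fit ``y = m x^b`` by least squares on the log-log scale.

    ``b`` is the log-log slope and ``m = exp(intercept)`` (the base of the
    logarithm is immaterial to ``b`` and r-squared, which is reported on
    the log scale).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power fit requires strictly positive data")
    fit = fit_linear(np.log(x), np.log(y))
    return RegressionFit(
        model="power",
        m=float(np.exp(fit.m)),
        b=fit.b,
        r_squared=fit.r_squared,
        n=fit.n,
        p_value=fit.p_value,
    )


def outlier_flags(
    fit: RegressionFit,
    x: Sequence[float],
    y: Sequence[float],
    k_sd: float = 2.5,
) -> np.ndarray:
    """Flag points whose residual exceeds ``k_sd`` residual standard deviations.

    Residuals are taken on the fit's own scale (log scale for a power
    fit).  Returns a boolean array aligned with the input points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if fit.model == "power":
        resid = np.log(y) - (np.log(fit.m) + fit.b * np.log(x))
    else:
        resid = y - fit.predict(x)
    sd = float(np.std(resid, ddof=2)) if resid.size > 2 else 0.0
    if sd == 0 or not np.isfinite(k_sd):
        return np.zeros(resid.shape, dtype=bool)
    return np.abs(resid) > k_sd * sd
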