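"""Seeded generator of synthetic mosaic-embryo lineage trees.

Produces complete binary trees in which each division partitions the
mother's volume (optionally with a per-generation decay), a tunable
fraction of divisions is drawn from an asymmetric split regime, and cell
lifetimes follow a power law of volume with multiplicative lognormal
noise -- the statistical structure the analysis modules assume, so every
stage is testable without external data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, List

import numpy as np

from difftree.lineage import CellNode, LineageTree


@dataclass
class SimulationConfig:
    """Knobs for :func:`simulate_tree`.

    The smaller-daughter volume fraction f is drawn per division from one
    of two regimes: with probability ``asym_fraction`` from
    ``0.5 * Beta(split_alpha, split_beta)`` (asymmetric, f in (0, 0.5)),
    otherwise from ``0.5 * (1 - U(0, sym_jitter))`` (near-symmetric;
    degenerate at exactly 0.5 when ``sym_jitter`` is 0).  Lifetimes are
    ``lifetime_coeff * volume**lifetime_exponent`` times lognormal noise
    with median 1 and coefficient of variation ``lifetime_noise_cv``, so
    (volume, lifetime) pairs are exactly power-law on the log scale in
    expectation.  ``asym_onset_depth`` restricts the asymmetric regime to
    divisions whose daughters are at that depth or deeper.
    """

    max_depth: int = 7
    split_alpha: float = 2.0
    split_beta: float = 6.0
    asym_fraction: float = 0.2
    sym_jitter: float = 0.02
    asym_onset_depth: int = 1
    lifetime_coeff: float = 20.0
    lifetime_exponent: float = -0.5
    lifetime_noise_cv: float = 0.1
    volume_decay: float = 1.0
    conserve_volume: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.split_alpha <= 0 or self.split_beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if not 0 <= self.asym_fraction <= 1:
            raise ValueError("asym_fraction must lie in [0, 1]")
        if not 0 <= self.sym_jitter < 1:
            raise ValueError("sym_jitter must lie in [0, 1)")
        if self.lifetime_noise_cv < 0:
            raise ValueError("lifetime_noise_cv must be non-negative")
        if not 0 < self.volume_decay <= 1:
            raise ValueError("volume_decay must lie in (0, 1]")

    def metadata(self) -> Dict[str, object]:
        return asdict(self)


def _lognormal_noise(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(sigma * rng.standard_normal()))


def simulate_tree(config: SimulationConfig) -> LineageTree:
    """Grow a complete binary lineage tree to ``config.max_depth``.

    The root ("Z") has volume 1.0 and is born at time 0.  At each
    division the smaller daughter takes fraction f of the (possibly
    decayed) mother volume and is assigned uniformly at random to the
    left or right lineage position, so the lineage ordering is
    uninformative about volume.  Terminal cells (at ``max_depth``) carry
    no division time.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    nodes: List[CellNode] = []
    children: Dict[str, List[str]] = {}

    def lifetime(volume: float) -> float:
        return (
            config.lifetime_coeff
            * volume**config.lifetime_exponent
            * _lognormal_noise(rng, config.lifetime_noise_cv)
        )

    def grow(name: str, parent: str | None, volume: float, birth: float, depth: int) -> None:
        if depth == config.max_depth:
            nodes.append(
                CellNode(name=name, parent_name=parent, volume=volume, birth_time=birth)
            )
            return
        life = lifetime(volume)
        division = birth + life
        nodes.append(
            CellNode(
                name=name,
                parent_name=parent,
                volume=volume,
                birth_time=birth,
                division_time=division,
            )
        )
        child_depth = depth + 1
        asym_allowed = child_depth >= config.asym_onset_depth
        # both candidate fractions are always drawn so that runs differing
        # only in asym_fraction share common random numbers
        u_regime = rng.random()
        f_asym = 0.5 * rng.beta(config.split_alpha, config.split_beta)
        f_sym = 0.5 * (1.0 - rng.uniform(0.0, config.sym_jitter))
        if asym_allowed and u_regime < config.asym_fraction:
            f = f_asym
        else:
            f = f_sym
        budget = volume if config.conserve_volume else volume * config.volume_decay
        small, large = f * budget, (1.0 - f) * budget
        # random anatomical placement: volume order independent of lineage order
        if rng.random() < 0.5:
            vols = (small, large)
        else:
            vols = (large, small)
        kids = [name + "a", name + "p"]
        children[name] = kids
        for kid, vol in zip(kids, vols):
            grow(kid, name, vol, division, child_depth)

    grow("Z", None, 1.0, 0.0, 0)
    return LineageTree(nodes, children=children, volume_units="relative")


def simulate_code_shuffle(tree: LineageTree, seed: int) -> LineageTree:
    """Null-model copy: child order re-drawn uniformly at every division.

    Topology, volumes and timing are unchanged; each division's left/right
    order is swapped independently with probability 1/2.
    """
    rng = np.random.default_rng(seed)
    children = {}
    for mother, kids in tree.children.items():
        children[mother] = list(reversed(kids)) if rng.random() < 0.5 else list(kids)
    out = tree.with_children(children, tree.ordering_kind)
    out.tie_flags = set(tree.tie_flags)
    out.unknown_flags = set(tree.unknown_flags)
    return out
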