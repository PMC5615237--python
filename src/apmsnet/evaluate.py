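"""Rank-based evaluation: hit curves, normalized AUC, network overlaps.

A ranked network is compared against a reference set of validated binary
interactions by walking the ranking and counting cumulative hits (the hit
curve), then summarizing the curve as a normalized area: the trapezoidal
area under the curve through ``(0,0), (1,y1), ..., (x_max, y_xmax)``
divided by ``x_max * y_max``. The normalized AUC lies in [0, 1]; a ranking
whose every reported pair is a hit scores exactly 0.5 (the diagonal), and
front-loaded hits push it toward 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from apmsnet.io import Pair, ReferenceSet, ScoredNetwork

logger = logging.getLogger(__name__)


@dataclass
class HitCurve:
    """Cumulative reference hits among the top-k ranked pairs, k = 1..x_max."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if self.y.ndim != 1 or self.y.size == 0:
            raise ValueError("hit curve needs at least one rank")
        if np.any(np.diff(self.y) < 0):
            raise ValueError("hit counts must be nondecreasing")
        if np.any(self.y > np.arange(1, self.y.size + 1)):
            raise ValueError("cannot have more hits than ranks inspected")

    @property
    def x(self) -> np.ndarray:
        return np.arange(1, self.y.size + 1)

    @property
    def x_max(self) -> int:
        return int(self.y.size)

    @property
    def y_max(self) -> int:
        return int(self.y[-1])


def hit_curve(net: ScoredNetwork, ref: ReferenceSet, x_max: int) -> HitCurve:
    """Hit curve of a network's canonical ranking against a reference set.

    ``x_max`` deeper than the network is truncated to the edge count (with
    a log message); an empty network is an error.
    """
    if x_max < 1:
        raise ValueError(f"x_max must be positive, got {x_max}")
    if not net.edges:
        raise ValueError("cannot evaluate an empty network")
    if x_max > len(net.edges):
        logger.info(
            "x_max=%d exceeds network size %d; truncating", x_max, len(net.edges)
        )
        x_max = len(net.edges)
    hits = np.fromiter(
        (pair in ref.pairs for pair in net.top_pairs(x_max)), dtype=int, count=x_max
    )
    return HitCurve(np.cumsum(hits))


def normalized_auc(curve: HitCurve) -> float:
    """Trapezoidal area under the hit curve, scaled by ``x_max * y_max``.

    Returns 0 for an all-miss curve (the defined limit of the quotient).
    """
    if curve.y_max == 0:
        return 0.0
    x = np.concatenate(([0], curve.x))
    y = np.concatenate(([0], curve.y))
    auc = float(np.trapezoid(y, x))
    return auc / (curve.x_max * curve.y_max)


def precision_at_k(net: ScoredNetwork, truth: set[Pair], k: int) -> float:
    """Fraction of the top-k ranked pairs that belong to ``truth``."""
    if k < 1:
        raise ValueError(f"k must be positive, got {k}")
    top = net.top_pairs(k)
    if not top:
        raise ValueError("cannot take top pairs of an empty network")
    return sum(p in truth for p in top) / len(top)


def compare_networks(
    nets: list[ScoredNetwork], k: int
) -> dict[str, dict]:
    """Top-k overlap structure of several rankings (Venn cell counts).

    Each network contributes its top-``k`` pair set (truncated with a log
    message if shorter). The result maps every nonempty subset of network
    indices — encoded as a sorted comma-joined string like ``"0,2"`` — to
    the number of pairs appearing in exactly those networks, alongside
    per-network totals and the union size.
    """
    if len(nets) < 2:
        raise ValueError("need at least two networks to compare")
    top_sets: list[set[Pair]] = []
    for i, net in enumerate(nets):
        if len(net.edges) < k:
            logger.info("network %d has only %d < %d edges", i, len(net.edges), k)
        top_sets.append(set(net.top_pairs(k)))

    union = set().union(*top_sets)
    cells: dict[str, int] = {}
    for r in range(1, len(nets) + 1):
        for subset in combinations(range(len(nets)), r):
            key = ",".join(map(str, subset))
            cells[key] = 0
    for pair in union:
        membership = tuple(i for i, ts in enumerate(top_sets) if pair in ts)
        cells[",".join(map(str, membership))] += 1
    return {
        "cells": cells,
        "totals": [len(ts) for ts in top_sets],
        "union": len(union),
        "tags": [net.method_tag for net in nets],
    }


@dataclass
class InitialVsFiltered:
    """Paired evaluation of an initial ranking and its refined ranking."""

    initial_curve: HitCurve
    filtered_curve: HitCurve
    initial_nauc: float
    filtered_nauc: float

    @property
    def improved(self) -> bool:
        """True iff refinement strictly increased the normalized AUC."""
        return self.filtered_nauc > self.initial_nauc

    @property
    def verdict(self) -> str:
        return "up" if self.improved else "down"


def compare_initial_vs_filtered(
    initial: ScoredNetwork,
    filtered: ScoredNetwork,
    ref: ReferenceSet,
    x_max: int,
) -> InitialVsFiltered:
    """Hit curves and normalized AUCs before and after refinement."""
    c_init = hit_curve(initial, ref, x_max)
    c_filt = hit_curve(filtered, ref, x_max)
    return InitialVsFiltered(
        initial_curve=c_init,
        filtered_curve=c_filt,
        initial_nauc=normalized_auc(c_init),
        filtered_nauc=normalized_auc(c_filt),
    )
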