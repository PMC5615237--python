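"""Synthetic AP-MS data with known direct / indirect / contaminant labels.

The generator emulates the noise structure of real qualitative bait-prey
data: proteins are organized into complexes wired by a connected random
graph (the direct interactions); a purification with bait b retrieves b's
direct partners with high probability, its co-complex but non-adjacent
partners with a lower probability (the indirect retrievals that phase II
is meant to suppress), and a Poisson number of sticky contaminants drawn
from a Zipf-weighted pool (a few contaminants recur across many
purifications, as in real data). All sampling comes from one seeded
stream, so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from apmsnet.io import Pair, Purification, PurificationDataset, make_pair


@dataclass
class SimulationConfig:
    """Generative parameters; defaults give a small but realistic data set.

    ``p_direct`` must exceed ``p_indirect``: a bait pulls down its physical
    partners more reliably than proteins merely sharing its complex.
    """

    n_complexes: int = 10
    complex_size_range: tuple[int, int] = (3, 6)
    n_contaminants: int = 50
    n_purifications: int = 300
    p_direct: float = 0.8
    p_indirect: float = 0.4
    contaminant_rate: float = 2.0
    extra_edge_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.complex_size_range
        if not (2 <= lo <= hi):
            raise ValueError(f"infeasible complex size range {self.complex_size_range}")
        if not 0.0 <= self.p_indirect < self.p_direct <= 1.0:
            raise ValueError(
                "need 0 <= p_indirect < p_direct <= 1, got "
                f"p_indirect={self.p_indirect}, p_direct={self.p_direct}"
            )
        for name in ("n_complexes", "n_contaminants", "n_purifications"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.contaminant_rate < 0:
            raise ValueError("contaminant_rate must be >= 0")


@dataclass
class GroundTruth:
    """True network labels backing a simulated dataset.

    ``direct_edges`` are physical contacts; ``indirect_pairs`` share a
    complex but have no direct edge; ``contaminants`` are sticky proteins
    outside every complex.
    """

    direct_edges: frozenset[Pair]
    indirect_pairs: frozenset[Pair]
    contaminants: frozenset[str]
    complexes: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direct_edges & self.indirect_pairs:
            raise ValueError("direct and indirect pair sets must be disjoint")
        members = {p for cx in self.complexes for p in cx}
        if members & self.contaminants:
            raise ValueError("contaminants must be disjoint from complex members")

    @property
    def complex_members(self) -> frozenset[str]:
        return frozenset(p for cx in self.complexes for p in cx)


def build_truth(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Sample complexes and their internal wiring.

    Each complex gets a uniform size from ``complex_size_range`` and a
    connected random graph on its members: a uniform random attachment
    spanning tree plus each remaining pair independently with
    ``extra_edge_prob``. Co-complex pairs without a direct edge become the
    indirect pairs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.complex_size_range
    direct: set[Pair] = set()
    indirect: set[Pair] = set()
    complexes: list[tuple[str, ...]] = []
    counter = 0
    for _ in range(config.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        members = tuple(f"P{counter + i:04d}" for i in range(size))
        counter += size
        complexes.append(members)
        # random attachment spanning tree keeps the complex connected
        for i in range(1, size):
            j = int(rng.integers(0, i))
            direct.add(make_pair(members[i], members[j]))
        for a, b in combinations(members, 2):
            pair = make_pair(a, b)
            if pair not in direct and rng.random() < config.extra_edge_prob:
                direct.add(pair)
        for a, b in combinations(members, 2):
            pair = make_pair(a, b)
            if pair not in direct:
                indirect.add(pair)
    contaminants = frozenset(
        f"CONT{i:03d}" for i in range(config.n_contaminants)
    )
    return GroundTruth(
        direct_edges=frozenset(direct),
        indirect_pairs=frozenset(indirect),
        contaminants=contaminants,
        complexes=complexes,
    )


def simulate_purifications(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PurificationDataset:
    """Draw purifications from the ground-truth network.

    Each experiment picks a bait uniformly among complex members; every
    direct neighbor is retrieved independently with ``p_direct``, every
    indirect co-complex partner with ``p_indirect``, and
    ``Poisson(contaminant_rate)`` contaminant picks are added with
    Zipf(s=1) propensities (weight 1/rank) over the contaminant pool.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    # adjacency over complex members, in sorted order for determinism
    neighbors: dict[str, list[str]] = {}
    co_indirect: dict[str, list[str]] = {}
    for a, b in sorted(truth.direct_edges):
        neighbors.setdefault(a, []).append(b)
        neighbors.setdefault(b, []).append(a)
    for a, b in sorted(truth.indirect_pairs):
        co_indirect.setdefault(a, []).append(b)
        co_indirect.setdefault(b, []).append(a)

    members = sorted(truth.complex_members)
    pool = sorted(truth.contaminants)
    weights = 1.0 / np.arange(1, len(pool) + 1)
    weights /= weights.sum()

    purifications = []
    for t in range(config.n_purifications):
        bait = members[int(rng.integers(0, len(members)))]
        preys: set[str] = set()
        for nb in sorted(neighbors.get(bait, [])):
            if rng.random() < config.p_direct:
                preys.add(nb)
        for cc in sorted(co_indirect.get(bait, [])):
            if rng.random() < config.p_indirect:
                preys.add(cc)
        n_cont = int(rng.poisson(config.contaminant_rate))
        if n_cont > 0 and pool:
            picks = rng.choice(len(pool), size=n_cont, replace=True, p=weights)
            preys.update(pool[i] for i in picks)
        purifications.append(
            Purification(f"sim{t:05d}", bait, frozenset(preys) - {bait})
        )
    return PurificationDataset(purifications)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GroundTruth, PurificationDataset]:
    """Generate truth and dataset from a single seeded random stream."""
    rng = np.random.default_rng(config.seed)
    truth = build_truth(config, rng)
    dataset = simulate_purifications(truth, config, rng)
    return truth, dataset
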