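"""Phase I: co-occurrence scoring of candidate protein pairs.

Four classical qualitative AP-MS scores are provided, all computed from the
same sufficient statistics (:class:`CooccurrenceCounts`):

* socioaffinity (SA) — a three-term log-odds of observed vs expected
  co-retrieval: two directed bait->prey "spoke" terms and one prey-prey
  "matrix" term under a random-assortment null;
* purification enrichment (PE) — a Bayesian log-odds that accumulates
  per-purification presence *and* absence evidence for the pair;
* Dice coefficient (DC) — set overlap of the purifications containing each
  protein;
* hypergeometric (Hart) — the -log10 tail probability of observing at
  least the seen number of co-memberships by chance.

Candidate universe: every unordered pair co-occurring at least once in any
role (the matrix-model universe). All scores are symmetric in the pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import hypergeom

from apmsnet.io import Pair, PurificationDataset, ScoredNetwork, make_pair


@dataclass
class CooccurrenceCounts:
    """Sufficient statistics of a purification dataset for pair scoring.

    Attributes
    ----------
    N:
        Number of purifications.
    b:
        Per-protein count of purifications where it is the bait.
    occ:
        Per-protein count of purifications containing it in any role.
    r:
        Per-protein count of purifications containing it as a prey
        (each purification counted once).
    s:
        Directed spoke counts: ``s[(i, j)]`` = purifications with bait i
        that retrieved prey j.
    m:
        Matrix counts: purifications whose bait is neither protein of the
        pair, containing both as preys. Symmetric, keyed canonically.
    k:
        Co-membership counts: purifications containing both proteins in
        any role. Symmetric, keyed canonically.
    sizes:
        Prey-list size of each purification, in dataset order.
    bait_slots:
        Per-protein total prey slots over the purifications it baited:
        ``sum(size_k for k with bait i)``.
    """

    N: int
    b: dict[str, int]
    occ: dict[str, int]
    r: dict[str, int]
    s: dict[tuple[str, str], int]
    m: dict[Pair, int]
    k: dict[Pair, int]
    sizes: list[int]
    bait_slots: dict[str, int]

    @property
    def T(self) -> int:
        """Total prey slots across the dataset."""
        return sum(self.sizes)

    @property
    def pair_universe(self) -> set[Pair]:
        """All candidate pairs: co-occurred at least once in any role."""
        return set(self.k)

    @property
    def proteins(self) -> set[str]:
        return set(self.occ)

    @property
    def sum_size_pairs(self) -> int:
        """``sum(size_k * (size_k - 1))`` — ordered prey-pair slots."""
        return sum(sz * (sz - 1) for sz in self.sizes)


def compute_counts(dataset: PurificationDataset) -> CooccurrenceCounts:
    """Tally all per-protein and per-pair counts in a single pass."""
    b: dict[str, int] = {}
    occ: dict[str, int] = {}
    r: dict[str, int] = {}
    s: dict[tuple[str, str], int] = {}
    m: dict[Pair, int] = {}
    k: dict[Pair, int] = {}
    sizes: list[int] = []
    bait_slots: dict[str, int] = {}

    for pur in dataset.purifications:
        bait = pur.bait
        preys = sorted(pur.preys)
        sizes.append(len(preys))
        b[bait] = b.get(bait, 0) + 1
        bait_slots[bait] = bait_slots.get(bait, 0) + len(preys)
        occ[bait] = occ.get(bait, 0) + 1
        for j in preys:
            occ[j] = occ.get(j, 0) + 1
            r[j] = r.get(j, 0) + 1
            s[(bait, j)] = s.get((bait, j), 0) + 1
        # prey-prey pairs: bait is never a prey, so the bait of the
        # purification is by construction neither member of the pair
        for a_idx in range(len(preys)):
            for b_idx in range(a_idx + 1, len(preys)):
                pair = make_pair(preys[a_idx], preys[b_idx])
                m[pair] = m.get(pair, 0) + 1
        members = sorted(pur.members)
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                pair = make_pair(members[a_idx], members[b_idx])
                k[pair] = k.get(pair, 0) + 1

    for p in dataset.proteins:
        occ.setdefault(p, 0)
        r.setdefault(p, 0)
        b.setdefault(p, 0)
        bait_slots.setdefault(p, 0)

    return CooccurrenceCounts(
        N=dataset.N, b=b, occ=occ, r=r, s=s, m=m, k=k,
        sizes=sizes, bait_slots=bait_slots,
    )


def score_sa(counts: CooccurrenceCounts) -> ScoredNetwork:
    """Socioaffinity: ln-ratio of observed to expected co-retrieval counts.

    ``SA(i,j) = ln(s_ij/E[s_ij]) + ln(s_ji/E[s_ji]) + ln(m_ij/E[m_ij])``
    where, under random assortment of prey slots, ``E[s_ij] = f_j *
    bait_slots_i`` with ``f_j = r_j / T``, and ``E[m_ij] = f_i * f_j *
    sum_k size_k (size_k - 1)``. A term whose observed count is zero
    contributes zero (absence is not treated as negative evidence here;
    PE carries an explicit absence term).
    """
    T = counts.T
    if T == 0:
        raise ValueError("SA undefined: dataset retrieved no preys at all (T = 0)")
    ssp = counts.sum_size_pairs
    edges: dict[Pair, float] = {}
    for (i, j) in counts.pair_universe:
        score = 0.0
        for x, y in ((i, j), (j, i)):  # spoke terms, both directions
            s_xy = counts.s.get((x, y), 0)
            if s_xy > 0:
                expected = (counts.r[y] / T) * counts.bait_slots[x]
                score += math.log(s_xy / expected)
        m_ij = counts.m.get((i, j), 0)
        if m_ij > 0:
            expected = (counts.r[i] / T) * (counts.r[j] / T) * ssp
            score += math.log(m_ij / expected)
        edges[(i, j)] = score
    return ScoredNetwork(edges, method_tag="sa")


def score_pe(
    counts: CooccurrenceCounts, r: float = 0.5, pseudo: float = 20.0
) -> ScoredNetwork:
    """Purification enrichment: Bayesian log-odds over purification events.

    Parameters
    ----------
    r:
        Assumed retrieval probability of a true interactor in a single
        purification, in (0, 1).
    pseudo:
        Pseudocount mass spread uniformly over the protein universe when
        smoothing the background prey frequencies.

    For each purification with bait i, prey j present contributes
    ``ln(r / f~_j)`` and prey j absent contributes ``ln((1-r)/(1-f~_j))``,
    where ``f~_j = (r_j + pseudo/|proteins|) / (T + pseudo)`` is the
    smoothed background frequency. The prey-prey (matrix) evidence is
    ``m_ij * ln(r / (f~_i f~_j S_bar))`` with ``S_bar`` the mean number of
    ordered prey pairs per purification.
    """
    if not 0.0 < r < 1.0:
        raise ValueError(f"retrieval probability r must be in (0, 1), got {r}")
    if pseudo < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudo}")
    T = counts.T
    n_prot = len(counts.proteins)
    s_bar = counts.sum_size_pairs / counts.N

    def f_smooth(p: str) -> float:
        f = (counts.r[p] + pseudo / n_prot) / (T + pseudo)
        # keep both ln arguments finite for degenerate datasets
        return min(max(f, 1e-300), 1.0 - 1e-12)

    edges: dict[Pair, float] = {}
    for (i, j) in counts.pair_universe:
        score = 0.0
        for x, y in ((i, j), (j, i)):  # bait x, partner y
            if counts.b[x] == 0:
                continue
            f_y = f_smooth(y)
            present = counts.s.get((x, y), 0)
            absent = counts.b[x] - present
            score += present * math.log(r / f_y)
            score += absent * math.log((1.0 - r) / (1.0 - f_y))
        m_ij = counts.m.get((i, j), 0)
        if m_ij > 0:
            denom = max(f_smooth(i) * f_smooth(j) * s_bar, 1e-300)
            score += m_ij * math.log(r / denom)
        edges[(i, j)] = score
    return ScoredNetwork(edges, method_tag="pe")


def score_dc(counts: CooccurrenceCounts) -> ScoredNetwork:
    """Dice coefficient over purification membership: ``2 k_ij / (occ_i + occ_j)``."""
    edges = {
        (i, j): 2.0 * k_ij / (counts.occ[i] + counts.occ[j])
        for (i, j), k_ij in counts.k.items()
    }
    return ScoredNetwork(edges, method_tag="dc")


def score_hart(
    counts: CooccurrenceCounts, p_floor: float = 1e-300
) -> ScoredNetwork:
    """Hypergeometric co-occurrence score.

    ``Hart(i,j) = -log10 P(X >= k_ij)`` with ``X ~ Hypergeom(N, occ_i,
    occ_j)``: the chance that two proteins occurring in ``occ_i`` and
    ``occ_j`` of ``N`` purifications share at least ``k_ij`` of them if
    memberships were random. Underflowing p-values are clamped at
    ``p_floor``.
    """
    edges: dict[Pair, float] = {}
    for (i, j), k_ij in counts.k.items():
        p = float(hypergeom.sf(k_ij - 1, counts.N, counts.occ[i], counts.occ[j]))
        p = min(max(p, p_floor), 1.0)
        edges[(i, j)] = -math.log10(p)
    return ScoredNetwork(edges, method_tag="hart")
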