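"""Independent brute-force oracles used to validate the production code.

Everything here is written as literal, per-definition loops over the raw
purification records (never via apmsnet.scoring.compute_counts) or as
literal transcriptions of the closed-form matrix formulas, so agreement
with the production implementations is a genuine dual-route check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def _purifications_with(dataset, protein):
    return [p for p in dataset.purifications if protein in p.members]


def naive_pair_counts(dataset, i, j):
    """Recount every statistic for one unordered pair by direct scanning."""
    s_ij = sum(1 for p in dataset.purifications if p.bait == i and j in p.preys)
    s_ji = sum(1 for p in dataset.purifications if p.bait == j and i in p.preys)
    m_ij = sum(
        1
        for p in dataset.purifications
        if p.bait not in (i, j) and i in p.preys and j in p.preys
    )
    k_ij = sum(1 for p in dataset.purifications if i in p.members and j in p.members)
    return s_ij, s_ji, m_ij, k_ij


def naive_protein_counts(dataset, i):
    b_i = sum(1 for p in dataset.purifications if p.bait == i)
    occ_i = sum(1 for p in dataset.purifications if i in p.members)
    r_i = sum(1 for p in dataset.purifications if i in p.preys)
    return b_i, occ_i, r_i


def candidate_pairs(dataset):
    pairs = set()
    for p in dataset.purifications:
        for a, b in combinations(sorted(p.members), 2):
            pairs.add((a, b))
    return pairs


def oracle_sa(dataset):
    """Straight-line socioaffinity over the candidate universe."""
    T = sum(len(p.preys) for p in dataset.purifications)
    sum_pairs = sum(len(p.preys) * (len(p.preys) - 1) for p in dataset.purifications)
    out = {}
    for (i, j) in candidate_pairs(dataset):
        s_ij, s_ji, m_ij, _ = naive_pair_counts(dataset, i, j)
        _, _, r_i = naive_protein_counts(dataset, i)
        _, _, r_j = naive_protein_counts(dataset, j)
        score = 0.0
        for x, y, s_xy, r_y in ((i, j, s_ij, r_j), (j, i, s_ji, r_i)):
            if s_xy > 0:
                slots_x = sum(
                    len(p.preys) for p in dataset.purifications if p.bait == x
                )
                score += math.log(s_xy / ((r_y / T) * slots_x))
        if m_ij > 0:
            score += math.log(m_ij / ((r_i / T) * (r_j / T) * sum_pairs))
        out[(i, j)] = score
    return out


def oracle_pe(dataset, r=0.5, pseudo=20.0):
    """Straight-line purification enrichment, event by event."""
    T = sum(len(p.preys) for p in dataset.purifications)
    n_prot = len(dataset.proteins)
    s_bar = sum(
        len(p.preys) * (len(p.preys) - 1) for p in dataset.purifications
    ) / dataset.N

    def f_tilde(y):
        r_y = sum(1 for p in dataset.purifications if y in p.preys)
        f = (r_y + pseudo / n_prot) / (T + pseudo)
        return min(max(f, 1e-300), 1.0 - 1e-12)

    out = {}
    for (i, j) in candidate_pairs(dataset):
        score = 0.0
        for x, y in ((i, j), (j, i)):
            for p in dataset.purifications:
                if p.bait != x:
                    continue
                if y in p.preys:
                    score += math.log(r / f_tilde(y))
                else:
                    score += math.log((1.0 - r) / (1.0 - f_tilde(y)))
        _, _, m_ij, _ = naive_pair_counts(dataset, i, j)
        if m_ij > 0:
            score += m_ij * math.log(r / max(f_tilde(i) * f_tilde(j) * s_bar, 1e-300))
        out[(i, j)] = score
    return out


def oracle_dc(dataset):
    out = {}
    for (i, j) in candidate_pairs(dataset):
        _, occ_i, _ = naive_protein_counts(dataset, i)
        _, occ_j, _ = naive_protein_counts(dataset, j)
        _, _, _, k_ij = naive_pair_counts(dataset, i, j)
        out[(i, j)] = 2.0 * k_ij / (occ_i + occ_j)
    return out


def hypergeom_tail_enum(N, n_success, n_draw, k):
    """P(X >= k) by exhaustive enumeration of all draw subsets (N small)."""
    successes = set(range(n_success))
    total = 0
    hits = 0
    for draw in combinations(range(N), n_draw):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_comb(N, n_success, n_draw, k):
    """P(X >= k) from first principles with binomial coefficients."""
    denom = math.comb(N, n_draw)
    num = sum(
        math.comb(n_success, x) * math.comb(N - n_success, n_draw - x)
        for x in range(k, min(n_success, n_draw) + 1)
    )
    return num / denom


def oracle_hart(dataset, p_floor=1e-300):
    out = {}
    for (i, j) in candidate_pairs(dataset):
        _, occ_i, _ = naive_protein_counts(dataset, i)
        _, occ_j, _ = naive_protein_counts(dataset, j)
        _, _, _, k_ij = naive_pair_counts(dataset, i, j)
        p = hypergeom_tail_comb(dataset.N, occ_i, occ_j, k_ij)
        out[(i, j)] = -math.log10(min(max(p, p_floor), 1.0))
    return out


def closure_series_matrix(G_dir):
    """Observed matrix of the transitive-closure series: G_dir (I - G_dir)^-1.

    Symmetrized to absorb the ~1e-16 floating-point asymmetry of the
    matrix product (the series of a symmetric matrix is symmetric).
    """
    n = G_dir.shape[0]
    M = G_dir @ np.linalg.inv(np.eye(n) - G_dir)
    return (M + M.T) / 2.0


def silencer_transcription(G):
    """Literal transcription of S = (G - I + D((G - I) G)) G^-1."""
    n = G.shape[0]
    I = np.eye(n)
    D = np.diag(np.diag((G - I) @ G))
    return (G - I + D) @ np.linalg.inv(G)


def trapezoid_nauc(y):
    """Hand trapezoid through (0,0),(1,y1),...,(x_max,y_xmax), normalized."""
    y = list(y)
    x_max, y_max = len(y), y[-1]
    if y_max == 0:
        return 0.0
    pts = [0.0] + [float(v) for v in y]
    area = sum((pts[k] + pts[k + 1]) / 2.0 for k in range(x_max))
    return area / (x_max * y_max)
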