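"""Phase II: remove indirect associations from an observed score matrix.

An observed pairwise association matrix G mixes direct effects with effects
propagated along paths through intermediate nodes. Two closed-form
operators recover an estimate S of the direct part:

* network deconvolution — inverts the transitive-closure series
  ``G = S + S^2 + S^3 + ... = S (I - S)^-1`` spectrally, mapping each
  eigenvalue ``lam -> lam / (1 + lam)``;
* silencing — ``S = (G - I + D((G - I) G)) G^-1``, which suppresses the
  indirect contributions carried by the inverse correlation matrix
  (``D(.)`` keeps only the diagonal of its argument).

Both consume a dense :class:`ScoreMatrix` built from a scored network by
min-max normalizing the scores into [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from apmsnet.io import Pair, ScoredNetwork, make_pair

logger = logging.getLogger(__name__)


@dataclass
class ScoreMatrix:
    """Dense symmetric score matrix over a lexicographically ordered index.

    ``diagonal_convention`` is ``"zero"`` (deconvolution input/output),
    ``"unit"`` (silencer input, which treats G as a correlation matrix) or
    ``"free"`` (an observed matrix whose diagonal carries no constraint,
    e.g. a transitive-closure series, which has nonzero diagonal terms).
    """

    proteins: list[str]
    M: np.ndarray
    diagonal_convention: str = "zero"

    def __post_init__(self) -> None:
        n = len(self.proteins)
        if self.M.shape != (n, n):
            raise ValueError(f"matrix shape {self.M.shape} != ({n}, {n})")
        if list(self.proteins) != sorted(self.proteins):
            raise ValueError("protein index must be lexicographically sorted")
        if not np.array_equal(self.M, self.M.T):
            raise ValueError("score matrix must be exactly symmetric")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("score matrix entries must be finite")
        if self.diagonal_convention not in ("zero", "unit", "free"):
            raise ValueError(f"unknown diagonal convention {self.diagonal_convention!r}")
        if self.diagonal_convention != "free":
            want = 0.0 if self.diagonal_convention == "zero" else 1.0
            if not np.allclose(np.diag(self.M), want, atol=0.0):
                raise ValueError(f"diagonal must be constant {want}")

    @property
    def n(self) -> int:
        return len(self.proteins)

    def index_of(self, protein: str) -> int:
        return self.proteins.index(protein)


def network_to_matrix(
    net: ScoredNetwork, diagonal_convention: str = "zero"
) -> ScoreMatrix:
    """Embed a scored network as a dense matrix with min-max scaled weights.

    Present edges map to ``(score - min) / (max - min)`` in [0, 1] (all to
    1 when every score is equal); absent pairs are 0. The protein index is
    the sorted union of the network's proteins.
    """
    if not net.edges:
        raise ValueError("cannot build a score matrix from an empty network")
    proteins = sorted(net.proteins)
    idx = {p: i for i, p in enumerate(proteins)}
    scores = np.array(list(net.edges.values()), dtype=float)
    lo, hi = scores.min(), scores.max()
    span = hi - lo
    M = np.zeros((len(proteins), len(proteins)), dtype=float)
    for (a, b), score in net.edges.items():
        w = 1.0 if span == 0.0 else (score - lo) / span
        M[idx[a], idx[b]] = w
        M[idx[b], idx[a]] = w
    if diagonal_convention == "unit":
        np.fill_diagonal(M, 1.0)
    return ScoreMatrix(proteins, M, diagonal_convention)


def scaled_direct_eigenvalues(eigvals: np.ndarray, beta: float) -> np.ndarray:
    """Shrink an observed spectrum, then apply ``lam -> lam / (1 + lam)``.

    The shrink factor ``m = max(lam+ (1-beta)/beta, |lam-| (1+beta)/beta,
    1)`` guarantees the transformed spectrum lies in ``[-beta, beta]``.
    """
    lam_pos = max(float(eigvals.max()), 0.0)
    lam_neg = min(float(eigvals.min()), 0.0)
    m = max(lam_pos * (1.0 - beta) / beta, abs(lam_neg) * (1.0 + beta) / beta, 1.0)
    scaled = eigvals / m
    return scaled / (1.0 + scaled)


def deconvolve_nd(
    G: ScoreMatrix,
    beta: float = 0.99,
    alpha: float = 1.0,
    force_no_scaling: bool = False,
) -> ScoreMatrix:
    """Network deconvolution of an observed association matrix.

    Parameters
    ----------
    G:
        Zero-diagonal symmetric observed matrix.
    beta:
        Target spectral bound of the deconvolved matrix in (0, 1); the
        observed spectrum is shrunk so the output eigenvalues lie in
        ``[-beta, beta]``.
    alpha:
        Fraction of nonzero off-diagonal entries (by magnitude) kept
        before deconvolution; 1 keeps everything.
    force_no_scaling:
        Skip the eigenvalue shrinkage entirely — exact inversion of the
        transitive-closure series, valid when the direct spectrum is
        already inside (-1, 1).
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if G.diagonal_convention == "unit":
        raise ValueError("deconvolution expects a zero-diagonal (or free) matrix")

    M = G.M.copy()
    if alpha < 1.0:
        iu = np.triu_indices(G.n, k=1)
        vals = np.abs(M[iu])
        nonzero = vals[vals > 0]
        if nonzero.size:
            n_keep = math.ceil(alpha * nonzero.size)
            thresh = np.sort(nonzero)[::-1][n_keep - 1]
            mask = np.abs(M) < thresh
            M[mask] = 0.0
            M = (M + M.T) / 2.0

    try:
        eigvals, eigvecs = np.linalg.eigh(M)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("eigendecomposition of the observed matrix failed") from exc

    if force_no_scaling:
        lam_direct = eigvals / (1.0 + eigvals)
    else:
        lam_direct = scaled_direct_eigenvalues(eigvals, beta)
    S = (eigvecs * lam_direct) @ eigvecs.T
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 0.0)
    return ScoreMatrix(G.proteins, S, "zero")


def silence(G: ScoreMatrix, ridge_eps: float | None = None) -> ScoreMatrix:
    """Silencing transform ``S = (G - I + D((G - I) G)) G^-1``.

    ``G`` must carry a unit diagonal (correlation-matrix convention). When
    G is numerically singular (condition number above 1e12) the inverse is
    taken of ``G + ridge_eps * I`` instead; the default ridge is
    ``1e-8 * trace(G) / n``. The result is re-symmetrized and its diagonal
    zeroed; off-diagonal magnitudes are the direct-association scores.
    """
    if G.diagonal_convention != "unit":
        raise ValueError("silencing expects a unit-diagonal matrix")
    n = G.n
    I = np.eye(n)
    Gm = G.M
    if ridge_eps is None:
        ridge_eps = 1e-8 * np.trace(Gm) / n
    target = Gm
    if np.linalg.cond(Gm) > 1e12:
        logger.warning(
            "observed matrix numerically singular; adding ridge %.3g", ridge_eps
        )
        target = Gm + ridge_eps * I
    try:
        G_inv = np.linalg.inv(target)
    except np.linalg.LinAlgError as exc:
        raise ValueError("observed matrix not invertible even after ridge") from exc
    S = (Gm - I + np.diag(np.diag((Gm - I) @ Gm))) @ G_inv
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 0.0)
    return ScoreMatrix(G.proteins, S, "zero")


def matrix_to_network(
    S: ScoreMatrix,
    keep_pairs: set[Pair] | None = None,
    method_tag: str = "",
    use_magnitude: bool = False,
) -> ScoredNetwork:
    """Flatten the upper triangle of a score matrix back into a network.

    With ``keep_pairs`` the output is restricted to exactly those pairs —
    the usual way to re-rank a refined matrix over the initial network's
    candidate universe. Without it, only nonzero entries become edges.
    ``use_magnitude`` ranks by ``|S_ij|`` (the silencer convention, where
    sign is not meaningful).
    """
    idx = {p: i for i, p in enumerate(S.proteins)}
    edges: dict[Pair, float] = {}
    if keep_pairs is not None:
        for (a, b) in keep_pairs:
            pair = make_pair(a, b)
            if pair[0] in idx and pair[1] in idx:
                v = float(S.M[idx[pair[0]], idx[pair[1]]])
                edges[pair] = abs(v) if use_magnitude else v
    else:
        iu = np.triu_indices(S.n, k=1)
        for i, j in zip(*iu):
            v = float(S.M[i, j])
            if v != 0.0:
                pair = (S.proteins[i], S.proteins[j])
                edges[pair] = abs(v) if use_magnitude else v
    return ScoredNetwork(edges, method_tag=method_tag)


def condition_correlation(G: ScoreMatrix, rho: float = 0.5) -> ScoreMatrix:
    """Shrink a unit-diagonal matrix until it is safely positive definite.

    The silencing closed form treats G as a correlation matrix — the
    identity plus a perturbation — and inverts it. A min-max embedded
    score network has no such guarantee: its off-diagonal block A = G - I
    can have eigenvalues below -1, making G indefinite and its inverse
    noise-dominated. When the spectral radius of A exceeds ``rho`` the
    block is rescaled to exactly ``rho``, which bounds the condition
    number of G by ``(1 + rho) / (1 - rho)`` while preserving the ranking
    information in A (a positive rescale). Matrices already inside the
    bound pass through untouched.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    if G.diagonal_convention != "unit":
        raise ValueError("conditioning applies to unit-diagonal matrices")
    A = G.M - np.eye(G.n)
    eigvals = np.linalg.eigvalsh(A)
    spectral_radius = max(eigvals.max(), -eigvals.min())
    if spectral_radius <= rho:
        return G
    A = A * (rho / spectral_radius)
    return ScoreMatrix(G.proteins, A + np.eye(G.n), "unit")


def refine_network(
    net: ScoredNetwork,
    method: str,
    beta: float = 0.99,
    alpha: float = 1.0,
    restrict_to_initial: bool = True,
    sil_cond_rho: float = 0.5,
) -> ScoredNetwork:
    """Run one refinement operator end to end on a scored network.

    ``method`` is ``"nd"`` (network deconvolution) or ``"silencer"``. By
    default the refined network is re-ranked over exactly the initial
    candidate pairs, so initial and filtered rankings are comparable. The
    silencer path spectrally conditions its input first (see
    :func:`condition_correlation`); deconvolution needs no such step
    because its own eigenvalue shrinkage plays that role.
    """
    keep = set(net.edges) if restrict_to_initial else None
    if method == "nd":
        G = network_to_matrix(net, "zero")
        S = deconvolve_nd(G, beta=beta, alpha=alpha)
        return matrix_to_network(S, keep, method_tag=f"{net.method_tag}+nd")
    if method == "silencer":
        G = condition_correlation(network_to_matrix(net, "unit"), rho=sil_cond_rho)
        S = silence(G)
        return matrix_to_network(
            S, keep, method_tag=f"{net.method_tag}+silencer", use_magnitude=True
        )
    raise ValueError(f"unknown refinement method {method!r}")
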