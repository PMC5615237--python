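import statistics

import numpy as np
import pytest

from apmsnet.evaluate import precision_at_k
from apmsnet.io import ScoredNetwork
from apmsnet.refine import (
    ScoreMatrix,
    condition_correlation,
    deconvolve_nd,
    matrix_to_network,
    network_to_matrix,
    refine_network,
    silence,
)
from apmsnet.scoring import compute_counts, score_dc, score_hart, score_pe, score_sa
from apmsnet.simulate import SimulationConfig, simulate_dataset

from _oracles import closure_series_matrix, silencer_transcription


def random_symmetric(rng, n, spectral_radius):
    A = rng.standard_normal((n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    lam = np.abs(np.linalg.eigvalsh(A)).max()
    return A * (spectral_radius / lam)


class TestNetworkToMatrix:
    def test_min_max_scaling(self):
        net = ScoredNetwork({("A", "B"): 2.0, ("A", "C"): 1.0, ("B", "C"): 0.0})
        G = network_to_matrix(net, "zero")
        assert G.proteins == ["A", "B", "C"]
        assert G.M[0, 1] == 1.0
        assert G.M[0, 2] == 0.5
        assert G.M[1, 2] == 0.0

    def test_single_edge_maps_to_one(self):
        G = network_to_matrix(ScoredNetwork({("A", "B"): 7.0}), "zero")
        assert G.M[0, 1] == 1.0

    def test_symmetry_and_diagonal(self):
        net = ScoredNetwork({("A", "B"): 1.0, ("B", "C"): -3.0})
        for conv, diag in (("zero", 0.0), ("unit", 1.0)):
            G = network_to_matrix(net, conv)
            assert np.array_equal(G.M, G.M.T)
            assert np.all(np.diag(G.M) == diag)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            network_to_matrix(ScoredNetwork({}), "zero")


class TestDeconvolution:
    def test_zero_matrix_fixed_point(self):
        G = ScoreMatrix(["A", "B", "C"], np.zeros((3, 3)), "zero")
        S = deconvolve_nd(G)
        assert np.allclose(S.M, 0.0)

    def test_closed_form_recovery_of_direct_matrix(self, rng):
        """Unscaled deconvolution inverts the transitive-closure series:
        G_obs = G_dir (I - G_dir)^-1 maps back to G_dir entrywise."""
        for n in (5, 12, 20):
            proteins = [f"P{i:02d}" for i in range(n)]
            G_dir = random_symmetric(rng, n, 0.4)
            G_obs = closure_series_matrix(G_dir)
            S = deconvolve_nd(
                ScoreMatrix(proteins, G_obs, "free"), force_no_scaling=True
            )
            assert np.allclose(S.M, G_dir, atol=1e-8)

    @pytest.mark.parametrize("beta", [0.5, 0.9, 0.99])
    def test_scaling_keeps_spectrum_inside_beta(self, rng, beta):
        from apmsnet.refine import scaled_direct_eigenvalues

        for scale in (0.5, 3.0, 40.0):
            eigvals = np.sort(rng.standard_normal(15)) * scale
            out = scaled_direct_eigenvalues(eigvals, beta)
            assert out.min() >= -beta - 1e-12
            assert out.max() <= beta + 1e-12

    def test_two_node_monotone(self):
        prev = -np.inf
        for w in (0.1, 0.4, 0.7, 0.9):
            G = ScoreMatrix(["A", "B"], np.array([[0.0, w], [w, 0.0]]), "zero")
            out = deconvolve_nd(G, force_no_scaling=True).M[0, 1]
            assert out > prev
            prev = out

    @pytest.mark.parametrize("beta", [0.0, 1.0, -1.0, 2.0])
    def test_bad_beta_rejected(self, beta):
        G = ScoreMatrix(["A", "B"], np.zeros((2, 2)), "zero")
        with pytest.raises(ValueError):
            deconvolve_nd(G, beta=beta)

    def test_alpha_keeps_top_fraction(self):
        M = np.array(
            [
                [0.0, 0.9, 0.1, 0.0],
                [0.9, 0.0, 0.5, 0.0],
                [0.1, 0.5, 0.0, 0.2],
                [0.0, 0.0, 0.2, 0.0],
            ]
        )
        proteins = list("ABCD")
        full = deconvolve_nd(ScoreMatrix(proteins, M, "zero"), alpha=1.0)
        half = deconvolve_nd(ScoreMatrix(proteins, M, "zero"), alpha=0.5)
        # alpha=0.5 keeps ceil(0.5*4)=2 entries: 0.9 and 0.5; on the
        # pruned input, the 0.1 and 0.2 edges start from zero weight
        M_kept = np.zeros_like(M)
        M_kept[0, 1] = M_kept[1, 0] = 0.9
        M_kept[1, 2] = M_kept[2, 1] = 0.5
        expected = deconvolve_nd(ScoreMatrix(proteins, M_kept, "zero"), alpha=1.0)
        assert np.allclose(half.M, expected.M, atol=1e-12)
        assert not np.allclose(full.M, half.M)


class TestSilencer:
    def test_identity_maps_to_zero(self):
        G = ScoreMatrix(list("ABC"), np.eye(3), "unit")
        assert np.allclose(silence(G).M, 0.0)

    @pytest.mark.parametrize("g", [-0.9, -0.3, 0.2, 0.5, 0.8])
    def test_two_node_fixed_point(self, g):
        G = ScoreMatrix(["A", "B"], np.array([[1.0, g], [g, 1.0]]), "unit")
        S = silence(G)
        assert S.M[0, 1] == pytest.approx(g, abs=1e-12)
        assert S.M[0, 0] == 0.0

    def test_matches_literal_transcription(self, rng):
        for _ in range(5):
            A = random_symmetric(rng, 6, 0.5)
            G = A + np.eye(6)
            S = silence(ScoreMatrix([f"P{i}" for i in range(6)], G, "unit"))
            ref = silencer_transcription(G)
            ref = (ref + ref.T) / 2.0
            np.fill_diagonal(ref, 0.0)
            assert np.allclose(S.M, ref, atol=1e-10)

    def test_non_unit_diagonal_rejected(self):
        G = ScoreMatrix(list("AB"), np.zeros((2, 2)), "zero")
        with pytest.raises(ValueError):
            silence(G)

    def test_conditioning_restores_positive_definiteness(self, rng):
        A = random_symmetric(rng, 8, 2.5)
        G = ScoreMatrix([f"P{i}" for i in range(8)], A + np.eye(8), "unit")
        assert np.linalg.eigvalsh(G.M).min() < 0  # indefinite input
        G2 = condition_correlation(G, rho=0.5)
        assert np.linalg.eigvalsh(G2.M).min() > 0
        # conditioning is idempotent up to rounding, and a matrix already
        # strictly inside the bound passes through untouched
        G3 = condition_correlation(G2, rho=0.5)
        assert np.allclose(G2.M, G3.M, atol=1e-12)
        inside = ScoreMatrix(
            [f"P{i}" for i in range(8)],
            random_symmetric(rng, 8, 0.3) + np.eye(8),
            "unit",
        )
        assert np.array_equal(condition_correlation(inside, rho=0.5).M, inside.M)


class TestMatrixToNetwork:
    def test_entries_become_ranked_edges(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = 0.3
        M[0, 2] = M[2, 0] = 0.1
        S = ScoreMatrix(list("ABC"), M, "zero")
        net = matrix_to_network(S)
        assert net.ranked()[0][0] == ("A", "B")
        assert set(net.edges) == {("A", "B"), ("A", "C")}

    def test_keep_pairs_restricts(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = 0.3
        M[0, 2] = M[2, 0] = 0.1
        S = ScoreMatrix(list("ABC"), M, "zero")
        net = matrix_to_network(S, keep_pairs={("A", "B")})
        assert set(net.edges) == {("A", "B")}

    def test_zero_matrix_gives_empty_network(self):
        S = ScoreMatrix(list("ABC"), np.zeros((3, 3)), "zero")
        assert len(matrix_to_network(S)) == 0


class TestRefinementProperties:
    """Both operators preserve symmetry and demote indirect associations."""

    def test_symmetric_in_symmetric_out(self, rng):
        A = random_symmetric(rng, 7, 0.6)
        p = [f"P{i}" for i in range(7)]
        S1 = deconvolve_nd(ScoreMatrix(p, A, "zero"))
        S2 = silence(ScoreMatrix(p, A + np.eye(7), "unit"))
        assert np.array_equal(S1.M, S1.M.T)
        assert np.array_equal(S2.M, S2.M.T)

    def test_rank_improvement_without_contaminants(self):
        """Removing indirect co-complex noise is the operators' core job:
        with purification noise limited to indirect retrievals, every
        scorer x refiner combination improves both the mean rank and the
        top-|direct| precision of true direct edges (10 seeds)."""
        scorers = {"sa": score_sa, "pe": score_pe, "dc": score_dc, "hart": score_hart}
        stats = {
            (s, r): {"rank_i": [], "rank_f": [], "prec_i": [], "prec_f": []}
            for s in scorers
            for r in ("nd", "silencer")
        }
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, contaminant_rate=0.0)
            truth, ds = simulate_dataset(cfg)
            counts = compute_counts(ds)
            direct = set(truth.direct_edges)
            k = len(direct)
            for s_name, scorer in scorers.items():
                net = scorer(counts)
                ranks = {p: i for i, (p, _) in enumerate(net.ranked(), start=1)}
                for r_name in ("nd", "silencer"):
                    refined = refine_network(net, r_name)
                    r_ranks = {
                        p: i for i, (p, _) in enumerate(refined.ranked(), start=1)
                    }
                    cell = stats[(s_name, r_name)]
                    cell["rank_i"].append(
                        statistics.mean(ranks[p] for p in direct if p in ranks)
                    )
                    cell["rank_f"].append(
                        statistics.mean(r_ranks[p] for p in direct if p in r_ranks)
                    )
                    cell["prec_i"].append(precision_at_k(net, direct, k))
                    cell["prec_f"].append(precision_at_k(refined, direct, k))
        for (s_name, r_name), cell in stats.items():
            label = f"{s_name}+{r_name}"
            assert statistics.mean(cell["rank_f"]) <= statistics.mean(
                cell["rank_i"]
            ), label
            assert statistics.mean(cell["prec_f"]) > statistics.mean(
                cell["prec_i"]
            ), label
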