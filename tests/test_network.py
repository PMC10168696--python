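"""Co-expression stack: adjacency, TOM, tree cut, eigengenes, merging,
module-trait correlation."""

import numpy as np
import pandas as pd
import pytest

import driftrescue as dr
from driftrescue.drift import bicor
from driftrescue.network import NetworkParams, detect_modules, reassign_by_kme


def tom_oracle(A):
    """Triple-loop topological overlap, independent of the vectorised path."""
    n = A.shape[0]
    k = A.sum(axis=1)
    omega = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                omega[i, j] = 1.0
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n))
            omega[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return omega


def random_adjacency(rng, n):
    A = rng.uniform(0, 1, size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


def two_block_matrix(rng, block=50, noise=0.3, n_samples=40):
    """Two independent latent factors, 50 genes each, within-block bicor ~0.9."""
    f = rng.normal(size=(2, n_samples))
    rows = []
    for b in range(2):
        rows.append(f[b][None, :] + noise * rng.normal(size=(block, n_samples)))
    X = np.vstack(rows)
    return dr.scale_genes(
        dr.ExpressionMatrix(
            pd.DataFrame(X, index=[f"g{i}" for i in range(2 * block)],
                         columns=[f"s{j}" for j in range(n_samples)]),
            scale="log10",
        )
    )


class TestAdjacency:
    def test_perfect_pair_and_anticorrelated_pair(self, rng):
        base = rng.normal(size=12)
        X = np.vstack([base, base, -base])
        m = dr.scale_genes(
            dr.ExpressionMatrix(pd.DataFrame(X, index=["a", "b", "c"]), scale="log10")
        )
        A = dr.adjacency_signed_hybrid(m, NetworkParams())
        assert A[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert A[0, 2] == 0.0  # signed hybrid clips negative correlations
        assert A[0, 0] == 0.0

    def test_matches_bruteforce_bicor_powering(self, rng):
        X = rng.normal(size=(20, 15))
        m = dr.scale_genes(dr.ExpressionMatrix(pd.DataFrame(X), scale="log10"))
        A = dr.adjacency_signed_hybrid(m, NetworkParams(beta=3))
        Xs = m.values.to_numpy()
        for i in range(20):
            for j in range(i + 1, 20):
                expected = max(bicor(Xs[i], Xs[j]), 0.0) ** 3
                assert A[i, j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_rejected(self, matrix_factory):
        m = dr.scale_genes(matrix_factory(np.random.default_rng(0).normal(size=(5, 3))))
        with pytest.raises(ValueError, match="4 samples"):
            dr.adjacency_signed_hybrid(m, NetworkParams())


class TestTOM:
    def test_three_node_hand_computation(self):
        A = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        omega = dr.topological_overlap(A)
        assert omega[0, 1] == pytest.approx(1.0)
        assert omega[0, 2] == pytest.approx(0.0)

    def test_empty_graph(self):
        omega = dr.topological_overlap(np.zeros((4, 4)))
        off = omega[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(5):
            A = random_adjacency(rng, 15)
            np.testing.assert_allclose(
                dr.topological_overlap(A), tom_oracle(A), atol=1e-12
            )

    def test_range_and_dissimilarity_validity(self, rng):
        A = random_adjacency(rng, 30)
        omega = dr.topological_overlap(A)
        assert omega.min() >= 0 and omega.max() <= 1
        d = dr.tom_dissimilarity(A)
        assert (np.diag(d) == 0).all() and d.min() >= 0
        np.testing.assert_allclose(d, d.T)

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            dr.topological_overlap(rng.uniform(size=(4, 4)))
        A = random_adjacency(rng, 4)
        np.fill_diagonal(A, 0.5)
        with pytest.raises(ValueError, match="diagonal"):
            dr.topological_overlap(A)
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            dr.topological_overlap(random_adjacency(rng, 4) * 3)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        m = two_block_matrix(rng)
        params = NetworkParams(min_module_size=20)
        A = dr.adjacency_signed_hybrid(m, params)
        labels = detect_modules(dr.tom_dissimilarity(A), params, gene_ids=m.gene_ids)
        found = labels[labels != "grey"]
        assert found.nunique() == 2
        truth = ["m1"] * 50 + ["m2"] * 50
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_pure_noise_is_mostly_grey(self):
        grey_fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = dr.scale_genes(
                dr.ExpressionMatrix(pd.DataFrame(rng.normal(size=(200, 30))), scale="log10")
            )
            params = NetworkParams()
            A = dr.adjacency_signed_hybrid(m, params)
            labels = detect_modules(dr.tom_dissimilarity(A), params)
            grey_fracs.append((labels == "grey").mean())
        assert np.mean(grey_fracs) >= 0.9

    def test_block_below_min_size_goes_grey(self, rng):
        f = rng.normal(size=(1, 40))
        X = np.vstack([f + 0.3 * rng.normal(size=(10, 40)),
                       rng.normal(size=(60, 40))])
        m = dr.scale_genes(dr.ExpressionMatrix(pd.DataFrame(X), scale="log10"))
        params = NetworkParams(min_module_size=30)
        A = dr.adjacency_signed_hybrid(m, params)
        labels = detect_modules(dr.tom_dissimilarity(A), params)
        assert (labels.iloc[:10] == "grey").all()

    def test_gene_permutation_invariance_up_to_renaming(self, rng):
        from sklearn.metrics import adjusted_rand_score

        m = two_block_matrix(rng)
        params = NetworkParams(min_module_size=20)
        D = dr.tom_dissimilarity(dr.adjacency_signed_hybrid(m, params))
        labels = detect_modules(D, params)
        perm = rng.permutation(m.n_genes)
        labels_p = detect_modules(D[np.ix_(perm, perm)], params)
        assert adjusted_rand_score(labels.to_numpy()[perm], labels_p.to_numpy()) == 1.0

    def test_min_size_larger_than_matrix_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_modules(np.zeros((5, 5)), NetworkParams(min_module_size=10))


class TestEigengenes:
    def test_identical_genes_module(self, rng):
        base = rng.normal(size=15)
        X = np.tile(base, (5, 1))
        m = dr.ExpressionMatrix(pd.DataFrame(X), scale="log10")
        labels = pd.Series(["blue"] * 5, index=m.gene_ids)
        eig, ve = dr.module_eigengenes(m, labels)
        scaled = (base - base.mean()) / base.std(ddof=1)
        r = np.corrcoef(eig.loc["blue"], scaled)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)
        assert ve["blue"] == pytest.approx(1.0)

    def test_sign_orientation_positive_toward_members(self, rng):
        f = rng.normal(size=20)
        X = f[None, :] + 0.2 * rng.normal(size=(8, 20))
        for flip in (1.0, -1.0):
            m = dr.ExpressionMatrix(pd.DataFrame(flip * X), scale="log10")
            labels = pd.Series(["blue"] * 8, index=m.gene_ids)
            eig, _ = dr.module_eigengenes(m, labels)
            members = dr.scale_genes(m).values.to_numpy()
            corr = np.corrcoef(np.vstack([eig.loc["blue"], members]))[0, 1:]
            assert corr.mean() > 0

    def test_planted_factor_recovered(self, rng):
        f = rng.normal(size=30)
        X = f[None, :] + 0.3 * rng.normal(size=(40, 30))
        m = dr.ExpressionMatrix(pd.DataFrame(X), scale="log10")
        labels = pd.Series(["blue"] * 40, index=m.gene_ids)
        eig, _ = dr.module_eigengenes(m, labels)
        assert abs(np.corrcoef(eig.loc["blue"], f)[0, 1]) >= 0.95

    def test_singleton_module_is_scaled_gene(self, rng):
        X = rng.normal(size=(3, 10))
        m = dr.ExpressionMatrix(pd.DataFrame(X), scale="log10")
        labels = pd.Series(["blue", "grey", "grey"], index=m.gene_ids)
        eig, ve = dr.module_eigengenes(m, labels)
        r = np.corrcoef(eig.loc["blue"], X[0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)


class TestMerging:
    def _labelled_blocks(self, rng, shared_factor):
        f1 = rng.normal(size=30)
        f2 = f1 if shared_factor else rng.normal(size=30)
        X = np.vstack([
            f1[None, :] + 0.2 * rng.normal(size=(20, 30)),
            f2[None, :] + 0.2 * rng.normal(size=(20, 30)),
        ])
        m = dr.ExpressionMatrix(pd.DataFrame(X), scale="log10")
        labels = pd.Series(["blue"] * 20 + ["brown"] * 20, index=m.gene_ids)
        return m, labels

    def test_duplicated_blocks_merge(self, rng):
        m, labels = self._labelled_blocks(rng, shared_factor=True)
        merged = dr.merge_close_modules(m, labels, merge_cut=0.15)
        assert merged[merged != "grey"].nunique() == 1

    def test_orthogonal_blocks_do_not_merge(self, rng):
        m, labels = self._labelled_blocks(rng, shared_factor=False)
        merged = dr.merge_close_modules(m, labels, merge_cut=0.15)
        assert merged[merged != "grey"].nunique() == 2

    def test_zero_cut_is_identity(self, rng):
        m, labels = self._labelled_blocks(rng, shared_factor=True)
        assert dr.merge_close_modules(m, labels, merge_cut=0.0).equals(labels)


class TestKmeReassignment:
    def test_background_genes_expelled_and_stragglers_reattached(self, rng):
        f = rng.normal(size=30)
        X = np.vstack([
            f[None, :] + 0.3 * rng.normal(size=(40, 30)),  # true members
            rng.normal(size=(20, 30)),                      # background
        ])
        m = dr.scale_genes(dr.ExpressionMatrix(pd.DataFrame(X), scale="log10"))
        # deliberately wrong start: 5 members grey, 5 background in the module
        labels = pd.Series(["blue"] * 35 + ["grey"] * 5 + ["blue"] * 5 + ["grey"] * 15,
                           index=m.gene_ids)
        out = reassign_by_kme(m, labels, kme_threshold=0.5)
        assert (out.iloc[:40] == "blue").all()
        assert (out.iloc[40:] == "grey").all()


class TestModuleTrait:
    def test_eigengene_equal_to_trait(self):
        eig = pd.DataFrame([[0, 0, 0, 1, 1, 1]], index=["blue"],
                           columns=[f"s{i}" for i in range(6)], dtype=float)
        traits = pd.DataFrame({"cond": [0, 0, 0, 1, 1, 1]},
                              index=[f"s{i}" for i in range(6)], dtype=float)
        out = dr.module_trait_correlation(eig, traits)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_planted_cord_module_is_significant_across_seeds(self):
        for seed in range(1, 11):
            p = dr.GeneratorParams(n_genes=2000, seed=seed)
            m, s, truth = dr.generate_study(p)
            labels = truth.table["module_id"].replace("", "grey")
            eig, _ = dr.module_eigengenes(dr.scale_genes(m), labels)
            traits = pd.DataFrame(
                {"cord": (s["environment"] == "cord").astype(float).to_numpy()},
                index=s["sample_id"].to_numpy(),
            )
            out = dr.module_trait_correlation(eig, traits)
            row = out[out["module"] == "module_1"].iloc[0]
            assert row["r"] > 0 and row["q"] < 0.05, seed

    def test_shuffled_traits_fall_below_permutation_quantile(self, rng):
        p = dr.GeneratorParams(n_genes=1000, seed=4)
        m, s, truth = dr.generate_study(p)
        labels = truth.table["module_id"].replace("", "grey")
        eig, _ = dr.module_eigengenes(dr.scale_genes(m), labels)
        cord = (s["environment"] == "cord").astype(float).to_numpy()
        hits = 0
        for mod in eig.index:
            e = eig.loc[mod].to_numpy()
            r_obs = abs(dr.bicor(e, rng.permutation(cord), 0.05))
            null = np.array([
                abs(dr.bicor(e, rng.permutation(cord), 0.05)) for _ in range(200)
            ])
            hits += r_obs <= np.quantile(null, 0.95)
        assert hits >= 0.95 * len(eig.index) - 1e-9

    def test_misaligned_traits_rejected(self):
        eig = pd.DataFrame([[0.0, 1.0]], index=["blue"], columns=["s0", "s1"])
        traits = pd.DataFrame({"c": [0.0, 1.0]}, index=["sX", "sY"])
        with pytest.raises(ValueError, match="aligned"):
            dr.module_trait_correlation(eig, traits)


def test_full_stack_recovery_on_planted_blocks():
    from sklearn.metrics import adjusted_rand_score

    p = dr.GeneratorParams(n_genes=800, pi_drift=0, pi_flow_rescue=0, pi_cc_rescue=0,
                           n_modules=5, module_size=120, module_loading=1.0,
                           noise_sd=0.5, seed=3)
    m, s, truth = dr.generate_study(p)
    labels, eig, ve = dr.build_network_modules(dr.scale_genes(m))
    truth_lab = truth.table["module_id"].replace("", "grey")
    assert adjusted_rand_score(truth_lab, labels.loc[truth_lab.index]) >= 0.8
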