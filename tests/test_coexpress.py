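"""Network construction: correlation, soft threshold, TOM, modules,
eigengenes, kME, and merging — each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest

from receptorfunc.containers import ExpressionMatrix
from receptorfunc.coexpress import (
    EigengeneMatrix,
    ModulePartition,
    bicor,
    clean_membership,
    compute_eigengenes,
    compute_kme,
    detect_modules,
    merge_modules,
    pick_power,
    scale_free_fit,
    signed_adjacency,
    tom_similarity,
)


def _frame(arr, prefix="g"):
    arr = np.asarray(arr, float)
    idx = [f"{prefix}{i}" for i in range(arr.shape[0])]
    cols = [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=idx, columns=cols)


def bicor_oracle(x, y, c=9.0):
    """Independent scalar evaluation of the biweight midcorrelation."""
    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (c * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    xt, yt = weights(np.asarray(x, float)), weights(np.asarray(y, float))
    return float(
        np.sum(xt * yt) / np.sqrt(np.sum(xt**2)) / np.sqrt(np.sum(yt**2))
    )


class TestBicor:
    def test_duplicate_and_negated_genes(self, rng):
        x = rng.normal(size=12)
        C = bicor(_frame([x, x, -x]))
        assert C.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert C.iloc[0, 2] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(4, 5))
        C = bicor(_frame(X))
        for i in range(4):
            for j in range(i + 1, 4):
                assert C.iloc[i, j] == pytest.approx(
                    bicor_oracle(X[i], X[j]), abs=1e-10
                )

    def test_downweights_gross_outlier(self):
        rng = np.random.default_rng(1)
        clean = rng.normal(size=20)
        partner = clean + 0.2 * rng.normal(size=20)
        spoiled = partner.copy()
        spoiled[0] = -40.0  # one gross outlier breaking the linear relation
        C = bicor(_frame([clean, spoiled]))
        pearson = np.corrcoef(clean, spoiled)[0, 1]
        assert abs(C.iloc[0, 1]) > abs(pearson)

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="4 samples"):
            bicor(_frame(rng.normal(size=(3, 3))))

    def test_constant_gene_warns_and_zeroes(self, rng):
        X = np.vstack([np.full(8, 2.0), rng.normal(size=(2, 8))])
        with pytest.warns(UserWarning, match="constant"):
            C = bicor(_frame(X))
        assert C.iloc[0, 1] == 0.0
        assert C.iloc[0, 0] == 1.0

    def test_mad_zero_gene_falls_back_to_pearson(self):
        # > half the values equal -> MAD 0, but the gene is not constant
        x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 4.0, 7.0, 9.0])
        y = np.arange(8.0)
        C = bicor(_frame([x, y]))
        assert C.iloc[0, 1] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)


class TestSignedAdjacency:
    def test_endpoints_any_power(self):
        cor = pd.DataFrame([[1.0, 1.0, -1.0], [1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])
        for beta in (1, 6, 14):
            a = signed_adjacency(cor, beta)
            assert a.iloc[0, 1] == pytest.approx(1.0)
            assert a.iloc[0, 2] == pytest.approx(0.0)
        assert signed_adjacency(cor, 14).iloc[1, 2] == pytest.approx(0.5**14)

    def test_matches_scalar_loop(self, rng):
        C = rng.uniform(-1, 1, size=(6, 6))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        cor = pd.DataFrame(C)
        a = signed_adjacency(cor, 14).to_numpy()
        for i in range(6):
            for j in range(6):
                assert a[i, j] == pytest.approx(
                    (0.5 * (1 + C[i, j])) ** 14, abs=1e-12
                )

    def test_monotone_in_correlation(self):
        cors = np.linspace(-1, 1, 21)
        vals = (0.5 * (1 + cors)) ** 6
        assert (np.diff(vals) >= 0).all()

    def test_requires_positive_power(self):
        with pytest.raises(ValueError):
            signed_adjacency(pd.DataFrame([[1.0]]), 0)


def tom_oracle(A):
    """Triple-loop evaluation of the topological overlap formula."""
    n = A.shape[0]
    k = A.sum(axis=1) - np.diag(A)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestTOM:
    def test_isolated_pair_is_zero(self):
        A = np.eye(4)
        A[2, 3] = A[3, 2] = 0.5  # pair (0,1): no edge, no common neighbor
        t = tom_similarity(pd.DataFrame(A))
        assert t.iloc[0, 1] == 0.0

    def test_complete_unit_graph_is_one(self):
        n = 5
        t = tom_similarity(pd.DataFrame(np.ones((n, n))))
        np.testing.assert_allclose(t.to_numpy(), 1.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_triple_loop_on_random_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        A = rng.uniform(0, 1, size=(n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        t = tom_similarity(pd.DataFrame(A)).to_numpy()
        np.testing.assert_allclose(t, tom_oracle(A), atol=1e-12)


class TestPickPower:
    def test_single_candidate_returned(self, rng):
        X = rng.normal(size=(30, 20))
        cor = pd.DataFrame(np.corrcoef(X))
        beta, table = pick_power(cor, candidate_powers=[7])
        assert beta == 7
        assert len(table) == 1

    def test_degenerate_connectivity_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            scale_free_fit(np.full(10, 3.0))

    def test_fallback_is_fourteen_when_no_power_reaches_target(self, rng):
        X = rng.normal(size=(40, 30))  # pure noise: nothing scale-free
        cor = pd.DataFrame(np.corrcoef(X))
        beta, table = pick_power(cor, candidate_powers=[1, 2, 3], target_r2=0.999)
        assert beta == 14
        assert (table["signed_r2"] < 0.999).all()

    def test_planted_hub_structure_reaches_target(self):
        """Hub-dominated factor data yields a decreasing log-log degree fit;
        the chosen power must reach the target R^2 and be the smallest doing so."""
        rng = np.random.default_rng(42)
        n_genes, n_samples = 300, 150
        g = rng.uniform(0, 1, n_genes) ** 3  # heavy-tailed memberships -> hubs
        f = rng.normal(size=n_samples)
        X = np.outer(g, f) + np.sqrt(1 - g[:, None] ** 2) * rng.normal(
            size=(n_genes, n_samples)
        )
        cor = pd.DataFrame(np.corrcoef(X))
        beta, table = pick_power(cor, target_r2=0.8)
        reached = table.loc[table["signed_r2"] >= 0.8, "power"]
        assert len(reached) > 0
        assert beta == reached.iloc[0]


class TestModules:
    def _two_block_data(self, rng, n=50, cor=0.9):
        f1, f2 = rng.normal(size=(2, 60))
        w = np.sqrt(cor)
        X = np.vstack(
            [
                w * f1 + np.sqrt(1 - cor) * rng.normal(size=(n, 60)),
                w * f2 + np.sqrt(1 - cor) * rng.normal(size=(n, 60)),
            ]
        )
        return _frame(X)

    def test_two_planted_blocks_recovered_exactly(self, rng):
        data = self._two_block_data(rng)
        diss = 1.0 - tom_similarity(signed_adjacency(bicor(data), 6))
        part = detect_modules(diss, min_module_size=30)
        assert len(part.module_ids) == 2
        truth = np.repeat([1, 2], 50)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, part.labels.to_numpy()) == 1.0

    def test_min_size_larger_than_clusters_gives_empty_partition(self, rng):
        data = self._two_block_data(rng)
        diss = 1.0 - tom_similarity(signed_adjacency(bicor(data), 6))
        with pytest.warns(UserWarning, match="minimum size"):
            part = detect_modules(diss, min_module_size=200)
        assert (part.labels == 0).all()

    def test_labels_ranked_by_size(self, rng):
        f1, f2 = np.random.default_rng(5).normal(size=(2, 60))
        big = 0.95 * f1 + 0.1 * np.random.default_rng(6).normal(size=(70, 60))
        small = 0.95 * f2 + 0.1 * np.random.default_rng(7).normal(size=(40, 60))
        data = _frame(np.vstack([small, big]))  # smaller block listed first
        diss = 1.0 - tom_similarity(signed_adjacency(bicor(data), 6))
        part = detect_modules(diss, min_module_size=30)
        assert part.sizes[1] > part.sizes[2]


class TestEigengenes:
    def test_identical_genes_give_perfect_correlation(self, rng):
        x = rng.normal(size=30)
        data = _frame(np.vstack([x, x, x, rng.normal(size=(2, 30))]))
        part = ModulePartition(labels=pd.Series([1, 1, 1, 0, 0], index=data.index))
        eig = compute_eigengenes(data, part)
        r = np.corrcoef(eig.values.loc[1], x)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert eig.explained_variance[1] == pytest.approx(1.0, abs=1e-10)

    def test_orientation_mean_member_kme_nonnegative(self, rng):
        f = rng.normal(size=40)
        X = 0.8 * f + 0.3 * rng.normal(size=(20, 40))
        for sign in (1.0, -1.0):
            data = _frame(sign * X)
            part = ModulePartition(labels=pd.Series(1, index=data.index))
            eig = compute_eigengenes(data, part)
            kme = compute_kme(data, eig)
            assert kme[1].mean() >= 0

    def test_single_gene_module_warns(self, rng):
        data = _frame(rng.normal(size=(3, 20)))
        part = ModulePartition(labels=pd.Series([1, 2, 2], index=data.index))
        with pytest.warns(UserWarning, match="single gene"):
            eig = compute_eigengenes(data, part)
        assert abs(np.corrcoef(eig.values.loc[1], data.iloc[0])[0, 1]) == pytest.approx(1.0)

    def test_planted_module_explains_more_than_random_set(self, pipeline_result, rng):
        res = pipeline_result
        part = res.partition
        ev_planted = res.eigengenes.explained_variance[1]
        size = int(part.sizes[1])
        random_genes = rng.choice(part.labels.index, size=size, replace=False)
        fake = ModulePartition(
            labels=pd.Series(
                [1 if g in set(random_genes) else 0 for g in part.labels.index],
                index=part.labels.index,
            )
        )
        ev_random = compute_eigengenes(res.residuals, fake).explained_variance[1]
        assert ev_planted > ev_random


class TestKME:
    def test_matches_loop_oracle(self, rng):
        data = _frame(rng.normal(size=(10, 25)))
        part = ModulePartition(labels=pd.Series([1] * 5 + [2] * 5, index=data.index))
        eig = compute_eigengenes(data, part)
        kme = compute_kme(data, eig)
        for g in data.index:
            for m in (1, 2):
                r = np.corrcoef(data.loc[g], eig.values.loc[m])[0, 1]
                assert kme.loc[g, m] == pytest.approx(r, abs=1e-10)

    def test_zero_variance_gene_row_is_zero(self, rng):
        X = rng.normal(size=(5, 20))
        X[2] = 3.0
        data = _frame(X)
        part = ModulePartition(labels=pd.Series([1] * 5, index=data.index))
        with pytest.warns(UserWarning):
            eig = compute_eigengenes(data, part)
            kme = compute_kme(data, eig)
        assert (kme.loc["g2"] == 0).all()


class TestMerge:
    def _correlated_module_data(self, rho_f, rng, n_genes=40, n_samples=80):
        """Two modules whose latent factors correlate at rho_f."""
        f1 = rng.normal(size=n_samples)
        f2 = rho_f * f1 + np.sqrt(1 - rho_f**2) * rng.normal(size=n_samples)
        X = np.vstack(
            [
                0.95 * f + 0.2 * rng.normal(size=(n_genes, n_samples))
                for f in (f1, f2)
            ]
        )
        data = _frame(X)
        labels = pd.Series([1] * n_genes + [2] * n_genes, index=data.index)
        return data, ModulePartition(labels=labels)

    def test_highly_correlated_modules_merge(self, rng):
        data, part = self._correlated_module_data(0.95, rng)
        eig = compute_eigengenes(data, part)
        assert np.corrcoef(eig.values)[0, 1] > 0.75
        merged, _ = merge_modules(part, eig, data, merge_height=0.25)
        assert len(merged.module_ids) == 1

    def test_weakly_correlated_modules_stay(self, rng):
        data, part = self._correlated_module_data(0.5, rng)
        eig = compute_eigengenes(data, part)
        merged, eig2 = merge_modules(part, eig, data, merge_height=0.25)
        assert len(merged.module_ids) == 2
        # fixed point: no remaining pair closer than the merge height
        C = np.corrcoef(eig2.values)
        assert (1 - C[0, 1]) >= 0.25

    def test_chain_of_three_modules_collapses_to_fixed_point(self, rng):
        """Pairwise eigengene correlations ~{0.85, 0.85, 0.72}: iterated
        merging must end in a single module."""
        n, s = 40, 200
        f1 = rng.normal(size=s)
        f2 = 0.85 * f1 + np.sqrt(1 - 0.85**2) * rng.normal(size=s)
        f3 = 0.85 * f2 + np.sqrt(1 - 0.85**2) * rng.normal(size=s)
        X = np.vstack(
            [0.97 * f + 0.15 * rng.normal(size=(n, s)) for f in (f1, f2, f3)]
        )
        data = _frame(X)
        part = ModulePartition(labels=pd.Series([1] * n + [2] * n + [3] * n, index=data.index))
        eig = compute_eigengenes(data, part)
        merged, eig2 = merge_modules(part, eig, data, merge_height=0.25)
        assert len(merged.module_ids) == 1
        again, _ = merge_modules(merged, eig2, data, merge_height=0.25)
        assert again.labels.equals(merged.labels)


def test_clean_membership_strips_weak_members(rng):
    f = rng.normal(size=60)
    strong = 0.9 * f + 0.3 * rng.normal(size=(35, 60))
    noise = rng.normal(size=(5, 60))
    data = _frame(np.vstack([strong, noise]))
    part = ModulePartition(labels=pd.Series(1, index=data.index))
    cleaned = clean_membership(data, part, min_kme=0.3, min_module_size=10)
    assert (cleaned.labels.iloc[:35] == 1).all()
    assert (cleaned.labels.iloc[35:] == 0).all()
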