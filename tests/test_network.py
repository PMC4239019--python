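"""Co-expression network: adjacency/TOM, soft power, modules, eigengenes,
families, trait association and alignment-order scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import devalign as dv
from devalign.network import (
    ModuleSet, connectivity, control_stage_levels, induced_stage_trait, scale_free_fit,
)
from tests.conftest import make_matrix


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Hand/brute-force topological overlap for a small adjacency."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestAdjacencyAndTOM:
    def test_adjacency_bounds_symmetry_diagonal(self, small_cohort):
        matrix, _ = small_cohort
        sub = matrix.subset_genes(matrix.gene_ids[:30])
        a = dv.adjacency(sub, power=6).to_numpy()
        assert ((a >= 0) & (a <= 1)).all()
        assert np.allclose(a, a.T) and np.allclose(np.diag(a), 1.0)

    def test_tom_matches_hand_computation_on_4_genes(self):
        a = np.array([
            [1.0, 0.8, 0.2, 0.1],
            [0.8, 1.0, 0.4, 0.3],
            [0.2, 0.4, 1.0, 0.9],
            [0.1, 0.3, 0.9, 1.0],
        ])
        adj = pd.DataFrame(a, index=list("abcd"), columns=list("abcd"))
        got = dv.topological_overlap(adj).to_numpy()
        assert np.allclose(got, brute_force_tom(a), atol=1e-12)

    def test_tom_bounds(self, small_cohort):
        matrix, _ = small_cohort
        sub = matrix.subset_genes(matrix.gene_ids[:40])
        tom = dv.topological_overlap(dv.adjacency(sub, 6)).to_numpy()
        assert ((tom >= 0) & (tom <= 1 + 1e-12)).all()
        assert np.allclose(np.diag(tom), 1.0)

    def test_random_tom_matches_brute_force(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 1, (8, 8))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(8)], columns=[f"g{i}" for i in range(8)])
        assert np.allclose(dv.topological_overlap(adj).to_numpy(), brute_force_tom(a), atol=1e-8)


class TestSoftPower:
    def test_exact_power_law_fits_perfectly(self):
        """Connectivities placed at integer values with frequencies on an
        exact power law give a log-log R^2 of 1."""
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        counts = (3600 / values**2).astype(int)  # freq ~ k^-2
        k = np.repeat(values, counts)
        r2, slope = scale_free_fit(k, n_bins=5)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert slope == pytest.approx(-2.0, abs=0.01)

    def test_fit_table_matches_independent_regression_oracle(self, small_cohort):
        matrix, _ = small_cohort
        sub = matrix.subset_genes(matrix.gene_ids[:60])
        _, table = dv.select_soft_power(sub, dv.NetworkConfig(candidate_powers=(1, 2, 4, 6)))
        for row in table.itertuples():
            adj = dv.adjacency(sub, row.power)
            k = connectivity(adj).to_numpy()
            k = k[k > 0]
            counts, edges = np.histogram(k, bins=10)
            sums, _ = np.histogram(k, bins=edges, weights=k)
            mask = counts > 0
            x = np.log10(sums[mask] / counts[mask])
            y = np.log10(counts[mask] / counts.sum())
            fit = sps.linregress(x, y)
            assert row.scale_free_r2 == pytest.approx(fit.rvalue**2, abs=1e-10)
            assert row.slope == pytest.approx(fit.slope, abs=1e-10)

    def test_degenerate_equal_correlations_fall_back_with_warning(self):
        t = np.linspace(0, 1, 8)
        x = np.vstack([2 * t, 3 * t + 1, -t, 0.5 * t])  # all |cor| = 1
        m = make_matrix(x, ["A"] * 8)
        with pytest.warns(UserWarning):
            power, table = dv.select_soft_power(m, dv.NetworkConfig(candidate_powers=(1, 2)))
        assert power in (1, 2)

    def test_too_few_genes_rejected(self):
        m = make_matrix(np.random.default_rng(1).normal(size=(2, 5)), ["A"] * 5)
        with pytest.raises(ValueError, match="at least 3 genes"):
            dv.select_soft_power(m)


class TestModules:
    def test_two_orthogonal_noise_free_modules_recovered_exactly(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=24)
        v = rng.normal(size=24)
        v -= u @ v / (u @ u) * u  # orthogonalise
        rows, ids = [], []
        for i in range(25):
            rows.append(u * (1 + 0.1 * i))
            ids.append(f"mu_{i}")
        for i in range(25):
            rows.append(v * (1 + 0.1 * i))
            ids.append(f"mv_{i}")
        m = make_matrix(np.array(rows), ["A"] * 24, gene_ids=ids)
        modules = dv.detect_modules(m, power=6, config=dv.NetworkConfig(min_module_size=10))
        from sklearn.metrics import adjusted_rand_score

        planted = [0] * 25 + [1] * 25
        assert adjusted_rand_score(planted, modules.labels.loc[ids]) == 1.0

    def test_small_clusters_go_to_label_zero(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=20)
        rows = [u * (1 + 0.05 * i) for i in range(30)] + [rng.normal(size=20) for _ in range(5)]
        ids = [f"g{i}" for i in range(35)]
        m = make_matrix(np.array(rows), ["A"] * 20, gene_ids=ids)
        modules = dv.detect_modules(m, power=6, config=dv.NetworkConfig(min_module_size=10))
        assert set(modules.labels.iloc[:30]) == {1}
        assert (modules.labels.iloc[30:] == 0).all()

    def test_labels_invariant_to_gene_order(self, small_cohort):
        matrix, _ = small_cohort
        sub = matrix.subset_genes(matrix.gene_ids[:80])
        rng = np.random.default_rng(4)
        perm = list(rng.permutation(sub.gene_ids))
        shuffled = sub.subset_genes(perm)
        cfg = dv.NetworkConfig(min_module_size=10)
        m1 = dv.detect_modules(sub, 6, cfg).labels.sort_index()
        m2 = dv.detect_modules(shuffled, 6, cfg).labels.sort_index()
        assert m1.equals(m2)


class TestEigengenes:
    def _modules_from_labels(self, genes, labels):
        return ModuleSet(labels=pd.Series(labels, index=genes), power=6,
                         linkage=np.empty((0, 4)), cut_height=0.9)

    def test_rank_one_module_correlates_perfectly_with_pattern(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=15)
        rows = [v * s + o for s, o in [(2, 1), (3, -1), (0.5, 0)]]
        m = make_matrix(np.array(rows), ["A"] * 15)
        modules = self._modules_from_labels(m.gene_ids, [1, 1, 1])
        e = dv.module_eigengenes(m, modules).loc["ME1"].to_numpy()
        r = np.corrcoef(e, v)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_unit_norm_and_sign_convention(self, small_cohort):
        matrix, truth = small_cohort
        members = truth.module_membership
        modules = self._modules_from_labels(members.index, members.to_numpy())
        eg = dv.module_eigengenes(matrix, modules)
        for me in eg.index:
            v = eg.loc[me].to_numpy()
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
            mid = int(me[2:])
            genes = members.index[members == mid]
            cors = [np.corrcoef(v, matrix.values.loc[g])[0, 1] for g in genes]
            assert np.mean(cors) >= 0

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 20))
        m = make_matrix(x, ["A"] * 20)
        modules = self._modules_from_labels(m.gene_ids, [1] * 12)
        e = dv.module_eigengenes(m, modules).loc["ME1"].to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        w, vecs = np.linalg.eigh(z.T @ z)
        oracle = vecs[:, np.argmax(w)]
        assert min(np.abs(e - oracle).max(), np.abs(e + oracle).max()) < 1e-8

    def test_eigengene_variance_dominance(self):
        """The eigengene explains at least as much standardized-module
        variance as random unit-norm combinations of member genes."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 25))
        m = make_matrix(x, ["A"] * 25)
        modules = self._modules_from_labels(m.gene_ids, [1] * 10)
        e = dv.module_eigengenes(m, modules).loc["ME1"].to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        explained = np.linalg.norm(z @ e) ** 2
        for _ in range(50):
            w = rng.normal(size=25)
            w /= np.linalg.norm(w)
            assert np.linalg.norm(z @ w) ** 2 <= explained + 1e-9

    def test_single_gene_module_is_standardized_gene(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(1, 10))
        m = make_matrix(x, ["A"] * 10)
        modules = self._modules_from_labels(m.gene_ids, [1])
        e = dv.module_eigengenes(m, modules).loc["ME1"].to_numpy()
        z = (x[0] - x[0].mean()) / x[0].std(ddof=1)
        z /= np.linalg.norm(z)
        assert np.allclose(np.abs(e), np.abs(z), atol=1e-9)


class TestFamilies:
    def _eigengene_frame(self, vectors):
        return pd.DataFrame(vectors, index=[f"ME{i + 1}" for i in range(len(vectors))],
                            columns=[f"s{j}" for j in range(len(vectors[0]))])

    def test_perfectly_correlated_modules_share_a_family(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=12)
        eg = self._eigengene_frame([v, 2 * v + 0.5, rng.normal(size=12)])
        fam = dv.cluster_families(eg, cut_height=0.5)
        assert fam.labels["ME1"] == fam.labels["ME2"]

    def test_anticorrelated_modules_split_below_distance_two(self):
        v = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        eg = self._eigengene_frame([v, -v])
        fam = dv.cluster_families(eg, cut_height=1.5)
        assert fam.labels["ME1"] != fam.labels["ME2"]

    def test_six_module_families_match_linkage_oracle(self):
        rng = np.random.default_rng(10)
        base1, base2 = rng.normal(size=20), rng.normal(size=20)
        vectors = [base1 + 0.1 * rng.normal(size=20) for _ in range(3)]
        vectors += [base2 + 0.1 * rng.normal(size=20) for _ in range(3)]
        eg = self._eigengene_frame(vectors)
        fam = dv.cluster_families(eg, cut_height=0.5)
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        d = 1 - np.corrcoef(np.array(vectors))
        np.fill_diagonal(d, 0.0)
        z = hierarchy.linkage(squareform(d, checks=False), method="average")
        oracle = hierarchy.fcluster(z, t=0.5, criterion="distance")
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(oracle, fam.labels.to_numpy()) == 1.0
        assert fam.labels.nunique() == 2


class TestTraitAssociation:
    def test_trait_equal_to_eigengene_gives_r_one(self):
        t = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        eg = pd.DataFrame([t.astype(float)], index=["ME1"],
                          columns=[f"s{i}" for i in range(8)])
        traits = pd.DataFrame({"T": t}, index=eg.columns)
        r, p = dv.trait_association(eg, traits)
        assert r.loc["ME1", "T"] == pytest.approx(1.0)
        assert p.loc["ME1", "T"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_pearson_and_t_cdf(self):
        rng = np.random.default_rng(11)
        eg = pd.DataFrame(rng.normal(size=(3, 40)), index=["ME1", "ME2", "ME3"],
                          columns=[f"s{i}" for i in range(40)])
        traits = pd.DataFrame({"A": rng.integers(0, 2, 40), "B": rng.integers(0, 2, 40)},
                              index=eg.columns)
        r, p = dv.trait_association(eg, traits)
        for me in eg.index:
            for name in traits.columns:
                rr, pp = sps.pearsonr(eg.loc[me], traits[name])
                assert r.loc[me, name] == pytest.approx(rr, abs=1e-10)
                assert p.loc[me, name] == pytest.approx(pp, abs=1e-10)

    def test_constant_trait_reported_missing(self):
        eg = pd.DataFrame(np.random.default_rng(12).normal(size=(1, 10)), index=["ME1"],
                          columns=[f"s{i}" for i in range(10)])
        traits = pd.DataFrame({"T": np.ones(10, dtype=int)}, index=eg.columns)
        r, p = dv.trait_association(eg, traits)
        assert np.isnan(r.loc["ME1", "T"]) and np.isnan(p.loc["ME1", "T"])

    def test_non_binary_trait_rejected(self):
        eg = pd.DataFrame(np.zeros((1, 4)), index=["ME1"], columns=list("abcd"))
        traits = pd.DataFrame({"T": [0, 1, 2, 1]}, index=list("abcd"))
        with pytest.raises(ValueError, match="0/1"):
            dv.trait_association(eg, traits)


class TestAlignmentOrders:
    def _cohort_metadata(self):
        rows = []
        for label, n, stage in [("C1", 2, 1), ("C2", 2, 2), ("C3", 1, 3), ("C4", 1, 4)]:
            for i in range(n):
                rows.append((f"{label}_{i}", label, "control", stage))
        for label, n in [("W", 3), ("X", 3), ("Y", 3), ("Z", 3)]:
            for i in range(n):
                rows.append((f"{label}_{i}", label, "tumor", np.nan))
        return pd.DataFrame(rows, columns=["sample_id", "group", "kind", "stage_index"]
                            ).set_index("sample_id")

    def test_exact_trait_eigengene_ranks_true_map_first_with_r_one(self):
        meta = self._cohort_metadata()
        true_map = {"W": 1, "X": 2, "Y": 3, "Z": 4}
        trait = induced_stage_trait(meta, true_map)
        eg = pd.DataFrame([trait.to_numpy(float)], index=["ME1"], columns=meta.index)
        hyps = dv.score_alignment_orders(eg, meta)
        assert hyps[0].stage_map == true_map
        assert hyps[0].score == pytest.approx(1.0)

    def test_reversed_map_scores_minus_one_under_positive_orientation(self):
        meta = self._cohort_metadata()
        true_map = {"W": 1, "X": 2, "Y": 3, "Z": 4}
        reversed_map = {"W": 4, "X": 3, "Y": 2, "Z": 1}
        trait = induced_stage_trait(meta, true_map)
        eg = pd.DataFrame([trait.to_numpy(float)], index=["ME1"], columns=meta.index)
        hyps = dv.score_alignment_orders(eg, meta, candidate_maps=[true_map, reversed_map])
        scores = {tuple(sorted(h.stage_map.items())): h.score for h in hyps}
        assert scores[tuple(sorted(true_map.items()))] == pytest.approx(1.0)
        # controls anchor the orientation, so the reversal scores well below 1
        assert scores[tuple(sorted(reversed_map.items()))] < 0.6

    def test_enumeration_covers_all_24_injective_maps(self):
        maps = dv.enumerate_stage_maps(["A", "B", "C", "D"], [1, 2, 3, 4])
        assert len(maps) == 24
        assert len({tuple(sorted(m.items())) for m in maps}) == 24
        assert all(len(set(m.values())) == 4 for m in maps)

    def test_non_injective_map_rejected(self):
        meta = self._cohort_metadata()
        eg = pd.DataFrame(np.zeros((1, len(meta))) + np.arange(len(meta)),
                          index=["ME1"], columns=meta.index)
        with pytest.raises(ValueError, match="injective"):
            dv.score_alignment_orders(eg, meta, candidate_maps=[{"W": 1, "X": 1, "Y": 2, "Z": 3}])

    def test_noise_free_true_map_beats_every_alternative_strictly(self):
        res = __import__("devalign.experiments", fromlist=["noise_free_alignment"])
        out = res.noise_free_alignment(seed=3)
        assert out["recovered"] and out["score"] == pytest.approx(1.0, abs=1e-9)

    def test_control_mean_encoding_runs(self, paper_cohort):
        matrix, truth = paper_cohort
        from devalign.experiments import _planted_eigengenes

        eg = _planted_eigengenes(matrix, truth)
        levels = control_stage_levels(matrix)
        hyps = dv.score_alignment_orders(eg, matrix.metadata, encoding="control_mean",
                                         control_level=levels)
        assert len(hyps) == 24
        assert all(-1 <= h.score <= 1 for h in hyps)
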