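import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import mantel as skbio_mantel

from rmtnet import (OtuTable, SampleMetadata, ValidationError, bray_curtis,
                    eigengene_hierarchy, group_ttests, mantel_test,
                    module_eigengene, module_eigengenes, module_env_heatmap,
                    summary_ttest)
from rmtnet.envlink import ModuleEigengene
from rmtnet.topology import ModulePartition


def _partition(assignment):
    sizes = {}
    for m in assignment.values():
        sizes[m] = sizes.get(m, 0) + 1
    return ModulePartition(assignment, sizes, q=0.0)


def _module_table(profiles, n_prefix="o"):
    profiles = np.asarray(profiles, dtype=float)
    ids = [f"{n_prefix}{i}" for i in range(profiles.shape[0])]
    samples = [f"S{j}" for j in range(profiles.shape[1])]
    return OtuTable(ids, samples, profiles, is_log_scale=True), ids


class TestEigengene:
    def test_identical_profiles_rank_one(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        profiles = np.vstack([base * c for c in (1, 2, 3, 4, 5, 6)])
        table, ids = _module_table(profiles)
        part = _partition({i: 1 for i in ids})
        eig = module_eigengene(table, part, 1)
        assert eig.variance_explained == pytest.approx(1.0)
        z = (base - base.mean()) / base.std()
        expected = z / np.linalg.norm(z)
        np.testing.assert_allclose(eig.eigengene, expected, atol=1e-10)

    def test_two_profile_variance_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(12)
        b = 0.6 * a + 0.8 * rng.standard_normal(12)
        # pad with copies so the module passes the >5 size rule
        profiles = np.vstack([a, b, a, b, a, b])
        table, ids = _module_table(profiles)
        part = _partition({i: 1 for i in ids})
        # closed form for a 2-distinct-profile module: members split evenly
        # between two standardized profiles with correlation r gives
        # leading eigenvalue (1+|r|)/2 of the profile correlation
        eig = module_eigengene(table, part, 1)
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        r = abs(np.corrcoef(za, zb)[0, 1])
        assert eig.variance_explained == pytest.approx((1 + r) / 2, abs=1e-10)

    def test_sign_convention_fixes_the_svd_ambiguity(self):
        # the eigengene always aligns with the module's mean profile, so
        # flipping every member flips the eigengene coherently (correlation
        # magnitudes downstream are unchanged) and repeated computation is
        # deterministic
        rng = np.random.default_rng(1)
        profiles = rng.standard_normal((7, 10))
        profiles[1:] = profiles[0] + 0.1 * profiles[1:]
        table, ids = _module_table(profiles)
        part = _partition({i: 1 for i in ids})
        eig = module_eigengene(table, part, 1)
        again = module_eigengene(table, part, 1)
        np.testing.assert_allclose(eig.eigengene, again.eigengene)
        z = (profiles - profiles.mean(axis=1, keepdims=True)) \
            / profiles.std(axis=1, keepdims=True)
        assert np.dot(eig.eigengene, z.mean(axis=0)) >= 0
        flipped, _ = _module_table(-profiles)
        eig2 = module_eigengene(flipped, part, 1)
        np.testing.assert_allclose(eig2.eigengene, -eig.eigengene,
                                   atol=1e-10)
        assert eig2.variance_explained == pytest.approx(
            eig.variance_explained)

    def test_small_module_skipped_with_warning(self):
        table, ids = _module_table(np.random.default_rng(2)
                                   .standard_normal((3, 8)))
        part = _partition({i: 1 for i in ids})
        with pytest.warns(UserWarning, match="skipped"):
            assert module_eigengene(table, part, 1) is None

    def test_variance_explained_monotone_in_correlation(self):
        from rmtnet import SynthSpec, generate_community
        ve = {}
        for rho in (0.6, 0.95):
            vals = []
            for seed in range(3):
                spec = SynthSpec(seed=seed, zero_inflation=0.0,
                                 within_module_correlation=rho)
                table, _ = generate_community(spec)
                truth = spec.planted_partition()
                logged = table.with_abundance(np.log10(table.abundance),
                                              is_log_scale=True)
                part = _partition(truth)
                eig = module_eigengene(logged, part, 1)
                vals.append(eig.variance_explained)
            ve[rho] = np.mean(vals)
        assert ve[0.95] > ve[0.6]


class TestHeatmap:
    def _eig(self, vec, module=1):
        v = np.asarray(vec, float)
        v = v / np.linalg.norm(v)
        return ModuleEigengene(module, v, 0.9,
                               [f"S{j}" for j in range(v.size)])

    def test_env_equal_to_eigengene_gives_r_one(self):
        eig = self._eig([0.1, 0.5, -0.3, 0.7, -0.2, 0.4])
        meta = SampleMetadata([f"S{j}" for j in range(6)],
                              {"mirror": eig.eigengene.copy()})
        df = module_env_heatmap([eig], meta)
        assert df.loc[0, "r"] == pytest.approx(1.0)
        assert df.loc[0, "significant"]

    def test_constant_variable_reported_missing(self):
        eig = self._eig([0.1, 0.5, -0.3, 0.7, -0.2, 0.4])
        meta = SampleMetadata([f"S{j}" for j in range(6)],
                              {"const": np.full(6, 3.0)})
        df = module_env_heatmap([eig], meta)
        assert np.isnan(df.loc[0, "r"])

    def test_planted_driver_is_most_significant_in_row(
            self, clean_planted_community):
        spec, table, meta = clean_planted_community
        truth = spec.planted_partition()
        logged = table.with_abundance(np.log10(table.abundance),
                                      is_log_scale=True)
        part = _partition(truth)
        eig = module_eigengene(logged, part, 1)
        rng = np.random.default_rng(9)
        meta2 = SampleMetadata(list(meta.sample_ids),
                               {"env_m1": meta.variables["env_m1"],
                                "noise1": rng.standard_normal(30),
                                "noise2": rng.standard_normal(30)})
        df = module_env_heatmap([eig], meta2)
        best = df.loc[df["p"].idxmin(), "variable"]
        assert best == "env_m1"

    def test_null_type_one_error_is_calibrated(self):
        """Independent variables are flagged at ~alpha."""
        rng = np.random.default_rng(11)
        hits = trials = 0
        for _ in range(200):
            eig = self._eig(rng.standard_normal(15))
            meta = SampleMetadata([f"S{j}" for j in range(15)],
                                  {"v": rng.standard_normal(15)})
            df = module_env_heatmap([eig], meta)
            hits += bool(df.loc[0, "significant"])
            trials += 1
        assert hits / trials == pytest.approx(0.05, abs=0.04)


class TestHierarchy:
    def _eigs(self, vectors):
        return [ModuleEigengene(m + 1, np.asarray(v) / np.linalg.norm(v),
                                0.9, [f"S{j}" for j in range(len(v))])
                for m, v in enumerate(vectors)]

    def test_identical_eigengenes_merge_at_zero(self):
        v = np.array([0.3, -0.1, 0.5, 0.2])
        newick, linkage = eigengene_hierarchy(self._eigs([v, v]))
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_three_leaf_merge_order(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(20)
        b = a + 0.1 * rng.standard_normal(20)   # closest pair
        c = rng.standard_normal(20)
        newick, linkage = eigengene_hierarchy(self._eigs([a, b, c]))
        # first merge joins leaves 0 and 1 (the a/b pair)
        assert set(linkage[0, :2].astype(int)) == {0, 1}

    def test_newick_parses_with_one_leaf_per_module(self):
        rng = np.random.default_rng(4)
        eigs = self._eigs(rng.standard_normal((4, 15)))
        newick, _ = eigengene_hierarchy(eigs)
        tree = TreeNode.read([newick])
        assert {t.name for t in tree.tips()} == {"M1", "M2", "M3", "M4"}


class TestMantel:
    def _table(self, seed=0, n_otus=20, n_samples=10):
        rng = np.random.default_rng(seed)
        counts = np.round(10 ** (2 + 0.5 * rng.standard_normal(
            (n_otus, n_samples))))
        return OtuTable([f"o{i}" for i in range(n_otus)],
                        [f"S{j}" for j in range(n_samples)], counts)

    def test_perfect_association(self):
        # a variable whose Euclidean distances reproduce the ordering of
        # community distances gives r near 1; use a 1-D abundance gradient
        grad = np.linspace(1, 5, 8)
        counts = np.vstack([grad, 10 - grad, grad * 2]) * 10
        table = OtuTable(["a", "b", "c"], [f"S{j}" for j in range(8)], counts)
        res = mantel_test(table, grad, "grad", n_permutations=999, seed=0)
        assert res.mantel_r > 0.9
        assert res.p == pytest.approx(1 / 1000, abs=5e-3)

    def test_hand_worked_four_sample_example(self):
        counts = np.array([[1.0, 2.0, 3.0, 4.0],
                           [4.0, 3.0, 2.0, 1.0],
                           [1.0, 1.0, 1.0, 1.0]])
        table = OtuTable(["a", "b", "c"], ["S1", "S2", "S3", "S4"], counts)
        var = np.array([0.0, 1.0, 3.0, 6.0])
        d = bray_curtis(table)
        x = d[np.tril_indices(4, -1)]
        vz = (var - var.mean()) / var.std()
        dv = np.abs(vz[:, None] - vz[None, :])
        y = dv[np.tril_indices(4, -1)]
        r_manual = np.corrcoef(x, y)[0, 1]
        res = mantel_test(table, var, "v", n_permutations=999, seed=1)
        assert res.mantel_r == pytest.approx(r_manual, abs=1e-12)

    def test_agrees_with_skbio_oracle(self):
        table = self._table(seed=5)
        rng = np.random.default_rng(6)
        var = rng.standard_normal(10)
        res = mantel_test(table, var, "v", n_permutations=999, seed=2)
        vz = (var - var.mean()) / var.std()
        dv = np.abs(vz[:, None] - vz[None, :])
        r_sk, p_sk, _ = skbio_mantel(DistanceMatrix(bray_curtis(table)),
                                     DistanceMatrix(dv), method="pearson",
                                     permutations=999, alternative="greater")
        assert res.mantel_r == pytest.approx(r_sk, abs=1e-10)
        assert res.p == pytest.approx(p_sk, abs=0.05)

    def test_invariant_to_consistent_relabeling(self):
        table = self._table(seed=7)
        rng = np.random.default_rng(8)
        var = rng.standard_normal(10)
        perm = rng.permutation(10)
        table_p = table.subset_samples([table.sample_ids[i] for i in perm])
        res1 = mantel_test(table, var, "v", 99, seed=3)
        res2 = mantel_test(table_p, var[perm], "v", 99, seed=3)
        assert res1.mantel_r == pytest.approx(res2.mantel_r, abs=1e-12)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            mantel_test(self._table(), np.full(10, 2.0), "c")

    def test_p_floor_respected(self):
        res = mantel_test(self._table(seed=9),
                          np.random.default_rng(10).standard_normal(10),
                          "v", n_permutations=99, seed=4)
        assert res.p >= 1 / 100


class TestGroupTTests:
    def test_identical_groups_give_t_zero_p_one(self):
        vec = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        meta = SampleMetadata([f"S{j}" for j in range(6)], {"v": vec},
                              group={f"S{j}": ("A" if j < 3 else "B")
                                     for j in range(6)})
        df = group_ttests(meta)
        assert df.loc[0, "t"] == pytest.approx(0.0)
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_large_shift_is_extremely_significant(self):
        rng = np.random.default_rng(12)
        a = rng.standard_normal(15)
        b = rng.standard_normal(15) + 5.0
        meta = SampleMetadata(
            [f"S{j}" for j in range(30)], {"v": np.concatenate([a, b])},
            group={f"S{j}": ("A" if j < 15 else "B") for j in range(30)})
        df = group_ttests(meta)
        assert df.loc[0, "p"] < 0.001
        assert df.loc[0, "stars"] == "***"

    def test_summary_statistics_ph_comparison(self):
        """Printed soil-pH summaries (7.20+-0.30 vs 7.64+-0.37, n=15 each)
        are very significantly different, consistent with the reported
        0.002 ** tier."""
        t, p = summary_ttest(7.20, 0.30, 15, 7.64, 0.37, 15)
        assert p < 0.01

    def test_three_groups_rejected(self):
        meta = SampleMetadata(["S1", "S2", "S3"], {"v": np.arange(3.0)},
                              group={"S1": "A", "S2": "B", "S3": "C"})
        with pytest.raises(ValidationError, match="2 groups"):
            group_ttests(meta)
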