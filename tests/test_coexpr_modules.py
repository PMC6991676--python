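import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from dynprognet import (GeneratorConfig, adjacency_matrix, detect_modules,
                        detect_modules_from_expression, generate,
                        gene_significance_and_mm, intramodular_connectivity,
                        module_eigengene, module_hub_table,
                        module_trait_correlation, soft_threshold_scan,
                        tom_matrix, zscore_normalize)
from dynprognet.coexpr_modules import GREY

from conftest import make_dataset


def tom_loop_oracle(a):
    """Literal triple-loop TOM."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def modular_dataset(seed=7, n_modules=4, module_size=50, noise_sd=0.5):
    cfg = GeneratorConfig(n_genes=n_modules * module_size + 20,
                          n_dynamic_de=0, n_rewired_pairs=0,
                          n_modules=n_modules, module_size=module_size,
                          noise_sd=noise_sd, seed=seed)
    return generate(cfg)


class TestSoftThreshold:
    def test_mean_connectivity_monotone(self, rng):
        d = make_dataset(rng.standard_normal((30, 12)), (6, 6))
        scan = soft_threshold_scan(d, powers=list(range(1, 11)), target_r2=0.9)
        k = scan.mean_connectivity
        assert all(k[i] >= k[i + 1] for i in range(len(k) - 1))

    def test_noise_fit_low_at_beta_one(self, rng):
        d = make_dataset(rng.standard_normal((100, 20)), (10, 10))
        scan = soft_threshold_scan(d, powers=[1], target_r2=0.9)
        assert scan.fit_r2[0] < 0.5

    def test_modular_data_reaches_good_fit(self):
        d, _ = modular_dataset()
        scan = soft_threshold_scan(d)
        assert max(scan.fit_r2) >= 0.8

    def test_chosen_is_lowest_meeting_target(self):
        d, _ = modular_dataset()
        scan = soft_threshold_scan(d, target_r2=0.5)
        assert scan.reached_target
        first = next(b for b, f in zip(scan.powers, scan.fit_r2) if f >= 0.5)
        assert scan.chosen_beta == first

    def test_preconditions(self, rng):
        small = make_dataset(rng.standard_normal((5, 12)), (6, 6))
        with pytest.raises(ValueError, match="genes"):
            soft_threshold_scan(small)
        const = make_dataset(np.ones((30, 12)), (6, 6))
        with pytest.raises(ValueError):
            detect_modules_from_expression(const, beta=6)


class TestTom:
    def test_isolated_genes(self):
        a = np.zeros((3, 3))
        tom = tom_matrix(a)
        assert tom[0, 1] == 0.0
        assert tom[0, 0] == 1.0

    def test_complete_unit_triangle(self):
        a = np.ones((3, 3))
        tom = tom_matrix(a)
        # k_i = 2, shared term = 1, so (1+1)/(2+1-1) = 1 off-diagonal
        np.testing.assert_allclose(tom, 1.0)

    def test_matches_triple_loop(self, rng):
        a = rng.uniform(size=(10, 10))
        a = (a + a.T) / 2
        np.testing.assert_allclose(tom_matrix(a), tom_loop_oracle(a),
                                   atol=1e-12)

    def test_range_invariant(self, rng):
        a = rng.uniform(size=(25, 25))
        a = (a + a.T) / 2
        tom = tom_matrix(a)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            tom_matrix(np.full((3, 3), 1.5))


class TestEigengene:
    def test_single_gene_module(self, rng):
        d = make_dataset(rng.standard_normal((3, 10)), (5, 5))
        me = module_eigengene(d, [d.genes[0]])
        z = stats.zscore(d.values.iloc[0], ddof=1)
        r = np.corrcoef(me, z)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)
        assert r > 0  # sign-oriented toward members

    def test_two_identical_genes(self, rng):
        row = rng.standard_normal(8)
        d = make_dataset(np.vstack([row, row]), (4, 4))
        me = module_eigengene(d, d.genes)
        assert np.corrcoef(me, row)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_svd_oracle(self, rng):
        d = make_dataset(rng.standard_normal((12, 15)), (5, 5, 5))
        me = module_eigengene(d, d.genes)
        z = stats.zscore(d.values.to_numpy(), axis=1, ddof=1)
        _, _, vt = np.linalg.svd(z)
        ref = vt[0]
        assert min(np.abs(me - ref).max(),
                   np.abs(me + ref).max()) < 1e-9
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_explains_more_variance_than_any_member(self):
        """For a one-factor module the eigengene's variance share beats the
        average share of any single member profile."""
        d, truth = modular_dataset(seed=13, n_modules=1)
        members = [g for g, m in truth.module_of.items() if m == "M1"]
        me = module_eigengene(d, members).to_numpy()
        z = stats.zscore(d.values.loc[members].to_numpy(), axis=1, ddof=1)
        total = (z ** 2).sum()
        share_me = ((z @ me) ** 2).sum() / total
        for row in z:
            u = row / np.linalg.norm(row)
            assert share_me >= ((z @ u) ** 2).sum() / total - 1e-9


class TestDetectModules:
    def test_block_diagonal_two_modules(self):
        diss = np.ones((80, 80))
        diss[:40, :40] = 0.0
        diss[40:, 40:] = 0.0
        np.fill_diagonal(diss, 0.0)
        genes = [f"g{i}" for i in range(80)]
        asg = detect_modules(diss, genes, min_module_size=30, cut_height=0.9)
        labels = asg.module_of
        assert labels.nunique() == 2
        assert GREY not in set(labels)
        assert labels.iloc[:40].nunique() == 1

    def test_all_identical_single_module(self):
        diss = np.zeros((40, 40))
        genes = [f"g{i}" for i in range(40)]
        asg = detect_modules(diss, genes, min_module_size=30)
        assert asg.module_of.nunique() == 1

    def test_small_clusters_go_grey(self):
        diss = np.ones((40, 40))
        diss[:35, :35] = 0.0
        diss[35:, 35:] = 0.0
        np.fill_diagonal(diss, 0.0)
        genes = [f"g{i}" for i in range(40)]
        asg = detect_modules(diss, genes, min_module_size=30, cut_height=0.9)
        assert (asg.module_of.iloc[35:] == GREY).all()

    def test_planted_modules_recovered(self):
        d, truth = modular_dataset(seed=5)
        asg, _ = detect_modules_from_expression(zscore_normalize(d), beta=6)
        genes = sorted(truth.module_of)
        ari = adjusted_rand_score([truth.module_of[g] for g in genes],
                                  [asg.module_of[g] for g in genes])
        assert ari >= 0.8

    def test_labels_invariant_under_gene_permutation(self, rng):
        d, truth = modular_dataset(seed=21, n_modules=3)
        z = zscore_normalize(d)
        perm = rng.permutation(len(z.genes))
        shuffled = z.with_values(z.values.iloc[perm])
        a1, _ = detect_modules_from_expression(z, beta=6)
        a2, _ = detect_modules_from_expression(shuffled, beta=6)
        genes = z.genes
        assert adjusted_rand_score(
            [a1.module_of[g] for g in genes],
            [a2.module_of[g] for g in genes]) == pytest.approx(1.0)


class TestModuleTrait:
    def test_trait_equals_eigengene(self, rng):
        me = pd.DataFrame({"blue": rng.standard_normal(30)},
                          index=[f"S{i}" for i in range(30)])
        traits = pd.DataFrame({"t": me["blue"]}, index=me.index)
        r, p = module_trait_correlation(me, traits)
        assert r.loc["blue", "t"] == pytest.approx(1.0)
        assert p.loc["blue", "t"] < 1e-100

    def test_p_from_t_distribution(self, rng):
        """r=0.55 at n=56 gives a p of order 1e-5, matching the closed form."""
        n, target_r = 56, 0.55
        t = target_r * np.sqrt(n - 2) / np.sqrt(1 - target_r ** 2)
        p_ref = 2 * stats.t.sf(t, df=n - 2)
        assert 1e-6 < p_ref < 1e-4
        # build vectors with that exact sample correlation
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        y = y - np.polyval(np.polyfit(x, y, 1), x)  # residualise
        xz, yz = stats.zscore(x), stats.zscore(y)
        v = target_r * xz + np.sqrt(1 - target_r ** 2) * yz
        me = pd.DataFrame({"m": v}, index=[f"S{i}" for i in range(n)])
        traits = pd.DataFrame({"t": xz}, index=me.index)
        r, p = module_trait_correlation(me, traits)
        assert r.loc["m", "t"] == pytest.approx(target_r, abs=1e-9)
        assert p.loc["m", "t"] == pytest.approx(p_ref, rel=1e-6)

    def test_null_p_uniform(self, rng):
        n = 40
        me = pd.DataFrame(rng.standard_normal((n, 25)),
                          index=[f"S{i}" for i in range(n)],
                          columns=[f"m{i}" for i in range(25)])
        traits = pd.DataFrame(rng.standard_normal((n, 40)),
                              index=me.index,
                              columns=[f"t{i}" for i in range(40)])
        _, p = module_trait_correlation(me, traits)
        ks = stats.kstest(p.to_numpy().ravel(), "uniform")
        assert ks.pvalue > 0.01

    def test_missing_traits_pairwise(self, rng):
        me = pd.DataFrame({"m": rng.standard_normal(20)},
                          index=[f"S{i}" for i in range(20)])
        tr = pd.DataFrame({"t": me["m"]})
        tr.iloc[:5] = np.nan
        r, _ = module_trait_correlation(me, tr)
        assert r.loc["m", "t"] == pytest.approx(1.0)

    def test_zero_variance_trait_undefined(self, rng):
        me = pd.DataFrame({"m": rng.standard_normal(10)},
                          index=[f"S{i}" for i in range(10)])
        tr = pd.DataFrame({"t": np.ones(10)}, index=me.index)
        r, p = module_trait_correlation(me, tr)
        assert np.isnan(r.loc["m", "t"])

    def test_trait_linked_module_has_top_r(self):
        d, truth = modular_dataset(seed=31)
        z = zscore_normalize(d)
        asg, _ = detect_modules_from_expression(z, beta=6)
        r, _ = module_trait_correlation(asg.eigengenes, d.traits)
        # which detected colour covers the planted trait module?
        members = {g for g, m in truth.module_of.items()
                   if m == truth.trait_module}
        cover = asg.module_of.loc[list(members)].mode()[0]
        best = r["trait"].abs().idxmax()
        assert best == cover


class TestGsMmAndConnectivity:
    def test_gs_mm_planted(self):
        d, truth = modular_dataset(seed=41)
        z = zscore_normalize(d)
        asg, adj = detect_modules_from_expression(z, beta=6)
        gs, mm = gene_significance_and_mm(z, d.traits, asg)
        members = [g for g, m in truth.module_of.items()
                   if m == truth.trait_module]
        others = [g for g in d.genes if g not in set(members)]
        assert gs.loc[members, "trait"].median() > gs.loc[others, "trait"].median()
        # members strongly belong to their own detected module
        cover = asg.module_of.loc[members].mode()[0]
        assert mm.loc[members, cover].abs().median() > 0.7

    def test_perfect_module_gene_mm(self, rng):
        row = rng.standard_normal(12)
        vals = np.vstack([row * (i + 1) for i in range(5)])
        d = make_dataset(vals, (6, 6))
        asg, _ = detect_modules_from_expression(d, beta=2, min_module_size=2,
                                                cut_height=1.0)
        traits = pd.DataFrame({"t": rng.standard_normal(12)},
                              index=d.samples)
        _, mm = gene_significance_and_mm(d, traits, asg)
        mod = asg.module_of.iloc[0]
        assert abs(mm.loc[d.genes[0], mod]) == pytest.approx(1.0, abs=1e-9)

    def test_two_gene_module_kim(self):
        adj = pd.DataFrame([[0.0, 0.6], [0.6, 0.0]],
                           index=["a", "b"], columns=["a", "b"])
        asg_labels = pd.Series(["blue", "blue"], index=["a", "b"])
        from dynprognet.coexpr_modules import ModuleAssignment
        asg = ModuleAssignment(module_of=asg_labels)
        k = intramodular_connectivity(adj, asg)
        assert k["a"] == pytest.approx(0.6)

    def test_grey_kim_undefined_and_loop_oracle(self, rng):
        n = 20
        a = rng.uniform(size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        genes = [f"g{i}" for i in range(n)]
        adj = pd.DataFrame(a, index=genes, columns=genes)
        labels = pd.Series(["blue"] * 8 + ["brown"] * 8 + [GREY] * 4,
                           index=genes)
        from dynprognet.coexpr_modules import ModuleAssignment
        asg = ModuleAssignment(module_of=labels)
        k = intramodular_connectivity(adj, asg)
        assert k.loc[labels == GREY].isna().all()
        for gi, g in enumerate(genes[:16]):
            members = [j for j, h in enumerate(genes)
                       if labels[h] == labels[g] and h != g]
            assert k[g] == pytest.approx(sum(a[gi, j] for j in members))
        hubs = module_hub_table(asg, top_k=3)
        assert (hubs.groupby("module").size() == 3).all()
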