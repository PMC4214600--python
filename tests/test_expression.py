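"""Differential-expression stages: filtering, normalization, the
permutation d-statistic, selection, clustering, gene-set tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shfgrn.expression import (
    ExpressionDataset,
    SamParams,
    cluster_samples,
    filter_probes,
    geneset_enrichment,
    normalize,
    sam_test,
    select_signature,
    storey_qvalues,
    stringent_candidates,
    _group_stats,
    _safe_ratio,
)
from shfgrn.synthetic import simulate_expression, simulate_genome

from conftest import make_dataset


class TestFilterProbes:
    def test_all_qc_fail_is_error(self):
        ds = make_dataset(np.ones((3, 4)) * 10, qc=np.zeros((3, 4), dtype=bool))
        with pytest.raises(ValueError, match="no probes survive"):
            filter_probes(ds)

    def test_median_split_on_spread(self):
        # log2(x+1) rows engineered to have IQRs 1, 2, 3, 4
        rows = [np.exp2(np.linspace(0, k, 7)) - 1 for k in (2, 4, 6, 8)]
        ds = make_dataset(np.array(rows) + 1e-9, n_case=4)
        out, report = filter_probes(ds)
        assert list(out.values.index) == ["p2", "p3"]
        assert report["removed_spread"] == 2

    def test_unannotated_probe_always_removed(self):
        vals = np.array([[1, 2, 3, 4], [1, 2, 3, 4]], dtype=float)
        ds = make_dataset(vals, gene_map={"p0": "g0", "p1": None})
        out, report = filter_probes(ds)
        assert "p1" not in out.values.index
        assert report["removed_unannotated"] == 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.lognormal(3, 1, size=(50, 7)), n_case=4)
        once, _ = filter_probes(ds)
        twice, report = filter_probes(once)
        assert list(once.values.index) == list(twice.values.index)
        assert report["n_retained"] == report["n_input"]

    def test_per_criterion_counts_sum(self):
        rng = np.random.default_rng(1)
        qc = rng.random((60, 7)) > 0.05
        gene_map = {f"p{i}": (f"g{i}" if i % 5 else None) for i in range(60)}
        ds = make_dataset(rng.lognormal(3, 1, size=(60, 7)), gene_map=gene_map, n_case=4, qc=qc)
        _, rep = filter_probes(ds)
        assert (
            rep["removed_qc"] + rep["removed_spread"] + rep["removed_unannotated"]
            == rep["n_input"] - rep["n_retained"]
        )


class TestNormalize:
    def test_identical_arrays_identical_columns(self):
        col = np.array([1.0, 5.0, 20.0, 100.0])
        ds = make_dataset(np.column_stack([col] * 4))
        out = normalize(ds)
        v = out.values.to_numpy()
        assert np.allclose(v, v[:, [0]])

    def test_pure_scale_removed(self):
        rng = np.random.default_rng(2)
        a = rng.lognormal(3, 1, size=100)
        ds = make_dataset(np.column_stack([a, 2 * a, a, 2 * a]))
        out = normalize(ds)
        v = out.values.to_numpy()
        assert np.allclose(v[:, 0], v[:, 1], atol=1e-6)

    def test_glog_approaches_log2_for_large_values(self):
        vals = np.column_stack([
            np.array([1e5, 2e5, 4e5, 1e3]),
            np.array([1e5, 2e5, 4e5, 1e3]),
        ])
        out = normalize(make_dataset(vals))
        v = out.values.to_numpy()[:, 0]
        assert abs((v[1] - v[0]) - 1.0) < 1e-3  # 2x -> +1 on log2 scale
        assert abs((v[2] - v[1]) - 1.0) < 1e-3

    def test_monotone_per_array(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(3, 1.5, size=(200, 4))
        out = normalize(make_dataset(vals))
        for j in range(4):
            order_raw = np.argsort(vals[:, j])
            order_norm = np.argsort(out.values.to_numpy()[:, j])
            assert np.array_equal(order_raw, order_norm)

    def test_zero_spread_array_rejected(self):
        vals = np.column_stack([np.ones(5), np.arange(1.0, 6.0)])
        with pytest.raises(ValueError, match="zero-spread"):
            normalize(make_dataset(vals))


class TestSamStatistic:
    def test_flat_data_gives_zero_d_and_q_one(self):
        ds = make_dataset(np.full((5, 6), 7.0), scale="glog2", n_case=3)
        res = sam_test(ds, SamParams(seed=0))
        assert np.allclose(res["d"], 0.0)
        assert np.allclose(res["q"], 1.0)

    def test_d_formula_hand_case(self):
        """case {4,4,4}, ctrl {2,2,2}: r=2, s=0, so d = 2/(0 + s0) = 2 at s0=1."""
        X = np.array([[4.0, 4.0, 4.0, 2.0, 2.0, 2.0]])
        r, s = _group_stats(X, [0, 1, 2], [3, 4, 5])
        assert r[0] == 4 - 2
        assert s[0] == 0
        assert _safe_ratio(r, s + 1.0)[0] == pytest.approx(2.0)

    def test_s0_zero_matches_classical_t(self):
        rng = np.random.default_rng(4)
        X = rng.normal(5, 1, size=(10, 7))
        r, s = _group_stats(X, [0, 1, 2, 3], [4, 5, 6])
        t_ours = _safe_ratio(r, s)
        t_ref = stats.ttest_ind(X[:, :4], X[:, 4:], axis=1, equal_var=True).statistic
        assert np.allclose(t_ours, t_ref)

    def test_too_few_samples_per_group(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(4, 4)), scale="glog2", n_case=1)
        with pytest.raises(ValueError, match="at least 2"):
            sam_test(ds)

    def test_exact_enumeration_for_small_designs(self):
        rng = np.random.default_rng(5)
        ds = make_dataset(rng.normal(8, 1, size=(20, 7)), scale="glog2", n_case=4)
        res = sam_test(ds, SamParams(n_perm=100, seed=0))
        assert res.attrs["n_permutations"] == 35  # C(7,4)
        assert res.attrs["exact_permutations"]

    def test_sampled_permutations_agree_with_enumeration(self):
        rng = np.random.default_rng(6)
        ds = make_dataset(rng.normal(8, 1, size=(40, 10)), scale="glog2", n_case=5)
        exact = sam_test(ds, SamParams(n_perm=252, seed=0))  # all C(10,5) splits
        sampled = sam_test(ds, SamParams(n_perm=100, seed=1))
        assert exact.attrs["exact_permutations"]
        assert not sampled.attrs["exact_permutations"]
        assert np.abs(exact["perm_p"] - sampled["perm_p"]).max() < 0.08

    def test_gene_collapsing_takes_extreme_probe(self):
        vals = np.array([
            [10.0, 10.0, 10.0, 5.0, 5.0, 5.0],   # strong probe of g0
            [7.0, 7.2, 6.9, 7.1, 7.0, 6.8],      # weak probe of g0
        ])
        ds = make_dataset(vals, gene_map={"p0": "g0", "p1": "g0"}, scale="glog2", n_case=3)
        res = sam_test(ds, SamParams(seed=0))
        assert list(res.index) == ["g0"]
        assert res.loc["g0", "probe_id"] == "p0"


class TestSelection:
    @staticmethod
    def fake_results(rows):
        df = pd.DataFrame(rows).set_index("gene_id")
        df["log2fc"] = np.log2(df["fc"])
        return df

    def test_down_regulated_gene_included(self):
        res = self.fake_results([
            {"gene_id": "g1", "fc": 0.4, "q": 0.004, "wilcoxon_p": 0.01, "emp_t_fdr": 0.01},
        ])
        sig = select_signature(res)
        assert sig.genes == {"g1": "down"}

    def test_small_fold_change_excluded(self):
        res = self.fake_results([
            {"gene_id": "g1", "fc": 1.5, "q": 0.004, "wilcoxon_p": 0.01, "emp_t_fdr": 0.01},
        ])
        assert len(select_signature(res)) == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        res = self.fake_results([
            {"gene_id": f"g{i}", "fc": float(np.exp2(rng.normal(0, 2))),
             "q": float(rng.random()), "wilcoxon_p": 0.5, "emp_t_fdr": 0.5}
            for i in range(200)
        ])
        base = set(select_signature(res, q_max=0.5, min_abs_fc=1.5).genes)
        tighter_q = set(select_signature(res, q_max=0.1, min_abs_fc=1.5).genes)
        tighter_fc = set(select_signature(res, q_max=0.5, min_abs_fc=3.0).genes)
        assert tighter_q <= base and tighter_fc <= base

    def test_stringent_requires_all_three(self):
        res = self.fake_results([
            {"gene_id": "gFC", "fc": 2.5, "q": 0.001, "wilcoxon_p": 0.01, "emp_t_fdr": 0.01},
            {"gene_id": "gOK", "fc": 9.0, "q": 0.001, "wilcoxon_p": 0.01, "emp_t_fdr": 0.01},
            {"gene_id": "gW", "fc": 9.0, "q": 0.001, "wilcoxon_p": 0.5, "emp_t_fdr": 0.01},
        ])
        assert stringent_candidates(res) == ["gOK"]

    def test_stringent_missing_stat_errors(self):
        res = self.fake_results([
            {"gene_id": "g1", "fc": 9.0, "q": 0.001, "wilcoxon_p": 0.01, "emp_t_fdr": 0.01},
        ]).drop(columns=["wilcoxon_p"])
        with pytest.raises(ValueError, match="wilcoxon_p"):
            stringent_candidates(res)

    def test_storey_qvalues_monotone_and_bounded(self):
        rng = np.random.default_rng(8)
        p = rng.random(500)
        q = storey_qvalues(p)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestClustering:
    def test_duplicated_blocks_split_perfectly(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 10
        vals = np.column_stack([a, a, a, b, b, b])
        ds = make_dataset(vals, scale="glog2", n_case=3)
        _, labels = cluster_samples(ds, [f"g{i}" for i in range(4)])
        lab = list(labels.values())
        assert lab[0] == lab[1] == lab[2]
        assert lab[3] == lab[4] == lab[5]
        assert lab[0] != lab[3]

    def test_planted_signature_separates_groups(self):
        from sklearn.metrics import adjusted_rand_score

        genome = simulate_genome(1, 200, 2_000_000, seed=0, min_spacing=1_000)
        ds, truth = simulate_expression(
            genome, de_spec={"n_down": 30, "n_up": 10, "lfc_range": (2.0, 3.0)}, seed=1
        )
        norm = normalize(ds)
        _, labels = cluster_samples(norm, list(truth.de_genes))
        true = [1 if ds.groups[s] == "case" else 2 for s in ds.values.columns]
        got = [labels[s] for s in ds.values.columns]
        assert adjusted_rand_score(true, got) == 1.0

    def test_single_sample_errors(self):
        ds = make_dataset(np.ones((3, 2)), scale="glog2", n_case=1)
        ds.values = ds.values.iloc[:, :1]
        ds.qc_flags = ds.qc_flags.iloc[:, :1]
        with pytest.raises(ValueError):
            cluster_samples(ds, ["g0"])


class TestGenesetEnrichment:
    def test_set_equal_to_signature_is_minimal_p(self):
        universe = [f"g{i}" for i in range(100)]
        sig = set(universe[:10])
        res = geneset_enrichment(sig, {"self": sig, "half": set(universe[:50])}, universe)
        assert res.loc["self", "p"] == min(res["p"])
        assert res.loc["self", "p"] == pytest.approx(
            stats.hypergeom.pmf(10, 100, 10, 10)
        )

    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(100)]
        res = geneset_enrichment(set(universe[:10]), {"far": set(universe[50:60])}, universe)
        assert res.loc["far", "p"] == pytest.approx(1.0)

    def test_null_pvalues_roughly_uniform(self):
        # the hypergeometric p is discrete, so smooth with the standard
        # randomized-p construction u = P(X >= a) - U * P(X = a), which is
        # exactly uniform when the reported tail probability is correct
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(2000)]
        sig = set(rng.choice(universe, 200, replace=False))
        sets = {
            f"s{k}": set(rng.choice(universe, 100, replace=False)) for k in range(200)
        }
        res = geneset_enrichment(sig, sets, universe)
        pmf = stats.hypergeom.pmf(res["a"], 2000, res["a"] + res["c"], res["a"] + res["b"])
        u = res["p"].to_numpy() - rng.random(len(res)) * np.asarray(pmf)
        ks = stats.kstest(u, "uniform")
        assert ks.pvalue > 0.01

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            geneset_enrichment({"g1"}, {"s": {"g1"}}, [])


class TestOnSimulatedData:
    def test_null_dataset_yields_no_signature(self):
        genome = simulate_genome(1, 300, 3_000_000, seed=0)
        fps = 0
        for seed in range(20):
            ds, _ = simulate_expression(genome, seed=100 + seed)
            filtered, _ = filter_probes(ds)
            res = sam_test(normalize(filtered), SamParams(seed=seed))
            fps += len(select_signature(res))
        assert fps <= 1

    def test_planted_genes_recovered(self):
        genome = simulate_genome(1, 500, 5_000_000, seed=0)
        ds, truth = simulate_expression(
            genome, de_spec={"n_down": 25, "n_up": 25, "lfc_range": (2.0, 2.0)}, seed=3
        )
        filtered, _ = filter_probes(ds)
        res = sam_test(normalize(filtered), SamParams(seed=3))
        sig = select_signature(res)
        planted = set(truth.de_genes)
        recall = len(set(sig.genes) & planted) / len(planted)
        assert recall >= 0.9
        for gene, direction in sig.genes.items():
            if gene in planted:
                assert (truth.de_genes[gene] < 0) == (direction == "down")
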