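"""QC filtering, downsampling, cluster log2 ratios, DE selection, enrichment
assignment and the binomial overrepresentation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organoidquant.screen import (
    CountMatrix,
    QCThresholds,
    cluster_aggregate_log2ratio,
    compute_cell_qc,
    downsample_cells,
    filter_enrichment,
    overrepresentation_test,
    qc_filter,
    select_de_genes,
)
from organoidquant.synthetic import make_count_experiment

from _oracles import binomial_tail


def small_matrix(counts, genes, cells, mito=(), clusters=None, sample="s"):
    return CountMatrix(
        np.asarray(counts), list(genes), list(cells), sample,
        None if clusters is None else np.asarray(clusters), frozenset(mito)
    )


class TestCellQC:
    def test_hand_computed_metrics(self):
        # genes g1, g2 (mito), g3; two cells
        m = small_matrix([[5, 5], [0, 5], [3, 0]], ["g1", "g2", "g3"], ["c1", "c2"], mito=["g2"])
        qc = compute_cell_qc(m)
        assert qc.loc["c1"].tolist() == [2, 8, 0.0]
        assert qc.loc["c2"].tolist() == [2, 10, 50.0]

    def test_six_cell_fixture_matches_hand_arithmetic(self):
        counts = np.array(
            [
                [4, 0, 1, 0, 2, 9],
                [0, 0, 3, 1, 0, 1],  # mito
                [1, 0, 0, 5, 0, 0],
                [0, 2, 0, 0, 0, 0],
            ]
        )
        m = small_matrix(counts, ["a", "MT-b", "c", "d"], [f"c{i}" for i in range(6)], mito=["MT-b"])
        qc = compute_cell_qc(m)
        assert qc["nFeature"].tolist() == [2, 1, 2, 2, 1, 2]
        assert qc["nCount"].tolist() == [5, 2, 4, 6, 2, 10]
        assert qc["pct_mito"].tolist() == pytest.approx([0, 0, 75.0, 100 / 6, 0, 10.0])

    def test_unknown_mito_gene_raises(self):
        m = small_matrix([[1]], ["g1"], ["c1"], mito=["gX"])
        with pytest.raises(KeyError):
            compute_cell_qc(m)


class TestQCFilter:
    def make_qc(self, nFeature=500, nCount=2000, pct_mito=5.0):
        return pd.DataFrame(
            {"nFeature": [nFeature], "nCount": [nCount], "pct_mito": [pct_mito]},
            index=pd.Index(["cell"], name="cell_id"),
        )

    @pytest.mark.parametrize(
        "kw, kept",
        [
            ({"nFeature": 200}, True),  # boundary: rule is strict '< 200'
            ({"nFeature": 199}, False),
            ({"nFeature": 8000}, True),  # strict '> 8000'
            ({"nFeature": 8001}, False),
            ({"nCount": 50000}, True),
            ({"nCount": 50001}, False),
            ({"pct_mito": 20.0}, True),
            ({"pct_mito": 20.01}, False),
        ],
    )
    def test_strict_boundary_semantics(self, kw, kept):
        survivors = qc_filter(self.make_qc(**kw))
        assert (len(survivors) == 1) is kept

    def test_planted_violators_removed_exactly(self):
        violations = {
            "A_cell_0000": "low_nFeature",
            "A_cell_0005": "high_nCount",
            "A_cell_0011": "high_pct_mito",
            "B_cell_0002": "low_nFeature",
            "B_cell_0003": "high_pct_mito",
            "B_cell_0004": "high_nCount",
            "B_cell_0017": "high_nCount",
        }
        (a, b), truth = make_count_experiment(
            n_genes=600, n_cells_per_sample=60, qc_violations=violations, seed=21
        )
        removed = []
        for m in (a, b):
            qc = compute_cell_qc(m)
            removed += sorted(set(m.cell_ids) - set(qc_filter(qc)))
        assert sorted(removed) == truth.qc_violators == sorted(violations)

    def test_survivors_preserve_input_order(self):
        qc = pd.DataFrame(
            {"nFeature": [300, 100, 400], "nCount": [1000] * 3, "pct_mito": [1.0] * 3},
            index=pd.Index(["z", "m", "a"], name="cell_id"),
        )
        assert qc_filter(qc) == ["z", "a"]


class TestDownsample:
    def big_matrix(self, n_cells=10_000, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 4, size=(5, n_cells))
        clusters = rng.integers(0, 4, size=n_cells).astype(str)
        return small_matrix(counts, [f"g{i}" for i in range(5)], [f"c{i}" for i in range(n_cells)], clusters=clusters)

    def test_seed_determinism(self):
        m = self.big_matrix()
        s1 = downsample_cells(m, 6400, seed=9)
        s2 = downsample_cells(m, 6400, seed=9)
        assert s1.cell_ids == s2.cell_ids
        assert np.array_equal(s1.counts, s2.counts)

    def test_full_size_is_identity(self):
        m = self.big_matrix(n_cells=50)
        s = downsample_cells(m, 50, seed=1)
        assert s.cell_ids == m.cell_ids

    def test_requesting_more_than_available_raises_unless_allowed(self):
        m = self.big_matrix(n_cells=10)
        with pytest.raises(ValueError):
            downsample_cells(m, 20, seed=0)
        with pytest.warns(UserWarning):
            s = downsample_cells(m, 20, seed=0, allow_smaller=True)
        assert s.n_cells == 10

    def test_cluster_proportions_preserved_hypergeometrically(self):
        m = self.big_matrix()
        source = pd.Series(m.clusters).value_counts(normalize=True)
        for seed in range(50):
            sub = downsample_cells(m, 6400, seed=seed)
            sampled = pd.Series(sub.clusters).value_counts(normalize=True)
            assert ((sampled - source).abs() < 0.03).all()


class TestClusterRatios:
    def two_sample(self, counts_a, counts_b, clusters):
        genes = [f"g{i}" for i in range(np.shape(counts_a)[0])]
        cells = [f"c{i}" for i in range(np.shape(counts_a)[1])]
        a = small_matrix(counts_a, genes, cells, clusters=clusters, sample="A")
        b = small_matrix(counts_b, genes, [f"d{i}" for i in range(np.shape(counts_b)[1])], clusters=clusters, sample="B")
        return a, b

    def test_fourfold_ratio_with_zero_pseudocount(self):
        # one gene, equal library sizes: normalized means are proportional to counts
        a, b = self.two_sample([[8, 8], [2, 2]], [[2, 2], [8, 8]], ["0", "0"])
        t = cluster_aggregate_log2ratio(a, b, pseudocount=0.0)
        assert t.loc[t.gene == "g0", "log2_ratio"].item() == pytest.approx(2.0)
        assert t.loc[t.gene == "g1", "log2_ratio"].item() == pytest.approx(-2.0)

    @pytest.mark.parametrize("eps", [0.01, 1.0])
    def test_equal_means_give_zero_for_any_pseudocount(self, eps):
        a, b = self.two_sample([[3, 5], [1, 2]], [[5, 3], [2, 1]], ["0", "0"])
        t = cluster_aggregate_log2ratio(a, b, pseudocount=eps)
        assert np.allclose(t["log2_ratio"], 0.0)

    def test_antisymmetric_under_sample_swap(self):
        rng = np.random.default_rng(3)
        ca = rng.integers(0, 10, size=(6, 8))
        cb = rng.integers(0, 10, size=(6, 8))
        clusters = ["0", "0", "1", "1", "0", "1", "0", "1"]
        a, b = self.two_sample(ca, cb, clusters)
        fwd = cluster_aggregate_log2ratio(a, b)["log2_ratio"]
        rev = cluster_aggregate_log2ratio(b, a)["log2_ratio"]
        assert np.allclose(fwd, -rev)

    def test_cluster_missing_in_one_sample_flagged(self):
        genes = ["g0"]
        a = small_matrix([[1, 2]], genes, ["c0", "c1"], clusters=["0", "1"])
        b = small_matrix([[3, 4]], genes, ["d0", "d1"], clusters=["0", "0"])
        t = cluster_aggregate_log2ratio(a, b)
        row = t[t.cluster == "1"].iloc[0]
        assert row["flag"] == "missing_in_one" and np.isnan(row["log2_ratio"])

    def test_planted_fold_change_recovered(self):
        (a, b), truth = make_count_experiment(
            n_genes=800,
            n_cells_per_sample=1500,
            n_clusters=3,
            planted_log2fc={("gene_0100", "0"): 2.0},
            seed=12,
        )
        t = cluster_aggregate_log2ratio(a, b)
        measured = t[(t.gene == "gene_0100") & (t.cluster == "0")]["log2_ratio"].item()
        assert measured == pytest.approx(2.0, abs=0.3)

    def test_pseudobulk_mode_collapses_clusters(self):
        a, b = self.two_sample([[1, 2], [3, 4]], [[1, 2], [3, 4]], ["0", "1"])
        t = cluster_aggregate_log2ratio(a, b, pseudobulk=True)
        assert set(t["cluster"]) == {"all"}


class TestSelectDE:
    def test_strict_threshold_boundary(self):
        t = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "cluster": "0",
                "log2_ratio": [1.0, 1.01, -1.01, 0.0],
            }
        )
        assert select_de_genes(t) == {"0": ["b", "c"]}

    def test_invariant_to_row_permutation(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(20)],
                "cluster": ["0", "1"] * 10,
                "log2_ratio": rng.normal(0, 1.2, 20),
            }
        )
        shuffled = t.sample(frac=1.0, random_state=5).reset_index(drop=True)
        assert select_de_genes(t) == select_de_genes(shuffled)

    def test_null_experiment_selects_almost_nothing(self):
        (a, b), _ = make_count_experiment(n_genes=500, n_cells_per_sample=1500, seed=8)
        t = cluster_aggregate_log2ratio(a, b)
        selected = select_de_genes(t)
        total = sum(len(v) for v in selected.values())
        assert total / len(t) < 0.05


class TestEnrichment:
    def test_boundary_and_unassigned(self):
        e = pd.DataFrame(
            {
                "cluster": ["0", "0", "1"],
                "set": ["neuronal", "glial", "neuronal"],
                "NES": [7.5, 7.49, 2.0],
            }
        )
        out = filter_enrichment(e).set_index("cluster")
        assert out.loc["0", "assignment"] == "neuronal"  # 7.5 kept: rule is >=
        assert out.loc["1", "assignment"] == "unassigned"

    def test_tie_broken_lexicographically_and_flagged(self):
        e = pd.DataFrame(
            {"cluster": ["0"] * 2, "set": ["zeta", "alpha"], "NES": [9.0, 9.0]}
        )
        out = filter_enrichment(e).iloc[0]
        assert out["assignment"] == "alpha" and out["tie"]


class TestOverrepresentation:
    def test_set_equal_to_background_gives_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        out = overrepresentation_test(bg[:4], bg, {"all": bg})
        row = out.iloc[0]
        assert row["p0"] == 1.0 and row["k"] == 4 and row["p_raw"] == 1.0

    def test_worked_example_binomial_tail(self):
        bg = [f"g{i}" for i in range(20)]
        half = bg[:10]  # p0 = 0.5
        query = bg[:5]  # all 5 in the set: k = 5, n = 5
        out = overrepresentation_test(query, bg, {"half": half, "other": bg[10:]})
        row = out.set_index("set").loc["half"]
        assert row["p_raw"] == pytest.approx(0.03125, abs=1e-12)
        assert row["p_bonferroni"] == pytest.approx(0.0625, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        out = overrepresentation_test(bg[:3], bg, {"s": bg[5:]})
        assert out.iloc[0]["k"] == 0 and out.iloc[0]["p_raw"] == 1.0

    def test_empty_query_all_p_one_and_empty_background_raises(self):
        bg = ["a", "b"]
        out = overrepresentation_test([], bg, {"s": ["a"]})
        assert (out["p_raw"] == 1.0).all()
        with pytest.raises(ValueError):
            overrepresentation_test([], [], {"s": ["a"]})
        with pytest.raises(ValueError):
            overrepresentation_test(["zz"], bg, {"s": ["a"]})

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n_query=st.integers(1, 50),
        set_size=st.integers(1, 60),
        seed=st.integers(0, 10_000),
    )
    def test_tail_property_holds_for_arbitrary_query_set_pairs(self, n_query, set_size, seed):
        rng = np.random.default_rng(seed)
        bg = [f"g{i}" for i in range(60)]
        query = list(rng.choice(bg, size=n_query, replace=False))
        s = list(rng.choice(bg, size=set_size, replace=False))
        row = overrepresentation_test(query, bg, {"s": s}).iloc[0]
        assert row["p_raw"] == pytest.approx(
            binomial_tail(int(row["k"]), int(row["n"]), row["p0"]), abs=1e-10
        )
        assert row["p_bonferroni"] == row["p_raw"]  # single set: m = 1

    def test_matches_brute_force_tail_sums(self):
        rng = np.random.default_rng(42)
        bg = [f"g{i}" for i in range(60)]
        for _ in range(50):
            n_query = int(rng.integers(1, 50))
            set_size = int(rng.integers(1, 60))
            query = list(rng.choice(bg, size=n_query, replace=False))
            s = list(rng.choice(bg, size=set_size, replace=False))
            out = overrepresentation_test(query, bg, {"s": s})
            row = out.iloc[0]
            expected = binomial_tail(int(row["k"]), int(row["n"]), row["p0"])
            assert row["p_raw"] == pytest.approx(expected, abs=1e-10)
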