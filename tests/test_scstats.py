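"""QC filtering, DEG selection, Jaccard overlap, and module scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichecoloc as nc
from nichecoloc.scstats import (
    DegThresholds,
    GeneSet,
    QcThresholds,
    jaccard,
    module_score,
    normalize,
    qc_filter,
    select_degs,
)

from conftest import make_cell_matrix


class TestQcFilter:
    def test_boundary_cells_retained_strict_rules(self):
        adata = make_cell_matrix(
            np.ones((3, 5), dtype=int),
            total_counts=[999, 1000, 50_000],
            n_genes=[400, 300, 5_000],
            mito_frac=[0.05, 0.10, 0.10],
        )
        filtered, removed = qc_filter(adata)
        # UMI=999 removed (strict <1000); exact-boundary cells retained
        assert filtered.obs_names.tolist() == ["cell1", "cell2"]
        assert removed["umi_low"] == 1 and removed["total_removed"] == 1

    def test_doublet_rule_toggle(self):
        adata = make_cell_matrix(
            np.ones((2, 5), dtype=int),
            total_counts=[2_000, 2_000],
            n_genes=[400, 400],
            doublet=[True, False],
        )
        kept, _ = qc_filter(adata)
        assert kept.n_obs == 1
        kept2, _ = qc_filter(adata, QcThresholds(drop_doublets=False))
        assert kept2.n_obs == 2

    def test_all_passing_identity(self):
        adata = make_cell_matrix(
            np.ones((4, 5), dtype=int), total_counts=[2000] * 4, n_genes=[400] * 4
        )
        filtered, removed = qc_filter(adata)
        assert filtered.obs_names.tolist() == adata.obs_names.tolist()
        assert removed["total_removed"] == 0

    def test_idempotent(self, sim_cells_lowq):
        once, _ = qc_filter(sim_cells_lowq)
        twice, removed = qc_filter(once)
        assert twice.obs_names.tolist() == once.obs_names.tolist()
        assert removed["total_removed"] == 0

    def test_survivor_count_matches_rowwise_oracle(self, sim_cells_lowq):
        obs = sim_cells_lowq.obs
        oracle = (
            (obs["total_counts"] >= 1000)
            & (obs["total_counts"] <= 50_000)
            & (obs["n_genes"] >= 300)
            & (obs["n_genes"] <= 5_000)
            & (obs["mito_frac"] <= 0.10)
            & ~obs["doublet"]
        )
        filtered, _ = qc_filter(sim_cells_lowq)
        assert filtered.n_obs == int(oracle.sum()) == 80

    def test_empty_input_warns(self):
        adata = make_cell_matrix(np.ones((2, 3), dtype=int))[:0]
        with pytest.warns(UserWarning):
            out, removed = qc_filter(adata)
        assert out.n_obs == 0 and removed == {}

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            QcThresholds(umi_min=100, umi_max=100)


class TestSelectDegs:
    @staticmethod
    def _toy(seed=0, shift_gene=0, shift=4.0, n_per_group=50):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3.0, size=(2 * n_per_group, 8))
        counts[:n_per_group, shift_gene] += rng.poisson(shift, size=n_per_group)
        adata = make_cell_matrix(counts)
        adata.obs["cluster"] = pd.Categorical(
            ["in"] * n_per_group + ["out"] * n_per_group
        )
        return normalize(adata)

    def test_low_fraction_gene_excluded(self):
        adata = self._toy()
        counts = adata.X.toarray()
        counts[:, 7] = 0
        counts[:3, 7] = 50  # expressed in 6% of the in-group
        adata.X = counts
        normalize(adata)
        res = select_degs(adata, "cluster")
        tested = res.table[(res.table["group"] == "in") & (res.table["gene"] == "g7")]
        assert tested.empty

    def test_planted_marker_selected_with_correct_log2fc(self):
        adata = self._toy()
        res = select_degs(adata, "cluster")
        row = res.table[(res.table["group"] == "in") & (res.table["gene"] == "g0")].iloc[0]
        # oracle: Seurat-style fold change on the lognorm layer
        ln = adata.layers["lognorm"]
        ln = ln.toarray() if hasattr(ln, "toarray") else np.asarray(ln)
        grp = adata.obs["cluster"].to_numpy()
        expected = np.log2(np.expm1(ln[grp == "in", 0]).mean() + 1) - np.log2(
            np.expm1(ln[grp == "out", 0]).mean() + 1
        )
        assert row["log2fc"] == pytest.approx(expected)
        assert row["selected"]
        assert "g0" in res.gene_sets["in"].genes

    def test_label_swap_negates_log2fc_keeps_p(self):
        adata = self._toy(seed=1)
        res = select_degs(adata, "cluster", DegThresholds(direction="both"))
        t = res.table.pivot(index="gene", columns="group", values="log2fc")
        assert np.allclose(t["in"], -t["out"])
        p = res.table.pivot(index="gene", columns="group", values="p_value")
        assert np.allclose(p["in"], p["out"])

    def test_small_group_excluded_with_warning(self):
        adata = self._toy()
        labels = adata.obs["cluster"].astype(str).to_numpy()
        labels[:2] = "tiny"
        adata.obs["cluster"] = pd.Categorical(labels)
        with pytest.warns(UserWarning, match="tiny"):
            res = select_degs(adata, "cluster")
        assert "tiny" not in set(res.table["group"])

    def test_permutation_null_mostly_empty(self):
        empties = 0
        trials = 30
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(2.0, size=(60, 10))
            adata = make_cell_matrix(counts)
            adata.obs["cluster"] = pd.Categorical(rng.permutation(["a"] * 30 + ["b"] * 30))
            normalize(adata)
            res = select_degs(adata, "cluster", DegThresholds(direction="both"))
            if res.table.empty or not res.table["selected"].any():
                empties += 1
        assert empties / trials >= 0.9


class TestJaccard:
    def test_forced_arithmetic(self):
        a = GeneSet("a", ["g1", "g2", "g3"])
        b = GeneSet("b", ["g2", "g3", "g4"])
        assert jaccard(a, b) == 0.5

    def test_identity_and_disjoint(self):
        a = GeneSet("a", ["x", "y"])
        assert jaccard(a, a) == 1.0
        assert jaccard(a, GeneSet("b", ["z"])) == 0.0

    def test_empty_set_rejected_at_construction(self):
        with pytest.raises(ValueError):
            GeneSet("empty", [])
        with pytest.raises(ValueError):
            GeneSet("dup", ["g1", "g1"])

    @settings(deadline=None, derandomize=True)
    @given(
        st.sets(st.integers(0, 30), min_size=1),
        st.sets(st.integers(0, 30), min_size=1),
    )
    def test_symmetric_bounded_equality_property(self, ga, gb):
        a = GeneSet("a", [f"g{i}" for i in sorted(ga)])
        b = GeneSet("b", [f"g{i}" for i in sorted(gb)])
        j = jaccard(a, b)
        assert j == jaccard(b, a)
        assert 0.0 <= j <= 1.0
        assert (j == 1.0) == (a.genes == b.genes)


class TestModuleScore:
    @staticmethod
    def _matrix(seed=0, n_cells=10, n_genes=20):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(rng.uniform(0.5, 8.0, size=n_genes), size=(n_cells, n_genes))
        return normalize(make_cell_matrix(counts))

    def test_self_control_gives_zero(self):
        adata = self._matrix()
        panel = GeneSet("s", ["g0", "g3", "g5"])
        res = module_score(adata, panel, n_bins=2, n_ctrl=3, control_genes=["g0", "g3", "g5"])
        assert np.allclose(res.score, 0.0)

    def test_shift_invariance(self):
        adata = self._matrix(seed=1)
        panel = GeneSet("s", ["g1", "g2"])
        base = module_score(adata, panel, n_bins=2, n_ctrl=3, seed=0)
        ln = adata.layers["lognorm"]
        ln = ln.toarray() if hasattr(ln, "toarray") else np.asarray(ln)
        adata.layers["lognorm"] = ln + 3.7
        shifted = module_score(adata, panel, n_bins=2, n_ctrl=3, seed=0)
        assert np.allclose(base.score, shifted.score)

    def test_monotone_in_set_expression(self):
        adata = self._matrix(seed=2)
        panel = GeneSet("s", ["g0", "g1"])
        ctrl = ["g5", "g6", "g7"]
        base = module_score(adata, panel, n_bins=2, n_ctrl=3, control_genes=ctrl)
        ln = adata.layers["lognorm"]
        ln = ln.toarray() if hasattr(ln, "toarray") else np.asarray(ln).copy()
        ln[:, [0, 1]] += 0.9  # uniformly increase set genes, controls fixed
        adata.layers["lognorm"] = ln
        boosted = module_score(adata, panel, n_bins=2, n_ctrl=3, control_genes=ctrl)
        assert np.all(boosted.score >= base.score - 1e-12)

    def test_seeded_determinism_and_bookkeeping(self):
        adata = self._matrix(seed=3)
        panel = GeneSet("s", ["g2", "g9"])
        r1 = module_score(adata, panel, n_bins=4, n_ctrl=2, seed=7)
        r2 = module_score(adata, panel, n_bins=4, n_ctrl=2, seed=7)
        assert np.array_equal(r1.score, r2.score)
        assert r1.control_genes == r2.control_genes
        assert set(r1.control_genes) == {"g2", "g9"}

    def test_missing_gene_listed_in_error(self):
        adata = self._matrix()
        with pytest.raises(ValueError, match="nope"):
            module_score(adata, GeneSet("s", ["g0", "nope"]), n_bins=2, n_ctrl=2)

    def test_small_bin_warns_and_samples_with_replacement(self):
        adata = self._matrix()
        with pytest.warns(UserWarning, match="replacement"):
            module_score(adata, GeneSet("s", ["g0"]), n_bins=2, n_ctrl=50, seed=0)

    def test_n_bins_lower_bound(self):
        adata = self._matrix()
        with pytest.raises(ValueError):
            module_score(adata, GeneSet("s", ["g0"]), n_bins=1, n_ctrl=2)
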