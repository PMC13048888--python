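"""kNN neighborhoods, the coloc statistic, positivity tables, and the k-sweep."""

import numpy as np
import pandas as pd
import pytest

import nichecoloc as nc
from nichecoloc.coloc import (
    ColocConfig,
    coloc_score,
    hub_gene_spot_test,
    k_sensitivity,
    knn_neighbors,
    neighborhood_means,
    positivity_table,
)


class TestKnn:
    def test_collinear_tie_broken_by_index(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        nbrs = knn_neighbors(pts, 1)
        # point 1 is equidistant from 0 and 2; ascending index wins
        assert nbrs.tolist() == [[1], [0], [1]]

    def test_matches_bruteforce_random(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 80))
            k = int(rng.integers(1, n))
            pts = rng.uniform(size=(n, 2))
            got = knn_neighbors(pts, k)
            dist = np.hypot(
                pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1]
            )
            for i in range(n):
                expected = sorted(
                    (j for j in range(n) if j != i), key=lambda j: (dist[i, j], j)
                )[:k]
                assert got[i].tolist() == expected

    def test_identical_points_contract(self):
        pts = np.zeros((5, 2))
        nbrs = knn_neighbors(pts, 3)
        assert nbrs.shape == (5, 3)
        for i in range(5):
            assert i not in nbrs[i]
            assert len(set(nbrs[i].tolist())) == 3

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            knn_neighbors(np.zeros((4, 2)), 4)


class TestNeighborhoodMeans:
    def test_constant_score(self):
        pts = np.random.default_rng(1).uniform(size=(30, 2))
        nbrs = knn_neighbors(pts, 4)
        assert np.allclose(neighborhood_means(np.full(30, 0.7), nbrs), 0.7)

    def test_four_spot_hand_computed(self):
        # square: each corner's 2 nearest neighbors are the adjacent corners
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        scores = np.array([0.0, 1.0, 1.0, 0.0])
        nbrs = knn_neighbors(pts, 2)
        means = neighborhood_means(scores, nbrs)
        assert np.allclose(means, [1.0, 0.0, 0.0, 1.0])

    def test_order_invariance(self, rng):
        pts = rng.uniform(size=(40, 2))
        scores = rng.uniform(size=40)
        nbrs = knn_neighbors(pts, 5)
        means = neighborhood_means(scores, nbrs)
        perm = rng.permutation(40)
        means_p = neighborhood_means(scores[perm], knn_neighbors(pts[perm], 5))
        inv = np.argsort(perm)
        assert np.allclose(means_p[inv], means)


def coloc_oracle(a, b, nbrs):
    """Independent direct transcription of the centered symmetric statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    za = (a - a.mean()) / a.std()
    zb = (b - b.mean()) / b.std()
    out = np.empty(len(a))
    for i in range(len(a)):
        out[i] = za[i] * zb[nbrs[i]].mean() + zb[i] * za[nbrs[i]].mean()
    return out


class TestColocScore:
    def test_constant_scores_give_zero(self, rng):
        pts = rng.uniform(size=(20, 2))
        nbrs = knn_neighbors(pts, 3)
        with pytest.warns(UserWarning):
            c = coloc_score(np.full(20, 0.5), np.full(20, 0.5), nbrs)
        assert np.all(c == 0)
        assert np.count_nonzero(c > 0) == 0

    def test_symmetry_in_a_and_b(self, rng):
        pts = rng.uniform(size=(50, 2))
        nbrs = knn_neighbors(pts, 4)
        a, b = rng.uniform(size=50), rng.uniform(size=50)
        assert np.allclose(coloc_score(a, b, nbrs), coloc_score(b, a, nbrs))

    def test_patch_fixture_against_oracle(self):
        # patch (0-2) high in both programs; far cluster (3-5) below-mean A /
        # above-mean B; pair (6-7) low in both
        pts = np.array(
            [
                [0, 0], [0.1, 0], [0, 0.1],
                [5, 5], [5.1, 5], [5, 5.1],
                [10, 10], [10.1, 10],
            ],
            dtype=float,
        )
        a = np.array([0.9, 0.8, 0.85, 0.1, 0.15, 0.2, 0.1, 0.15])
        b = np.array([0.9, 0.95, 0.8, 0.9, 0.95, 0.85, 0.1, 0.05])
        nbrs = knn_neighbors(pts, 2)
        c = coloc_score(a, b, nbrs)
        assert np.allclose(c, coloc_oracle(a, b, nbrs))
        assert np.all(c[:3] > 0)  # jointly enriched patch
        assert np.all(c[3:6] < 0)  # discordant: below-mean A, above-mean B

    def test_affine_invariance(self, rng):
        pts = rng.uniform(size=(40, 2))
        nbrs = knn_neighbors(pts, 5)
        a, b = rng.uniform(size=40), rng.uniform(size=40)
        base = coloc_score(a, b, nbrs)
        scaled = coloc_score(3.2 * a - 1.0, 0.25 * b + 7.0, nbrs)
        assert np.allclose(base, scaled)

    def test_centering_none_variant(self, rng):
        pts = rng.uniform(size=(30, 2))
        nbrs = knn_neighbors(pts, 3)
        a, b = rng.uniform(size=30), rng.uniform(size=30)
        cfg = ColocConfig(centering="none", symmetric=True)
        c = coloc_score(a, b, nbrs, cfg)
        assert np.allclose(c, a * neighborhood_means(b, nbrs) + b * neighborhood_means(a, nbrs))


class TestPositivity:
    def test_all_nonpositive(self):
        coloc = np.array([-1.0, 0.0, -0.5, 0.0])
        cond = np.array(["disease", "disease", "control", "control"])
        table = positivity_table(coloc, cond)
        assert table[:, 0].tolist() == [0, 0]

    def test_exact_zero_is_negative(self):
        table = positivity_table(np.array([0.0, 1e-12]), np.array(["disease", "control"]))
        assert table.tolist() == [[0, 1], [1, 0]]

    def test_planted_counts(self, rng):
        coloc = np.where(rng.random(200) < 0.3, 1.0, -1.0)
        cond = np.array(["disease"] * 120 + ["control"] * 80)
        table = positivity_table(coloc, cond)
        assert table[0].sum() == 120 and table[1].sum() == 80
        assert table[0, 0] == int((coloc[:120] > 0).sum())

    def test_missing_condition_errors(self):
        with pytest.raises(ValueError):
            positivity_table(np.ones(3), np.array(["disease"] * 3))


class TestKSensitivity:
    def test_duplicating_samples_preserves_proportions(self, small_spots):
        cfg = ColocConfig(k_list=(3, 5))
        res1 = k_sensitivity(small_spots, "score_A", "score_B", cfg)
        dup = small_spots.copy()
        dup["sample_id"] = dup["sample_id"] + "_copy"
        dup["spot_id"] = dup["spot_id"] + "_copy"
        res2 = k_sensitivity(
            pd.concat([small_spots, dup], ignore_index=True), "score_A", "score_B", cfg
        )
        for col in ("prop_pos_disease", "prop_pos_control"):
            assert np.allclose(res1.summary[col], res2.summary[col])

    def test_spot_order_invariance(self, small_spots, rng):
        cfg = ColocConfig(k_list=(4,))
        res1 = k_sensitivity(small_spots, "score_A", "score_B", cfg)
        shuffled = small_spots.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res2 = k_sensitivity(shuffled, "score_A", "score_B", cfg)
        pd.testing.assert_frame_equal(res1.summary, res2.summary)

    def test_effect_detected_single_run(self):
        spots = nc.generate_spot_table(
            nc.SpatialSimParams(seed=11, n_spots_per_sample=600, hub_genes=())
        )
        res = k_sensitivity(spots, "score_SPP1_myeloid", "score_POSTN_fibroblast")
        assert (res.summary["odds_ratio"] > 1).all()
        assert list(res.summary["k"]) == list(nc.DEFAULT_K_LIST)

    def test_k_exceeding_sample_size_errors(self, small_spots):
        with pytest.raises(ValueError):
            k_sensitivity(small_spots, "score_A", "score_B", ColocConfig(k_list=(60,)))

    def test_missing_column_errors(self, small_spots):
        with pytest.raises(ValueError):
            k_sensitivity(small_spots, "score_A", "score_missing")


class TestHubGeneSpotTest:
    def test_two_point_exact(self):
        spots = pd.DataFrame(
            {
                "condition": ["disease", "disease", "control", "control"],
                "expr_SPP1": [3.0, 4.0, 1.0, 2.0],
            }
        )
        out = hub_gene_spot_test(spots, ["SPP1"])
        assert out.loc[0, "p_value"] == pytest.approx(1 / 6)

    def test_missing_gene_warned_and_skipped(self):
        spots = pd.DataFrame(
            {
                "condition": ["disease", "control"] * 3,
                "expr_SPP1": np.arange(6, dtype=float),
            }
        )
        with pytest.warns(UserWarning, match="POSTN"):
            out = hub_gene_spot_test(spots, ["SPP1", "POSTN"])
        assert out["gene"].tolist() == ["SPP1"]

    def test_null_p_roughly_uniform(self):
        hits = 0
        trials = 60
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            spots = pd.DataFrame(
                {
                    "condition": ["disease"] * 100 + ["control"] * 100,
                    "expr_SPP1": rng.poisson(2.0, size=200).astype(float),
                }
            )
            out = hub_gene_spot_test(spots, ["SPP1"])
            hits += out.loc[0, "p_value"] < 0.05
        assert hits / trials <= 0.1  # ~5% nominal, one-sided slack
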