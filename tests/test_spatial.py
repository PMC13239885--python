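"""Spot scoring, seed calling, window dilation and the niche association test."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_grid
from nichesig.datasets import SignatureSet, ValidationError
from nichesig.experiments import dilation_oracle_study
from nichesig.spatial import (
    dilate_niche,
    high_enrichment_spots,
    niche_association_test,
    run_niche_pipeline,
    spot_signature_score,
)


class TestSpotScore:
    def test_single_gene_signature_equals_gene_row(self, colocalized_grid):
        _, grid = colocalized_grid
        gene = grid.var_names[0]
        score = spot_signature_score(grid, [gene])
        assert np.allclose(score.to_numpy(),
                           np.asarray(grid[:, [gene]].X.todense()).ravel())

    def test_two_gene_sum(self, colocalized_grid):
        _, grid = colocalized_grid
        g1, g2 = grid.var_names[0], grid.var_names[1]
        score = spot_signature_score(grid, [g1, g2])
        expected = np.asarray(grid[:, [g1, g2]].X.todense()).sum(axis=1)
        assert np.allclose(score.to_numpy(), expected)

    def test_unmatched_gene_warns_and_is_dropped(self, colocalized_grid):
        _, grid = colocalized_grid
        gene = grid.var_names[0]
        with pytest.warns(UserWarning, match="GHOST"):
            score = spot_signature_score(grid, [gene, "GHOST"])
        assert np.allclose(score.to_numpy(),
                           spot_signature_score(grid, [gene]).to_numpy())

    def test_no_matched_genes_is_error(self, colocalized_grid):
        _, grid = colocalized_grid
        with pytest.raises(ValidationError):
            spot_signature_score(grid, ["GHOST"])


class TestSeedCalling:
    def test_distinct_ladder(self):
        scores = pd.Series(np.arange(1.0, 1001.0),
                           index=[f"s{i}" for i in range(1000)])
        seeds, thr = high_enrichment_spots(scores)
        assert thr == pytest.approx(975.025)
        assert len(seeds) == 25
        assert set(scores[seeds]) == set(range(976, 1001))

    def test_four_point_quantile(self):
        seeds, thr = high_enrichment_spots(pd.Series([0.0, 1.0, 2.0, 3.0]))
        assert thr == pytest.approx(2.925)
        assert len(seeds) == 1

    def test_flat_scores_yield_no_seeds(self):
        seeds, thr = high_enrichment_spots(pd.Series([7.0] * 50))
        assert thr == 7.0
        assert len(seeds) == 0

    def test_raising_quantile_never_adds_seeds(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.random(200))
        prev = None
        for q in (0.5, 0.8, 0.95, 0.99):
            seeds, _ = high_enrichment_spots(scores, quantile=q)
            if prev is not None:
                assert set(seeds) <= set(prev)
            prev = seeds


class TestDilation:
    def test_interior_seed_makes_nine(self):
        grid = make_grid(5, 5)
        lab = dilate_niche(["s2_2"], grid)
        assert lab.n_niche == 9

    def test_corner_seed_makes_four(self):
        grid = make_grid(5, 5)
        lab = dilate_niche(["s0_0"], grid)
        assert lab.n_niche == 4

    def test_adjacent_seeds_merge_to_twelve(self):
        grid = make_grid(6, 6)
        lab = dilate_niche(["s2_2", "s3_2"], grid)
        assert lab.n_niche == 12  # a 4x3 block

    def test_niche_bounded_by_nine_per_seed(self):
        grid = make_grid(8, 8)
        rng = np.random.default_rng(1)
        seeds = list(rng.choice(grid.obs_names, size=5, replace=False))
        lab = dilate_niche(seeds, grid)
        assert lab.n_niche <= 9 * len(seeds)
        assert set(lab.seed_spots) <= set(lab.niche_spots)

    def test_matches_bruteforce_chebyshev(self):
        res = dilation_oracle_study(n_instances=40, seed=0)
        assert res["agreement_frac"] == 1.0

    def test_unknown_seed_rejected(self):
        grid = make_grid(3, 3)
        with pytest.raises(ValidationError, match="unknown"):
            dilate_niche(["nope"], grid)


class TestAssociation:
    def _labeling(self, grid, member_ids):
        from nichesig.spatial import NicheLabeling
        membership = pd.Series(grid.obs_names.isin(member_ids), index=grid.obs_names)
        return NicheLabeling("ctx", 0.0, pd.Index(member_ids),
                             grid.obs_names[membership], membership)

    def test_exact_separated_example(self):
        grid = make_grid(6, 1, values=[2, 3, 4, 0.5, 1, 1.5])
        lab = self._labeling(grid, ["s0_0", "s1_0", "s2_0"])
        res = niche_association_test(spot_signature_score(grid, ["g"]), lab)
        assert res["p"] == pytest.approx(0.1)
        assert res["direction"] == "niche_higher"

    def test_zero_score_spots_excluded(self):
        grid = make_grid(7, 1, values=[2, 3, 4, 0.5, 1, 1.5, 0.0])
        lab = self._labeling(grid, ["s0_0", "s1_0", "s2_0"])
        res = niche_association_test(spot_signature_score(grid, ["g"]), lab)
        assert res["n_excluded"] == 1
        assert res["n_other"] == 3
        assert res["p"] == pytest.approx(0.1)

    def test_identical_distributions_give_p_one(self):
        grid = make_grid(6, 1, values=[1, 2, 3, 1, 2, 3])
        lab = self._labeling(grid, ["s0_0", "s1_0", "s2_0"])
        res = niche_association_test(spot_signature_score(grid, ["g"]), lab)
        assert res["p"] == pytest.approx(1.0)

    def test_empty_group_is_error(self):
        grid = make_grid(4, 1, values=[0.0, 0.0, 1.0, 2.0])
        lab = self._labeling(grid, ["s0_0", "s1_0"])
        with pytest.raises(ValidationError, match="empty group"):
            niche_association_test(spot_signature_score(grid, ["g"]), lab)


class TestPipelinePermutationInvariance:
    def test_spot_order_does_not_matter(self, colocalized_grid):
        _, grid = colocalized_grid
        sigs = SignatureSet({"DPT": [f"D{i}" for i in range(10)],
                             "capillaryEC": [f"C{i}" for i in range(10)]})
        rep1 = run_niche_pipeline(grid, "DPT", sigs, ["capillaryEC"])
        rng = np.random.default_rng(5)
        perm = rng.permutation(grid.n_obs)
        rep2 = run_niche_pipeline(grid[perm].copy(), "DPT", sigs, ["capillaryEC"])
        for col in ("p", "statistic", "n_niche", "n_other", "threshold", "n_seeds"):
            assert rep1.iloc[0][col] == pytest.approx(rep2.iloc[0][col])

    def test_strong_colocalization_is_detected(self, colocalized_grid):
        _, grid = colocalized_grid
        sigs = SignatureSet({"DPT": [f"D{i}" for i in range(10)],
                             "capillaryEC": [f"C{i}" for i in range(10)]})
        rep = run_niche_pipeline(grid, "DPT", sigs, ["capillaryEC"])
        assert rep.iloc[0]["p"] < 0.05
        assert rep.iloc[0]["direction"] == "niche_higher"
        assert rep.iloc[0]["p_adj"] == pytest.approx(rep.iloc[0]["p"])  # single context
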