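"""QC filters, normalisation, rank-sum DE and dual-criterion signatures."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from nichesig.datasets import EmptyDatasetError, SignatureSet, ValidationError
from nichesig.signatures import (
    SingleSubclusterError,
    bh_adjust,
    derive_subcluster_signature,
    filter_cells,
    normalize_counts,
    prioritize_risk_genes,
    wilcoxon_de,
)
from nichesig.synthetic import marker_gene_names


def _cells(count_rows, mito=None, **obs_cols):
    """AnnData from explicit per-cell count rows."""
    X = sp.csr_matrix(np.asarray(count_rows, dtype=float))
    n, g = X.shape
    var = pd.DataFrame({"mito": mito if mito is not None else [False] * g},
                       index=[f"g{i}" for i in range(g)])
    obs = pd.DataFrame(obs_cols or {}, index=[f"c{i}" for i in range(n)])
    return ad.AnnData(X=X, obs=obs, var=var)


class TestFilterCells:
    def test_boundary_rules(self):
        # 510 genes so detected-gene boundaries are reachable
        g = 510
        rows = []
        rows.append(np.full(g, 24))           # 12240 UMI -> excluded (umi)
        ok = np.zeros(g); ok[:500] = 1
        rows.append(ok)                        # exactly 500 detected -> retained
        low = np.zeros(g); low[:499] = 1
        rows.append(low)                       # 499 detected -> excluded
        mito_cell = np.zeros(g); mito_cell[:500] = 1; mito_cell[0] = 33
        rows.append(mito_cell)                 # mito frac 33/532 ~ 6.2% -> excluded
        mito = [True] + [False] * (g - 1)
        adata = _cells(rows, mito=mito)
        kept = filter_cells(adata)
        assert list(kept.obs_names) == ["c1"]
        rep = kept.uns["qc_report"]
        assert rep["removed_umi"] == 1
        assert rep["removed_gene_count"] == 1
        assert rep["removed_mito"] == 1

    def test_idempotent(self):
        from nichesig.synthetic import SimSingleCellConfig, SubclusterSpec, generate_single_cell
        cfg = SimSingleCellConfig(
            n_genes=2000,
            subclusters=(SubclusterSpec("A", "T", {("tumour", "short"): 50}),),
            seed=0,
        )
        adata = generate_single_cell(cfg)
        once = filter_cells(adata)
        assert 0 < once.n_obs <= adata.n_obs
        twice = filter_cells(once)
        assert list(once.obs_names) == list(twice.obs_names)

    def test_all_removed_is_explicit_error(self):
        adata = _cells([np.full(10, 2000)])  # 20000 UMI, 10 detected genes
        with pytest.raises(EmptyDatasetError):
            filter_cells(adata)


class TestNormalize:
    def test_closed_form_value(self):
        row = np.zeros(100)
        row[0] = 10
        row[1] = 9990
        adata = normalize_counts(_cells([row]))
        val = adata.layers["lognorm"][0, 0]
        assert np.isclose(val, np.log(11.0))
        assert adata.layers["lognorm"][0, 2] == 0.0

    def test_depth_invariance(self):
        row = np.array([3.0, 7.0, 0.0, 5.0])
        a = normalize_counts(_cells([row]))
        b = normalize_counts(_cells([2 * row]))
        assert np.allclose(a.layers["lognorm"].todense(), b.layers["lognorm"].todense())

    def test_zero_total_cell_named(self):
        adata = _cells([[1, 2], [0, 0]])
        with pytest.raises(EmptyDatasetError, match="c1"):
            normalize_counts(adata)


def _de_fixture(vals_a, vals_b):
    """Single-gene dataset with groups a and b holding the given lognorm values."""
    n = len(vals_a) + len(vals_b)
    adata = _cells([[0.0]] * n)
    adata.layers["lognorm"] = np.asarray(vals_a + vals_b, dtype=float).reshape(n, 1)
    ids = list(adata.obs_names)
    return adata, ids[:len(vals_a)], ids[len(vals_a):]


class TestWilcoxonDE:
    def test_exact_small_sample_p(self):
        """Fully separated 3-vs-3 data: 2 of the 20 rank assignments are as extreme."""
        adata, a, b = _de_fixture([1, 2, 3], [4, 5, 6])
        res = wilcoxon_de(adata, a, b)
        assert np.isclose(res["p"].iloc[0], 0.1)

    def test_fully_tied_gene_has_p_one(self):
        adata, a, b = _de_fixture([2, 2, 2], [2, 2, 2])
        res = wilcoxon_de(adata, a, b)
        assert res["p"].iloc[0] == 1.0
        assert res["log2fc"].iloc[0] == 0.0

    def test_group_swap_negates_lfc_and_keeps_p(self):
        rng = np.random.default_rng(0)
        adata, a, b = _de_fixture(list(rng.random(8)), list(rng.random(10)))
        r1 = wilcoxon_de(adata, a, b)
        r2 = wilcoxon_de(adata, b, a)
        assert np.allclose(r1["p"], r2["p"])
        assert np.allclose(r1["log2fc"], -r2["log2fc"])

    def test_matches_permutation_oracle(self):
        """Tie-corrected asymptotic p vs a label-permutation null, 200 cells."""
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.poisson(3, 100), rng.poisson(4, 100)]).astype(float)
        adata, a, b = _de_fixture(list(vals[:100]), list(vals[100:]))
        p_impl = wilcoxon_de(adata, a, b)["p"].iloc[0]

        from scipy.stats import rankdata
        ranks = rankdata(vals)
        obs = abs(ranks[:100].sum() - 100 * (len(vals) + 1) / 2)
        n_perm = 100_000
        idx = np.argsort(rng.random((n_perm, vals.size)), axis=1)[:, :100]
        perm_sums = ranks[idx].sum(axis=1)
        perm = np.abs(perm_sums - 100 * (len(vals) + 1) / 2)
        p_perm = (np.sum(perm >= obs - 1e-9) + 1) / (n_perm + 1)
        assert abs(p_impl - p_perm) < 4 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-3

    def test_overlapping_groups_rejected(self):
        adata, a, b = _de_fixture([1, 2, 3], [4, 5, 6])
        with pytest.raises(ValidationError, match="overlap"):
            wilcoxon_de(adata, a, a)


class TestBHAdjust:
    def test_hand_computed_examples(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_adjusted_at_least_raw(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)

    def test_matches_stepup_reference(self):
        """Cummin step-up reference agreement to 1e-12 on random vectors."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            m = p.size
            order = np.argsort(p)
            ref = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            ref = np.minimum(ref, 1.0)
            out = np.empty(m)
            out[order] = ref
            assert np.allclose(bh_adjust(p), out, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestSignatureDerivation:
    def test_recovers_planted_markers(self, small_cells, normed_cells):
        cfg, _ = small_cells
        planted = set(marker_gene_names(cfg)["DPT"])
        genes, prov = derive_subcluster_signature(normed_cells, "DPT")
        got = set(genes)
        assert len(got & planted) >= 0.9 * len(planted)
        assert len(got - planted) <= 0.1 * max(len(got), 1)
        assert prov["n_signature"] == len(genes)

    def test_ordering_by_global_log2fc(self, normed_cells):
        genes, _ = derive_subcluster_signature(normed_cells, "DPT")
        de = wilcoxon_de(normed_cells,
                         normed_cells.obs_names[normed_cells.obs["subcluster"] == "DPT"],
                         normed_cells.obs_names[normed_cells.obs["subcluster"] != "DPT"])
        lfcs = de.loc[genes, "log2fc"].to_numpy()
        assert np.all(np.diff(lfcs) <= 1e-12)

    def test_impossible_threshold_warns_and_is_empty(self, normed_cells):
        with pytest.warns(UserWarning, match="empty"):
            genes, _ = derive_subcluster_signature(normed_cells, "DPT", p_thresh=0.0)
        assert genes == []

    def test_singleton_major_type_is_flagged(self, normed_cells):
        with pytest.raises(SingleSubclusterError, match="global comparison"):
            derive_subcluster_signature(normed_cells, "Bcell")


class TestRiskGenePrioritisation:
    def test_triple_intersection(self):
        curated = SignatureSet({"cytokines": ["C"]})
        res = prioritize_risk_genes({"A", "B", "C"}, {"B", "C", "D"}, curated)
        assert list(res["cytokines"].index[res["cytokines"]["selected"]]) == ["C"]

    def test_disjoint_inputs_empty_not_error(self):
        curated = SignatureSet({"s": ["X", "Y"]})
        res = prioritize_risk_genes({"A"}, {"B"}, curated)
        assert res["s"]["selected"].sum() == 0

    def test_case_mismatch_reported_not_merged(self):
        curated = SignatureSet({"s": ["HBEGF"]})
        res = prioritize_risk_genes({"hbegf"}, {"HBEGF"}, curated)
        row = res["s"].loc["HBEGF"]
        assert not row["selected"]
        assert "de:hbegf" in row["case_mismatch"]

    def test_empty_curated_set_rejected(self):
        with pytest.raises(ValidationError):
            prioritize_risk_genes({"A"}, {"A"}, SignatureSet())
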