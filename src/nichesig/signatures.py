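"""Cell QC, normalisation, rank-sum differential expression and
dual-criterion subcluster signature construction.

A subcluster's signature is the set of genes that are significantly
up-regulated (BH-adjusted p < .05, log2FC > .5 by default) in BOTH of two
rank-sum comparisons: the subcluster against the other cells of its own
major type, and the subcluster against all remaining cells in the
dataset.  Genes passing both criteria form the final signature, ordered
by descending fold change of the global comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import (
    EmptyDatasetError,
    NichesigError,
    SignatureSet,
    ValidationError,
)

__all__ = [
    "filter_cells",
    "normalize_counts",
    "wilcoxon_de",
    "bh_adjust",
    "derive_subcluster_signature",
    "prioritize_risk_genes",
    "SingleSubclusterError",
]

LOGNORM_LAYER = "lognorm"


class SingleSubclusterError(NichesigError):
    """The subcluster is the only one of its major type.

    The within-major-type comparison degenerates; callers should fall
    back to the global comparison explicitly rather than have it
    substituted silently.
    """


# ---------------------------------------------------------------------------
# QC and normalisation
# ---------------------------------------------------------------------------


def filter_cells(adata: ad.AnnData, max_umi: int = 10_000, min_genes: int = 500,
                 max_genes: int = 6_000, max_mito_frac: float = 0.05) -> ad.AnnData:
    """Apply the three cell quality criteria and return the retained cells.

    A cell is kept when its total UMI count is strictly below ``max_umi``,
    its detected-gene count lies in ``[min_genes, max_genes]`` (both ends
    inclusive) and its mitochondrial count fraction is strictly below
    ``max_mito_frac``.  Removal counts per criterion are stored in
    ``.uns['qc_report']``.
    """
    if "mito" not in adata.var.columns:
        raise ValidationError("var must carry a boolean 'mito' flag")
    x = sp.csr_matrix(adata.X)
    total = np.asarray(x.sum(axis=1)).ravel()
    detected = np.asarray((x > 0).sum(axis=1)).ravel()
    mito_mask = adata.var["mito"].to_numpy(dtype=bool)
    mito_counts = np.asarray(x[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() \
        else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)

    pass_umi = total < max_umi
    pass_genes = (detected >= min_genes) & (detected <= max_genes)
    pass_mito = mito_frac < max_mito_frac
    keep = pass_umi & pass_genes & pass_mito

    report = {
        "n_input": int(adata.n_obs),
        "removed_umi": int((~pass_umi).sum()),
        "removed_gene_count": int((~pass_genes).sum()),
        "removed_mito": int((~pass_mito).sum()),
        "n_retained": int(keep.sum()),
    }
    if report["n_retained"] == 0:
        raise EmptyDatasetError(
            f"all {adata.n_obs} cells removed by QC "
            f"(umi: {report['removed_umi']}, genes: {report['removed_gene_count']}, "
            f"mito: {report['removed_mito']})")
    out = adata[keep].copy()
    out.uns["qc_report"] = report
    return out


def normalize_counts(adata: ad.AnnData, scale: float = 10_000.0,
                     layer: str = LOGNORM_LAYER) -> ad.AnnData:
    """Depth-normalise to ``scale`` counts per cell and natural-log1p.

    value = log(1 + count / cell_total * scale).  The result is stored in
    ``adata.layers[layer]`` and the same object is returned.
    """
    x = sp.csr_matrix(adata.X, dtype=float)
    total = np.asarray(x.sum(axis=1)).ravel()
    zero = np.flatnonzero(total == 0)
    if zero.size:
        raise EmptyDatasetError(
            f"cells with zero total counts cannot be normalised: "
            f"{list(adata.obs_names[zero[:10]])}")
    norm = x.multiply(scale / total[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    adata.layers[layer] = norm
    return adata


# ---------------------------------------------------------------------------
# rank-sum DE and BH
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _resolve_cells(adata: ad.AnnData, sel) -> np.ndarray:
    """Boolean mask, positional indices or cell ids -> positional indices."""
    arr = np.asarray(sel)
    if arr.dtype.kind == "b":
        if arr.size != adata.n_obs:
            raise ValidationError("boolean cell mask has wrong length")
        return np.flatnonzero(arr)
    if arr.dtype.kind in "iu":
        return arr.astype(np.intp)
    idx = adata.obs_names.get_indexer(arr)
    if np.any(idx < 0):
        missing = list(np.asarray(arr)[idx < 0][:5])
        raise ValidationError(f"unknown cell ids in group selection: {missing}")
    return idx


def _dense(layer_mat, rows: np.ndarray) -> np.ndarray:
    sub = layer_mat[rows]
    return np.asarray(sub.todense()) if sp.issparse(sub) else np.asarray(sub)


def _log2fc(mean_a: np.ndarray, mean_b: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount))


def wilcoxon_de(adata: ad.AnnData, cells_a, cells_b, layer: str = LOGNORM_LAYER,
                method: str = "auto", use_continuity: bool = False) -> pd.DataFrame:
    """Per-gene two-sided rank-sum (Mann–Whitney) differential expression.

    ``cells_a`` / ``cells_b`` are disjoint cell-id (or boolean/positional)
    selections.  P values are exact for small tie-free groups and use the
    tie-corrected normal approximation otherwise; BH adjustment is across
    all tested genes.  The fold change is
    ``log2((mean(expm1 a) + 1) / (mean(expm1 b) + 1))`` on the de-logged
    normalised values.
    """
    idx_a = _resolve_cells(adata, cells_a)
    idx_b = _resolve_cells(adata, cells_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValidationError("each group needs >= 2 cells")
    if np.intersect1d(idx_a, idx_b).size:
        raise ValidationError("cell groups overlap")

    if layer not in adata.layers:
        raise ValidationError(f"layer {layer!r} not found; run normalize_counts first")
    mat = adata.layers[layer]
    a = _dense(mat, idx_a)
    b = _dense(mat, idx_b)

    res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided",
                             method=method, use_continuity=use_continuity)
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    # fully tied genes have zero rank variance: z = 0, p = 1 by convention
    p[np.isnan(p)] = 1.0

    mean_a = np.expm1(a).mean(axis=0)
    mean_b = np.expm1(b).mean(axis=0)
    lfc = _log2fc(mean_a, mean_b)

    out = pd.DataFrame({
        "log2fc": lfc,
        "p": p,
        "p_adj": bh_adjust(p),
        "mean_a": mean_a,
        "mean_b": mean_b,
        "direction": np.where(lfc >= 0, "up", "down"),
    }, index=adata.var_names.copy())
    out.index.name = "gene"
    return out


# ---------------------------------------------------------------------------
# dual-criterion signature
# ---------------------------------------------------------------------------


def derive_subcluster_signature(adata: ad.AnnData, subcluster: str,
                                p_thresh: float = 0.05, lfc_thresh: float = 0.5,
                                layer: str = LOGNORM_LAYER) -> tuple[list[str], dict]:
    """Dual-criterion signature of one subcluster.

    Genes must be up-regulated (adjusted p < ``p_thresh`` and
    log2FC > ``lfc_thresh``) both against the other cells of the same
    major type and against all remaining cells in the dataset.  Returns
    the gene list (ordered by descending global log2FC) and a provenance
    record.
    """
    obs = adata.obs
    in_sub = (obs["subcluster"] == subcluster).to_numpy()
    if not in_sub.any():
        raise ValidationError(f"unknown subcluster {subcluster!r}")
    major = obs.loc[in_sub, "major_type"].iloc[0]
    in_major = (obs["major_type"] == major).to_numpy()
    within_rest = in_major & ~in_sub
    if not within_rest.any():
        raise SingleSubclusterError(
            f"subcluster {subcluster!r} is the only subcluster of major type {major!r}; "
            "the within-major-type criterion degenerates — run the global comparison alone")
    global_rest = ~in_sub

    sub_ids = adata.obs_names[in_sub]
    de_within = wilcoxon_de(adata, sub_ids, adata.obs_names[within_rest], layer=layer)
    de_global = wilcoxon_de(adata, sub_ids, adata.obs_names[global_rest], layer=layer)

    ok_within = (de_within["p_adj"] < p_thresh) & (de_within["log2fc"] > lfc_thresh)
    ok_global = (de_global["p_adj"] < p_thresh) & (de_global["log2fc"] > lfc_thresh)
    both = ok_within & ok_global
    genes = de_global.loc[both].sort_values("log2fc", ascending=False, kind="stable").index.tolist()
    if not genes:
        warnings.warn(f"signature of {subcluster!r} is empty at thresholds "
                      f"(p_adj < {p_thresh}, log2FC > {lfc_thresh})")
    provenance = {
        "subcluster": subcluster,
        "major_type": str(major),
        "p_thresh": p_thresh,
        "lfc_thresh": lfc_thresh,
        "n_within_pass": int(ok_within.sum()),
        "n_global_pass": int(ok_global.sum()),
        "n_signature": len(genes),
    }
    return genes, provenance


def derive_signatures(adata: ad.AnnData, subclusters=None, p_thresh: float = 0.05,
                      lfc_thresh: float = 0.5, layer: str = LOGNORM_LAYER) -> SignatureSet:
    """Dual-criterion signatures for several subclusters as a SignatureSet."""
    if subclusters is None:
        subclusters = list(adata.obs["subcluster"].unique())
    sigs = SignatureSet(provenance={"p_thresh": p_thresh, "lfc_thresh": lfc_thresh})
    prov = {}
    skipped = {}
    for sub in subclusters:
        try:
            genes, p = derive_subcluster_signature(adata, sub, p_thresh, lfc_thresh, layer)
        except SingleSubclusterError as exc:
            warnings.warn(str(exc))
            skipped[str(sub)] = str(exc)
            continue
        sigs.add(sub, genes)
        prov[sub] = p
    sigs.provenance["per_subcluster"] = prov
    if skipped:
        sigs.provenance["skipped"] = skipped
    return sigs


# ---------------------------------------------------------------------------
# risk-gene triple intersection
# ---------------------------------------------------------------------------


def prioritize_risk_genes(de_up_in_short, cox_risk_genes, curated_sets: SignatureSet
                          ) -> dict[str, pd.DataFrame]:
    """Triple intersection of survival-associated evidence per curated set.

    For every curated gene set (e.g. chemokine receptors, cytokines),
    returns the genes that are simultaneously up-regulated in short-term
    survivors, flagged as risk genes by the univariate Cox screen, and
    members of the curated set — with per-gene provenance.  Matching is
    exact and case-sensitive; symbols that would match only after case
    folding are reported as unmatched instead of being merged.
    """
    de_set = set(de_up_in_short)
    cox_set = set(cox_risk_genes)
    if len(curated_sets) == 0:
        raise ValidationError("no curated sets supplied")
    out: dict[str, pd.DataFrame] = {}
    for name, genes in curated_sets.items():
        if not genes:
            raise ValidationError(f"curated set {name!r} is empty")
        rows = []
        de_lower = {g.lower(): g for g in de_set}
        cox_lower = {g.lower(): g for g in cox_set}
        for g in genes:
            in_de, in_cox = g in de_set, g in cox_set
            case_only = []
            if not in_de and g.lower() in de_lower:
                case_only.append(f"de:{de_lower[g.lower()]}")
            if not in_cox and g.lower() in cox_lower:
                case_only.append(f"cox:{cox_lower[g.lower()]}")
            rows.append({
                "gene": g,
                "in_de_up_short": in_de,
                "in_cox_risk": in_cox,
                "selected": in_de and in_cox,
                "case_mismatch": ";".join(case_only),
            })
        df = pd.DataFrame(rows).set_index("gene")
        out[name] = df
    return out


def risk_gene_lists(intersections: dict[str, pd.DataFrame]) -> dict[str, list[str]]:
    """Just the selected genes per curated set."""
    return {name: df.index[df["selected"]].tolist() for name, df in intersections.items()}
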