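"""Binned spatial-transcriptomics niche analysis.

The procedure, per signature: (1) sum the expression of the signature's
detected genes at every spot; (2) call spots scoring strictly above the
97.5th percentile "high-enrichment" seeds; (3) dilate every seed by a
3x3 coordinate window (Chebyshev distance 1 on integer bin indices),
merging duplicates, to form the niche; (4) compare a target signature's
spot scores between niche and non-niche spots with a two-sided rank-sum
test, after excluding spots whose target score is not positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .datasets import ValidationError
from .signatures import bh_adjust

__all__ = [
    "NicheLabeling",
    "spot_signature_score",
    "high_enrichment_spots",
    "dilate_niche",
    "niche_association_test",
    "run_niche_pipeline",
]


@dataclass
class NicheLabeling:
    """Per-spot membership of a signature-defined niche."""

    signature: str
    threshold: float
    seed_spots: pd.Index          # score strictly above the threshold
    niche_spots: pd.Index         # seeds plus dilated neighbours
    membership: pd.Series         # bool per spot, indexed like the grid

    @property
    def n_seeds(self) -> int:
        return len(self.seed_spots)

    @property
    def n_niche(self) -> int:
        return len(self.niche_spots)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "signature": self.signature,
            "is_seed": self.membership.index.isin(self.seed_spots),
            "is_niche": self.membership.to_numpy(),
        }, index=self.membership.index.rename("spot_id"))


def spot_signature_score(grid: ad.AnnData, genes, name: str = "signature",
                         depth_normalize: bool = False) -> pd.Series:
    """Per-spot sum of the signature genes detected in the grid.

    Unmatched genes are dropped with a warning; matching none is an
    error.  With ``depth_normalize`` the sum is divided by the spot's
    total counts (off by default: raw stored values are summed).
    """
    genes = list(genes)
    present = [g for g in genes if g in grid.var_names]
    missing = [g for g in genes if g not in grid.var_names]
    if missing:
        warnings.warn(f"signature {name!r}: genes absent from the grid dropped: {missing}")
    if not present:
        raise ValidationError(f"signature {name!r} matches no genes in the grid")
    sub = grid[:, present].X
    vals = np.asarray(sub.sum(axis=1)).ravel() if sp.issparse(sub) \
        else np.asarray(sub).sum(axis=1)
    if depth_normalize:
        tot = np.asarray(grid.X.sum(axis=1)).ravel()
        if np.any(tot == 0):
            raise ValidationError("spots with zero total counts cannot be depth-normalised")
        vals = vals / tot
    return pd.Series(vals, index=grid.obs_names, name=name)


def high_enrichment_spots(scores: pd.Series, quantile: float = 0.975
                          ) -> tuple[pd.Index, float]:
    """Spots scoring strictly above the linear-interpolation quantile.

    Returns (seed spot index, threshold).  With all-equal scores the
    threshold equals the common value and no spot is a seed.
    """
    s = pd.Series(scores)
    if len(s) < 2:
        raise ValidationError("need >= 2 spots to call high-enrichment spots")
    if not (0 < quantile < 1):
        raise ValidationError("quantile must lie in (0, 1)")
    threshold = float(np.quantile(s.to_numpy(dtype=float), quantile))  # type-7 linear
    seeds = s.index[s.to_numpy(dtype=float) > threshold]
    return seeds, threshold


def dilate_niche(seeds, grid: ad.AnnData, distance: int = 1,
                 signature: str = "signature", threshold: float = np.nan) -> NicheLabeling:
    """Union of each seed's (2d+1)x(2d+1) coordinate window, on-grid only.

    Membership uses Chebyshev distance on integer bin coordinates, so
    ``distance=1`` is the 3x3 window.  Neighbour coordinates that do not
    exist in the grid (tissue boundary, holes) are silently absent;
    duplicates are merged.
    """
    seeds = pd.Index(seeds)
    unknown = seeds.difference(grid.obs_names)
    if len(unknown):
        raise ValidationError(f"unknown seed spot ids: {list(unknown[:10])}")
    coords = grid.obs[["x", "y"]].astype(int)
    coord_to_spot = {(int(x), int(y)): sid
                     for sid, x, y in zip(grid.obs_names, coords["x"], coords["y"])}
    niche: set[str] = set()
    offsets = [(dx, dy) for dx in range(-distance, distance + 1)
               for dy in range(-distance, distance + 1)]
    for sid in seeds:
        x0, y0 = int(coords.at[sid, "x"]), int(coords.at[sid, "y"])
        for dx, dy in offsets:
            hit = coord_to_spot.get((x0 + dx, y0 + dy))
            if hit is not None:
                niche.add(hit)
    membership = pd.Series(grid.obs_names.isin(niche), index=grid.obs_names)
    niche_idx = grid.obs_names[membership.to_numpy()]
    return NicheLabeling(signature=signature, threshold=float(threshold),
                         seed_spots=seeds, niche_spots=niche_idx, membership=membership)


def niche_association_test(target_scores: pd.Series, niche: NicheLabeling,
                           min_score: float = 0.0) -> dict:
    """Rank-sum comparison of target scores, niche vs non-niche spots.

    Spots whose target score is <= ``min_score`` are excluded from both
    groups before the two-sided Mann–Whitney test; both groups must stay
    non-empty.  Reports medians, group sizes and the excluded count.
    """
    s = pd.Series(target_scores)
    member = niche.membership.reindex(s.index)
    if member.isna().any():
        raise ValidationError("niche labelling does not cover all scored spots")
    keep = s.to_numpy(dtype=float) > min_score
    n_excluded = int((~keep).sum())
    inside = s[keep & member.to_numpy(dtype=bool)].to_numpy(dtype=float)
    outside = s[keep & ~member.to_numpy(dtype=bool)].to_numpy(dtype=float)
    if inside.size == 0 or outside.size == 0:
        raise ValidationError(
            f"empty group after min_score filter (niche: {inside.size}, "
            f"other: {outside.size}, excluded: {n_excluded})")
    res = stats.mannwhitneyu(inside, outside, alternative="two-sided", method="auto")
    med_in, med_out = float(np.median(inside)), float(np.median(outside))
    return {
        "context": niche.signature,
        "statistic": float(res.statistic), "p": float(res.pvalue),
        "n_niche": int(inside.size), "n_other": int(outside.size),
        "n_excluded": n_excluded,
        "median_niche": med_in, "median_other": med_out,
        "direction": "niche_higher" if med_in > med_out
        else ("other_higher" if med_out > med_in else "equal"),
    }


def run_niche_pipeline(grid: ad.AnnData, target_name: str, signatures,
                       context_names=None, quantile: float = 0.975,
                       distance: int = 1, min_score: float = 0.0) -> pd.DataFrame:
    """Full niche co-localisation analysis of one target signature.

    For every context signature: score spots, call seeds at ``quantile``,
    dilate by ``distance``, then test whether the target signature's
    scores are elevated inside the context niche.  Unadjusted and
    BH-adjusted p values are both reported (one row per context).
    """
    if context_names is None:
        context_names = [n for n in signatures.names() if n != target_name]
    if not context_names:
        raise ValidationError("no context signatures to test against")
    target_scores = spot_signature_score(grid, signatures[target_name], name=target_name)
    rows = []
    labelings = {}
    for ctx in context_names:
        ctx_scores = spot_signature_score(grid, signatures[ctx], name=ctx)
        seeds, thr = high_enrichment_spots(ctx_scores, quantile=quantile)
        labeling = dilate_niche(seeds, grid, distance=distance, signature=ctx, threshold=thr)
        labelings[ctx] = labeling
        r = niche_association_test(target_scores, labeling, min_score=min_score)
        r.update({"target": target_name, "threshold": thr,
                  "n_seeds": labeling.n_seeds, "n_niche_total": labeling.n_niche})
        rows.append(r)
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out.attrs["labelings"] = labelings
    return out
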