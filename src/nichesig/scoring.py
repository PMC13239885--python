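"""Single-sample gene-set enrichment (ssGSEA) and score-level statistics.

The per-sample score of a gene set is the sum of the running difference
between a rank-weighted in-set empirical CDF and a uniform out-of-set
CDF, evaluated over the genes ranked by descending expression:

    ES = sum_k [ cum(w * 1_in)(k) / sum(w * 1_in)  -  cum(1_out)(k) / (N - m) ]

with rank weights ``w = rank^alpha`` (the most expressed gene has rank N)
and ``alpha = 0.25`` by default.  Because the statistic depends on ranks
only, it is invariant to any strictly increasing per-sample transform of
expression.  Optional normalisation rescales the whole score matrix by
its range, which preserves within-signature sample rankings.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import NichesigError, SignatureSet, ValidationError

__all__ = ["ssgsea_scores", "ssgsea_sample_score", "score_spearman",
           "compare_scores_by_response"]


def _rank_order(expr: np.ndarray) -> np.ndarray:
    """Gene order by descending expression, ties broken by ascending gene index.

    Deterministic: a stable sort on (-expression) gives the lowest gene
    index first among tied values.
    """
    return np.argsort(-expr, kind="stable")


def ssgsea_sample_score(expr: np.ndarray, in_set: np.ndarray, alpha: float = 0.25) -> float:
    """Un-normalised ssGSEA enrichment score of one sample.

    ``expr`` is the sample's expression over the full gene universe,
    ``in_set`` a boolean membership mask of the gene set.
    """
    n = expr.size
    m = int(in_set.sum())
    if m == 0:
        raise ValidationError("gene set matches no genes in the matrix")
    if m == n:
        raise ValidationError("gene set covers the whole gene universe; "
                              "the out-of-set CDF is undefined")
    order = _rank_order(expr)
    in_ordered = in_set[order]
    # rank weight: position k (0-based, most expressed first) has rank n-k
    weights = (n - np.arange(n)).astype(float) ** alpha
    w_in = np.where(in_ordered, weights, 0.0)
    cdf_in = np.cumsum(w_in) / w_in.sum()
    cdf_out = np.cumsum(~in_ordered) / (n - m)
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_scores(expression: pd.DataFrame, signatures: SignatureSet,
                  alpha: float = 0.25, normalize: bool = True) -> pd.DataFrame:
    """ssGSEA score of every signature for every sample.

    ``expression`` is samples x genes.  Signature genes absent from the
    matrix are dropped with a warning; a signature with no matched genes
    is an error.  With ``normalize`` the score matrix is divided by its
    range (max - min over all samples and signatures).
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    genes = expression.columns
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    masks: dict[str, np.ndarray] = {}
    for name, sig_genes in signatures.items():
        matched = [g for g in sig_genes if g in gene_pos]
        missing = [g for g in sig_genes if g not in gene_pos]
        if missing:
            warnings.warn(f"signature {name!r}: {len(missing)} genes absent from the "
                          f"matrix were dropped: {missing[:10]}")
        if not matched:
            raise ValidationError(f"signature {name!r} matches no genes in the matrix")
        if len(matched) == n:
            raise ValidationError(f"signature {name!r} covers all genes; "
                                  "the out-of-set CDF is undefined")
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in matched]] = True
        masks[name] = mask

    x = expression.to_numpy(dtype=float)
    n_samples = x.shape[0]
    # precompute per-sample descending order and rank weights once
    orders = np.argsort(-x, axis=1, kind="stable")
    weights = (n - np.arange(n)).astype(float) ** alpha

    scores = np.empty((n_samples, len(masks)))
    for j, (name, mask) in enumerate(masks.items()):
        in_ordered = mask[orders]                       # samples x genes
        w_in = np.where(in_ordered, weights[None, :], 0.0)
        cdf_in = np.cumsum(w_in, axis=1) / w_in.sum(axis=1, keepdims=True)
        cdf_out = np.cumsum(~in_ordered, axis=1) / (n - mask.sum())
        scores[:, j] = np.sum(cdf_in - cdf_out, axis=1)

    out = pd.DataFrame(scores, index=expression.index, columns=list(masks))
    out.columns.name = "signature"
    if normalize:
        rng = out.to_numpy().max() - out.to_numpy().min()
        if rng == 0:
            warnings.warn("score matrix has zero range; normalisation skipped")
        else:
            out = out / rng
    out.attrs["alpha"] = alpha
    out.attrs["normalized"] = bool(normalize)
    return out


def score_spearman(scores, covariate) -> tuple[float, float]:
    """Spearman correlation between per-unit scores and a covariate.

    Returns (rho, two-sided p by the t approximation).  Constant input on
    either side leaves rho undefined and raises.
    """
    s = np.asarray(scores, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if s.size != c.size:
        raise ValidationError("scores and covariate must be paired")
    if s.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.ptp(s) == 0 or np.ptp(c) == 0:
        raise ValidationError("Spearman rho undefined for constant input")
    rho, p = stats.spearmanr(s, c)
    return float(rho), float(p)


def compare_scores_by_response(scores: pd.Series, response: pd.Series) -> dict:
    """Two-sided Mann–Whitney comparison of responder vs non-responder scores.

    Samples with missing response are excluded before testing.  Returns
    the statistic, p, group medians/sizes and the direction of the
    difference (which group has the higher median).
    """
    s = pd.Series(scores)
    resp = pd.Series(response)
    if not s.index.equals(resp.index):
        resp = resp.reindex(s.index)
    valid = resp.isin(["responder", "non_responder"])
    s, resp = s[valid], resp[valid]
    a = s[resp == "responder"].to_numpy(dtype=float)
    b = s[resp == "non_responder"].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError(
            f"both response groups must be non-empty after exclusions "
            f"(responders: {a.size}, non-responders: {b.size})")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n_responder": int(a.size),
        "n_non_responder": int(b.size),
        "median_responder": med_a,
        "median_non_responder": med_b,
        "direction": "responder_higher" if med_a > med_b
        else ("non_responder_higher" if med_b > med_a else "equal"),
        "n_excluded": int((~valid).sum()),
    }
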