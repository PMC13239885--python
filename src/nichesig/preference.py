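"""Tissue and survival-group distribution preferences of cell subsets.

The primary statistic is Ro/e — the ratio of observed to expected cell
counts from the chi-square decomposition of a subsets x strata
contingency table.  A ratio above 1 marks over-representation of a
subset in a stratum (e.g. a T-cell state preferring tumour tissue over
blood).  A complementary per-patient strategy compares subset fractions
across patients by rank-sum, guarding against patient-composition
confounding.  Survival-group enrichment within one tissue is summarised
as a 2x2 odds ratio (short vs long survivors, subset vs other cells).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ValidationError
from .signatures import bh_adjust

__all__ = [
    "composition_table",
    "roe_enrichment",
    "survival_group_enrichment",
    "per_patient_fraction_test",
]


def composition_table(meta: pd.DataFrame, row: str = "subcluster",
                      col: str = "tissue") -> pd.DataFrame:
    """Cell-count contingency table of subsets x strata from per-cell metadata."""
    if row not in meta.columns or col not in meta.columns:
        raise ValidationError(f"metadata lacks {row!r} or {col!r}")
    return pd.crosstab(meta[row], meta[col])


def roe_enrichment(table: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Observed/expected (Ro/e) ratios plus the table-wide chi-square test.

    expected(i, j) = row_i total * col_j total / grand total.  Returns
    (ratio table, chi-square statistic, p).  By construction the
    column-total-weighted mean of every row's ratios is exactly 1.
    """
    counts = table.to_numpy(dtype=float)
    if np.any(counts < 0) or counts.sum() == 0:
        raise ValidationError("contingency table must be non-negative with a positive total")
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    if np.any(row_tot == 0):
        empty = list(table.index[row_tot == 0])
        raise ValidationError(f"empty rows in contingency table: {empty}")
    if np.any(col_tot == 0):
        empty = list(table.columns[col_tot == 0])
        raise ValidationError(f"empty columns in contingency table: {empty}")
    chi2, p, _, expected = stats.chi2_contingency(counts, correction=False)
    ratio = pd.DataFrame(counts / expected, index=table.index, columns=table.columns)
    return ratio, float(chi2), float(p)


def roe_long_format(table: pd.DataFrame) -> pd.DataFrame:
    """Ro/e as a tidy table (subset, stratum, observed, expected, ratio)."""
    ratio, chi2, p = roe_enrichment(table)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.to_numpy().sum()
    rows = []
    for i, subset in enumerate(table.index):
        for j, stratum in enumerate(table.columns):
            rows.append({"subset": subset, "stratum": stratum,
                         "observed": int(table.iat[i, j]),
                         "expected": expected[i, j],
                         "ratio": ratio.iat[i, j]})
    out = pd.DataFrame(rows)
    out.attrs["chi2"] = chi2
    out.attrs["p"] = p
    return out


def survival_group_enrichment(meta: pd.DataFrame, subset: str, tissue: str,
                              subset_col: str = "subcluster") -> dict:
    """Odds of subset membership in short- vs long-term survivors within a tissue.

    Builds the 2x2 table (subset vs other cells) x (short vs long) among
    the tissue's cells.  Zero cells trigger the Haldane–Anscombe 0.5
    correction (flagged in the output); p is Fisher exact for tables
    totalling <= 10^4 cells and chi-square beyond that.
    """
    sub = meta[meta["tissue"] == tissue]
    groups = set(sub["survival_group"].unique())
    if not {"short", "long"} <= groups:
        raise ValidationError(
            f"both survival groups required in tissue {tissue!r}; found {sorted(groups)}")
    is_subset = sub[subset_col] == subset
    is_short = sub["survival_group"] == "short"
    a = int((is_subset & is_short).sum())      # subset, short
    b = int((~is_subset & is_short).sum())     # other, short
    c = int((is_subset & ~is_short).sum())     # subset, long
    d = int((~is_subset & ~is_short).sum())    # other, long

    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    odds = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    zq = stats.norm.ppf(0.975)
    ci = (float(np.exp(np.log(odds) - zq * se)), float(np.exp(np.log(odds) + zq * se)))

    total = a + b + c + d
    if total <= 10_000:
        _, p = stats.fisher_exact([[a, b], [c, d]])
        test = "fisher"
    else:
        _, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
        test = "chi2"
    return {"subset": subset, "tissue": tissue, "or": float(odds),
            "ci_low": ci[0], "ci_high": ci[1], "p": float(p),
            "table": ((a, b), (c, d)), "corrected": corrected, "test": test}


def survival_group_enrichment_all(meta: pd.DataFrame, subset_col: str = "subcluster"
                                  ) -> pd.DataFrame:
    """Survival-group odds for every (subset, tissue) pair, BH-adjusted."""
    rows = []
    for tissue in meta["tissue"].unique():
        for subset in meta[subset_col].unique():
            try:
                r = survival_group_enrichment(meta, subset, tissue, subset_col)
            except ValidationError:
                continue
            rows.append({k: r[k] for k in
                         ("subset", "tissue", "or", "ci_low", "ci_high", "p", "corrected")})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def per_patient_fraction_test(meta: pd.DataFrame, subset: str, tissue: str,
                              subset_col: str = "subcluster") -> dict:
    """Complementary strategy: per-patient subset fractions, short vs long.

    Computes the fraction of the subset among each patient's cells in the
    tissue and compares the two survival groups by two-sided rank-sum —
    robust to a few patients dominating the pooled counts.
    """
    sub = meta[meta["tissue"] == tissue]
    frac = (sub.groupby("patient", observed=True)
            .apply(lambda df: (df[subset_col] == subset).mean(), include_groups=False))
    group = sub.groupby("patient", observed=True)["survival_group"].first()
    a = frac[group == "short"].to_numpy(dtype=float)
    b = frac[group == "long"].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both survival groups need >= 1 patient in the tissue")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {"subset": subset, "tissue": tissue,
            "statistic": float(res.statistic), "p": float(res.pvalue),
            "median_frac_short": float(np.median(a)),
            "median_frac_long": float(np.median(b)),
            "n_patients_short": int(a.size), "n_patients_long": int(b.size)}
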