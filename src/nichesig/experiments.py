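"""Seeded simulation studies that characterise the pipeline's behaviour.

Each function sets up a planted-truth or null scenario with the
synthetic generators, runs the corresponding pipeline stage, and returns
summary metrics: oracle agreement for the deterministic primitives,
parameter recovery and confidence-interval coverage for the Cox layer,
type-I calibration for the rank tests, and detection power for the
planted-signal scenarios.  ``scripts/acceptance.py`` and the test suite
both drive these functions; the analysis scripts reuse several of them.

The reference evaluators in this module (:func:`ssgsea_reference`,
:func:`dilate_reference`, the brute-force cutpoint search) are written
as plain direct computations and share no code with the implementations
they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datasets import SignatureSet
from .scoring import compare_scores_by_response, ssgsea_scores
from .signatures import derive_subcluster_signature, filter_cells, normalize_counts
from .spatial import (
    dilate_niche,
    high_enrichment_spots,
    run_niche_pipeline,
    spot_signature_score,
)
from .survival import cox_fit, logrank_test, optimal_cutpoint
from .synthetic import (
    SimBulkConfig,
    SimSingleCellConfig,
    SimSpatialConfig,
    SubclusterSpec,
    bulk_signature_score,
    generate_bulk_cohort,
    generate_single_cell,
    generate_spatial_grid,
    marker_gene_names,
)

MAX_SEED = 2**31 - 1


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, MAX_SEED))


# ---------------------------------------------------------------------------
# independent reference evaluators
# ---------------------------------------------------------------------------


def ssgsea_reference(expr_row, gene_names, set_genes, alpha: float = 0.25) -> float:
    """Direct loop evaluation of the single-sample running-sum score."""
    n = len(gene_names)
    order = sorted(range(n), key=lambda i: (-expr_row[i], i))
    in_set = [gene_names[i] in set_genes for i in order]
    m = sum(in_set)
    denom_in = 0.0
    for pos in range(n):
        if in_set[pos]:
            denom_in += float(n - pos) ** alpha
    es, cum_in, cum_out = 0.0, 0.0, 0.0
    for pos in range(n):
        if in_set[pos]:
            cum_in += float(n - pos) ** alpha / denom_in
        else:
            cum_out += 1.0 / (n - m)
        es += cum_in - cum_out
    return es


def dilate_reference(seed_coords, all_coords, distance: int = 1) -> set:
    """Brute-force all-pairs Chebyshev filter: spots within ``distance`` of any seed."""
    out = set()
    for (x, y) in all_coords:
        for (sx, sy) in seed_coords:
            if max(abs(x - sx), abs(y - sy)) <= distance:
                out.add((x, y))
                break
    return out


# ---------------------------------------------------------------------------
# oracle-agreement studies
# ---------------------------------------------------------------------------


def ssgsea_oracle_study(n_instances: int = 200, seed: int = 0) -> dict:
    """Max |implementation - reference| over random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_genes = int(rng.integers(5, 51))
        n_samples = int(rng.integers(2, 11))
        genes = [f"g{i}" for i in range(n_genes)]
        expr = pd.DataFrame(rng.random((n_samples, n_genes)) * 100, columns=genes)
        set_size = int(rng.integers(1, n_genes))
        set_genes = list(rng.choice(genes, size=set_size, replace=False))
        alpha = float(rng.choice([0.0, 0.25, 0.5, 1.0]))
        sigs = SignatureSet({"s": set_genes})
        scores = ssgsea_scores(expr, sigs, alpha=alpha, normalize=False)["s"]
        for i in range(n_samples):
            ref = ssgsea_reference(expr.iloc[i].to_numpy(), genes, set(set_genes), alpha)
            worst = max(worst, abs(scores.iloc[i] - ref))
    return {"max_abs_diff": worst, "n": n_instances}


def dilation_oracle_study(n_instances: int = 100, seed: int = 0) -> dict:
    """Agreement of the window dilation with the brute-force Chebyshev filter
    on random incomplete lattices."""
    import anndata as ad
    import scipy.sparse as sp

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        w, h = int(rng.integers(5, 15)), int(rng.integers(5, 15))
        coords = [(x, y) for x in range(w) for y in range(h)]
        keep = rng.random(len(coords)) < rng.uniform(0.4, 1.0)  # punch holes
        coords = [c for c, k in zip(coords, keep) if k]
        if len(coords) < 3:
            continue
        obs = pd.DataFrame({"x": [c[0] for c in coords], "y": [c[1] for c in coords]},
                           index=[f"s{x}_{y}" for x, y in coords])
        grid = ad.AnnData(X=sp.csr_matrix((len(coords), 1)), obs=obs,
                          var=pd.DataFrame(index=["g"]))
        n_seeds = int(rng.integers(1, max(2, len(coords) // 4)))
        seed_ids = list(rng.choice(obs.index, size=n_seeds, replace=False))
        dist = int(rng.integers(1, 3))
        lab = dilate_niche(seed_ids, grid, distance=dist)
        got = {(int(obs.at[s, "x"]), int(obs.at[s, "y"])) for s in lab.niche_spots}
        ref = dilate_reference([(int(obs.at[s, "x"]), int(obs.at[s, "y"]))
                                for s in seed_ids], coords, dist)
        agree += got == ref
    return {"agreement_frac": agree / n_instances, "n": n_instances}


def cutpoint_oracle_study(n_instances: int = 50, n: int = 40, seed: int = 0) -> dict:
    """Returned cutpoint vs exhaustive-search argmax with an external log-rank."""
    from lifelines.statistics import logrank_test as ll_logrank

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        scores = rng.normal(size=n)
        time = rng.exponential(10, size=n) + 0.01
        event = (rng.random(n) < 0.7).astype(int)
        res = optimal_cutpoint(scores, time, event, minprop=0.1)

        distinct = np.unique(scores)
        mids = (distinct[:-1] + distinct[1:]) / 2
        best_c, best_stat = None, -1.0
        for c in mids:
            high = scores > c
            n_low = int((~high).sum())
            if n_low < 0.1 * n or (n - n_low) < 0.1 * n:
                continue
            r = ll_logrank(time[high], time[~high], event[high], event[~high])
            if r.test_statistic > best_stat + 1e-12:
                best_c, best_stat = c, r.test_statistic
        agree += best_c is not None and math.isclose(res.cutpoint, best_c)
    return {"agreement_frac": agree / n_instances, "n": n_instances}


# ---------------------------------------------------------------------------
# Cox recovery and rank-test calibration
# ---------------------------------------------------------------------------


def cox_recovery_study(n_replicates: int = 100, n: int = 500,
                       true_hr: float = 2.0, seed: int = 0) -> dict:
    """Fit the planted score on cohorts with a known hazard ratio per SD."""
    rng = np.random.default_rng(seed)
    hrs, covered = [], 0
    for _ in range(n_replicates):
        cfg = SimBulkConfig(n_samples=n, n_genes=60,
                            signature=tuple(f"SIG{i:03d}" for i in range(20)),
                            log_hr_per_sd=math.log(true_hr), seed=_subseed(rng))
        cohort = generate_bulk_cohort(cfg)
        score = bulk_signature_score(cohort, cfg.signature)
        fit = cox_fit(score.to_frame("score"),
                      cohort.clinical["time"], cohort.clinical["event"])
        hrs.append(fit.hr[0])
        covered += fit.ci_low[0] <= true_hr <= fit.ci_high[0]
    return {"mean_hr": float(np.mean(hrs)), "ci_coverage": covered / n_replicates,
            "n_replicates": n_replicates, "n": n}


def logrank_null_study(n_replicates: int = 2000, n: int = 200,
                       alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rate of the log-rank test between score-median halves
    when the signature carries no hazard effect."""
    rng = np.random.default_rng(seed)
    rejections = 0
    sig = tuple(f"SIG{i:03d}" for i in range(10))
    for _ in range(n_replicates):
        cfg = SimBulkConfig(n_samples=n, n_genes=30, signature=sig,
                            log_hr_per_sd=0.0, seed=_subseed(rng))
        cohort = generate_bulk_cohort(cfg)
        score = bulk_signature_score(cohort, sig)
        high = (score > score.median()).astype(int).to_numpy()
        _, p = logrank_test(cohort.clinical["time"], cohort.clinical["event"], high)
        rejections += p < alpha
    return {"rejection_rate": rejections / n_replicates, "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# planted-signal studies
# ---------------------------------------------------------------------------


def _recovery_config(seed: int) -> SimSingleCellConfig:
    split = {("tumour", "short"): 70, ("tumour", "long"): 70,
             ("blood", "short"): 30, ("blood", "long"): 30}
    return SimSingleCellConfig(
        n_genes=2000,
        subclusters=(
            SubclusterSpec("DPT", "T", dict(split), n_markers=30, marker_fold=3.0),
            SubclusterSpec("Tconv", "T", dict(split), n_markers=30, marker_fold=3.0),
            SubclusterSpec("Bcell", "B", dict(split), n_markers=20, marker_fold=3.0),
        ),
        seed=seed,
    )


def signature_recovery_study(n_seeds: int = 20, seed: int = 0) -> dict:
    """Dual-criterion recovery of 30 planted markers (fold 3, 200 cells)."""
    rng = np.random.default_rng(seed)
    recoveries, false_rates = [], []
    for _ in range(n_seeds):
        cfg = _recovery_config(_subseed(rng))
        adata = generate_single_cell(cfg)
        planted = set(marker_gene_names(cfg)["DPT"])
        adata = filter_cells(adata)
        adata = normalize_counts(adata)
        genes, _ = derive_subcluster_signature(adata, "DPT")
        got = set(genes)
        recoveries.append(len(got & planted) / len(planted))
        false_rates.append(len(got - planted) / max(len(got), 1))
    return {"mean_recovery": float(np.mean(recoveries)),
            "mean_false_rate": float(np.mean(false_rates)),
            "min_recovery": float(np.min(recoveries)),
            "max_false_rate": float(np.max(false_rates)),
            "n_seeds": n_seeds}


def null_signature_study(n_seeds: int = 50, seed: int = 0) -> dict:
    """Mean signature size when subcluster labels are permuted (no real markers)."""
    rng = np.random.default_rng(seed)
    sizes = []
    for _ in range(n_seeds):
        cfg = SimSingleCellConfig(
            n_genes=500,
            subclusters=(
                SubclusterSpec("A", "T", {("tumour", "short"): 60}),
                SubclusterSpec("B", "T", {("tumour", "short"): 60}),
            ),
            seed=_subseed(rng),
        )
        adata = generate_single_cell(cfg)
        adata = normalize_counts(adata)
        genes, _ = derive_subcluster_signature(adata, "A")
        sizes.append(len(genes))
    return {"mean_size": float(np.mean(sizes)), "n_seeds": n_seeds}


def _spatial_signatures() -> SignatureSet:
    return SignatureSet({
        "DPT": [f"DPT{i:02d}" for i in range(15)],
        "capillaryEC": [f"CEC{i:02d}" for i in range(15)],
    })


def niche_power_study(n_seeds: int = 100, seed: int = 0, alpha: float = 0.05) -> dict:
    """Detection rate of fully co-localised (shared-centre) niche grids."""
    rng = np.random.default_rng(seed)
    sigs = _spatial_signatures()
    sig_map = {name: tuple(sigs[name]) for name in sigs.names()}
    hits = 0
    for _ in range(n_seeds):
        cfg = SimSpatialConfig(signatures=sig_map, colocalization=1.0,
                               seed=_subseed(rng))
        grid = generate_spatial_grid(cfg)
        report = run_niche_pipeline(grid, "DPT", sigs, ["capillaryEC"])
        row = report.iloc[0]
        hits += (row["p"] < alpha) and (row["direction"] == "niche_higher")
    return {"power": hits / n_seeds, "n_seeds": n_seeds}


def niche_null_study(n_seeds: int = 200, seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I rate when the target signature has no planted niches.

    The context signature keeps its discs (so a niche exists) while the
    target signature is flat background everywhere — the no-planted-effect
    null under which niche membership is independent of the target score.
    """
    rng = np.random.default_rng(seed)
    sigs = _spatial_signatures()
    sig_map = {name: tuple(sigs[name]) for name in sigs.names()}
    rejections = 0
    for _ in range(n_seeds):
        w = h = 40
        centers = {
            "capillaryEC": tuple((float(rng.uniform(0, w)), float(rng.uniform(0, h)), 4.0)
                                 for _ in range(3)),
            "DPT": (),
        }
        cfg = SimSpatialConfig(width=w, height=h, signatures=sig_map,
                               niche_centers=centers, seed=_subseed(rng))
        grid = generate_spatial_grid(cfg)
        report = run_niche_pipeline(grid, "DPT", sigs, ["capillaryEC"])
        rejections += report.iloc[0]["p"] < alpha
    return {"type1_rate": rejections / n_seeds, "n_seeds": n_seeds}


def response_power_study(n_seeds: int = 100, n: int = 100, seed: int = 0,
                         alpha: float = 0.05) -> dict:
    """Power of the responder-vs-non-responder score comparison at a 1 SD shift."""
    rng = np.random.default_rng(seed)
    sig = tuple(f"SIG{i:03d}" for i in range(20))
    sigs = SignatureSet({"planted": list(sig)})
    hits = 0
    for _ in range(n_seeds):
        cfg = SimBulkConfig(n_samples=n, n_genes=60, signature=sig,
                            response_rate=0.5, response_effect=1.0,
                            seed=_subseed(rng))
        cohort = generate_bulk_cohort(cfg)
        scores = ssgsea_scores(cohort.expression, sigs)["planted"]
        res = compare_scores_by_response(scores, cohort.clinical["response"])
        hits += (res["p"] < alpha) and (res["direction"] == "responder_higher")
    return {"power": hits / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# deterministic contract examples (recomputed, not asserted, here)
# ---------------------------------------------------------------------------


def deterministic_examples() -> dict:
    """The enumerable rank/quantile/contingency examples, recomputed."""
    from .preference import roe_enrichment
    from .datasets import ValidationError

    out: dict[str, float] = {}

    # exact two-sided Mann–Whitney on fully separated 3-vs-3 data
    res = compare_scores_by_response(
        pd.Series([2, 3, 4, 0.5, 1, 1.5], index=list("abcdef")),
        pd.Series(["responder"] * 3 + ["non_responder"] * 3, index=list("abcdef")))
    out["mannwhitney_exact_p"] = res["p"]

    # hand-computable two-subject log-rank
    chi2, _ = logrank_test([1.0, 2.0], [1, 1], [0, 1])
    out["logrank_two_subject_chi2"] = chi2

    # seed calling on the 1..1000 ladder and on a flat score vector
    seeds, thr = high_enrichment_spots(
        pd.Series(np.arange(1, 1001, dtype=float),
                  index=[f"s{i}" for i in range(1000)]))
    out["ladder_threshold"] = thr
    out["ladder_n_seeds"] = float(len(seeds))
    flat_seeds, _ = high_enrichment_spots(pd.Series([5.0] * 100))
    out["flat_n_seeds"] = float(len(flat_seeds))

    # Ro/e on the balanced preference table
    ratio, _, _ = roe_enrichment(pd.DataFrame([[30, 10], [10, 30]]))
    out["roe_corner_ratio"] = float(ratio.iat[0, 0])
    return out
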