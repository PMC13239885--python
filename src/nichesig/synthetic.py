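"""Synthetic single-cell, bulk-survival and spatial datasets.

The generators plant the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any cohort download:

* :func:`generate_single_cell` — negative-binomial counts with planted
  subcluster marker genes and configurable tissue / survival-group
  composition;
* :func:`generate_bulk_cohort` — FPKM-like bulk expression whose
  signature score drives an exponential-baseline proportional hazard with
  independent exponential censoring, plus an optional treatment-response
  label shifted in responders;
* :func:`generate_spatial_grid` — an integer bin lattice with disc-shaped
  "niches" of elevated signature expression and a tunable degree of
  centre sharing (co-localisation) between two signatures.

All generators are deterministic given their config seed: the same config
produces bit-identical outputs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datasets import (
    BulkCohort,
    ConfigurationError,
    SURVIVAL_GROUPS,
    TISSUES,
    validate_cell_dataset,
    validate_spatial_grid,
)

__all__ = [
    "SimSingleCellConfig",
    "SimBulkConfig",
    "SimSpatialConfig",
    "SubclusterSpec",
    "generate_single_cell",
    "generate_bulk_cohort",
    "generate_spatial_grid",
    "write_run_manifest",
]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """NB(mean, size) draws in the mean/size parameterisation.

    variance = mu + mu^2 / size; p = size / (size + mu).
    """
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubclusterSpec:
    """One planted subcluster.

    ``cells`` maps (tissue, survival_group) to a cell count; ``n_markers``
    genes receive a ``marker_fold`` (>1) elevation of their NB mean inside
    this subcluster only.
    """

    name: str
    major_type: str
    cells: dict  # (tissue, survival_group) -> count
    n_markers: int = 0
    marker_fold: float = 1.0

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells.values()))


@dataclass(frozen=True)
class SimSingleCellConfig:
    n_genes: int = 2000
    subclusters: tuple[SubclusterSpec, ...] = ()
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    mito_fraction_genes: float = 0.01
    patients_per_group: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigurationError("baseline_mean and dispersion must be positive")
        if not (0 <= self.mito_fraction_genes < 1):
            raise ConfigurationError("mito_fraction_genes must lie in [0, 1)")
        if not self.subclusters:
            raise ConfigurationError("at least one subcluster required")
        names = [s.name for s in self.subclusters]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate subcluster names")
        total_markers = sum(s.n_markers for s in self.subclusters)
        if total_markers > self.n_genes:
            raise ConfigurationError(
                f"{total_markers} marker genes requested but only {self.n_genes} genes exist; "
                "marker blocks of distinct subclusters must be disjoint")
        for s in self.subclusters:
            if s.n_cells < 2:
                raise ConfigurationError(f"subcluster {s.name!r} has < 2 cells")
            if s.n_markers and s.marker_fold <= 0:
                raise ConfigurationError(f"subcluster {s.name!r}: marker_fold must be > 0")
            for key in s.cells:
                tissue, group = key
                if tissue not in TISSUES or group not in SURVIVAL_GROUPS:
                    raise ConfigurationError(f"unknown (tissue, survival_group) {key!r}")


def marker_gene_names(config: SimSingleCellConfig) -> dict[str, list[str]]:
    """The disjoint marker blocks planted for each subcluster (by construction)."""
    config.validate()
    out: dict[str, list[str]] = {}
    start = 0
    for s in config.subclusters:
        out[s.name] = [f"MK{start + i:04d}" for i in range(s.n_markers)]
        start += s.n_markers
    return out


def _gene_names(config: SimSingleCellConfig) -> tuple[list[str], np.ndarray]:
    n_markers = sum(s.n_markers for s in config.subclusters)
    n_mito = int(round(config.mito_fraction_genes * config.n_genes))
    n_mito = min(n_mito, config.n_genes - n_markers)
    names = [f"MK{i:04d}" for i in range(n_markers)]
    names += [f"MT-G{i:04d}" for i in range(n_mito)]
    names += [f"G{i:05d}" for i in range(config.n_genes - n_markers - n_mito)]
    mito = np.zeros(config.n_genes, dtype=bool)
    mito[n_markers:n_markers + n_mito] = True
    return names, mito


def generate_single_cell(config: SimSingleCellConfig) -> ad.AnnData:
    """Simulate an annotated single-cell count matrix.

    Counts are NB(mean, dispersion) with a per-gene baseline mean drawn
    once from a gamma distribution around ``baseline_mean`` (so genes
    differ in abundance), multiplied by ``marker_fold`` for a subcluster's
    marker genes inside that subcluster.  Cells are assigned round-robin
    to ``patients_per_group`` pseudo-patients within each survival group.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_names, mito = _gene_names(config)

    # per-gene baseline abundance; gamma keeps it positive and skewed
    gene_mean = config.baseline_mean * rng.gamma(shape=2.0, scale=0.5, size=config.n_genes)
    gene_mean = np.maximum(gene_mean, 1e-3)

    marker_blocks = marker_gene_names(config)
    name_to_idx = {g: i for i, g in enumerate(gene_names)}

    rows = []
    obs_records = []
    patient_counter = {g: itertools.cycle(range(config.patients_per_group))
                       for g in SURVIVAL_GROUPS}
    cell_i = 0
    for s in config.subclusters:
        mean_vec = gene_mean.copy()
        idx = [name_to_idx[g] for g in marker_blocks[s.name]]
        mean_vec[idx] = mean_vec[idx] * s.marker_fold
        for (tissue, group), n in sorted(s.cells.items()):
            for _ in range(int(n)):
                rows.append(_nb_draw(rng, mean_vec, config.dispersion))
                pid = next(patient_counter[group])
                obs_records.append({
                    "patient": f"P_{group}_{pid}",
                    "tissue": tissue,
                    "major_type": s.major_type,
                    "subcluster": s.name,
                    "survival_group": group,
                })
                cell_i += 1

    counts = sp.csr_matrix(np.vstack(rows).astype(np.int64))
    obs = pd.DataFrame(obs_records, index=[f"cell{i:06d}" for i in range(cell_i)])
    var = pd.DataFrame({"mito": mito}, index=gene_names)
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["sim"] = {"kind": "single_cell", "seed": config.seed,
                        "marker_genes": marker_blocks}
    validate_cell_dataset(adata)
    return adata


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimBulkConfig:
    n_samples: int = 200
    n_genes: int = 500
    signature: tuple[str, ...] = tuple(f"SIG{i:03d}" for i in range(20))
    log_hr_per_sd: float = 0.0
    baseline_hazard: float = 1.0 / 40.0   # events per month
    censor_rate: float = 1.0 / 80.0       # independent exponential censoring
    signature_loading: float = 0.5        # log-scale loading of the latent factor
    noise_sd: float = 0.5                 # per-gene log-scale noise
    response_rate: float = 0.0            # fraction of samples with a response label drawn responder
    response_effect: float = 0.0          # latent-factor shift (SD units) in responders
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 1 or self.n_genes <= 0:
            raise ConfigurationError("n_samples must be > 1 and n_genes positive")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ConfigurationError("censor_rate must be >= 0")
        if not (0 <= self.response_rate <= 1):
            raise ConfigurationError("response_rate must lie in [0, 1]")
        if len(set(self.signature)) != len(self.signature) or not self.signature:
            raise ConfigurationError("signature must be a non-empty, duplicate-free gene list")
        if len(self.signature) > self.n_genes:
            raise ConfigurationError("signature larger than the gene universe")


def bulk_signature_score(cohort: BulkCohort, signature: Sequence[str]) -> pd.Series:
    """Standardised mean expression of the signature genes (the planted score)."""
    sub = cohort.expression[list(signature)]
    score = sub.mean(axis=1)
    return (score - score.mean()) / score.std(ddof=0)


def generate_bulk_cohort(config: SimBulkConfig) -> BulkCohort:
    """Simulate a bulk cohort whose signature score drives the hazard.

    A per-sample latent factor (shifted by ``response_effect`` in
    responders) loads multiplicatively on the signature genes, so the
    standardised mean signature expression tracks it.  Event times are
    exponential with rate ``baseline_hazard * exp(log_hr_per_sd * score)``
    where the score is the realised standardised mean signature
    expression; censoring is an independent exponential clock.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    genes = list(config.signature)
    genes += [f"B{i:04d}" for i in range(g - len(genes))]
    sig_idx = np.arange(len(config.signature))

    response = np.full(n, np.nan, dtype=object)
    responder = np.zeros(n, dtype=bool)
    if config.response_rate > 0:
        responder = rng.random(n) < config.response_rate
        response = np.where(responder, "responder", "non_responder")

    factor = rng.normal(size=n) + config.response_effect * responder

    base = rng.lognormal(mean=1.0, sigma=1.0, size=g)        # FPKM-like gene abundances
    log_expr = np.log(base)[None, :] + config.noise_sd * rng.normal(size=(n, g))
    log_expr[:, sig_idx] += config.signature_loading * factor[:, None]
    expr = np.exp(log_expr)

    expression = pd.DataFrame(expr, columns=genes,
                              index=[f"S{i:04d}" for i in range(n)])

    score = (expression[list(config.signature)].mean(axis=1)
             .pipe(lambda s: (s - s.mean()) / s.std(ddof=0)).to_numpy())

    rate = config.baseline_hazard * np.exp(config.log_hr_per_sd * score)
    t_event = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    clinical = pd.DataFrame({
        "time": time,
        "event": event,
        "sex": rng.integers(0, 2, size=n),
        "age": rng.normal(55.0, 10.0, size=n).round(1),
        "treatment": rng.integers(0, 2, size=n),
        "hbv": rng.integers(0, 2, size=n),
        "response": response,
    }, index=expression.index)

    return BulkCohort(expression, clinical)


# ---------------------------------------------------------------------------
# spatial grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimSpatialConfig:
    width: int = 40
    height: int = 40
    signatures: dict = None          # name -> tuple of genes
    n_niches: int = 3
    niche_radius: float = 4.0
    niche_centers: dict = None       # optional name -> ((x, y, r), ...); None => sampled
    colocalization: float = 0.0      # fraction of shared disc centres between consecutive signatures
    background_mean: float = 1.0
    niche_mean: float = 3.0
    dispersion: float = 10.0
    n_extra_genes: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.width * self.height == 0:
            raise ConfigurationError("lattice must be non-empty (width*height > 0)")
        if self.signatures is None or len(self.signatures) < 1:
            raise ConfigurationError("at least one signature required")
        if self.niche_mean < self.background_mean:
            raise ConfigurationError("niche_mean must be >= background_mean")
        if not (0 <= self.colocalization <= 1):
            raise ConfigurationError("colocalization must lie in [0, 1]")
        if self.niche_centers is not None:
            for name, discs in self.niche_centers.items():
                for (x, y, r) in discs:
                    if not (0 <= x < self.width and 0 <= y < self.height):
                        raise ConfigurationError(
                            f"niche centre ({x}, {y}) of {name!r} outside the lattice")


def _sample_centers(rng, config: SimSpatialConfig) -> dict[str, list[tuple[float, float, float]]]:
    """Disc centres per signature.

    ``colocalization`` is the fraction of each later signature's discs
    that reuse the first signature's centres; the rest are placed
    uniformly at random, independent of the other signatures.
    A signature listed with an explicit empty tuple has no niches.
    """
    names = list(config.signatures)
    if config.niche_centers is not None:
        return {n: list(config.niche_centers.get(n, ())) for n in names}
    centers: dict[str, list[tuple[float, float, float]]] = {}
    first = [(rng.uniform(0, config.width), rng.uniform(0, config.height), config.niche_radius)
             for _ in range(config.n_niches)]
    centers[names[0]] = first
    n_shared = int(round(config.colocalization * config.n_niches))
    for name in names[1:]:
        own = [(rng.uniform(0, config.width), rng.uniform(0, config.height), config.niche_radius)
               for _ in range(config.n_niches - n_shared)]
        centers[name] = first[:n_shared] + own
    return centers


def generate_spatial_grid(config: SimSpatialConfig) -> ad.AnnData:
    """Simulate a full bin lattice with disc-shaped elevated niches.

    Every (x, y) in {0..width-1} x {0..height-1} is one spot.  Genes of a
    signature have NB mean ``niche_mean`` at spots inside any of that
    signature's discs and ``background_mean`` elsewhere; filler genes sit
    at background everywhere.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    xs, ys = np.meshgrid(np.arange(config.width), np.arange(config.height), indexing="ij")
    xs, ys = xs.ravel(), ys.ravel()
    n_spots = xs.size

    centers = _sample_centers(rng, config)

    genes: list[str] = []
    means = []
    for name, sig_genes in config.signatures.items():
        inside = np.zeros(n_spots, dtype=bool)
        for (cx, cy, r) in centers[name]:
            inside |= (xs - cx) ** 2 + (ys - cy) ** 2 <= r ** 2
        mean_vec = np.where(inside, config.niche_mean, config.background_mean)
        for gname in sig_genes:
            genes.append(gname)
            means.append(mean_vec)
    for i in range(config.n_extra_genes):
        genes.append(f"BG{i:04d}")
        means.append(np.full(n_spots, config.background_mean))
    if len(set(genes)) != len(genes):
        raise ConfigurationError("signature gene lists overlap")

    mean_mat = np.vstack(means)  # genes x spots
    counts = _nb_draw(rng, mean_mat, config.dispersion).astype(np.int64)

    obs = pd.DataFrame({"x": xs.astype(int), "y": ys.astype(int)},
                       index=[f"spot_{x}_{y}" for x, y in zip(xs, ys)])
    adata = ad.AnnData(X=sp.csr_matrix(counts.T), obs=obs, var=pd.DataFrame(index=genes))
    adata.uns["sim"] = {"kind": "spatial", "seed": config.seed,
                        "centers": {k: [list(map(float, c)) for c in v]
                                    for k, v in centers.items()}}
    validate_spatial_grid(adata)
    return adata


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def write_run_manifest(path: str | Path, configs: dict, extra: dict | None = None) -> None:
    """Record every generator config (seeds included) as a JSON manifest."""
    def _clean(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return _clean(asdict(obj))
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    payload = {"configs": _clean(configs)}
    if extra:
        payload.update(_clean(extra))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
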