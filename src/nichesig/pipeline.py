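"""Config-driven orchestration of the full analysis chain.

Stages run in dependency order:

    simulate -> signature -> score -> survive -> prefer -> niche

Each stage reads the previous stage's plain-text outputs from the run
directory, so stages can be re-run in isolation.  A single config seed
fans out to per-stage seeds through :func:`stage_seed` (a SeedSequence
spawned on the stage name), and a JSON run manifest records the config
snapshot, the seeds, and a SHA-256 checksum of every file written.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import (
    BulkCohort,
    NichesigError,
    SignatureSet,
    read_mtx_dataset,
    read_spatial_grid,
    write_mtx_dataset,
    write_spatial_grid,
)
from .preference import composition_table, roe_long_format, survival_group_enrichment_all
from .scoring import compare_scores_by_response, ssgsea_scores
from .signatures import derive_signatures, filter_cells, normalize_counts
from .spatial import run_niche_pipeline
from .survival import cox_fit, optimal_cutpoint, km_estimate, logrank_test
from .synthetic import (
    SimBulkConfig,
    SimSingleCellConfig,
    SimSpatialConfig,
    SubclusterSpec,
    generate_bulk_cohort,
    generate_single_cell,
    generate_spatial_grid,
    write_run_manifest,
)

STAGES = ("simulate", "signature", "score", "survive", "prefer", "niche")


class DependencyError(NichesigError):
    """An enabled stage is missing an upstream output."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 (SeedSequence on seed + stage crc)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """All tunable parameters of one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    stages: tuple = STAGES
    # signature derivation
    p_thresh: float = 0.05
    lfc_thresh: float = 0.5
    # scoring
    alpha: float = 0.25
    normalize_scores: bool = True
    # survival
    minprop: float = 0.1
    adjust: tuple = ("sex", "age", "treatment", "hbv")
    # niche
    quantile: float = 0.975
    distance: int = 1
    min_score: float = 0.0
    niche_target: str = "DPT"
    niche_contexts: tuple = ("capillaryEC",)
    score_signature: str = "DPT"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise NichesigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "adjust", "niche_contexts"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("stages", "adjust", "niche_contexts"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def demo_sim_configs(seed: int) -> dict:
    """The bundled demo scenario: a prognostic DPT-like subcluster.

    Single-cell data with three T subclusters (the focal one enriched in
    tumours of short-term survivors) plus a B compartment; a bulk cohort
    whose planted signature carries HR 2 per SD and responds to therapy;
    a spatial grid with fully co-localised target/context niches.
    """
    tum_short = {("tumour", "short"): 90, ("tumour", "long"): 30,
                 ("adjacent", "short"): 25, ("adjacent", "long"): 25,
                 ("blood", "short"): 15, ("blood", "long"): 15}
    balanced = {("tumour", "short"): 35, ("tumour", "long"): 35,
                ("adjacent", "short"): 35, ("adjacent", "long"): 35,
                ("blood", "short"): 30, ("blood", "long"): 30}
    sc_cfg = SimSingleCellConfig(
        n_genes=2000,
        subclusters=(
            SubclusterSpec("DPT", "T", tum_short, n_markers=30, marker_fold=3.0),
            SubclusterSpec("Tconv", "T", balanced, n_markers=25, marker_fold=3.0),
            SubclusterSpec("CD8T", "T", balanced, n_markers=25, marker_fold=3.0),
            SubclusterSpec("Bcell", "B", dict(balanced), n_markers=20, marker_fold=3.0),
        ),
        seed=stage_seed(seed, "simulate_sc"),
    )
    bulk_cfg = SimBulkConfig(
        n_samples=200, n_genes=300,
        signature=tuple(f"MK{i:04d}" for i in range(30)),  # the DPT marker block
        log_hr_per_sd=np.log(2.0), response_rate=0.35, response_effect=1.0,
        seed=stage_seed(seed, "simulate_bulk"),
    )
    spatial_cfg = SimSpatialConfig(
        signatures={"DPT": tuple(f"MK{i:04d}" for i in range(15)),
                    "capillaryEC": tuple(f"CEC{i:02d}" for i in range(15))},
        colocalization=1.0,
        seed=stage_seed(seed, "simulate_spatial"),
    )
    return {"single_cell": sc_cfg, "bulk": bulk_cfg, "spatial": spatial_cfg}


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage {stage!r} needs missing input {path}")
    return path


def _run_simulate(cfg: PipelineConfig, outdir: Path, manifest: dict) -> list[Path]:
    sims = demo_sim_configs(cfg.seed)
    written: list[Path] = []
    sc = generate_single_cell(sims["single_cell"])
    written += write_mtx_dataset(sc, outdir / "data", prefix="sc_").values()
    bulk = generate_bulk_cohort(sims["bulk"])
    bulk.write(outdir / "data" / "bulk_expression.csv", outdir / "data" / "bulk_clinical.csv")
    written += [outdir / "data" / "bulk_expression.csv", outdir / "data" / "bulk_clinical.csv"]
    grid = generate_spatial_grid(sims["spatial"])
    written += write_spatial_grid(grid, outdir / "data").values()
    spatial_sigs = SignatureSet({name: list(genes)
                                 for name, genes in sims["spatial"].signatures.items()})
    spatial_sigs.to_gmt(outdir / "data" / "spatial_signatures.gmt")
    written.append(outdir / "data" / "spatial_signatures.gmt")
    write_run_manifest(outdir / "data" / "sim_manifest.json", sims)
    written.append(outdir / "data" / "sim_manifest.json")
    manifest["sim_seeds"] = {k: v.seed for k, v in sims.items()}
    return written


def _run_signature(cfg: PipelineConfig, outdir: Path, manifest: dict) -> list[Path]:
    _require(outdir / "data" / "sc_matrix.mtx", "signature")
    adata = read_mtx_dataset(outdir / "data", prefix="sc_")
    adata = filter_cells(adata)
    adata = normalize_counts(adata)
    sigs = derive_signatures(adata, p_thresh=cfg.p_thresh, lfc_thresh=cfg.lfc_thresh)
    gmt = outdir / "signatures.gmt"
    sigs.to_gmt(gmt)
    prov = outdir / "signature_provenance.json"
    prov.write_text(json.dumps(sigs.provenance, indent=2, sort_keys=True))
    manifest["qc_report"] = adata.uns.get("qc_report", {})
    return [gmt, prov]


def _run_score(cfg: PipelineConfig, outdir: Path, manifest: dict) -> list[Path]:
    _require(outdir / "signatures.gmt", "score")
    _require(outdir / "data" / "bulk_expression.csv", "score")
    sigs = SignatureSet.from_gmt(outdir / "signatures.gmt")
    cohort = BulkCohort.read(outdir / "data" / "bulk_expression.csv",
                             outdir / "data" / "bulk_clinical.csv")
    usable = SignatureSet({n: [g for g in sigs[n] if g in cohort.expression.columns]
                           for n in sigs.names()
                           if any(g in cohort.expression.columns for g in sigs[n])})
    scores = ssgsea_scores(cohort.expression, usable,
                           alpha=cfg.alpha, normalize=cfg.normalize_scores)
    out = scores.stack().rename("score").reset_index()
    out.columns = ["sample_id", "signature", "score"]
    path = outdir / "scores.csv"
    out.to_csv(path, index=False)
    return [path]


def _run_survive(cfg: PipelineConfig, outdir: Path, manifest: dict) -> list[Path]:
    _require(outdir / "scores.csv", "survive")
    scores = pd.read_csv(outdir / "scores.csv")
    cohort = BulkCohort.read(outdir / "data" / "bulk_expression.csv",
                             outdir / "data" / "bulk_clinical.csv")
    sig = cfg.score_signature
    s = (scores[scores["signature"] == sig]
         .set_index("sample_id")["score"].loc[cohort.clinical.index])
    t, e = cohort.clinical["time"], cohort.clinical["event"]

    written = []
    cut = optimal_cutpoint(s.to_numpy(), t, e, minprop=cfg.minprop)
    (outdir / "cutpoint.json").write_text(json.dumps(cut.to_dict(), indent=2))
    written.append(outdir / "cutpoint.json")

    high = s > cut.cutpoint
    km_rows = []
    for label, mask in (("high", high), ("low", ~high)):
        km = km_estimate(t[mask], e[mask])
        df = km.to_frame()
        df.insert(0, "group", label)
        km_rows.append(df)
    km_path = outdir / "km_curves.csv"
    pd.concat(km_rows).to_csv(km_path, index=False)
    written.append(km_path)

    uni = cox_fit(s.to_frame(sig), t, e).summary().assign(model="univariate")
    covs = s.to_frame(sig).join(cohort.clinical[list(cfg.adjust)])
    multi = cox_fit(covs, t, e).summary().assign(model="multivariable")
    forest = pd.concat([uni, multi])
    forest_path = outdir / "cox_forest.csv"
    forest.to_csv(forest_path)
    written.append(forest_path)

    if cohort.clinical["response"].isin(["responder", "non_responder"]).any():
        resp = compare_scores_by_response(s, cohort.clinical["response"])
        (outdir / "response.json").write_text(json.dumps(resp, indent=2))
        written.append(outdir / "response.json")
    return written


def _run_prefer(cfg: PipelineConfig, outdir: Path, manifest: dict) -> list[Path]:
    _require(outdir / "data" / "sc_metadata.csv", "prefer")
    meta = pd.read_csv(outdir / "data" / "sc_metadata.csv", index_col="cell_id")
    roe = roe_long_format(composition_table(meta))
    roe_path = outdir / "roe_tissue.csv"
    roe.to_csv(roe_path, index=False)
    enr = survival_group_enrichment_all(meta)
    enr_path = outdir / "survival_group_enrichment.csv"
    enr.to_csv(enr_path, index=False)
    return [roe_path, enr_path]


def _run_niche(cfg: PipelineConfig, outdir: Path, manifest: dict) -> list[Path]:
    _require(outdir / "data" / "spatial_matrix.mtx", "niche")
    _require(outdir / "signatures.gmt", "niche")
    grid = read_spatial_grid(outdir / "data")
    sigs = SignatureSet.from_gmt(outdir / "signatures.gmt")
    # niche signatures may live in a separate GMT shipped with the spatial data
    extra = outdir / "data" / "spatial_signatures.gmt"
    if extra.exists():
        for name, genes in SignatureSet.from_gmt(extra).items():
            if name not in sigs:
                sigs.add(name, genes)
    contexts = [c for c in cfg.niche_contexts if c in sigs]
    usable = SignatureSet({n: [g for g in sigs[n] if g in grid.var_names]
                           for n in [cfg.niche_target, *contexts]
                           if any(g in grid.var_names for g in sigs[n])})
    contexts = [c for c in contexts if c in usable]
    report = run_niche_pipeline(grid, cfg.niche_target, usable, contexts,
                                quantile=cfg.quantile, distance=cfg.distance,
                                min_score=cfg.min_score)
    assoc_path = outdir / "niche_association.json"
    assoc_path.write_text(report.to_json(orient="records", indent=2))
    labels = pd.concat([lab.to_frame() for lab in report.attrs["labelings"].values()])
    labels_path = outdir / "niche_labels.csv"
    labels.to_csv(labels_path)
    return [assoc_path, labels_path]


_STAGE_FUNCS = {
    "simulate": _run_simulate,
    "signature": _run_signature,
    "score": _run_score,
    "survive": _run_survive,
    "prefer": _run_prefer,
    "niche": _run_niche,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def validate_inputs(paths: dict) -> list[str]:
    """Structural validation of the external input files; never mutates them.

    ``paths`` maps kinds to locations: ``single_cell`` (a directory with
    the MTX bundle), ``bulk_expression``/``bulk_clinical`` CSVs,
    ``spatial`` directory, ``gmt`` file.  Returns a list of error
    strings (empty when everything checks out).
    """
    errors: list[str] = []
    try:
        if "single_cell" in paths:
            from .datasets import validate_cell_dataset
            validate_cell_dataset(read_mtx_dataset(paths["single_cell"], prefix="sc_"))
        if "bulk_expression" in paths:
            BulkCohort.read(paths["bulk_expression"], paths["bulk_clinical"])
        if "spatial" in paths:
            read_spatial_grid(paths["spatial"])
        if "gmt" in paths:
            SignatureSet.from_gmt(paths["gmt"])
    except (NichesigError, FileNotFoundError, KeyError) as exc:
        errors.append(str(exc))
    return errors


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    Any stage failure aborts with a stage-scoped error.  Identical config
    (seed included) and inputs produce identical outputs; the manifest
    records a checksum of every file written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "outputs": {},
        "warnings": [],
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        fn = _STAGE_FUNCS[stage]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                written = fn(config, outdir, manifest)
            except NichesigError as exc:
                raise type(exc)(f"stage {stage!r}: {exc}") from exc
        manifest["warnings"] += [f"{stage}: {w.message}" for w in caught]
        manifest["outputs"][stage] = {str(p): _sha256(p) for p in written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
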