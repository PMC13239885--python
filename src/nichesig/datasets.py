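"""Core data containers and plain-text IO.

Four substrates flow through the pipeline:

* annotated single-cell counts (an :class:`anndata.AnnData`, cells x genes,
  with ``obs`` columns ``patient``, ``tissue``, ``major_type``, ``subcluster``,
  ``survival_group`` and a boolean ``var['mito']`` flag),
* a bulk expression cohort with survival/covariate/response annotations
  (:class:`BulkCohort`),
* a binned spatial grid (AnnData with integer ``obs['x']``/``obs['y']`` bin
  coordinates),
* named gene lists (:class:`SignatureSet`, GMT-backed).

All on-disk formats are plain text: Matrix Market + TSV for sparse counts,
CSV for tables, GMT for gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

TISSUES = ("blood", "adjacent", "tumour")
SURVIVAL_GROUPS = ("short", "long")

CELL_OBS_COLUMNS = ("patient", "tissue", "major_type", "subcluster", "survival_group")


class NichesigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NichesigError):
    """Invalid configuration or parameters."""


class ValidationError(NichesigError):
    """Structurally invalid input data."""


class EmptyDatasetError(NichesigError):
    """An operation removed or received no usable observations."""


# ---------------------------------------------------------------------------
# SignatureSet
# ---------------------------------------------------------------------------


class SignatureSet:
    """Named, ordered, duplicate-free gene lists with a provenance record.

    The central exchange object between signature derivation, enrichment
    scoring and the spatial niche procedure.  Backed by the GMT format
    (one set per line: name, description, tab-separated genes).
    """

    def __init__(self, sets: Mapping[str, Iterable[str]] | None = None,
                 provenance: dict | None = None):
        self._sets: dict[str, list[str]] = {}
        self.provenance: dict = dict(provenance or {})
        if sets:
            for name, genes in sets.items():
                self.add(name, genes)

    def add(self, name: str, genes: Iterable[str]) -> None:
        if name in self._sets:
            raise ValidationError(f"duplicate signature name: {name!r}")
        genes = list(genes)
        seen: set[str] = set()
        deduped = []
        for g in genes:
            if g not in seen:
                seen.add(g)
                deduped.append(g)
        if len(deduped) != len(genes):
            warnings.warn(f"signature {name!r}: dropped {len(genes) - len(deduped)} duplicate genes")
        self._sets[name] = deduped

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def names(self) -> list[str]:
        return list(self._sets)

    def items(self):
        return ((k, list(v)) for k, v in self._sets.items())

    def __eq__(self, other) -> bool:
        return isinstance(other, SignatureSet) and self._sets == other._sets

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}({len(v)})" for k, v in self._sets.items())
        return f"SignatureSet[{inner}]"

    # -- GMT IO ---------------------------------------------------------

    def to_gmt(self, path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
        descriptions = descriptions or {}
        with open(path, "w") as fh:
            for name, genes in self._sets.items():
                desc = descriptions.get(name, self.provenance.get("description", "na"))
                fh.write("\t".join([name, str(desc), *genes]) + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "SignatureSet":
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValidationError(
                        f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
                sets[parts[0]] = [g for g in parts[2:] if g]
        return cls(sets, provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# BulkCohort
# ---------------------------------------------------------------------------


CLINICAL_COLUMNS = ("time", "event", "sex", "age", "treatment", "hbv")


@dataclass
class BulkCohort:
    """Bulk expression (samples x genes, FPKM-like) plus clinical annotations.

    ``clinical`` is indexed by sample id and carries ``time`` (months),
    ``event`` (0/1), the adjustment covariates ``sex``/``age``/``treatment``/
    ``hbv`` and an optional ``response`` column with values ``responder`` /
    ``non_responder`` / missing (NaN).
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.clinical.index):
            raise ValidationError("expression and clinical tables must share the same sample index")
        if self.expression.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if self.expression.columns.has_duplicates:
            raise ValidationError("duplicate gene symbols in expression matrix")
        vals = self.expression.to_numpy()
        if np.any(vals < 0):
            raise ValidationError("negative expression values")
        t = self.clinical["time"].to_numpy(dtype=float)
        if np.any(t[~np.isnan(t)] <= 0):
            raise ValidationError("survival times must be > 0")
        ev = self.clinical["event"].dropna().unique()
        if not set(np.asarray(ev, dtype=float)) <= {0.0, 1.0}:
            raise ValidationError("event indicator must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def genes(self) -> pd.Index:
        return self.expression.columns

    def write(self, expr_path: str | Path, clinical_path: str | Path) -> None:
        self.expression.to_csv(expr_path, index_label="sample_id")
        self.clinical.to_csv(clinical_path, index_label="sample_id")

    @classmethod
    def read(cls, expr_path: str | Path, clinical_path: str | Path) -> "BulkCohort":
        expr = pd.read_csv(expr_path, index_col="sample_id")
        clin = pd.read_csv(clinical_path, index_col="sample_id")
        return cls(expr, clin.loc[expr.index])


# ---------------------------------------------------------------------------
# Single-cell / spatial AnnData IO and validation
# ---------------------------------------------------------------------------


def validate_cell_dataset(adata: ad.AnnData) -> None:
    """Check the single-cell container contract.

    Raises :class:`ValidationError` on duplicate ids, missing annotation
    columns, negative counts, or subclusters mapping to more than one
    major type.
    """
    if adata.obs_names.has_duplicates:
        raise ValidationError("duplicate cell ids")
    if adata.var_names.has_duplicates:
        raise ValidationError("duplicate gene ids")
    missing = [c for c in CELL_OBS_COLUMNS if c not in adata.obs.columns]
    if missing:
        raise ValidationError(f"missing per-cell metadata columns: {missing}")
    if "mito" not in adata.var.columns:
        raise ValidationError("missing boolean var column 'mito'")
    x = adata.X
    mn = x.min() if sp.issparse(x) else np.min(x)
    if mn < 0:
        raise ValidationError("negative counts")
    mapping = adata.obs.groupby("subcluster", observed=True)["major_type"].nunique()
    bad = mapping[mapping > 1]
    if len(bad):
        raise ValidationError(f"subclusters mapped to multiple major types: {list(bad.index)}")


def validate_spatial_grid(adata: ad.AnnData) -> None:
    if adata.obs_names.has_duplicates:
        raise ValidationError("duplicate spot ids")
    for c in ("x", "y"):
        if c not in adata.obs.columns:
            raise ValidationError(f"missing spot coordinate column {c!r}")
        if not np.issubdtype(adata.obs[c].dtype, np.integer):
            raise ValidationError(f"spot coordinate {c!r} must be integer bin indices")
    coords = adata.obs[["x", "y"]]
    if coords.duplicated().any():
        raise ValidationError("duplicate (x, y) bin coordinates")


def write_mtx_dataset(adata: ad.AnnData, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write an AnnData as genes x cells MTX + features/barcodes TSV (+ metadata CSV).

    Returns the paths written.  The matrix is stored genes x cells, the usual
    orientation of the exchange format, regardless of the in-memory layout.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}matrix.mtx",
        "features": outdir / f"{prefix}features.tsv",
        "barcodes": outdir / f"{prefix}barcodes.tsv",
        "metadata": outdir / f"{prefix}metadata.csv",
    }
    x = adata.X
    mat = sp.csr_matrix(x).T if not sp.issparse(x) else x.T.tocsr()
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(mat))
    feat = pd.DataFrame({"gene": adata.var_names})
    if "mito" in adata.var.columns:
        feat["mito"] = adata.var["mito"].astype(int).to_numpy()
    feat.to_csv(paths["features"], sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    adata.obs.to_csv(paths["metadata"], index_label="cell_id")
    return paths


def read_mtx_dataset(outdir: str | Path, prefix: str = "") -> ad.AnnData:
    """Read a genes x cells MTX + TSV + metadata CSV bundle into AnnData."""
    outdir = Path(outdir)
    mat = scipy.io.mmread(str(outdir / f"{prefix}matrix.mtx")).tocsr().T.tocsr()
    feat = pd.read_csv(outdir / f"{prefix}features.tsv", sep="\t", header=None)
    features = feat[0].astype(str)
    barcodes = pd.read_csv(outdir / f"{prefix}barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if mat.shape[0] != len(barcodes):
        raise ValidationError(
            f"barcodes TSV has {len(barcodes)} entries but matrix has {mat.shape[0]} columns")
    if mat.shape[1] != len(features):
        raise ValidationError(
            f"features TSV has {len(features)} entries but matrix has {mat.shape[1]} rows")
    var = pd.DataFrame(index=pd.Index(features.to_numpy(), name=None))
    if feat.shape[1] > 1:
        var["mito"] = feat[1].to_numpy().astype(bool)
    obs = pd.DataFrame(index=pd.Index(barcodes.to_numpy(), name=None))
    adata = ad.AnnData(X=mat, obs=obs, var=var)
    meta_path = outdir / f"{prefix}metadata.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col="cell_id")
        meta.index = pd.Index(meta.index.astype(str), name=None)
        adata.obs = meta.loc[adata.obs_names]
    return adata


def write_spatial_grid(adata: ad.AnnData, outdir: str | Path, prefix: str = "spatial_") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}matrix.mtx",
        "features": outdir / f"{prefix}features.tsv",
        "coordinates": outdir / f"{prefix}coordinates.csv",
    }
    x = adata.X
    mat = sp.csr_matrix(x).T if not sp.issparse(x) else x.T.tocsr()
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(mat))
    pd.Series(adata.var_names).to_csv(paths["features"], sep="\t", index=False, header=False)
    coords = adata.obs[["x", "y"]].copy()
    coords.to_csv(paths["coordinates"], index_label="spot_id")
    return paths


def read_spatial_grid(outdir: str | Path, prefix: str = "spatial_") -> ad.AnnData:
    outdir = Path(outdir)
    mat = scipy.io.mmread(str(outdir / f"{prefix}matrix.mtx")).tocsr().T.tocsr()
    features = pd.read_csv(outdir / f"{prefix}features.tsv", sep="\t", header=None)[0].astype(str)
    coords = pd.read_csv(outdir / f"{prefix}coordinates.csv", index_col="spot_id")
    coords.index = pd.Index(coords.index.astype(str), name=None)
    if mat.shape[0] != len(coords):
        raise ValidationError(
            f"coordinates CSV has {len(coords)} spots but matrix has {mat.shape[0]} columns")
    adata = ad.AnnData(X=mat, obs=coords[["x", "y"]].astype(int),
                       var=pd.DataFrame(index=pd.Index(features.to_numpy(), name=None)))
    validate_spatial_grid(adata)
    return adata
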