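"""Delimited file formats, pipeline configuration, and run manifests.

All tabular artifacts are header-full, tab-delimited, UTF-8, with ISO-8601
dates, so fixtures diff cleanly and round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .claims import ClaimsTables, EligibilityConfig
from .imputation import (
    EQTLWeightSet,
    GWASSummary,
    GeneAnnotation,
    LDReference,
    TissueSignature,
)
from .screen import PerturbagenLibrary

SEP = "\t"


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def _check_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    extra = [c for c in df.columns if c not in required]
    if missing:
        raise SchemaError(
            f"{path}: missing columns {missing}"
            + (f"; extra columns {extra}" if extra else "")
        )


def _numeric_column(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    """Coerce a column to float, reporting the first bad value's file line."""
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"{path}: non-numeric {col!r} value {df[col].iloc[row]!r} "
            f"at line {row + 2}"  # +1 header, +1 one-based
        )
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna())[0])
        raise SchemaError(f"{path}: missing {col!r} value at line {row + 2}")
    return vals.astype(float)



def _to_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None,
            **kwargs) -> None:
    """Write a TSV, optionally stamped with a leading '#' comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep=SEP, **kwargs)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def write_gwas(gwas: GWASSummary, path: str | Path,
               comment: str | None = None) -> None:
    _to_tsv(gwas.table, path, comment, index=False)


def read_gwas(path: str | Path) -> GWASSummary:
    path = Path(path)
    df = pd.read_csv(path, sep=SEP, dtype=str, comment="#")
    _check_columns(df, ["variant_id", "effect_allele", "other_allele", "z"], path)
    df["z"] = _numeric_column(df, "z", path)
    return GWASSummary(df)


# ---------------------------------------------------------------------------
# LD matrix (square, variant ids as header row and first column)
# ---------------------------------------------------------------------------

def write_ld(ld: LDReference, path: str | Path,
             comment: str | None = None) -> None:
    df = pd.DataFrame(ld.matrix, index=ld.variant_ids, columns=ld.variant_ids)
    _to_tsv(df, path, comment, index_label="variant_id")


def read_ld(path: str | Path, sym_tol: float = 1e-8) -> LDReference:
    path = Path(path)
    df = pd.read_csv(path, sep=SEP, index_col=0, comment="#")
    if list(df.index) != list(df.columns):
        raise SchemaError(f"{path}: LD row ids do not match column ids")
    mat = df.to_numpy(dtype=float)
    asym = np.abs(mat - mat.T)
    if asym.size and asym.max() > sym_tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise SchemaError(
            f"{path}: asymmetric LD entry at cell ({df.index[i]}, {df.columns[j]}): "
            f"{mat[i, j]:.6g} vs {mat[j, i]:.6g}"
        )
    return LDReference(list(df.index), (mat + mat.T) / 2.0)


# ---------------------------------------------------------------------------
# eQTL weights (long form: tissue, gene, variant_id, weight[, alleles])
# ---------------------------------------------------------------------------

def write_weights(weight_sets: dict[str, EQTLWeightSet], path: str | Path,
                  comment: str | None = None) -> None:
    rows = []
    for tissue in sorted(weight_sets):
        ws = weight_sets[tissue]
        for gene in ws.genes:
            for v, w in ws.weights[gene].items():
                rows.append((tissue, gene, v, w))
    df = pd.DataFrame(rows, columns=["tissue", "gene", "variant_id", "weight"])
    _to_tsv(df, path, comment, index=False)


def read_weights(path: str | Path) -> dict[str, EQTLWeightSet]:
    path = Path(path)
    df = pd.read_csv(path, sep=SEP, dtype=str, comment="#")
    _check_columns(df, ["tissue", "gene", "variant_id", "weight"], path)
    df["weight"] = _numeric_column(df, "weight", path)
    out: dict[str, EQTLWeightSet] = {}
    for tissue, sub in df.groupby("tissue", sort=True):
        wmap: dict[str, dict[str, float]] = {}
        for gene, gsub in sub.groupby("gene", sort=True):
            wmap[gene] = dict(zip(gsub["variant_id"], gsub["weight"]))
        out[str(tissue)] = EQTLWeightSet(str(tissue), wmap)
    return out


# ---------------------------------------------------------------------------
# Gene annotation (gene-variant map + tissue panels)
# ---------------------------------------------------------------------------

def write_annotation(annotation: GeneAnnotation, prefix: str | Path,
                     comment: str | None = None) -> None:
    prefix = Path(prefix)
    rows = [(g, v) for g in sorted(annotation.gene_variants)
            for v in annotation.gene_variants[g]]
    _to_tsv(pd.DataFrame(rows, columns=["gene", "variant_id"]),
            prefix.with_suffix(".gene_variants.tsv"), comment, index=False)
    prows = [(t, g) for t in sorted(annotation.tissue_panels)
             for g in sorted(annotation.tissue_panels[t])]
    _to_tsv(pd.DataFrame(prows, columns=["tissue", "gene"]),
            prefix.with_suffix(".tissue_panels.tsv"), comment, index=False)
    meta = {
        "nervous_tissues": sorted(annotation.nervous_tissues),
        "whole_blood": annotation.whole_blood,
    }
    prefix.with_suffix(".annotation.yaml").write_text(yaml.safe_dump(meta))


def read_annotation(prefix: str | Path) -> GeneAnnotation:
    prefix = Path(prefix)
    gv = pd.read_csv(prefix.with_suffix(".gene_variants.tsv"), sep=SEP, dtype=str, comment="#")
    _check_columns(gv, ["gene", "variant_id"], prefix.with_suffix(".gene_variants.tsv"))
    panels = pd.read_csv(prefix.with_suffix(".tissue_panels.tsv"), sep=SEP, dtype=str, comment="#")
    _check_columns(panels, ["tissue", "gene"], prefix.with_suffix(".tissue_panels.tsv"))
    meta = yaml.safe_load(prefix.with_suffix(".annotation.yaml").read_text())
    gene_variants = {g: sub["variant_id"].tolist()
                     for g, sub in gv.groupby("gene", sort=True)}
    tissue_panels = {t: set(sub["gene"]) for t, sub in panels.groupby("tissue", sort=True)}
    return GeneAnnotation(
        gene_variants=gene_variants,
        tissue_panels=tissue_panels,
        nervous_tissues=set(meta["nervous_tissues"]),
        whole_blood=meta["whole_blood"],
    )


# ---------------------------------------------------------------------------
# Tissue signatures
# ---------------------------------------------------------------------------

def write_signatures(signatures: list[TissueSignature], path: str | Path,
                     comment: str | None = None) -> None:
    rows = [(s.tissue, g, z) for s in signatures for g, z in s.z.items()]
    _to_tsv(pd.DataFrame(rows, columns=["tissue", "gene", "z_twas"]),
            path, comment, index=False)


def read_signatures(path: str | Path) -> list[TissueSignature]:
    path = Path(path)
    df = pd.read_csv(path, sep=SEP, dtype=str, comment="#")
    _check_columns(df, ["tissue", "gene", "z_twas"], path)
    df["z_twas"] = _numeric_column(df, "z_twas", path)
    return [
        TissueSignature(str(t), sub.set_index("gene")["z_twas"])
        for t, sub in df.groupby("tissue", sort=True)
    ]


# ---------------------------------------------------------------------------
# Perturbagen library (gene x signature matrix + metadata sidecar)
# ---------------------------------------------------------------------------

def write_library(library: PerturbagenLibrary, prefix: str | Path,
                  comment: str | None = None) -> None:
    """Write the matrix (genes in rows) and the signature metadata table.

    Conversion stub for native binary signature archives (e.g. GCTX): export
    the Level-5-like matrix with genes as rows and signature ids as columns
    to TSV, plus a metadata table (signature_id, perturbagen, cell_line),
    and read it back with :func:`read_library`.
    """
    prefix = Path(prefix)
    _to_tsv(library.matrix, prefix.with_suffix(".matrix.tsv"), comment,
            index_label="gene")
    _to_tsv(library.meta, prefix.with_suffix(".meta.tsv"), comment,
            index=False)


def read_library(prefix: str | Path) -> PerturbagenLibrary:
    prefix = Path(prefix)
    mpath = prefix.with_suffix(".matrix.tsv")
    matrix = pd.read_csv(mpath, sep=SEP, index_col=0, comment="#")
    for col in matrix.columns:
        matrix[col] = _numeric_column(matrix, col, mpath)
    meta = pd.read_csv(prefix.with_suffix(".meta.tsv"), sep=SEP, dtype=str, comment="#")
    _check_columns(meta, ["signature_id", "perturbagen", "cell_line"],
                   prefix.with_suffix(".meta.tsv"))
    return PerturbagenLibrary(matrix, meta)


# ---------------------------------------------------------------------------
# Drug map
# ---------------------------------------------------------------------------

def write_drug_map(drug_map: pd.DataFrame, path: str | Path,
                   comment: str | None = None) -> None:
    _to_tsv(drug_map, path, comment, index=False)


def read_drug_map(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=SEP, dtype=str, comment="#")
    _check_columns(df, ["perturbagen", "approved", "drug_name", "drug_class"], path)
    return df


# ---------------------------------------------------------------------------
# Claims tables
# ---------------------------------------------------------------------------

_CLAIMS_FILES = {
    "enrollment": "enrollment.tsv",
    "diagnoses": "diagnoses.tsv",
    "prescriptions": "prescriptions.tsv",
}


def write_claims(claims: ClaimsTables, outdir: str | Path,
                 comment: str | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _CLAIMS_FILES.items():
        df = getattr(claims, attr).copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        _to_tsv(df, outdir / fname, comment, index=False)


def read_claims(indir: str | Path) -> ClaimsTables:
    indir = Path(indir)
    frames = {}
    for attr, fname in _CLAIMS_FILES.items():
        path = indir / fname
        if not path.exists():
            raise FileNotFoundError(f"missing claims table: {path}")
        frames[attr] = pd.read_csv(path, sep=SEP, dtype=str, comment="#")
    frames["enrollment"]["birth_year"] = _numeric_column(
        frames["enrollment"], "birth_year", indir / _CLAIMS_FILES["enrollment"]
    ).astype(int)
    return ClaimsTables(**frames)


# ---------------------------------------------------------------------------
# Truth sidecar
# ---------------------------------------------------------------------------

def write_truth(truth_table: pd.DataFrame, path: str | Path,
                comment: str | None = None) -> None:
    _to_tsv(truth_table, path, comment, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=SEP, dtype=str, comment="#")
    _check_columns(df, ["key", "value"], path)
    return df


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Scalar knobs for every pipeline stage, serializable to YAML."""

    # screen
    fraction: float = 0.10
    alpha: float = 1e-4
    n_updown: int = 150
    top_k: int = 200
    min_genes_spearman: int = 20
    min_genes_per_set: int = 10
    # imputation
    ridge: float = 0.1
    # claims
    window_days: int = 365
    min_partial_days: int = 90
    step_days: int | None = None  # None: consecutive non-overlapping windows
    # synthetic sizes
    n_variants: int = 3000
    n_genes: int = 1000
    n_tissues: int = 6
    causal_fraction: float = 0.05
    ld_block_size: int = 5
    ld_rho: float = 0.3
    n_signatures: int = 300
    n_reversers: int = 6
    n_mimickers: int = 6
    strength: float = 0.6
    noise_sd: float = 1.0
    n_patients: int = 1500
    n_windows_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.ridge <= 1:
            raise ValueError("ridge must be in [0, 1]")
        for name in ("n_updown", "top_k", "window_days", "min_partial_days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: PipelineConfig, seed: int,
                   extra: dict | None = None) -> None:
    import scipy

    manifest = {
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
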