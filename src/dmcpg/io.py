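"""Data model and I/O for the methylation prioritization pipeline.

In-memory containers are plain :class:`pandas.DataFrame` objects with fixed
schemas (validated on read):

ProbeManifest
    columns ``probe_id, chrom, pos, island_relation, gene_symbol,
    tss_distance, flag_snp, flag_crossreactive``; one row per array probe,
    sorted by (chrom, pos), ``pos`` 1-based. ``island_relation`` is one of
    ``core`` (CpG-island core), ``shelf_shore`` (island flank) or
    ``open_sea`` (outside any island).

BetaMatrix
    probes x samples DataFrame of methylation fractions (beta values) in
    [0, 1], indexed by ``probe_id``; columns are sample ids. Row order
    follows the manifest.

SampleSheet
    columns ``sample_id, group, cell_type, replicate_set``; ``group`` is
    ``HC`` or ``RA``; ``replicate_set`` ties technical replicates to their
    parent sample (empty string for singleton samples).

All text exports carry a deterministic provenance header line prefixed
with ``#`` (tool version and a config hash, never a timestamp) so that
fixed-seed pipeline runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ISLAND_RELATIONS",
    "MANIFEST_COLUMNS",
    "SAMPLESHEET_COLUMNS",
    "beta_to_m",
    "m_to_beta",
    "read_manifest",
    "read_matrix",
    "read_samplesheet",
    "write_manifest",
    "write_matrix",
    "write_samplesheet",
    "export_clusters_bed",
    "read_clusters_bed",
    "export_summary_json",
    "provenance_header",
    "analysis_sample_mask",
]

TOOL_VERSION = "0.1.0"

ISLAND_RELATIONS = ("core", "shelf_shore", "open_sea")
MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "island_relation",
    "gene_symbol",
    "tss_distance",
    "flag_snp",
    "flag_crossreactive",
]
SAMPLESHEET_COLUMNS = ["sample_id", "group", "cell_type", "replicate_set"]


class SchemaError(ValueError):
    """Raised when an input file or container violates the documented schema."""


# ---------------------------------------------------------------------------
# beta <-> M transforms
# ---------------------------------------------------------------------------

def beta_to_m(beta, epsilon: float = 1e-3):
    """Convert methylation fractions to M values, ``M = log2(b / (1 - b))``.

    Beta values are clipped to ``[epsilon, 1 - epsilon]`` before the logit so
    that fully (un)methylated probes map to finite M values; interior values
    are untouched.

    Parameters
    ----------
    beta
        Scalar or array of methylation fractions in [0, 1].
    epsilon
        Clipping margin, ``0 < epsilon < 0.5``. Default 1e-3.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: ``b = 2**M / (2**M + 1)``.

    Exact (to floating precision) for beta values inside the clipped range.
    """
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.power(2.0, -m))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def provenance_header(config_hash: str = "na") -> str:
    return f"# dmcpg {TOOL_VERSION} config_hash={config_hash}"


def _write_table(df: pd.DataFrame, path, sep: str, config_hash: str = "na",
                 index: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(config_hash) + "\n")
        df.to_csv(fh, sep=sep, index=index, lineterminator="\n")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise SchemaError(f"manifest missing columns: {missing}")
    if manifest["probe_id"].duplicated().any():
        dup = manifest.loc[manifest["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise SchemaError(f"duplicate probe_id in manifest: {dup!r}")
    if (manifest["pos"] < 1).any():
        bad = manifest.loc[manifest["pos"] < 1, "probe_id"].iloc[0]
        raise SchemaError(f"probe {bad!r} has non-positive position")
    bad_rel = ~manifest["island_relation"].isin(ISLAND_RELATIONS)
    if bad_rel.any():
        val = manifest.loc[bad_rel, "island_relation"].iloc[0]
        raise SchemaError(f"unknown island_relation {val!r}")
    out = manifest.sort_values(["chrom", "pos"], kind="mergesort")
    return out.reset_index(drop=True)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"probe_id": str, "chrom": str, "gene_symbol": str},
                     keep_default_na=False)
    for col in ("flag_snp", "flag_crossreactive"):
        if col in df.columns:
            df[col] = df[col].astype(int).astype(bool)
    if "pos" in df.columns:
        df["pos"] = df["pos"].astype(int)
    if "tss_distance" in df.columns:
        df["tss_distance"] = df["tss_distance"].astype(int)
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path, config_hash: str = "na") -> None:
    out = manifest.copy()
    out["flag_snp"] = out["flag_snp"].astype(int)
    out["flag_crossreactive"] = out["flag_crossreactive"].astype(int)
    _write_table(out[MANIFEST_COLUMNS], path, "\t", config_hash)


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------

def validate_matrix(matrix: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    if matrix.columns.duplicated().any():
        raise SchemaError("duplicated sample id in matrix columns")
    unknown = matrix.index.difference(manifest["probe_id"])
    if len(unknown):
        raise SchemaError(f"matrix probe {unknown[0]!r} absent from manifest")
    vals = matrix.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1) | ~np.isfinite(vals)
    if bad.any():
        i = int(np.argwhere(bad.any(axis=1))[0][0])
        raise SchemaError(
            f"beta value outside [0, 1] at probe {matrix.index[i]!r}")
    # align to manifest order, restricted to probes present in the matrix
    order = manifest.loc[manifest["probe_id"].isin(matrix.index), "probe_id"]
    return matrix.loc[order]


def read_matrix(path, manifest: pd.DataFrame) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="probe_id")
    return validate_matrix(df, manifest)


def write_matrix(matrix: pd.DataFrame, path, config_hash: str = "na") -> None:
    out = matrix.copy()
    out.index.name = "probe_id"
    _write_table(out, path, "\t", config_hash, index=True)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def validate_samplesheet(sheet: pd.DataFrame,
                         matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    missing = [c for c in SAMPLESHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise SchemaError(f"sample sheet missing columns: {missing}")
    bad = ~sheet["group"].isin(("HC", "RA"))
    if bad.any():
        raise SchemaError(
            f"unknown group label {sheet.loc[bad, 'group'].iloc[0]!r}")
    if sheet["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample_id in sample sheet")
    if matrix is not None:
        extra = set(matrix.columns) - set(sheet["sample_id"])
        if extra:
            raise SchemaError(f"unknown sample in matrix: {sorted(extra)[0]!r}")
    return sheet.reset_index(drop=True)


def read_samplesheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    return validate_samplesheet(df)


def write_samplesheet(sheet: pd.DataFrame, path, config_hash: str = "na") -> None:
    _write_table(sheet[SAMPLESHEET_COLUMNS], path, ",", config_hash)


def analysis_sample_mask(sheet: pd.DataFrame) -> pd.Series:
    """Boolean mask of samples used for group comparisons.

    Technical replicates exist for the reproducibility filter only; for each
    replicate set every sample after the first (in sheet order) is excluded
    so replicates never inflate the per-group n.
    """
    rep = sheet["replicate_set"].fillna("").astype(str)
    dup = (rep != "") & rep.duplicated(keep="first")
    return ~dup


# ---------------------------------------------------------------------------
# cluster BED / summary JSON exports
# ---------------------------------------------------------------------------

def export_clusters_bed(clusters: Iterable, path, config_hash: str = "na") -> None:
    """Write clusters as BED4+score (0-based half-open intervals).

    The 1-based inclusive cluster span [start, end] becomes the BED interval
    (start - 1, end]. The name field is the cluster's top gene symbol (first
    in sorted order, ``.`` if none) and the score field is the cluster score
    capped at 1000.
    """
    lines = [provenance_header(config_hash)]
    for cl in clusters:
        name = sorted(cl.genes)[0] if cl.genes else "."
        score = min(int(cl.score), 1000)
        lines.append(f"{cl.chrom}\t{cl.start - 1}\t{cl.end}\t{name}\t{score}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_clusters_bed(path) -> pd.DataFrame:
    """Read a cluster BED back to a table with 1-based inclusive coordinates."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "bed_start", "bed_end", "name", "score"])
    df["start"] = df["bed_start"] + 1
    df["end"] = df["bed_end"]
    return df[["chrom", "start", "end", "name", "score"]]


def export_summary_json(summary: dict, path, config_hash: str = "na") -> None:
    payload = {"_provenance": provenance_header(config_hash).lstrip("# "),
               **summary}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
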