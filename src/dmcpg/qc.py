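"""Probe-level QC: blacklist removal and the beta-range reproducibility filter.

Probes flagged as common SNPs or cross-reactive (multi-mapping) are removed
first; probes whose beta range across technical replicates exceeds the
reproducibility threshold (default: range > 0.10) are removed next. Removal
reasons are counted once per probe with fixed priority
SNP > cross-reactive > reproducibility > missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import analysis_sample_mask

__all__ = ["QCReport", "apply_blacklist", "reproducibility_filter", "run_qc"]

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    n_input: int = 0
    n_removed_snp: int = 0
    n_removed_crossreactive: int = 0
    n_removed_reproducibility: int = 0
    n_removed_missing: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict:
        return asdict(self)

    def check(self) -> None:
        removed = (self.n_removed_snp + self.n_removed_crossreactive
                   + self.n_removed_reproducibility + self.n_removed_missing)
        assert self.n_retained == self.n_input - removed, "QC accounting broken"


def apply_blacklist(matrix: pd.DataFrame, manifest: pd.DataFrame):
    """Drop probes flagged flag_snp or flag_crossreactive; order preserved.

    A probe carrying both flags is counted once, under SNP.
    """
    flags = manifest.set_index("probe_id").loc[
        matrix.index, ["flag_snp", "flag_crossreactive"]]
    snp = flags["flag_snp"].to_numpy(bool)
    cross = flags["flag_crossreactive"].to_numpy(bool) & ~snp
    keep = ~(snp | cross)
    report = QCReport(
        n_input=len(matrix),
        n_removed_snp=int(snp.sum()),
        n_removed_crossreactive=int(cross.sum()),
        n_retained=int(keep.sum()),
    )
    return matrix.loc[keep], report


def reproducibility_filter(matrix: pd.DataFrame, samplesheet: pd.DataFrame,
                           threshold: float = 0.10, mode: str = "replicate"):
    """Remove probes whose beta range within a replicate set exceeds ``threshold``.

    For each probe the within-set range (max beta - min beta) is taken over
    every replicate set with >= 2 samples, and the probe is removed iff the
    maximum such range is strictly greater than ``threshold``.

    ``mode="group"`` ranges over the HC and RA groups instead (an
    alternative reading of a min/max beta reproducibility rule); the default
    ``"replicate"`` mode is a no-op with a warning when no replicate set has
    two samples.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if mode not in ("replicate", "group"):
        raise ValueError(f"unknown mode {mode!r}")

    sheet = samplesheet[samplesheet["sample_id"].isin(matrix.columns)]
    if mode == "replicate":
        key = sheet["replicate_set"].fillna("").astype(str)
        groups = [g["sample_id"].tolist()
                  for k, g in sheet.groupby(key) if k != ""]
    else:
        groups = [g["sample_id"].tolist() for _, g in sheet.groupby("group")]
    groups = [g for g in groups if len(g) >= 2]

    if not groups:
        logger.warning("reproducibility filter: no replicate set with >= 2 "
                       "samples; no probes removed")
        return matrix, []

    worst = np.zeros(len(matrix))
    for cols in groups:
        block = matrix[cols].to_numpy()
        worst = np.maximum(worst, block.max(axis=1) - block.min(axis=1))
    remove = worst > threshold
    removed_ids = matrix.index[remove].tolist()
    return matrix.loc[~remove], removed_ids


def run_qc(matrix: pd.DataFrame, manifest: pd.DataFrame,
           samplesheet: pd.DataFrame, threshold: float = 0.10,
           mode: str = "replicate"):
    """Full QC stage: blacklist then reproducibility filter.

    Returns (filtered matrix, QCReport, removed reproducibility probe ids).
    Probes with any missing entry are dropped last (complete matrices are
    required downstream) with a logged count.
    """
    filtered, report = apply_blacklist(matrix, manifest)
    filtered, removed_rep = reproducibility_filter(
        filtered, samplesheet, threshold=threshold, mode=mode)
    report.n_removed_reproducibility = len(removed_rep)

    missing = filtered.isna().any(axis=1)
    if missing.any():
        logger.warning("dropping %d probes with missing entries",
                       int(missing.sum()))
        filtered = filtered.loc[~missing]
    report.n_removed_missing = int(missing.sum())
    report.n_retained = len(filtered)
    report.check()
    return filtered, report, removed_rep
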