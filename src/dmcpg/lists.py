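"""Empirical delta-beta cutoffs and DM gene-list construction.

The effect-size cutoff is not fixed a priori: the 2.5% tails of the
observed per-probe delta-beta distribution define negative/positive
cutoffs, and the working symmetric cutoff is their larger magnitude
rounded up to the next 0.01 (tails near -0.046/+0.044 thus yield a
+/- 0.05 working cutoff). Probes passing |delta_beta| >= cutoff and
p <= 1e-3 are annotated to their nearest-TSS gene and deduplicated per
gene into a named list ("LIST-2" style); a stricter list keeps genes whose
maximal supporting-probe |delta_beta| reaches 0.10 ("LIST-3" style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TailCutoffs",
    "GeneList",
    "compute_tail_cutoffs",
    "build_list2",
    "build_list3",
    "intersect_lists",
    "nearest_tss",
]

GENE_LIST_COLUMNS = ["gene_symbol", "direction", "n_supporting_probes",
                     "best_p", "max_abs_delta_beta", "mixed_direction"]


@dataclass(frozen=True)
class TailCutoffs:
    q_low: float
    q_high: float
    recommended_symmetric: float
    tail_fraction: float = 0.025

    def as_dict(self) -> dict:
        return {"q_low": self.q_low, "q_high": self.q_high,
                "recommended_symmetric": self.recommended_symmetric,
                "tail_fraction": self.tail_fraction}


@dataclass
class GeneList:
    """Named, per-gene deduplicated DM gene list.

    ``entries`` has one row per gene (columns ``gene_symbol, direction,
    n_supporting_probes, best_p, max_abs_delta_beta, mixed_direction``);
    ``unassigned`` collects selected probes without a gene symbol.
    """

    name: str
    entries: pd.DataFrame
    unassigned: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["probe_id", "delta_beta", "p_value"]))

    @property
    def symbols(self) -> set:
        return set(self.entries["gene_symbol"])

    def counts(self) -> dict:
        d = self.entries["direction"]
        return {"n_genes": len(self.entries),
                "n_hyper": int((d == "hyper").sum()),
                "n_hypo": int((d == "hypo").sum())}


def _ceil_to_cents(x: float) -> float:
    """Round a magnitude up to the next multiple of 0.01 (0.04612 -> 0.05)."""
    return math.ceil(round(x * 100, 9)) / 100.0


def compute_tail_cutoffs(diff: pd.DataFrame, tail_fraction: float = 0.025
                         ) -> TailCutoffs:
    """Empirical delta-beta quantile cutoffs at ``tail_fraction`` per side.

    Quantiles use linear interpolation of order statistics. Requires at
    least 100 probes — tail quantiles of smaller samples are unstable.
    """
    delta = np.asarray(diff["delta_beta"], dtype=float)
    if len(delta) < 100:
        raise ValueError(
            f"need >= 100 probes for tail cutoffs, got {len(delta)}")
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    q_low = float(np.quantile(delta, tail_fraction))
    q_high = float(np.quantile(delta, 1.0 - tail_fraction))
    rec = _ceil_to_cents(max(abs(q_low), abs(q_high)))
    return TailCutoffs(q_low=q_low, q_high=q_high,
                       recommended_symmetric=rec,
                       tail_fraction=tail_fraction)


def nearest_tss(pos: int, chrom: str, tss_table: pd.DataFrame,
                max_distance: int = 100_000) -> str:
    """Nearest-TSS gene symbol for an arbitrary position.

    ``tss_table`` needs columns gene_symbol/chrom/tss. Ties on distance go
    to the lexicographically smaller symbol; positions whose nearest TSS is
    farther than ``max_distance`` get an empty symbol.
    """
    cand = tss_table[tss_table["chrom"] == chrom]
    if cand.empty:
        return ""
    dist = (cand["tss"] - pos).abs()
    best = dist.min()
    if best > max_distance:
        return ""
    return min(cand.loc[dist == best, "gene_symbol"])


def _assigned_probes(diff: pd.DataFrame, manifest: pd.DataFrame,
                     max_tss_distance: int) -> pd.DataFrame:
    ann = manifest.set_index("probe_id")
    tab = diff.join(ann[["gene_symbol", "tss_distance"]], how="inner").copy()
    too_far = tab["tss_distance"].abs() > max_tss_distance
    tab.loc[too_far, "gene_symbol"] = ""
    return tab


def build_list2(diff: pd.DataFrame, manifest: pd.DataFrame, cutoff: float,
                p_max: float = 1e-3, max_tss_distance: int = 100_000,
                name: str = "LIST2") -> GeneList:
    """Gene list of probes with |delta_beta| >= cutoff and p <= p_max.

    Selected probes are annotated to their nearest-TSS gene and
    deduplicated per gene: the entry keeps the minimum p, the maximum
    |delta_beta| and the supporting-probe count. A gene whose supporting
    probes disagree in direction takes the direction of the probe with the
    largest |delta_beta| and is flagged ``mixed_direction``. Probes with no
    gene assignment go to the ``unassigned`` side table.
    """
    tab = _assigned_probes(diff, manifest, max_tss_distance)
    sel = tab[(tab["delta_beta"].abs() >= cutoff)
              & (tab["p_value"] <= p_max)].copy()
    sel["abs_delta"] = sel["delta_beta"].abs()

    unassigned = sel[sel["gene_symbol"] == ""]
    unassigned = pd.DataFrame({
        "probe_id": unassigned.index,
        "delta_beta": unassigned["delta_beta"].to_numpy(),
        "p_value": unassigned["p_value"].to_numpy(),
    })

    assigned = sel[sel["gene_symbol"] != ""]
    rows = []
    for gene, g in assigned.groupby("gene_symbol", sort=True):
        top = g.loc[g["abs_delta"].idxmax()]
        dirs = set(g["direction"])
        rows.append({
            "gene_symbol": gene,
            "direction": top["direction"],
            "n_supporting_probes": len(g),
            "best_p": float(g["p_value"].min()),
            "max_abs_delta_beta": float(g["abs_delta"].max()),
            "mixed_direction": len(dirs) > 1,
        })
    entries = pd.DataFrame(rows, columns=GENE_LIST_COLUMNS)
    return GeneList(name=name, entries=entries, unassigned=unassigned)


def build_list3(list2: GeneList, cutoff: float = 0.10,
                name: str = "LIST3") -> GeneList:
    """Stricter list: genes whose max supporting |delta_beta| >= cutoff.

    Candidacy (p threshold, delta-beta floor) is inherited from the input
    list, so the result is a subset of it by construction.
    """
    entries = list2.entries[
        list2.entries["max_abs_delta_beta"] >= cutoff].reset_index(drop=True)
    return GeneList(name=name, entries=entries,
                    unassigned=list2.unassigned.iloc[0:0].copy())


def intersect_lists(list_a, list_b) -> tuple[set, dict]:
    """Case-normalized exact-symbol intersection of two gene-symbol sets.

    Accepts :class:`GeneList` objects or plain symbol iterables. Returns
    the overlap (upper-cased symbols) and counts |A|, |B|, |A & B|.
    """
    def norm(x):
        syms = x.symbols if isinstance(x, GeneList) else x
        return {str(s).strip().upper() for s in syms if str(s).strip()}

    a, b = norm(list_a), norm(list_b)
    overlap = a & b
    return overlap, {"n_a": len(a), "n_b": len(b), "n_overlap": len(overlap)}
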