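"""Cluster prioritization of differentially methylated CpGs.

Highly significant "selecting" CpGs (p <= 1e-4) seed clusters; every
significantly DM CpG (p <= 1e-2) of the same direction within +/- 1500 bp
of a seed joins as a member. Seeds whose member sets intersect — including
seeds lying inside each other's windows — merge transitively into one
cluster, which is how clusters accumulate several selecting CpGs and
scores well beyond a single window's probe count. The cluster score is
the number of distinct member probes (seed included), so a seed with one
DM neighbour scores 2. Single-probe "clusters" are not clusters: a seed
with no qualifying neighbour is routed to the isolated list when it
passes the isolated threshold (p <= 1e-3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Cluster",
    "find_clusters",
    "find_isolated",
    "cluster_score_summary",
    "clusters_to_table",
]


@dataclass
class Cluster:
    chrom: str
    start: int                    # 1-based inclusive, min member position
    end: int                      # 1-based inclusive, max member position
    direction: str                # "hyper" or "hypo"
    selecting_probes: frozenset = field(default_factory=frozenset)
    member_probes: frozenset = field(default_factory=frozenset)
    genes: frozenset = field(default_factory=frozenset)

    @property
    def score(self) -> int:
        return len(self.member_probes)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def find_clusters(diff: pd.DataFrame, manifest: pd.DataFrame,
                  p_select: float = 1e-4, p_member: float = 1e-2,
                  window: int = 1500,
                  direction_mode: str = "concordant") -> list[Cluster]:
    """Agglomerate DM CpGs around selecting CpGs within ``+/- window`` bp.

    Parameters
    ----------
    diff
        Differential-test results indexed by probe_id (needs p_value and
        direction columns).
    manifest
        Probe manifest supplying chrom/pos/gene annotation.
    p_select, p_member
        Seed and member p-value thresholds (inclusive). ``p_select`` may
        not exceed ``p_member``.
    window
        Half-width of the member window in bp, inclusive at the boundary.
    direction_mode
        ``"concordant"`` (default) restricts members to the seed's
        direction; ``"any"`` ignores direction (clusters are then split by
        nothing and take the seed's direction label).

    Returns clusters sorted by (chrom, start); every returned cluster has
    score >= 2.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if p_select > p_member:
        raise ValueError("p_select must be <= p_member")
    if direction_mode not in ("concordant", "any"):
        raise ValueError(f"unknown direction_mode {direction_mode!r}")

    ann = manifest.set_index("probe_id")
    tab = diff.join(ann[["chrom", "pos", "gene_symbol"]], how="inner")
    dm = tab[tab["p_value"] <= p_member]

    clusters: list[Cluster] = []
    directions = ("hyper", "hypo") if direction_mode == "concordant" else ("any",)
    for chrom, chrom_dm in dm.groupby("chrom", sort=True):
        for direction in directions:
            cand = (chrom_dm if direction == "any"
                    else chrom_dm[chrom_dm["direction"] == direction])
            if cand.empty:
                continue
            cand = cand.sort_values("pos", kind="mergesort")
            pos = cand["pos"].to_numpy()
            pval = cand["p_value"].to_numpy()
            seed_idx = np.flatnonzero(pval <= p_select)
            if len(seed_idx) == 0:
                continue
            # members per seed: candidates within the closed window
            lo = np.searchsorted(pos, pos[seed_idx] - window, side="left")
            hi = np.searchsorted(pos, pos[seed_idx] + window, side="right")
            member_sets = [frozenset(range(l, h)) for l, h in zip(lo, hi)]
            # transitive merging of seeds with overlapping member sets
            # (a seed inside another seed's window is itself a candidate
            # member, so mutual containment is covered by intersection)
            uf = _UnionFind(len(seed_idx))
            owner: dict[int, int] = {}
            for si, members in enumerate(member_sets):
                for m in members:
                    if m in owner:
                        uf.union(owner[m], si)
                    else:
                        owner[m] = si
            merged: dict[int, set] = {}
            for si, members in enumerate(member_sets):
                merged.setdefault(uf.find(si), set()).update(members)
            seed_of: dict[int, set] = {}
            for si in range(len(seed_idx)):
                seed_of.setdefault(uf.find(si), set()).add(int(seed_idx[si]))
            for root, members in merged.items():
                if len(members) < 2:
                    continue    # lone seed: not a cluster
                rows = cand.iloc[sorted(members)]
                genes = frozenset(g for g in rows["gene_symbol"] if g)
                dir_label = (direction if direction != "any"
                             else cand.iloc[min(seed_of[root])]["direction"])
                clusters.append(Cluster(
                    chrom=chrom,
                    start=int(rows["pos"].min()),
                    end=int(rows["pos"].max()),
                    direction=dir_label,
                    selecting_probes=frozenset(
                        cand.index[sorted(seed_of[root])]),
                    member_probes=frozenset(rows.index),
                    genes=genes,
                ))
    clusters.sort(key=lambda c: (c.chrom, c.start, c.direction))
    return clusters


def find_isolated(diff: pd.DataFrame, manifest: pd.DataFrame,
                  clusters: list[Cluster],
                  p_isolated: float = 1e-3) -> pd.DataFrame:
    """DM CpGs (p <= ``p_isolated``) not belonging to any cluster.

    Returns a table ranked by ascending p-value with island context and
    nearest-gene annotation carried through.
    """
    in_cluster = set()
    for cl in clusters:
        in_cluster.update(cl.member_probes)
    hits = diff[(diff["p_value"] <= p_isolated)
                & ~diff.index.isin(in_cluster)]
    ann = manifest.set_index("probe_id")
    out = pd.DataFrame({
        "probe_id": hits.index,
        "p_value": hits["p_value"].to_numpy(),
        "delta_beta": hits["delta_beta"].to_numpy(),
        "direction": hits["direction"].to_numpy(),
        "island_relation": ann["island_relation"].reindex(hits.index).to_numpy(),
        "gene_symbol": ann["gene_symbol"].reindex(hits.index).to_numpy(),
    })
    return (out.sort_values(["p_value", "probe_id"], kind="mergesort")
               .reset_index(drop=True))


def cluster_score_summary(clusters: list[Cluster]) -> dict:
    """Per-direction score tallies: n(score=2), n(score>=3), median and
    range of the score>=3 subset (None where that subset is empty)."""
    out = {}
    for direction in ("hyper", "hypo"):
        scores = np.array([c.score for c in clusters
                           if c.direction == direction])
        high = scores[scores >= 3]
        out[direction] = {
            "n_score_2": int((scores == 2).sum()),
            "n_score_ge3": int(len(high)),
            "median_score_ge3": float(np.median(high)) if len(high) else None,
            "score_range_ge3": ((int(high.min()), int(high.max()))
                                if len(high) else None),
        }
    return out


def clusters_to_table(clusters: list[Cluster]) -> pd.DataFrame:
    """Long-format member table (one row per member probe) for TSV export."""
    rows = []
    for k, cl in enumerate(clusters):
        for pid in sorted(cl.member_probes):
            rows.append({
                "cluster_id": k,
                "chrom": cl.chrom,
                "start": cl.start,
                "end": cl.end,
                "direction": cl.direction,
                "score": cl.score,
                "probe_id": pid,
                "is_selecting": pid in cl.selecting_probes,
                "genes": ";".join(sorted(cl.genes)),
            })
    cols = ["cluster_id", "chrom", "start", "end", "direction", "score",
            "probe_id", "is_selecting", "genes"]
    return pd.DataFrame(rows, columns=cols)
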