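"""Summary tables and the end-to-end pipeline driver.

The summary mirrors the canonical per-cell-type report of this kind of
study: DM counts with percentages of probes tested, tier counts as
percentages of DM probes, island-context and direction breakdowns of DM
probes, island-by-direction counts as percentages of the p <= 1e-3
subset, cluster score tallies, gene counts and isolated-CpG tallies.
All percentages are round-half-up to two decimals.
"""

from __future__ import annotations

import decimal
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clusters as _clusters
from . import differential as _diff
from . import io as _io
from . import lists as _lists
from . import qc as _qc
from . import simulate as _sim

__all__ = ["percent", "summarize", "format_summary",
           "PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


def percent(a: int | float, b: int | float) -> float:
    """``100 * a / b`` rounded half-up to 2 decimals; 0.0 when b == 0."""
    if b == 0:
        return 0.0
    a = int(a) if float(a).is_integer() else float(a)
    b = int(b) if float(b).is_integer() else float(b)
    frac = decimal.Decimal(a) * 100 / decimal.Decimal(b)
    return float(frac.quantize(decimal.Decimal("0.01"),
                               rounding=decimal.ROUND_HALF_UP))


def _n_pct(n: int, denom: int) -> dict:
    return {"n": int(n), "pct": percent(n, denom)}


def summarize(diff: pd.DataFrame, clusters: list, isolated: pd.DataFrame,
              genelists: dict | None = None,
              manifest: pd.DataFrame | None = None,
              qc_report=None) -> dict:
    """Build the per-run summary dictionary.

    Percentages use two denominators: the DM count (p <= 0.01) for tier /
    island-context / direction rows, and the p <= 1e-3 count for the
    island-by-direction rows — the two reference populations of this style
    of report.
    """
    if manifest is not None:
        missing = diff.index.difference(manifest["probe_id"])
        if len(missing):
            raise ValueError(
                f"probe universe mismatch: {missing[0]!r} not in manifest")
        rel = manifest.set_index("probe_id")["island_relation"]
        island = rel.reindex(diff.index)
    else:
        island = None

    n_tested = len(diff)
    p = diff["p_value"]
    dm = diff[p <= _diff.P_DM]
    n_dm = len(dm)
    strong = diff[p <= 1e-3]
    n_strong = len(strong)

    tiers = {t: _n_pct((dm["tier"] == t).sum(), n_dm)
             for t in ("high", "medium", "low")}
    direction = {d: _n_pct((dm["direction"] == d).sum(), n_dm)
                 for d in ("hyper", "hypo")}

    out = {
        "n_tested": int(n_tested),
        "dm": _n_pct(n_dm, n_tested),
        "tiers": tiers,
        "direction": direction,
        "n_p_le_1e3": int(n_strong),
    }

    if island is not None:
        dm_island = island.loc[dm.index]
        out["island_context"] = {
            rel: _n_pct((dm_island == rel).sum(), n_dm)
            for rel in _io.ISLAND_RELATIONS}
        # island vs open sea, split by direction, % of p <= 1e-3 probes
        strong_island = island.loc[strong.index]
        in_island = strong_island.isin(("core", "shelf_shore"))
        by_dir = {}
        for ctx, mask in (("island_shelf_shore", in_island),
                          ("open_sea", ~in_island)):
            by_dir[ctx] = {
                d: _n_pct(((strong["direction"] == d) & mask).sum(), n_strong)
                for d in ("hyper", "hypo")}
        out["island_by_direction"] = by_dir

    out["clusters"] = _clusters.cluster_score_summary(clusters)

    cluster_genes = {"hyper": set(), "hypo": set()}
    for cl in clusters:
        cluster_genes[cl.direction].update(cl.genes)
    out["cluster_genes"] = {d: len(cluster_genes[d]) for d in ("hyper", "hypo")}

    iso = {}
    if len(isolated):
        iso_island = isolated["island_relation"].isin(("core", "shelf_shore"))
        for ctx, mask in (("island_shelf_shore", iso_island),
                          ("open_sea", ~iso_island)):
            iso[ctx] = {
                d: int(((isolated["direction"] == d) & mask).sum())
                for d in ("hyper", "hypo")}
    else:
        iso = {ctx: {"hyper": 0, "hypo": 0}
               for ctx in ("island_shelf_shore", "open_sea")}
    out["isolated"] = iso

    if genelists:
        out["gene_lists"] = {name: gl.counts()
                             for name, gl in genelists.items()}
    if qc_report is not None:
        out["qc"] = qc_report.as_dict()
    return out


def format_summary(summary: dict) -> str:
    """Human-readable text table mirroring the canonical report row order."""
    L = []
    add = L.append
    add(f"Probes tested                          {summary['n_tested']}")
    add(f"DM (p <= 0.01)                         "
        f"{summary['dm']['n']} ({summary['dm']['pct']:.2f}%)")
    add("Significance tiers (% of DM)")
    for t, label in (("high", "high   (p <= 1e-4)"),
                     ("medium", "medium (1e-4 < p <= 1e-3)"),
                     ("low", "low    (1e-3 < p <= 1e-2)")):
        c = summary["tiers"][t]
        add(f"  {label:36s} {c['n']} ({c['pct']:.2f}%)")
    if "island_context" in summary:
        add("Island context of DM probes (% of DM)")
        for rel, label in (("core", "Core island"),
                           ("shelf_shore", "Shelves/shore island"),
                           ("open_sea", "Outside of CpG island")):
            c = summary["island_context"][rel]
            add(f"  {label:36s} {c['n']} ({c['pct']:.2f}%)")
    add("Direction (% of DM)")
    for d, label in (("hyper", "Hypermethylation in RA"),
                     ("hypo", "Hypomethylation in RA")):
        c = summary["direction"][d]
        add(f"  {label:36s} {c['n']} ({c['pct']:.2f}%)")
    if "island_by_direction" in summary:
        add("Island context x direction (% of p <= 1e-3)")
        for ctx, label in (("island_shelf_shore", "Island/shelve/shore"),
                           ("open_sea", "Open sea")):
            for d in ("hyper", "hypo"):
                c = summary["island_by_direction"][ctx][d]
                add(f"  {label + ' ' + d:36s} {c['n']} ({c['pct']:.2f}%)")
    add("DM CpG clusters")
    for d in ("hyper", "hypo"):
        c = summary["clusters"][d]
        med = c["median_score_ge3"]
        rng = c["score_range_ge3"]
        rng_s = f"{med} ({rng[0]}-{rng[1]})" if rng else "NA"
        add(f"  {d:6s} score=2: {c['n_score_2']}  score>=3: "
            f"{c['n_score_ge3']}  median (range): {rng_s}")
    add("Cluster genes")
    for d in ("hyper", "hypo"):
        add(f"  {d:6s} {summary['cluster_genes'][d]}")
    add("Isolated DM CpGs")
    for ctx, label in (("island_shelf_shore", "Island/shelve/shore"),
                       ("open_sea", "Open sea")):
        for d in ("hyper", "hypo"):
            add(f"  {label + ' ' + d:36s} {summary['isolated'][ctx][d]}")
    return "\n".join(L) + "\n"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One structured configuration for the whole pipeline.

    ``cutoff="auto"`` selects the delta-beta cutoff from the empirical
    2.5% tails; a float fixes it.
    """

    sim: _sim.SimConfig = field(default_factory=_sim.SimConfig)
    qc_threshold: float = 0.10
    qc_mode: str = "replicate"
    variance_mode: str = "pooled"
    epsilon: float = 1e-3
    p_select: float = 1e-4
    p_member: float = 1e-2
    p_isolated: float = 1e-3
    window: int = 1500
    cutoff: float | str = "auto"
    p_max: float = 1e-3
    list3_cutoff: float = 0.10
    tail_fraction: float = 0.025

    def validate(self) -> None:
        if self.p_select > self.p_member:
            raise ValueError(
                f"p_select ({self.p_select}) must be <= p_member "
                f"({self.p_member})")
        if not 0 < self.qc_threshold <= 1:
            raise ValueError("qc_threshold must be in (0, 1]")
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if isinstance(self.cutoff, str) and self.cutoff != "auto":
            raise ValueError(f"cutoff must be 'auto' or a float, "
                             f"got {self.cutoff!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        mix_raw = sim_raw.pop("baseline_mix", None)
        planted = {
            key: tuple(_sim.PlantedEffect(**e)
                       for e in sim_raw.pop(key, []) or [])
            for key in ("planted_clusters", "planted_isolated")}
        sim = _sim.SimConfig(
            **sim_raw, **planted,
            **({"baseline_mix": _sim.BetaMixture(**mix_raw)}
               if mix_raw else {}))
        cfg = cls(sim=sim, **raw)
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig, outdir,
                 manifest: pd.DataFrame | None = None,
                 matrix: pd.DataFrame | None = None,
                 samplesheet: pd.DataFrame | None = None) -> dict:
    """Run qc -> difftest -> clusters -> cutoffs -> lists -> summarize.

    When no real data is supplied the synthetic generator provides
    manifest, matrix and sample sheet (and a truth table, also written).
    All artifacts land in ``outdir`` with deterministic provenance
    headers; a fixed-seed run is byte-identical across invocations.
    Returns the in-memory artifacts keyed by stage name.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.sim.config_hash()

    stage = "simulate"
    try:
        truth = None
        if manifest is None:
            manifest = _sim.generate_manifest(config.sim)
            matrix, samplesheet, truth = _sim.generate_dataset(
                config.sim, manifest)
            _io.write_manifest(manifest, outdir / "manifest.tsv", chash)
            _io.write_matrix(matrix, outdir / "beta.tsv", chash)
            _io.write_samplesheet(samplesheet, outdir / "samples.csv", chash)
            _io._write_table(truth, outdir / "truth.tsv", "\t", chash)

        stage = "qc"
        filtered, qc_report, removed_rep = _qc.run_qc(
            matrix, manifest, samplesheet,
            threshold=config.qc_threshold, mode=config.qc_mode)
        _io.export_summary_json(qc_report.as_dict(),
                                outdir / "qc_report.json", chash)
        pd.Series(removed_rep, name="probe_id").to_csv(
            outdir / "removed_probes.tsv", sep="\t", index=False)

        stage = "difftest"
        diff = _diff.ttest_per_probe(filtered, samplesheet,
                                     variance_mode=config.variance_mode,
                                     epsilon=config.epsilon)
        _io._write_table(diff.reset_index(), outdir / "diff.tsv", "\t", chash)

        stage = "clusters"
        cls = _clusters.find_clusters(
            diff, manifest, p_select=config.p_select,
            p_member=config.p_member, window=config.window)
        iso = _clusters.find_isolated(diff, manifest, cls,
                                      p_isolated=config.p_isolated)
        _io.export_clusters_bed(cls, outdir / "clusters.bed", chash)
        _io._write_table(_clusters.clusters_to_table(cls),
                         outdir / "clusters.tsv", "\t", chash)
        _io._write_table(iso, outdir / "isolated.tsv", "\t", chash)

        stage = "cutoffs"
        cutoffs = _lists.compute_tail_cutoffs(diff, config.tail_fraction)
        _io.export_summary_json(cutoffs.as_dict(),
                                outdir / "cutoffs.json", chash)
        cutoff = (cutoffs.recommended_symmetric
                  if config.cutoff == "auto" else float(config.cutoff))

        stage = "lists"
        list2 = _lists.build_list2(diff, manifest, cutoff,
                                   p_max=config.p_max, name="LIST2")
        list3 = _lists.build_list3(list2, cutoff=config.list3_cutoff,
                                   name="LIST3")
        for gl in (list2, list3):
            _io._write_table(gl.entries,
                             outdir / f"{gl.name.lower()}.tsv", "\t", chash)

        stage = "summarize"
        summary = summarize(diff, cls, iso,
                            genelists={"LIST2": list2, "LIST3": list3},
                            manifest=manifest, qc_report=qc_report)
        _io.export_summary_json(summary, outdir / "summary.json", chash)
        (outdir / "summary.txt").write_text(
            _io.provenance_header(chash) + "\n" + format_summary(summary))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    logger.info("pipeline complete: %d probes tested, %d clusters",
                len(diff), len(cls))
    return {"manifest": manifest, "matrix": matrix,
            "samplesheet": samplesheet, "truth": truth,
            "qc_report": qc_report, "diff": diff, "clusters": cls,
            "isolated": iso, "cutoffs": cutoffs, "cutoff_used": cutoff,
            "list2": list2, "list3": list3, "summary": summary}
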