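"""Synthetic 450K-style methylation data with known planted truth.

The generator emulates the features of promoter-array methylation data that
the downstream prioritization stages depend on:

* a bimodal beta-value background — CpG-island cores are mostly
  unmethylated (mode near 0.1), open-sea probes mostly methylated (mode
  near 0.9), island flanks in between;
* variable probe spacing (exponential inter-probe gaps, mean 500 bp) so a
  +/- 1500 bp window contains a realistic, variable number of probes;
* a small two-group design (default 6 healthy controls vs 10 patients);
* planted differential effects — clusters of neighbouring affected probes
  and isolated single probes — recorded in a truth table for
  parameter-recovery testing;
* technical replicate sets (parent sample + jitter on the M scale) so the
  reproducibility filter has a meaningful target.

Every output is a deterministic function of the :class:`SimConfig`
(including its seed).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import beta_to_m, m_to_beta, validate_manifest

__all__ = [
    "BetaMixture",
    "PlantedEffect",
    "SimConfig",
    "generate_manifest",
    "generate_dataset",
    "random_planted_clusters",
    "EFFECT_KINDS",
]

EFFECT_KINDS = ("none", "cluster_member", "cluster_anchor", "isolated")

# Mean-mu clip so beta-noise parameters a = mu*phi, b = (1-mu)*phi stay sane.
_MU_CLIP = (0.01, 0.99)
# Feasibility margin for planted shifts: both group means kept in this band
# when possible, so the realized difference equals the requested one.
_EFFECT_MARGIN = 0.05


@dataclass(frozen=True)
class BetaMixture:
    """Two-component beta mixture for baseline (HC) probe means.

    ``a_unmeth/b_unmeth`` parameterize the unmethylated mode (default mode
    0.1), ``a_meth/b_meth`` the methylated mode (default mode 0.9).
    ``weight_unmeth`` maps each island relation to the probability of the
    unmethylated component: island cores are biased unmethylated, open sea
    methylated.
    """

    a_unmeth: float = 3.0
    b_unmeth: float = 19.0
    a_meth: float = 19.0
    b_meth: float = 3.0
    weight_unmeth: dict = field(default_factory=lambda: {
        "core": 0.85, "shelf_shore": 0.50, "open_sea": 0.15})


@dataclass(frozen=True)
class PlantedEffect:
    """One planted differential-methylation effect (patient minus control).

    ``direction`` must match the sign of ``delta_beta`` (``hyper`` for
    positive shifts in the patient group). For cluster effects ``width``
    may not exceed 3000 bp so all affected probes fall inside a +/- 1500 bp
    window around the anchor.
    """

    chromosome: str
    anchor_position: int
    width: int
    n_affected_probes: int
    delta_beta: float
    direction: str

    def __post_init__(self):
        if abs(self.delta_beta) > 1:
            raise ValueError("|delta_beta| must be <= 1")
        if self.delta_beta == 0:
            raise ValueError("planted delta_beta must be non-zero")
        want = "hyper" if self.delta_beta > 0 else "hypo"
        if self.direction != want:
            raise ValueError(
                f"direction {self.direction!r} does not match sign of "
                f"delta_beta {self.delta_beta}")
        if self.n_affected_probes < 1:
            raise ValueError("n_affected_probes must be >= 1")
        if self.n_affected_probes > 1 and self.width > 3000:
            raise ValueError("cluster width must be <= 3000 bp")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic methylation study.

    Defaults encode the emulated study design: 6 HC vs 10 RA samples on a
    450K-style promoter array with roughly one third of probes in island
    cores, one third on shelves/shores and one third in open sea.
    """

    n_chromosomes: int = 2
    probes_per_chromosome: int = 5000
    island_fraction: float = 0.34
    shelf_shore_fraction: float = 0.33
    n_hc: int = 6
    n_ra: int = 10
    n_replicate_sets: int = 2
    baseline_mix: BetaMixture = field(default_factory=BetaMixture)
    noise_precision: float = 100.0
    planted_clusters: tuple = ()
    planted_isolated: tuple = ()
    seed: int = 0
    # plumbing parameters (not part of the emulated design)
    mean_probe_gap: float = 500.0
    mean_gene_gap: float = 10_000.0
    snp_fraction: float = 0.01
    crossreactive_fraction: float = 0.01
    replicate_jitter_sd: float = 0.15   # SD of technical jitter on M scale
    poor_probe_fraction: float = 0.02   # probes with unstable measurements
    poor_probe_jitter_sd: float = 1.5   # their (much larger) M-scale jitter
    max_tss_distance: int = 100_000
    cell_type: str = "naive_cd4"

    def __post_init__(self):
        for name in ("n_chromosomes", "probes_per_chromosome", "n_hc", "n_ra"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_replicate_sets < 0:
            raise ValueError("n_replicate_sets must be >= 0")
        if not 0 <= self.island_fraction <= 1:
            raise ValueError("island_fraction must be in [0, 1]")
        if not 0 <= self.shelf_shore_fraction <= 1:
            raise ValueError("shelf_shore_fraction must be in [0, 1]")
        if self.island_fraction + self.shelf_shore_fraction > 1:
            raise ValueError("island_fraction + shelf_shore_fraction > 1")
        if self.noise_precision <= 0:
            raise ValueError("noise_precision must be > 0")
        if self.n_replicate_sets > self.n_hc + self.n_ra:
            raise ValueError("more replicate sets than samples")
        object.__setattr__(self, "planted_clusters",
                           tuple(self.planted_clusters))
        object.__setattr__(self, "planted_isolated",
                           tuple(self.planted_isolated))
        for eff in self.planted_isolated:
            if eff.n_affected_probes != 1:
                raise ValueError("isolated effects must affect exactly 1 probe")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng([int(config.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def generate_manifest(config: SimConfig) -> pd.DataFrame:
    """Generate a probe manifest: positions, island relation, nearest gene.

    Probe positions follow exponential inter-probe gaps (strictly
    increasing); island relation is drawn i.i.d. per probe with
    probabilities (island_fraction, shelf_shore_fraction, remainder); gene
    transcription start sites form their own exponential-gap process and
    each probe is annotated with the nearest TSS within
    ``max_tss_distance`` (empty symbol beyond that).
    """
    rng = _rng(config, 0)
    rows = []
    rel_p = [config.island_fraction, config.shelf_shore_fraction,
             1.0 - config.island_fraction - config.shelf_shore_fraction]
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n = config.probes_per_chromosome
        gaps = 1 + np.floor(rng.exponential(config.mean_probe_gap, n)).astype(np.int64)
        pos = np.cumsum(gaps)
        relation = rng.choice(np.array(["core", "shelf_shore", "open_sea"]),
                              size=n, p=rel_p)
        # gene TSS process covering the chromosome span
        span = int(pos[-1]) + int(config.mean_gene_gap)
        n_genes = max(2, int(np.ceil(span / config.mean_gene_gap * 1.5)))
        tss_gaps = rng.exponential(config.mean_gene_gap, n_genes)
        tss = np.cumsum(1 + np.floor(tss_gaps)).astype(np.int64)
        tss = tss[tss <= span + config.mean_gene_gap]
        if len(tss) == 0:
            tss = np.array([span // 2], dtype=np.int64)
        symbols = np.array([f"G{ci + 1}_{k:04d}" for k in range(len(tss))])
        gene_symbol, tss_distance = _nearest_tss(pos, tss, symbols,
                                                 config.max_tss_distance)
        flag_snp = rng.random(n) < config.snp_fraction
        flag_cross = rng.random(n) < config.crossreactive_fraction
        rows.append(pd.DataFrame({
            "probe_id": [f"cg_{chrom}_{p:09d}" for p in pos],
            "chrom": chrom,
            "pos": pos,
            "island_relation": relation,
            "gene_symbol": gene_symbol,
            "tss_distance": tss_distance,
            "flag_snp": flag_snp,
            "flag_crossreactive": flag_cross,
        }))
    return validate_manifest(pd.concat(rows, ignore_index=True))


def _nearest_tss(pos: np.ndarray, tss: np.ndarray, symbols: np.ndarray,
                 max_distance: int):
    """Nearest-TSS annotation; ties broken by lexicographically smaller symbol."""
    order = np.argsort(tss, kind="mergesort")
    tss = tss[order]
    symbols = symbols[order]
    idx = np.searchsorted(tss, pos)
    left = np.clip(idx - 1, 0, len(tss) - 1)
    right = np.clip(idx, 0, len(tss) - 1)
    d_left = np.abs(pos - tss[left])
    d_right = np.abs(pos - tss[right])
    use_left = (d_left < d_right) | (
        (d_left == d_right) & (symbols[left] <= symbols[right]))
    best = np.where(use_left, left, right)
    dist = (pos - tss[best]).astype(np.int64)   # signed: probe minus TSS
    sym = symbols[best].astype(object)
    too_far = np.abs(dist) > max_distance
    sym[too_far] = ""
    return sym, dist


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def _affected_probe_indices(manifest: pd.DataFrame, eff: PlantedEffect):
    """Indices (manifest row order) of the probes an effect lands on.

    Candidates are probes on the effect's chromosome within width/2 of the
    anchor; the ``n_affected_probes`` closest to the anchor are taken. The
    single closest probe is the anchor probe.
    """
    on_chrom = manifest.index[manifest["chrom"] == eff.chromosome]
    if len(on_chrom) == 0:
        return np.array([], dtype=int), -1
    pos = manifest.loc[on_chrom, "pos"].to_numpy()
    half = max(eff.width / 2.0, 0.0)
    inside = np.abs(pos - eff.anchor_position) <= half
    cand = np.asarray(on_chrom)[inside]
    if len(cand) == 0:
        return np.array([], dtype=int), -1
    dist = np.abs(manifest.loc[cand, "pos"].to_numpy() - eff.anchor_position)
    take = np.asarray(cand)[np.argsort(dist, kind="mergesort")][:eff.n_affected_probes]
    anchor = take[0]
    return np.sort(take), anchor


def generate_dataset(config: SimConfig, manifest: pd.DataFrame):
    """Generate (beta matrix, sample sheet, truth table) for a config.

    HC baseline means for unaffected probes come from the bimodal mixture;
    probes carrying a planted effect get a baseline drawn uniformly from
    the sub-interval of [0.05, 0.95] where the shift fits, so the realized
    group difference equals the requested delta_beta whenever
    |delta_beta| <= 0.90 (larger shifts are clipped, recorded as realized
    in the truth table, and warned about). Per-sample beta values follow a
    beta distribution re-parameterized by (group mean, noise_precision).
    """
    rng = _rng(config, 1)
    n_probes = len(manifest)
    mix = config.baseline_mix

    # baseline HC means from the bimodal mixture
    w = manifest["island_relation"].map(mix.weight_unmeth).to_numpy(dtype=float)
    take_unmeth = rng.random(n_probes) < w
    mu_hc = np.where(
        take_unmeth,
        rng.beta(mix.a_unmeth, mix.b_unmeth, n_probes),
        rng.beta(mix.a_meth, mix.b_meth, n_probes))
    mu_hc = np.clip(mu_hc, *_MU_CLIP)

    true_delta = np.zeros(n_probes)
    effect_kind = np.full(n_probes, "none", dtype=object)
    effect_id = np.full(n_probes, "", dtype=object)

    for k, (eff, is_cluster) in enumerate(
            [(e, True) for e in config.planted_clusters]
            + [(e, False) for e in config.planted_isolated]):
        idx, anchor = _affected_probe_indices(manifest, eff)
        if len(idx) == 0:
            warnings.warn(
                f"planted effect at {eff.chromosome}:{eff.anchor_position} "
                "covers no probes; skipped")
            continue
        if len(idx) < eff.n_affected_probes:
            warnings.warn(
                f"planted effect at {eff.chromosome}:{eff.anchor_position} "
                f"covers only {len(idx)}/{eff.n_affected_probes} probes")
        lo = max(_EFFECT_MARGIN, _EFFECT_MARGIN - eff.delta_beta)
        hi = min(1 - _EFFECT_MARGIN, 1 - _EFFECT_MARGIN - eff.delta_beta)
        if lo < hi:
            mu_hc[idx] = rng.uniform(lo, hi, len(idx))
        else:   # shift too large to fit: centre it and accept truncation
            mu_hc[idx] = np.clip(0.5 - eff.delta_beta / 2, *_MU_CLIP)
        mu_ra_eff = np.clip(mu_hc[idx] + eff.delta_beta, *_MU_CLIP)
        realized = mu_ra_eff - mu_hc[idx]
        if np.any(np.abs(realized - eff.delta_beta) > 1e-12):
            warnings.warn(
                f"planted delta_beta {eff.delta_beta} truncated by the "
                "[0, 1] range; truth table records the realized value")
        true_delta[idx] = realized
        effect_id[idx] = f"c{k}" if is_cluster else f"i{k}"
        if is_cluster:
            effect_kind[idx] = "cluster_member"
            effect_kind[anchor] = "cluster_anchor"
        else:
            effect_kind[idx] = "isolated"

    mu_ra = np.clip(mu_hc + true_delta, *_MU_CLIP)

    # per-sample draws: Beta(mu * phi, (1 - mu) * phi)
    phi = config.noise_precision
    sample_ids, groups, rep_ids = [], [], []
    columns = {}
    for g, n, mu in (("HC", config.n_hc, mu_hc), ("RA", config.n_ra, mu_ra)):
        for k in range(n):
            sid = f"{g}{k + 1:02d}"
            columns[sid] = rng.beta(mu * phi, (1 - mu) * phi)
            sample_ids.append(sid)
            groups.append(g)
            rep_ids.append("")

    # technical replicate sets: parent + one jittered copy each. A small
    # fraction of probes is "poorly reproducible" (much larger technical
    # jitter) — the population the reproducibility filter exists to remove.
    poor = rng.random(n_probes) < config.poor_probe_fraction
    jitter_sd = np.where(poor, config.poor_probe_jitter_sd,
                         config.replicate_jitter_sd)
    parents = sample_ids[:config.n_replicate_sets]
    for j, parent in enumerate(parents):
        set_id = f"rep{j + 1}"
        rep_ids[sample_ids.index(parent)] = set_id
        sid = f"{parent}r"
        m = beta_to_m(columns[parent]) + rng.normal(0.0, 1.0, n_probes) * jitter_sd
        columns[sid] = m_to_beta(m)
        sample_ids.append(sid)
        groups.append(parent[:2])
        rep_ids.append(set_id)

    matrix = pd.DataFrame(columns, index=pd.Index(manifest["probe_id"],
                                                  name="probe_id"))
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "group": groups,
        "cell_type": config.cell_type,
        "replicate_set": rep_ids,
    })
    truth = pd.DataFrame({
        "probe_id": manifest["probe_id"].to_numpy(),
        "true_delta_beta": true_delta,
        "effect_kind": effect_kind,
        "effect_id": effect_id,
    })
    return matrix, sheet, truth


# ---------------------------------------------------------------------------
# convenience: random non-overlapping planted clusters
# ---------------------------------------------------------------------------

def random_planted_clusters(manifest: pd.DataFrame, n_clusters: int,
                            n_probes: int, delta_beta: float, seed: int,
                            width: int = 2500,
                            min_separation: int = 20_000) -> tuple:
    """Place ``n_clusters`` non-overlapping cluster effects at real probe
    positions, anchored at probes with at least ``n_probes`` neighbours
    inside the window. Returns a tuple of :class:`PlantedEffect`.
    """
    rng = np.random.default_rng(int(seed) % (2**31))
    direction = "hyper" if delta_beta > 0 else "hypo"
    effects = []
    used = {}   # chrom -> list of anchor positions
    order = rng.permutation(len(manifest))
    pos_by_chrom = {c: g["pos"].to_numpy()
                    for c, g in manifest.groupby("chrom")}
    for i in order:
        if len(effects) >= n_clusters:
            break
        chrom = manifest["chrom"].iat[i]
        anchor = int(manifest["pos"].iat[i])
        pos = pos_by_chrom[chrom]
        if np.sum(np.abs(pos - anchor) <= width / 2) < n_probes:
            continue
        if any(abs(anchor - a) < min_separation for a in used.get(chrom, ())):
            continue
        used.setdefault(chrom, []).append(anchor)
        effects.append(PlantedEffect(
            chromosome=chrom, anchor_position=anchor, width=width,
            n_affected_probes=n_probes, delta_beta=delta_beta,
            direction=direction))
    if len(effects) < n_clusters:
        warnings.warn(
            f"placed only {len(effects)}/{n_clusters} planted clusters")
    return tuple(effects)
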