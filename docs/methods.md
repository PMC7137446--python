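# Methods

## Statistical model

Methylation at a CpG is measured as a fraction β ∈ [0,1]. Because β is
bounded and heteroscedastic, hypothesis testing uses the M value
`M = log2(β′/(1−β′))` with `β′ = clip(β, ε, 1−ε)`, ε = 10⁻³. The clipping
margin only affects fully (un)methylated probes; the inverse transform is
exact inside the clipped range. The per-probe statistic is a classical
two-sample t-test on M values — pooled variance by default
(df = n₁+n₂−2), since the small-sample row-wise t-test is the standard
screen in this setting; Welch is available when group variances are
suspect. Effect size is always reported on the β scale
(Δβ = patient minus control group mean) because Δβ is the biologically
interpretable quantity: the approximate fraction of cells that changed
methylation state.

Zero within-group variance is a degenerate case the data cannot inform:
equal means give t = 0, p = 1; unequal means give a sentinel p (smallest
positive float) and a `zero_variance` flag rather than a pretend
inference.

Multiple testing: BH q-values are computed and written with every result,
but tier assignment (high/medium/low at p ≤ 10⁻⁴ / 10⁻³ / 10⁻²) uses the
raw p. The prioritization is an exploratory screen whose stringency comes
from the combination of p-value tiers, spatial clustering and effect-size
cutoffs, not from FDR control; the q-values are there so users can apply
it if they want.

## Cluster scoring

Selecting CpGs (p ≤ 10⁻⁴) seed clusters; same-direction DM CpGs
(p ≤ 10⁻²) within a closed ±1500 bp window join as members; seeds whose
member sets intersect merge transitively (a seed inside another seed's
window is itself a candidate member, so mutual containment is covered by
intersection). The score is the distinct member count, seed included —
calibrated so that "seed + one neighbour" scores 2 — and a lone seed is
not a cluster (it falls through to the isolated list when p ≤ 10⁻³).
Direction concordance inside a cluster is required by default
(`direction_mode="any"` relaxes it): hypo- and hypermethylated runs are
tabulated separately downstream, and a discordant neighbour more likely
reflects a distinct event than the same regional change. Transitive
merging is what lets clusters accumulate several selecting CpGs and
scores far beyond one window's capacity. The implementation
(searchsorted windows + union–find) is tested for exact agreement with a
brute-force all-pairs window scan with transitive closure.

## Empirical Δβ cutoff and gene lists

Rather than imposing a universal effect-size threshold, the 2.5% tails of
the study's own Δβ distribution set the scale of observable effects; the
working symmetric cutoff is `ceil_to_0.01(max(|q2.5|, |q97.5|))`. Gene
lists select probes by `|Δβ| ≥ cutoff` and `p ≤ 10⁻³`, annotate them to
the nearest TSS (capped at 100 kb — distal open-sea probes are left
unassigned rather than attributed to an arbitrary gene; ties break to the
lexicographically smaller symbol for determinism), and deduplicate per
gene keeping min p, max |Δβ| and the supporting-probe count. A gene whose
supporting probes disagree in direction takes the direction of its
largest-|Δβ| probe and carries a `mixed_direction` flag — the upstream
convention leaves this case undefined, so it is surfaced rather than
hidden. The strict list (max |Δβ| ≥ 0.10) inherits its candidacy from the
broad list and is a subset of it by construction; a flag can relax that
inheritance.

## QC

Blacklist flags (common SNP, cross-reactive) are removed first, counted
once per probe with fixed priority SNP > cross-reactive >
reproducibility > missing. The reproducibility filter computes, per
probe, the maximum β range within any technical-replicate set and removes
the probe iff that range exceeds the threshold (default 0.10, strict
inequality — a range of exactly 0.10 is kept). Ranging over designated
replicate sets is the default because only technical replication measures
reproducibility; a "within-group range" mode exists for designs without
replicates, at the cost of also filtering genuine biological variation.

## Synthetic data generator

The generator emulates the features of a 450K-style two-group study that
the pipeline's behaviour depends on, with defaults fixed to the emulated
design (6 HC vs 10 RA; ~1/3 of probes each in island core, shelf/shore,
open sea):

* **Baseline bimodality** — per-probe HC means from a two-component beta
  mixture (modes ≈ 0.1 and 0.9); island cores take the unmethylated
  component with probability 0.85, shelves/shores 0.5, open sea 0.15.
  This reproduces the canonical bimodal β landscape and gives the
  tail-cutoff stage realistic quantile behaviour.
* **Probe spacing** — exponential inter-probe gaps (mean 500 bp), so a
  ±1500 bp window holds a variable, realistic number of probes; gene TSSs
  follow their own exponential process (mean 10 kb) and probes annotate
  to the nearest TSS within 100 kb.
* **Noise** — per-sample β ~ Beta(μφ, (1−μ)φ) with precision φ = 100 by
  default, i.e. a β standard deviation of ≈ 0.05 at μ = 0.5 and ≈ 0.03
  near the modes — the scale typical of bead-array technical + biological
  noise. φ is a free parameter of the generator, not a value estimated
  from any particular dataset.
* **Planted effects** — cluster effects shift the patient-group mean of
  the n probes nearest the anchor (width ≤ 3000 bp keeps them inside one
  ±1500 bp window); isolated effects shift one probe. HC baselines of
  *affected* probes are drawn uniformly from the sub-interval of
  [0.05, 0.95] where the shift fits, so the realized difference equals
  the requested Δβ for |Δβ| ≤ 0.90. This is a deliberate design choice:
  detectable differential methylation presupposes dynamic range at the
  locus, and tying planted effects to feasible baselines makes
  parameter-recovery results measure the detector rather than boundary
  clipping. Larger shifts are clipped into [0.01, 0.99], recorded at
  their realized value in the truth table, and warned about.
* **Replicates** — technical replicates are the parent sample plus
  Gaussian jitter on the M scale (SD 0.15), back-transformed; 2% of
  probes are "poorly reproducible" with jitter SD 1.5. The second
  component is what the reproducibility filter exists to remove and
  yields a removal fraction near 1% at the default threshold, matching
  the sub-percent scale seen on real arrays. Replicates carry their
  parent's group label but only the first sample of each replicate set
  enters the t-tests, so replication never inflates the effective n.
* **Determinism** — all outputs are pure functions of the config
  (including seed); manifest and dataset use independent seeded streams.

What the generator does **not** emulate: probe type I/II chemistry and
dye bias, batch/position effects, cell-composition heterogeneity,
correlated (co-methylated) background beyond planted clusters, missing
values, and SNP-driven trimodality. Passing recovery tests on this
generator therefore shows the pipeline's logic is correct under clean
bimodal noise — not that real-data confounders are handled; on real data
the upstream normalization pipeline is assumed to have dealt with those.

## Numerical conventions

* Quantiles: linear interpolation of order statistics (the numpy
  default), which an independent sort-and-interpolate oracle reproduces
  exactly; ≥ 100 probes are required before tail cutoffs are computed.
* Percentages: round-half-up to 2 decimals via exact decimal arithmetic,
  so formatter output matches hand-computed tables digit for digit.
* Coordinates: 1-based inclusive internally (manifest convention);
  BED exports convert to 0-based half-open.
* Ties: direction at Δβ = 0 is called hypo by a fixed rule and flagged;
  tier boundaries are inclusive upper bounds; isolated CpGs with equal p
  order by probe id.
* Exports carry a deterministic provenance header (tool version + config
  hash, never a timestamp) so fixed-seed runs are byte-identical.

## Problem sizes used in the shipped analyses

The analysis drivers and the acceptance script run at 5,000-probe
(recovery, 20 replicate datasets → 200 planted clusters) and
50,000-probe (null calibration) scales with 6 vs 10 samples — large
enough that binomial intervals around the null DM rate and recovery
rates over 200 clusters are tight, while a full run stays in the
seconds-to-minutes range on one core.

## Known limitations

* The cluster score weights selecting and ordinary members equally; if a
  use case needs seed-weighted scores the `Cluster` object retains both
  sets, but no weighting is built in.
* LIST-style gene lists depend entirely on the manifest's nearest-TSS
  annotation; no transcript-model-aware reannotation is attempted.
* The pipeline requires complete matrices; probes with missing entries
  are dropped (with a count) rather than imputed.
* With no replicate sets the reproducibility filter is a warned no-op in
  its default mode; results then rest on blacklist filtering alone.
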