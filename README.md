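# dmcpg — differential CpG methylation prioritization

`dmcpg` implements an effect-size-aware prioritization pipeline for
two-group CpG methylation array studies (450K-style promoter arrays), of
the kind used to compare immune-cell subsets between healthy controls (HC)
and patients (here labelled RA). It is aimed at epigenomics analysts who
have a normalized β-value matrix, a probe manifest and a small two-group
design, and who need ranked, annotated lists of differentially methylated
(DM) CpGs, CpG clusters and genes — together with a synthetic-data
generator that plants known effects so every stage can be validated by
parameter recovery.

## The method

For probe *j* with methylation fraction (β value) `β_j ∈ [0,1]`, testing is
done on the M value `M = log2(β/(1−β))` (β clipped to `[ε, 1−ε]`,
ε = 10⁻³). Per probe:

* **Test** — two-sided pooled-variance t-test of M values, HC vs RA
  (Welch optional); effect size `Δβ = mean β(RA) − mean β(HC)`, so Δβ > 0
  means hypermethylation in RA. Benjamini–Hochberg q-values are reported
  but tiers use the raw p — the screen is deliberately exploratory.
* **Tiers** — high `p ≤ 10⁻⁴`, medium `10⁻⁴ < p ≤ 10⁻³`, low
  `10⁻³ < p ≤ 10⁻²`; a probe is DM iff `p ≤ 0.01`.
* **Clusters** — each highly significant "selecting" CpG (`p ≤ 10⁻⁴`)
  collects same-direction DM CpGs (`p ≤ 10⁻²`) within ±1500 bp; seeds
  whose member sets intersect merge transitively. The cluster **score** is
  the number of distinct member CpGs (a seed with one DM neighbour scores
  2). DM CpGs at `p ≤ 10⁻³` outside every cluster form the isolated list,
  ranked by p.
* **Empirical cutoff** — the 2.5%/97.5% quantiles of the observed Δβ
  distribution define a data-driven effect-size threshold; the working
  symmetric cutoff is their larger magnitude rounded up to the next 0.01
  (e.g. tails at −0.046/+0.044 → ±0.05).
* **Gene lists** — probes with `|Δβ| ≥ cutoff` and `p ≤ 10⁻³` are annotated
  to the nearest transcription start site and deduplicated per gene
  (min p, max |Δβ|, probe count); a stricter list keeps genes whose best
  probe reaches `|Δβ| ≥ 0.10`. Symbol-set intersection with external gene
  lists (e.g. differentially expressed genes) is built in.

Before any statistics, probes flagged as common SNPs or cross-reactive are
removed, and a reproducibility filter drops probes whose β range across
technical replicates exceeds 0.10.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data with planted truth (outputs land under `results/`):

```
python analysis/01_simulate.py
python analysis/02_qc.py
python analysis/03_differential.py
python analysis/04_clusters.py
python analysis/05_thresholds_lists.py
python analysis/06_report.py
```

`01` plants twelve 5-probe DM clusters (six hypo-, six hypermethylated,
|Δβ| = 0.15) and eight isolated DM CpGs into a 5,000-probe, 6 HC vs 10 RA
array with two technical replicate sets. The drivers then print, among
other things:

```
input 5000 probes: removed 41 SNP, 37 cross-reactive, 53 poorly reproducible
tested 4869 probes: 116 DM at p <= 0.01 (2.38%)
13 clusters, 12 isolated DM CpGs
planted-cluster recovery: 12/12 detected, 1 detected clusters contain no planted probe
delta-beta 2.5%/97.5% quantiles: -0.03675 / +0.03871 -> working cutoff +/- 0.04
LIST2: 24 genes (11 hypo, 13 hyper)   LIST3: 19 genes (9 hypo, 10 hyper)
LIST2 vs planted truth genes: 20/21 recovered
```

Reading this: QC retains 4,869/5,000 probes; 2.38% of probes are DM (the
excess over the 1% null rate is the planted signal); all 12 planted
clusters are found (one extra cluster is a chance aggregation of null
probes); the empirical tails recommend a ±0.04 cutoff on this dataset's
noise level; and the strict gene list recovers 19 of the 21 genes nearest
to planted probes with no false genes.

Equivalent one-shot run via the CLI: `dmcpg run --outdir out --seed 7`
(subcommands `simulate`, `qc`, `difftest`, `clusters`, `lists`, `report`
expose the individual stages).

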