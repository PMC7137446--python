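"""Build the synthetic methylation study used by the downstream analyses.

Emulates the study design: 6 healthy controls vs 10 patients on a
450K-style promoter array (2 chromosomes x 2,500 probes here), with two
technical replicate sets, twelve planted 5-probe DM clusters (six
hypomethylated, six hypermethylated, |delta-beta| = 0.15) and eight
isolated DM CpGs (|delta-beta| = 0.12). Writes manifest, beta matrix,
sample sheet and the planted-truth table under results/data/.
"""

import dataclasses
import pathlib

from dmcpg import io
from dmcpg.simulate import (
    PlantedEffect, SimConfig, generate_dataset, generate_manifest,
    random_planted_clusters,
)

SEED = 20260930
OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    base = SimConfig(n_chromosomes=2, probes_per_chromosome=2500,
                     n_replicate_sets=2, seed=SEED)
    manifest = generate_manifest(base)

    hypo = random_planted_clusters(manifest, 6, 5, -0.15, seed=SEED + 1)
    hyper = random_planted_clusters(manifest, 6, 5, +0.15, seed=SEED + 2,
                                    min_separation=40_000)
    taken = {(e.chromosome, e.anchor_position) for e in hypo}
    hyper = tuple(e for e in hyper
                  if all(e.chromosome != c or abs(e.anchor_position - a) > 20_000
                         for c, a in taken))
    # isolated DM CpGs at probes far from the clusters
    iso = []
    rows = manifest.sample(n=200, random_state=SEED + 3)
    for _, r in rows.iterrows():
        if len(iso) >= 8:
            break
        if all(e.chromosome != r["chrom"]
               or abs(e.anchor_position - r["pos"]) > 20_000
               for e in hypo + hyper + tuple(iso)):
            delta = -0.12 if len(iso) % 2 == 0 else 0.12
            iso.append(PlantedEffect(
                chromosome=r["chrom"], anchor_position=int(r["pos"]),
                width=10, n_affected_probes=1, delta_beta=delta,
                direction="hypo" if delta < 0 else "hyper"))

    cfg = dataclasses.replace(base, planted_clusters=hypo + hyper,
                              planted_isolated=tuple(iso))
    matrix, sheet, truth = generate_dataset(cfg, manifest)
    chash = cfg.config_hash()
    io.write_manifest(manifest, OUT / "manifest.tsv", chash)
    io.write_matrix(matrix, OUT / "beta.tsv", chash)
    io.write_samplesheet(sheet, OUT / "samples.csv", chash)
    io._write_table(truth, OUT / "truth.tsv", "\t", chash)

    n_aff = (truth["effect_kind"] != "none").sum()
    print(f"wrote {len(manifest)} probes x {matrix.shape[1]} samples "
          f"({sheet['group'].eq('HC').sum()} HC, "
          f"{sheet['group'].eq('RA').sum()} RA incl. replicates)")
    print(f"planted: {len(hypo)} hypo + {len(hyper)} hyper clusters, "
          f"{len(iso)} isolated CpGs -> {n_aff} affected probes")


if __name__ == "__main__":
    main()
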