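"""Per-CpG differential testing: pooled t-tests on M values, HC vs RA.

Technical replicates are excluded from testing. Writes the per-probe
result table plus Manhattan- and volcano-plot data under
results/differential/, and prints the DM tally by significance tier.
"""

import pathlib

from dmcpg import io
from dmcpg.differential import (
    manhattan_data, ttest_per_probe, volcano_data,
)

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    manifest = io.read_manifest(ROOT / "data" / "manifest.tsv")
    matrix = io.read_matrix(ROOT / "qc" / "beta.filtered.tsv", manifest)
    sheet = io.read_samplesheet(ROOT / "data" / "samples.csv")

    out = ROOT / "differential"
    out.mkdir(parents=True, exist_ok=True)
    diff = ttest_per_probe(matrix, sheet, variance_mode="pooled")
    io._write_table(diff.reset_index(), out / "diff.tsv", "\t")
    io._write_table(manhattan_data(diff, manifest),
                    out / "manhattan.tsv", "\t")
    io._write_table(volcano_data(diff), out / "volcano.tsv", "\t")

    n = len(diff)
    dm = diff[diff["p_value"] <= 1e-2]
    print(f"tested {n} probes: {len(dm)} DM at p <= 0.01 "
          f"({100 * len(dm) / n:.2f}%)")
    for tier in ("high", "medium", "low"):
        k = (dm["tier"] == tier).sum()
        print(f"  {tier:6s} {k:5d} ({100 * k / max(len(dm), 1):.2f}% of DM)")
    print(f"  hyper {int((dm['direction'] == 'hyper').sum())} / "
          f"hypo {int((dm['direction'] == 'hypo').sum())}")


if __name__ == "__main__":
    main()
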