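"""QC stage: blacklist (SNP / cross-reactive) removal, then the
reproducibility filter (replicate beta range > 0.10 removes the probe).

Reads results/data/, writes the filtered matrix and the QC report under
results/qc/.
"""

import json
import pathlib

import pandas as pd

from dmcpg import io
from dmcpg.qc import run_qc

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    manifest = io.read_manifest(ROOT / "data" / "manifest.tsv")
    matrix = io.read_matrix(ROOT / "data" / "beta.tsv", manifest)
    sheet = io.read_samplesheet(ROOT / "data" / "samples.csv")

    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    filtered, report, removed = run_qc(matrix, manifest, sheet,
                                       threshold=0.10, mode="replicate")
    io.write_matrix(filtered, out / "beta.filtered.tsv")
    io.export_summary_json(report.as_dict(), out / "qc_report.json")
    pd.Series(removed, name="probe_id").to_csv(
        out / "removed_probes.tsv", sep="\t", index=False)

    r = report.as_dict()
    print(f"input {r['n_input']} probes: removed {r['n_removed_snp']} SNP, "
          f"{r['n_removed_crossreactive']} cross-reactive, "
          f"{r['n_removed_reproducibility']} poorly reproducible "
          f"(replicate beta range > 0.10)")
    print(f"retained {r['n_retained']} probes "
          f"({100 * r['n_retained'] / r['n_input']:.1f}%)")


if __name__ == "__main__":
    main()
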