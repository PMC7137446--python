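"""Final summary: assemble the per-run report table (counts, percentages,
cluster score tallies, gene and isolated-CpG counts) from the artifacts of
the previous stages, write it as JSON + text under results/report/, and
print it.
"""

import pathlib

import pandas as pd

from dmcpg import io
from dmcpg.clusters import find_clusters, find_isolated
from dmcpg.lists import build_list2, build_list3, compute_tail_cutoffs
from dmcpg.report import format_summary, summarize

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    manifest = io.read_manifest(ROOT / "data" / "manifest.tsv")
    diff = pd.read_csv(ROOT / "differential" / "diff.tsv", sep="\t",
                       comment="#", index_col="probe_id")

    # re-derive cluster/list objects from the per-probe table so every
    # reported count is reproducible from the written artifacts
    cls = find_clusters(diff, manifest)
    iso = find_isolated(diff, manifest, cls)
    cuts = compute_tail_cutoffs(diff)
    l2 = build_list2(diff, manifest, cuts.recommended_symmetric)
    l3 = build_list3(l2)

    out = ROOT / "report"
    out.mkdir(parents=True, exist_ok=True)
    summary = summarize(diff, cls, iso, {"LIST2": l2, "LIST3": l3},
                        manifest=manifest)
    io.export_summary_json(summary, out / "summary.json")
    text = format_summary(summary)
    (out / "summary.txt").write_text(text)
    print(text, end="")


if __name__ == "__main__":
    main()
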