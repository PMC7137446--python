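"""Empirical delta-beta cutoffs and gene lists.

The 2.5% tails of the observed delta-beta distribution pick the working
symmetric cutoff (rounded up to the next 0.01). Probes with
|delta-beta| >= cutoff and p <= 1e-3 build the broad gene list (LIST2
style); genes whose best probe reaches |delta-beta| >= 0.10 form the
strict list (LIST3 style). Both are intersected with the planted truth
genes. Writes under results/lists/.
"""

import pathlib

import pandas as pd

from dmcpg import io
from dmcpg.lists import (
    build_list2, build_list3, compute_tail_cutoffs, intersect_lists,
)

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    manifest = io.read_manifest(ROOT / "data" / "manifest.tsv")
    diff = pd.read_csv(ROOT / "differential" / "diff.tsv", sep="\t",
                       comment="#", index_col="probe_id")
    truth = pd.read_csv(ROOT / "data" / "truth.tsv", sep="\t", comment="#",
                        keep_default_na=False)

    out = ROOT / "lists"
    out.mkdir(parents=True, exist_ok=True)
    cuts = compute_tail_cutoffs(diff)
    io.export_summary_json(cuts.as_dict(), out / "cutoffs.json")
    print(f"delta-beta 2.5%/97.5% quantiles: {cuts.q_low:+.5f} / "
          f"{cuts.q_high:+.5f} -> working cutoff "
          f"+/- {cuts.recommended_symmetric:.2f}")

    l2 = build_list2(diff, manifest, cuts.recommended_symmetric)
    l3 = build_list3(l2)
    io._write_table(l2.entries, out / "list2.tsv", "\t")
    io._write_table(l3.entries, out / "list3.tsv", "\t")
    for gl in (l2, l3):
        c = gl.counts()
        print(f"{gl.name}: {c['n_genes']} genes "
              f"({c['n_hypo']} hypo, {c['n_hyper']} hyper)")

    ann = manifest.set_index("probe_id")["gene_symbol"]
    planted_genes = {g for g in ann.reindex(
        truth.loc[truth["effect_kind"] != "none", "probe_id"]) if g}
    for gl in (l2, l3):
        _, counts = intersect_lists(gl, planted_genes)
        print(f"{gl.name} vs planted truth genes: "
              f"{counts['n_overlap']}/{counts['n_b']} recovered "
              f"({counts['n_a']} genes listed)")


if __name__ == "__main__":
    main()
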