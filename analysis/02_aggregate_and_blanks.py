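#!/usr/bin/env python
"""Aggregate assigned counts cumulatively, normalise, and audit blanks.

Reads the synthetic inputs from results/synthetic/ and writes cumulative
counts, all-reads and viral-reads abundance tables, and the blank
contamination summary under results/tables/.
"""

import argparse
import json
from pathlib import Path

from sedavirome.tables import (
    aggregate_cumulative,
    blank_summary,
    read_lca_counts,
    read_sample_metadata,
    relative_abundance,
    write_lca_counts,
)
from sedavirome.taxonomy import parse_taxonomy


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--outdir", type=Path, default=Path("results/tables"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    tree = parse_taxonomy(args.indir / "nodes.tsv", args.indir / "names.tsv")
    counts, ann = read_lca_counts(args.indir / "counts.tsv")
    meta = read_sample_metadata(args.indir / "metadata.csv")

    cum = aggregate_cumulative(counts, tree)
    ann_full = ann.reindex(cum.data.index)
    ann_full["name"] = [tree.name(int(t)) for t in cum.data.index]
    ann_full["rank"] = [tree.rank(int(t)) for t in cum.data.index]
    write_lca_counts(cum, ann_full, args.outdir / "cumulative_counts.tsv")

    viral_root = tree.find_by_name("Viruses")
    for scope, label in ((tree.root, "all_reads"), (viral_root, "viral_reads")):
        ab = relative_abundance(cum, tree, scope)
        ab.data.to_csv(args.outdir / f"abundance_{label}.tsv", sep="\t")

    summ = blank_summary(cum, meta, viral_root)
    payload = {
        "n_blanks": summ.n_blanks,
        "clean_blanks": summ.clean_blanks,
        "blank_reads": summ.blank_reads,
        "total_reads": summ.total_reads,
        "fraction_pct": summ.fraction_pct,
        "fraction_pct_2sf": summ.fraction_pct_rounded(2),
    }
    (args.outdir / "blank_summary.json").write_text(json.dumps(payload, indent=1))

    viral_total = int(cum.data.loc[viral_root].sum())
    all_total = int(cum.data.loc[tree.root].sum())
    print(f"viral reads: {viral_total} "
          f"({100 * viral_total / all_total:.3f}% of mapped reads)")
    print(f"blanks: {summ.clean_blanks}/{summ.n_blanks} clean; "
          f"{summ.blank_reads} blank viral reads "
          f"({summ.fraction_pct_rounded(2)}% of viral reads)")


if __name__ == "__main__":
    main()
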