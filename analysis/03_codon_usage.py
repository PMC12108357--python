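#!/usr/bin/env python
"""Codon-usage patterns: mean RSCU per gene, CUP interval summary, codon
aversion motifs, and hierarchical clustering of the 13 RSCU profiles.

Reads the simulated population (run 01 first); writes the RSCU matrix, the
CAM membership matrix, the interval x codon-ending summary and a Newick
dendrogram under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from mitocup.codon_usage import (
    cam,
    cluster_rscu,
    count_codons,
    interval_summary,
    mean_rscu,
    rscu,
    rscu_matrix,
)
from mitocup.genetic_code import CODON_ORDER, load_code
from mitocup.seq_io import CANONICAL_GENES, read_genbank, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixture", type=Path, default=Path("scratch/population/population.gb"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--k", type=int, default=5, help="cluster count to report")
    args = ap.parse_args()

    code = load_code("vertebrate-mito")
    records = read_genbank(args.fixture)

    mean_tables = []
    for gene in CANONICAL_GENES:
        tables = [
            rscu(count_codons(r.gene(gene), code), code) for r in records
        ]
        mean_tables.append(mean_rscu(tables, unit_id=gene))

    write_table(
        rscu_matrix(mean_tables).reset_index(names="codon"),
        args.results / "03_mean_rscu_matrix.tsv",
    )
    cams = {t.unit_id: cam(t) for t in mean_tables}
    write_table(
        pd.DataFrame(
            {g: [1 if c in cams[g] else 0 for c in CODON_ORDER] for g in cams},
            index=list(CODON_ORDER),
        ).reset_index(names="codon"),
        args.results / "03_cam_matrix.tsv",
    )
    summary = interval_summary(mean_tables)
    write_table(summary.as_frame(), args.results / "03_interval_summary.tsv")

    clust = cluster_rscu(mean_tables)
    (args.results / "03_rscu_dendrogram.nwk").write_text(clust.newick() + "\n")
    groups: dict[int, list[str]] = {}
    for gene, label in clust.cut(args.k).items():
        groups.setdefault(label, []).append(gene)

    union = set().union(*cams.values())
    sizes = {g: len(c) for g, c in cams.items()}
    print(f"interval summary ({summary.grand_total} gene-codon pairs): "
          f"unused {summary.row_percentage('unused')}%, "
          f"under {summary.row_percentage('under')}%, "
          f"unbiased {summary.row_percentage('unbiased')}%, "
          f"over {summary.row_percentage('over')}% "
          f"(non-random {summary.nonrandom_percentage}%)")
    print(f"G-ending share of unused: {summary.ending_share('unused', 'G')}%; "
          f"A-ending share of over-represented: {summary.ending_share('over', 'A')}%")
    print(f"CAM sizes {min(sizes.values())}-{max(sizes.values())} per gene, "
          f"union {len(union)} codons")
    print(f"{args.k}-group clustering: "
          + "; ".join("{" + ", ".join(sorted(g)) + "}" for g in groups.values()))


if __name__ == "__main__":
    main()
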