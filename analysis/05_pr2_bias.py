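#!/usr/bin/env python
"""PR2 bias plot: A3/(A3+T3) against G3/(G3+C3) at third positions of
four-fold degenerate codons, pooled per gene across genomes.

Reads the simulated population (run 01 first). Points at (0.5, 0.5) are
consistent with strand-symmetric mutation pressure alone; displaced points
indicate additional strand-specific pressure or selection.
"""

import argparse
from pathlib import Path

import pandas as pd

from mitocup.genetic_code import load_code
from mitocup.pr2_analysis import extract_fourfold, pr2_point_from_codons
from mitocup.seq_io import CANONICAL_GENES, read_genbank, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixture", type=Path, default=Path("scratch/population/population.gb"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    code = load_code("vertebrate-mito")
    records = read_genbank(args.fixture)
    rows = []
    for gene in CANONICAL_GENES:
        pooled = []
        for r in records:
            pooled.extend(extract_fourfold(r.gene(gene), code))
        rows.append(pr2_point_from_codons(pooled, gene).as_row())
    table = pd.DataFrame(rows)
    out = write_table(table, args.results / "05_pr2_table.tsv")

    by_quadrant = table.groupby("quadrant")["gene"].apply(list).to_dict()
    for quadrant, genes in sorted(by_quadrant.items()):
        print(f"quadrant {quadrant}: {', '.join(genes)}")
    print(f"table: {out}")


if __name__ == "__main__":
    main()
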