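"""Parity rule 2 (PR2) bias at third positions of four-fold degenerate codons.

Under strand-symmetric mutation and selection, within-strand A ≈ T and
G ≈ C (PR2). Deviations are measured per gene over the third positions of
its four-fold degenerate codons — the 24 codons (Ala, Arg, Gly, Pro, Thr,
Val under the vertebrate mito code) where the third base is synonymous —
as AT-bias = A3/(A3 + T3) and GC-bias = G3/(G3 + C3). A gene driven by
mutation pressure alone sits at (0.5, 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .genetic_code import GeneticCode, fourfold_degenerate_codons
from .seq_io import CodingSequence, codonize

#: Genes with fewer four-fold codons than this carry a low-support flag:
#: bias ratios from so few draws are sampling-noise dominated.
MIN_FOURFOLD_SUPPORT = 10


@dataclass(frozen=True)
class PR2Point:
    """Third-position counts and PR2 bias coordinates for one gene."""

    unit_id: str
    a3: int
    t3: int
    g3: int
    c3: int

    @property
    def n_fourfold(self) -> int:
        return self.a3 + self.t3 + self.g3 + self.c3

    @property
    def at_bias(self) -> float:
        """A3/(A3 + T3); NaN when no A- or U-ending four-fold codons."""
        denom = self.a3 + self.t3
        return self.a3 / denom if denom else math.nan

    @property
    def gc_bias(self) -> float:
        """G3/(G3 + C3); NaN when no G- or C-ending four-fold codons."""
        denom = self.g3 + self.c3
        return self.g3 / denom if denom else math.nan

    @property
    def low_support(self) -> bool:
        return self.n_fourfold < MIN_FOURFOLD_SUPPORT

    @property
    def quadrant(self) -> str:
        """Quadrant relative to the (0.5, 0.5) PR2 centre.

        Convention: x = GC-bias, y = AT-bias. Quadrants are numbered
        counter-clockwise from (+,+): I = G&A preferring, II = C&A,
        III = C&T, IV = G&T. A point with either coordinate exactly 0.5
        (or undefined) is "on-axis" rather than in a quadrant.
        """
        x, y = self.gc_bias, self.at_bias
        if math.isnan(x) or math.isnan(y) or x == 0.5 or y == 0.5:
            return "on-axis"
        if x > 0.5:
            return "I" if y > 0.5 else "IV"
        return "II" if y > 0.5 else "III"

    def as_row(self) -> dict:
        return {
            "gene": self.unit_id,
            "A3": self.a3, "T3": self.t3, "G3": self.g3, "C3": self.c3,
            "n_fourfold": self.n_fourfold,
            "at_bias": self.at_bias, "gc_bias": self.gc_bias,
            "quadrant": self.quadrant,
            "low_support": self.low_support,
        }


def extract_fourfold(
    cds: CodingSequence, code: GeneticCode, stop_policy: str = "drop-partial"
) -> list[str]:
    """Order-preserving sublist of a gene's codons in four-fold families."""
    fourfold = fourfold_degenerate_codons(code)
    return [c for c in codonize(cds, code, stop_policy=stop_policy) if c in fourfold]


def pr2_point_from_codons(codons: list[str], unit_id: str = "") -> PR2Point:
    """PR2 coordinates from an already-extracted four-fold codon list."""
    thirds = [c[2] for c in codons]
    return PR2Point(
        unit_id,
        a3=thirds.count("A"),
        t3=thirds.count("U"),
        g3=thirds.count("G"),
        c3=thirds.count("C"),
    )


def pr2_point(
    cds: CodingSequence, code: GeneticCode, stop_policy: str = "drop-partial"
) -> PR2Point:
    """PR2 bias coordinates for one CDS."""
    return pr2_point_from_codons(extract_fourfold(cds, code, stop_policy), cds.gene)


def pr2_table(
    genes: list[CodingSequence], code: GeneticCode, stop_policy: str = "drop-partial"
) -> pd.DataFrame:
    """Per-gene PR2 rows ready for the bias plot."""
    return pd.DataFrame([pr2_point(g, code, stop_policy).as_row() for g in genes])


def pooled_pr2_point(
    per_individual: list[list[str]], unit_id: str = ""
) -> PR2Point:
    """PR2 from four-fold codons pooled within a gene across individuals."""
    pooled = [c for codons in per_individual for c in codons]
    return pr2_point_from_codons(pooled, unit_id)
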