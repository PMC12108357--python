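"""Nucleotide composition and strand-asymmetry (skew) statistics.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C) computed over a
sequence's unambiguous bases. Positive AT-skew with negative GC-skew is the
classic mammalian mitochondrial heavy-strand signature (A and C enriched
over T and G); a minus-strand gene read in mRNA sense shows the mirrored
pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .seq_io import CodingSequence


@dataclass(frozen=True)
class CompositionSummary:
    """Base counts, contents and skews for one sequence unit."""

    unit_id: str
    a: int
    t: int
    g: int
    c: int

    @property
    def total(self) -> int:
        return self.a + self.t + self.g + self.c

    @property
    def at_content(self) -> float:
        return (self.a + self.t) / self.total

    @property
    def gc_content(self) -> float:
        return (self.g + self.c) / self.total

    @property
    def at_skew(self) -> float:
        """(A − T)/(A + T); NaN (reported missing) when A + T = 0."""
        denom = self.a + self.t
        return (self.a - self.t) / denom if denom else math.nan

    @property
    def gc_skew(self) -> float:
        """(G − C)/(G + C); NaN (reported missing) when G + C = 0."""
        denom = self.g + self.c
        return (self.g - self.c) / denom if denom else math.nan

    def as_row(self) -> dict:
        return {
            "unit_id": self.unit_id,
            "A": self.a, "T": self.t, "G": self.g, "C": self.c,
            "at_content": self.at_content, "gc_content": self.gc_content,
            "at_content_pct": 100 * self.at_content,
            "gc_content_pct": 100 * self.gc_content,
            "at_skew": self.at_skew, "gc_skew": self.gc_skew,
        }


def composition(seq: str, unit_id: str = "") -> CompositionSummary:
    """Count A/T(U)/G/C over unambiguous bases and derive contents and skews.

    Ambiguity codes (N, R, Y, ...) are excluded from all counts. Skews are
    composition-only statistics: invariant to shuffling, sign-flipped by
    complementation.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    a, t, g, c = s.count("A"), s.count("T"), s.count("G"), s.count("C")
    if a + t + g + c == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return CompositionSummary(unit_id, a, t, g, c)


def skew_points(genes: list[CodingSequence]) -> pd.DataFrame:
    """Per-gene skewness-plot coordinates.

    One row per gene with both plot variants: (at_content_pct, at_skew) and
    (gc_content_pct, gc_skew) — content on x as percent, skew on y.
    """
    if not genes:
        raise ValueError("need at least one gene")
    rows = []
    for g in genes:
        comp = composition(g.seq, unit_id=g.gene)
        rows.append(
            {
                "gene": g.gene,
                "at_content_pct": 100 * comp.at_content,
                "at_skew": comp.at_skew,
                "gc_content_pct": 100 * comp.gc_content,
                "gc_skew": comp.gc_skew,
            }
        )
    return pd.DataFrame(rows)


def composition_table(units: list[tuple[str, str]]) -> pd.DataFrame:
    """CompositionSummary rows for (unit_id, sequence) pairs."""
    return pd.DataFrame([composition(seq, uid).as_row() for uid, seq in units])
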