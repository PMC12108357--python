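"""Wright's effective number of codons (ENC), GC3, and the ENC-plot.

ENC summarizes codon bias on a scale from 20 (one codon per amino acid) up
to the genetic code's sense capacity. Each synonymous family contributes a
codon-homozygosity estimate F = (n·Σp_j² − 1)/(n − 1); class averages F̄_s
over families of degeneracy s combine as ENC = Σ_s N_s / F̄_s. The ENC-plot
compares observed ENC against the mutation-only expectation
ENC* = 2 + GC3 + 29/(GC3² + (1 − GC3)²): genes far below the curve are
shaped by selection, genes on it by mutation pressure alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_usage import CodonCountTable
from .genetic_code import GeneticCode

#: Family-count structure of the standard code, used by standard-compat
#: mode to mimic CodonW's printed ENC range (max 61): 2 single-codon amino
#: acids + 9 two-fold + 1 three-fold + 5 four-fold + 3 six-fold families.
_STANDARD_CLASS_COUNTS = {1: 2, 2: 9, 3: 1, 4: 5, 6: 3}

ENC_MODES = ("code-derived", "standard-compat")


class ENCError(ValueError):
    """ENC cannot be estimated for this count table."""


@dataclass
class ENCResult:
    unit_id: str
    enc: float
    gc3: float
    family_F: dict[str, float]  # amino acid -> F (families with n >= 2)
    mode: str
    interpolated_classes: tuple[int, ...] = ()

    @property
    def quality_flag(self) -> str:
        return "interpolated" if self.interpolated_classes else "ok"


def gc3(table: CodonCountTable, code: GeneticCode, include_stops: bool = False) -> float:
    """Fraction of counted codons with G or C at the third position.

    All sense codons enter (CodonW's GC3s definition); stop codons are
    excluded by default since third-position synonymity is undefined for
    the stop pseudo-family.
    """
    total = 0
    gc = 0
    for codon, n in table.counts.items():
        if not include_stops and code.is_stop(codon):
            continue
        total += n
        if codon[2] in "GC":
            gc += n
    if total == 0:
        raise ENCError(f"{table.unit_id}: no codons to compute GC3 over")
    return gc / total


def gc3_synonymous(table: CodonCountTable, code: GeneticCode) -> float:
    """GC3 restricted to codons of families with degeneracy >= 2.

    Under the vertebrate mito code every sense codon is in such a family,
    so this equals :func:`gc3`; the variant matters for codes with
    single-codon amino acids.
    """
    total = 0
    gc = 0
    for fam in code.families:
        if fam.degeneracy < 2:
            continue
        for codon in fam.codons:
            n = table.counts[codon]
            total += n
            if codon[2] in "GC":
                gc += n
    if total == 0:
        raise ENCError(f"{table.unit_id}: no synonymous codons for GC3")
    return gc / total


def expected_enc(gc3_value: float) -> float:
    """Mutation-only expected ENC at a given GC3.

    ENC* = 2 + GC3 + 29/(GC3² + (1 − GC3)²); equals exactly 60.5 at
    GC3 = 0.5, with the true maximum marginally above that (the linear
    term breaks exact symmetry of the peak position).
    """
    if not 0 <= gc3_value <= 1:
        raise ValueError(f"GC3 must be in [0, 1], got {gc3_value}")
    s = gc3_value
    return 2 + s + 29 / (s * s + (1 - s) * (1 - s))


def standard_curve(step: float = 0.001) -> pd.DataFrame:
    """The ENC-plot standard curve on an inclusive GC3 grid [0, 1].

    The default 0.001 spacing yields 1001 points.
    """
    if not 0 < step <= 0.5:
        raise ValueError("step must be in (0, 0.5]")
    n = round(1 / step)
    xs = np.linspace(0.0, 1.0, n + 1)
    return pd.DataFrame(
        {"gc3": xs, "expected_enc": [expected_enc(x) for x in xs]}
    )


def _family_F(counts: list[int]) -> float | None:
    """Wright's codon homozygosity for one family; None if n < 2."""
    n = sum(counts)
    if n < 2:
        return None
    p2 = sum((x / n) ** 2 for x in counts)
    return (n * p2 - 1) / (n - 1)


def enc(
    table: CodonCountTable,
    code: GeneticCode,
    mode: str = "code-derived",
) -> ENCResult:
    """Wright's ENC for one gene's codon counts.

    code-derived mode uses the code's own family structure (vertebrate
    mito: 12 two-fold + 6 four-fold + 2 six-fold, maximum 60).
    standard-compat mode combines the same family F values with the
    standard code's class structure (2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,
    maximum 61) to mirror CodonW's printed range on mitochondrial genes.

    Families with n < 2 observations, or with F = 0 (all observed codons
    distinct, carrying no homozygosity signal), are excluded from class
    means as in CodonW. A class with no estimable family is interpolated
    as the mean of its neighbouring classes where possible, and the result
    flagged; stop codons never enter.
    """
    if mode not in ENC_MODES:
        raise ValueError(f"unknown ENC mode {mode!r}; options: {ENC_MODES}")

    family_F: dict[str, float] = {}
    class_F: dict[int, list[float]] = {}
    for fam in code.families:
        if fam.degeneracy < 2:
            continue
        F = _family_F([table.counts[c] for c in fam.codons])
        if F is None or F == 0:
            continue
        family_F[fam.amino_acid] = F
        class_F.setdefault(fam.degeneracy, []).append(F)
    if not class_F:
        raise ENCError(f"{table.unit_id}: no estimable synonymous family")

    Fbar = {s: float(np.mean(v)) for s, v in class_F.items()}

    if mode == "code-derived":
        class_counts = {
            s: n for s, n in code.degeneracy_class_counts().items() if s >= 2
        }
        max_enc = sum(s * n for s, n in class_counts.items())
        n_single = sum(
            n for s, n in code.degeneracy_class_counts().items() if s == 1
        )
        base = n_single
        max_enc += n_single
    else:
        class_counts = {s: n for s, n in _STANDARD_CLASS_COUNTS.items() if s >= 2}
        base = _STANDARD_CLASS_COUNTS[1]
        max_enc = 61

    interpolated: list[int] = []
    for s in class_counts:
        if s not in Fbar:
            est = _interpolate_class(Fbar, s)
            if est is None:
                raise ENCError(
                    f"{table.unit_id}: class {s}-fold has no estimable family "
                    "and cannot be interpolated"
                )
            Fbar[s] = est
            interpolated.append(s)

    value = base + sum(n / Fbar[s] for s, n in class_counts.items())
    value = min(value, max_enc)  # cap at the mode's theoretical maximum
    return ENCResult(
        unit_id=table.unit_id,
        enc=value,
        gc3=gc3(table, code),
        family_F=family_F,
        mode=mode,
        interpolated_classes=tuple(interpolated),
    )


def _interpolate_class(Fbar: dict[int, float], s: int) -> float | None:
    """Wright's interpolation for a missing class (F̄₃ ≈ (F̄₂ + F̄₄)/2)."""
    lower = max((t for t in Fbar if t < s), default=None)
    upper = min((t for t in Fbar if t > s), default=None)
    if lower is not None and upper is not None:
        return (Fbar[lower] + Fbar[upper]) / 2
    if lower is not None:
        return Fbar[lower]
    if upper is not None:
        return Fbar[upper]
    return None


def enc_plot_points(
    tables: list[CodonCountTable],
    code: GeneticCode,
    mode: str = "code-derived",
    margin: float = 0.0,
) -> pd.DataFrame:
    """ENC-plot coordinates per gene: (GC3, ENC) with the curve reference.

    ``below_curve`` flags genes with ENC < ENC*(GC3) − margin, the ENC-plot
    reading of selection acting on codon choice.
    """
    if not tables:
        raise ValueError("need at least one count table")
    rows = []
    for t in tables:
        res = enc(t, code, mode=mode)
        exp = expected_enc(res.gc3)
        rows.append(
            {
                "gene": t.unit_id,
                "gc3": res.gc3,
                "enc": res.enc,
                "expected_enc": exp,
                "below_curve": bool(res.enc < exp - margin),
                "mode": mode,
                "quality": res.quality_flag,
            }
        )
    return pd.DataFrame(rows)
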