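"""Genetic code tables and synonymous-family structure.

The vertebrate mitochondrial code (NCBI translation table 2) is the default
for every downstream statistic; the standard code (table 1) is included for
ENC-compatibility mode. Codons are held internally in the RNA alphabet (U);
DNA input is normalized transparently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

NUCLEOTIDES_RNA = "UCAG"
#: Codon ordering used in every table and export: U < C < A < G at each
#: position, the conventional codon-table layout.
CODON_ORDER: tuple[str, ...] = tuple(
    n1 + n2 + n3 for n1 in NUCLEOTIDES_RNA for n2 in NUCLEOTIDES_RNA for n3 in NUCLEOTIDES_RNA
)

STOP = "*"

# NCBI translation table 2 (vertebrate mitochondrial): AUA=Met, UGA=Trp,
# AGA/AGG=Stop relative to the standard code.
_TABLE_2_AA = (
    "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG"
)
_TABLE_2_STARTS = {"AUU", "AUC", "AUA", "AUG", "GUG"}

# NCBI translation table 1 (standard).
_TABLE_1_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_TABLE_1_STARTS = {"UUG", "CUG", "AUG"}

_CODE_TABLES: dict[int, tuple[str, str, frozenset[str]]] = {
    2: ("vertebrate-mito", _TABLE_2_AA, frozenset(_TABLE_2_STARTS)),
    1: ("standard", _TABLE_1_AA, frozenset(_TABLE_1_STARTS)),
}

_ALIASES: dict[str, int] = {
    "vertebrate-mito": 2,
    "vertebrate-mitochondrial": 2,
    "mito": 2,
    "2": 2,
    "standard": 1,
    "1": 1,
}


class UnknownCodeError(ValueError):
    """Raised for a genetic-code name this package does not ship."""


class StopCodonFamilyError(ValueError):
    """Raised when a stop codon is passed where a sense codon is required.

    Stop codons form their own pseudo-family for RSCU display purposes and
    never belong to an amino-acid synonymous family.
    """


def normalize_codon(codon: str) -> str:
    """Uppercase and convert T to U; reject anything outside ACGU(T).

    The normalization is idempotent, and bijective on the DNA alphabet.
    """
    c = codon.upper().replace("T", "U")
    if len(c) != 3 or any(b not in NUCLEOTIDES_RNA for b in c):
        raise ValueError(f"invalid codon {codon!r}")
    return c


def to_dna(codon: str) -> str:
    """Inverse of :func:`normalize_codon` onto the DNA alphabet."""
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class SynonymousFamily:
    """One amino acid's set of synonymous codons under a given code."""

    amino_acid: str
    codons: tuple[str, ...]

    @property
    def degeneracy(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table with derived family structure."""

    name: str
    table_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    families: tuple[SynonymousFamily, ...] = field(default=())

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(CODON_ORDER):
            raise ValueError("codon_to_aa must map exactly the 64 codons")
        fams = _build_families(self.codon_to_aa)
        object.__setattr__(self, "families", fams)

    # -- basic queries ----------------------------------------------------
    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODON_ORDER if self.codon_to_aa[c] == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODON_ORDER if self.codon_to_aa[c] != STOP)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[normalize_codon(codon)] == STOP

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[normalize_codon(codon)]

    def family_of(self, codon: str) -> SynonymousFamily:
        """Synonymous family containing ``codon``.

        Stop codons raise :class:`StopCodonFamilyError`: they are carried as
        a pseudo-family for RSCU only (see :mod:`mitocup.codon_usage`).
        """
        c = normalize_codon(codon)
        aa = self.codon_to_aa[c]
        if aa == STOP:
            raise StopCodonFamilyError(
                f"{c} is a stop codon; stop codons form their own pseudo-family"
            )
        return self._family_index[aa]

    @property
    def _family_index(self) -> dict[str, SynonymousFamily]:
        return {f.amino_acid: f for f in self.families}

    def stop_pseudo_family(self) -> SynonymousFamily:
        """The stop codons grouped as one family, used only for RSCU display."""
        return SynonymousFamily(STOP, self.stop_codons)

    def degeneracy_class_counts(self) -> dict[int, int]:
        """Number of synonymous families of each degeneracy (degeneracy >= 2)."""
        out: dict[int, int] = {}
        for f in self.families:
            out[f.degeneracy] = out.get(f.degeneracy, 0) + 1
        return dict(sorted(out.items()))

    def to_json(self) -> str:
        """Export the table for inspection (DNA spelling not applied)."""
        return json.dumps(
            {
                "name": self.name,
                "table_id": self.table_id,
                "codon_to_aa": {c: self.codon_to_aa[c] for c in CODON_ORDER},
                "start_codons": sorted(self.start_codons),
                "families": [
                    {"amino_acid": f.amino_acid, "codons": list(f.codons)}
                    for f in self.families
                ],
            },
            indent=2,
        )


def _build_families(codon_to_aa: dict[str, str]) -> tuple[SynonymousFamily, ...]:
    by_aa: dict[str, list[str]] = {}
    for codon in CODON_ORDER:
        aa = codon_to_aa[codon]
        if aa == STOP:
            continue
        by_aa.setdefault(aa, []).append(codon)
    return tuple(
        SynonymousFamily(aa, tuple(codons))
        for aa, codons in sorted(by_aa.items())
    )


@lru_cache(maxsize=None)
def load_code(name: str) -> GeneticCode:
    """Load a genetic code by name or NCBI translation-table number.

    Supported: ``"vertebrate-mito"`` (table 2, the default throughout) and
    ``"standard"`` (table 1, used by the ENC standard-compat mode).
    """
    key = str(name).strip().lower()
    if key not in _ALIASES:
        raise UnknownCodeError(
            f"unknown genetic code {name!r}; supported: {sorted(set(_ALIASES))}"
        )
    table_id = _ALIASES[key]
    canonical, aa_string, starts = _CODE_TABLES[table_id]
    codon_to_aa = {c: aa_string[i] for i, c in enumerate(CODON_ORDER)}
    return GeneticCode(canonical, table_id, codon_to_aa, starts)


def fourfold_degenerate_codons(code: GeneticCode) -> frozenset[str]:
    """All codons in synonymous families of degeneracy exactly 4.

    Under the vertebrate mitochondrial code these are 24 codons covering
    Ala, Arg, Gly, Pro, Thr and Val; the third position is then free.
    """
    return frozenset(
        c for f in code.families if f.degeneracy == 4 for c in f.codons
    )


def family_of(code: GeneticCode, codon: str) -> SynonymousFamily:
    """Module-level alias for :meth:`GeneticCode.family_of`."""
    return code.family_of(codon)
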