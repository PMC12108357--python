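"""Reading annotated mitogenomes and writing tabular results.

CDS sequences are always handed downstream in mRNA sense: minus-strand genes
(canonically ND6) are reverse-complemented on load, so their opposite skew
and PR2 behaviour emerges from composition rather than special-casing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .genetic_code import GeneticCode, normalize_codon

logger = logging.getLogger(__name__)

#: The 13 canonical mitochondrial protein-coding genes, in genome order.
CANONICAL_GENES: tuple[str, ...] = (
    "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
)

# Annotation synonym table (MITOS/MitoZ/GenBank spellings -> canonical).
_GENE_SYNONYMS: dict[str, str] = {
    "COB": "CYTB", "CYTB": "CYTB", "CYB": "CYTB", "MT-CYB": "CYTB",
    "COI": "COX1", "CO1": "COX1", "COXI": "COX1", "COX1": "COX1", "MT-CO1": "COX1",
    "COII": "COX2", "CO2": "COX2", "COXII": "COX2", "COX2": "COX2", "MT-CO2": "COX2",
    "COIII": "COX3", "CO3": "COX3", "COXIII": "COX3", "COX3": "COX3", "MT-CO3": "COX3",
    "ATP6": "ATP6", "ATPASE6": "ATP6", "MT-ATP6": "ATP6",
    "ATP8": "ATP8", "ATPASE8": "ATP8", "MT-ATP8": "ATP8",
    **{f"NAD{i}": f"ND{i}" for i in range(1, 7)},
    **{f"ND{i}": f"ND{i}" for i in range(1, 7)},
    **{f"MT-ND{i}": f"ND{i}" for i in range(1, 7)},
    "NAD4L": "ND4L", "ND4L": "ND4L", "MT-ND4L": "ND4L",
}


def normalize_gene_symbol(symbol: str) -> str | None:
    """Map an annotation gene/product string to a canonical PCG symbol.

    Returns None if the symbol cannot be resolved. Idempotent on canonical
    symbols.
    """
    key = symbol.strip().upper().replace(" ", "")
    return _GENE_SYNONYMS.get(key)


class CodonizationError(ValueError):
    """A CDS that cannot be split into sense codons (internal stop, etc.)."""


@dataclass
class CodingSequence:
    """One gene's CDS in mRNA sense, with completeness metadata.

    ``seq`` is a DNA-alphabet string read 5'→3' on the coding strand;
    ``stop_codon`` may be a 1–2 nt partial tail (e.g. ``"T"`` for the
    classic T-- stop completed by polyadenylation).
    """

    gene: str
    seq: str
    strand: str = "+"
    complete_stop: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if len(self.seq) < 6:
            raise ValueError(f"{self.gene}: CDS shorter than 6 nt")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene}: strand must be + or -")

    @property
    def partial_tail(self) -> str:
        """Trailing 1–2 nt of an incomplete stop codon ('' if none)."""
        return self.seq[len(self.seq) - len(self.seq) % 3:]

    @property
    def start_codon(self) -> str:
        return self.seq[:3]

    @property
    def stop_codon(self) -> str:
        """Annotated stop: the final full codon, or the partial tail."""
        tail = self.partial_tail
        return tail if tail else self.seq[-3:]


@dataclass
class GenomeRecord:
    """One annotated mitogenome: id, length and its PCG set."""

    id: str
    length: int
    genes: list[CodingSequence]
    full_seq: str | None = None

    def __post_init__(self) -> None:
        symbols = [g.gene for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError(f"{self.id}: duplicate gene symbols")
        if len(self.genes) < 13:
            logger.warning(
                "%s: only %d of 13 PCGs present", self.id, len(self.genes)
            )

    def gene(self, symbol: str) -> CodingSequence:
        for g in self.genes:
            if g.gene == symbol:
                return g
        raise KeyError(symbol)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Read GenBank flat file(s); one GenomeRecord per LOCUS.

    CDS features are extracted via their gene/product qualifiers; features
    on the complement strand are reverse-complemented to mRNA sense. CDS
    with unresolvable gene symbols are skipped with a warning.
    """
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        genes: list[CodingSequence] = []
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            raw = (
                feat.qualifiers.get("gene", [None])[0]
                or feat.qualifiers.get("product", [""])[0]
            )
            symbol = normalize_gene_symbol(raw or "")
            if symbol is None:
                logger.warning(
                    "%s: skipping CDS with unresolvable gene symbol %r",
                    rec.id, raw,
                )
                continue
            cds_seq = str(feat.extract(rec.seq))  # handles complement strand
            strand = "-" if feat.location.strand == -1 else "+"
            genes.append(
                CodingSequence(
                    gene=symbol,
                    seq=cds_seq,
                    strand=strand,
                    complete_stop=(len(cds_seq) % 3 == 0),
                )
            )
        records.append(
            GenomeRecord(rec.id, len(rec.seq), genes, full_seq=str(rec.seq))
        )
    if not records:
        raise ValueError(f"no GenBank records parsed from {path}")
    return records


def read_fasta_with_table(
    fasta: str | Path,
    coords: str | Path,
    convention: str = "one-based-inclusive",
) -> list[GenomeRecord]:
    """Read genomes from FASTA plus a gene-coordinate TSV.

    The TSV needs columns seq_id, gene, start, end, strand. Coordinates are
    1-based inclusive by default (GenBank convention); pass
    ``convention="zero-based-half-open"`` for BED-style rows. All internal
    arithmetic is 0-based half-open; this is the single conversion point.
    """
    if convention not in ("one-based-inclusive", "zero-based-half-open"):
        raise ValueError(f"unknown coordinate convention {convention!r}")
    table = pd.read_csv(coords, sep="\t", comment="#")
    required = {"seq_id", "gene", "start", "end", "strand"}
    if not required.issubset(table.columns):
        raise ValueError(f"coordinate table must have columns {sorted(required)}")

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    records: list[GenomeRecord] = []
    for seq_id, group in table.groupby("seq_id", sort=False):
        if seq_id not in seqs:
            raise ValueError(f"coordinate table references unknown sequence {seq_id!r}")
        genome = seqs[seq_id]
        genes = []
        for row in group.itertuples():
            start, end = int(row.start), int(row.end)
            if convention == "one-based-inclusive":
                start -= 1  # -> 0-based half-open
            if not (0 <= start < end <= len(genome)):
                raise ValueError(
                    f"{seq_id}/{row.gene}: coordinates [{row.start}, {row.end}] "
                    f"out of range for {len(genome)} bp genome"
                )
            segment = genome[start:end]
            if row.strand == "-":
                segment = str(Seq(segment).reverse_complement())
            symbol = normalize_gene_symbol(str(row.gene)) or str(row.gene)
            genes.append(
                CodingSequence(
                    gene=symbol,
                    seq=segment,
                    strand=str(row.strand),
                    complete_stop=(len(segment) % 3 == 0),
                )
            )
        records.append(GenomeRecord(str(seq_id), len(genome), genes, full_seq=genome))
    return records


# ---------------------------------------------------------------------------
# codonization
# ---------------------------------------------------------------------------

def codonize(
    cds: CodingSequence,
    code: GeneticCode,
    stop_policy: str = "drop-partial",
) -> list[str]:
    """Split a CDS into consecutive RNA-alphabet codons from position 1.

    A trailing 1–2 nt incomplete stop (completed in vivo by polyadenylation)
    is excluded under ``stop_policy="drop-partial"`` (default) or completed
    with A's and included under ``"polyadenylate"``. An internal stop codon
    raises :class:`CodonizationError` — it signals misannotation.
    """
    if stop_policy not in ("drop-partial", "polyadenylate"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    n_full = len(cds.seq) // 3
    codons = [
        normalize_codon(cds.seq[3 * i: 3 * i + 3]) for i in range(n_full)
    ]
    tail = cds.partial_tail
    if tail and stop_policy == "polyadenylate":
        completed = normalize_codon(tail + "A" * (3 - len(tail)))
        if not code.is_stop(completed):
            raise CodonizationError(
                f"{cds.gene}: polyadenylated tail {tail!r} does not form a stop codon"
            )
        codons.append(completed)
    for i, codon in enumerate(codons[:-1]):
        if code.is_stop(codon):
            raise CodonizationError(
                f"{cds.gene}: internal stop codon {codon} at codon position {i + 1}"
            )
    return codons


# ---------------------------------------------------------------------------
# table writer
# ---------------------------------------------------------------------------

def write_table(rows: pd.DataFrame, path: str | Path, run_id: str | None = None) -> Path:
    """Write a result table as TSV with header, UTF-8, deterministic order.

    An optional run id is recorded as a leading ``#`` comment line so every
    bundle table can be traced to its manifest; :func:`read_table` skips it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if run_id is not None:
            fh.write(f"# run_id={run_id}\n")
        rows.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
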