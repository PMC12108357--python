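"""RSCU, codon-usage-pattern classification, codon aversion motifs, and
hierarchical clustering of per-gene RSCU profiles.

RSCU (relative synonymous codon usage) for codon j in a synonymous family i
of size k_i is ``RSCU_ij = k_i * n_ij / N_i`` — observed count over the mean
count of the family; 1 means no bias and the values are independent of gene
length. Codons are classified (CUP) as unused (RSCU = 0), under-represented
(0 < RSCU < 0.6), over-represented (RSCU > 1.6) or unbiased otherwise, and a
gene's codon aversion motif (CAM) is the set of codons it never uses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genetic_code import CODON_ORDER, GeneticCode, SynonymousFamily, normalize_codon
from .seq_io import CodingSequence, codonize

logger = logging.getLogger(__name__)

CUP_CLASSES = ("unused", "under", "unbiased", "over")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, the rounding used in printed percentage tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CodonCountTable:
    """Integer counts over all 64 codons for one gene or concatenation."""

    unit_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        full = {c: 0 for c in CODON_ORDER}
        for codon, n in self.counts.items():
            c = normalize_codon(codon)
            if n < 0:
                raise ValueError(f"negative count for {c}")
            full[c] += int(n)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.counts[c] + other.counts[c] for c in CODON_ORDER}
        return CodonCountTable(f"{self.unit_id}+{other.unit_id}", merged)

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[c] for c in CODON_ORDER], dtype=float)


@dataclass
class RSCUTable:
    """Per-codon RSCU values with CUP classes and CAM membership.

    ``rscu`` holds NaN for members of families with zero observations
    ("family-absent"); those codons still have usage count 0, so by default
    they classify as unused and join the CAM.
    """

    unit_id: str
    rscu: dict[str, float]
    family_absent: frozenset[str] = frozenset()
    cup_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cup_class:
            self.cup_class = {
                c: classify_cup(v) for c, v in self.rscu.items()
            }

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODON_ORDER if c in self.rscu)

    def value(self, codon: str) -> float:
        return self.rscu[normalize_codon(codon)]


def classify_cup(rscu_value: float) -> str:
    """CUP class from an RSCU value (NaN = unobserved family -> unused)."""
    if math.isnan(rscu_value) or rscu_value == 0:
        return "unused"
    if rscu_value < 0.6:
        return "under"
    if rscu_value > 1.6:
        return "over"
    return "unbiased"


# ---------------------------------------------------------------------------
# counting and RSCU
# ---------------------------------------------------------------------------

def count_codons(
    cds: CodingSequence,
    code: GeneticCode,
    stop_policy: str = "drop-partial",
) -> CodonCountTable:
    """Codon counts over the full codonization of one CDS.

    The initiator codon and (when complete) the terminal stop codon are
    included: start- and stop-codon preferences are part of the usage
    profile being characterized.
    """
    codons = codonize(cds, code, stop_policy=stop_policy)
    counts: dict[str, int] = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    return CodonCountTable(cds.gene, counts)


def count_codon_list(codons: list[str], unit_id: str = "") -> CodonCountTable:
    counts: dict[str, int] = {}
    for c in codons:
        cc = normalize_codon(c)
        counts[cc] = counts.get(cc, 0) + 1
    return CodonCountTable(unit_id, counts)


def _rscu_families(
    code: GeneticCode,
    include_stops: bool,
    split_sixfold: bool,
) -> list[SynonymousFamily]:
    families = list(code.families)
    if split_sixfold:
        split: list[SynonymousFamily] = []
        for fam in families:
            if fam.degeneracy == 6:
                # split on the first two codon positions (e.g. mito Leu ->
                # CUN four-fold + UUR two-fold; Ser -> UCN + AGY)
                groups: dict[str, list[str]] = {}
                for c in fam.codons:
                    groups.setdefault(c[:2], []).append(c)
                for prefix, codons in sorted(groups.items()):
                    split.append(
                        SynonymousFamily(f"{fam.amino_acid}({prefix}N)", tuple(codons))
                    )
            else:
                split.append(fam)
        families = split
    if include_stops:
        families.append(code.stop_pseudo_family())
    return families


def rscu(
    table: CodonCountTable,
    code: GeneticCode,
    include_stops: bool = True,
    split_sixfold: bool = False,
) -> RSCUTable:
    """RSCU values for one codon-count table.

    Stop codons are treated as a single pseudo-family (their usage is part
    of the displayed profile) unless ``include_stops=False``. Families with
    zero observations yield NaN, flagged family-absent.
    """
    values: dict[str, float] = {}
    absent: set[str] = set()
    for fam in _rscu_families(code, include_stops, split_sixfold):
        total = sum(table.counts[c] for c in fam.codons)
        k = fam.degeneracy
        for c in fam.codons:
            if total == 0:
                values[c] = math.nan
                absent.add(c)
            else:
                values[c] = k * table.counts[c] / total
    return RSCUTable(table.unit_id, values, frozenset(absent))


def mean_rscu(tables: list[RSCUTable], unit_id: str | None = None) -> RSCUTable:
    """Arithmetic mean RSCU per codon across individuals.

    NaN (family-absent) entries are ignored per codon; a codon missing in
    every individual stays NaN. CUP classification is applied to the means.
    """
    if not tables:
        raise ValueError("need at least one RSCU table")
    codons = tables[0].codons
    for t in tables[1:]:
        if t.codons != codons:
            raise ValueError(f"mismatched codon structure between {tables[0].unit_id} and {t.unit_id}")
    means: dict[str, float] = {}
    absent: set[str] = set()
    for c in codons:
        vals = [t.rscu[c] for t in tables if not math.isnan(t.rscu[c])]
        if vals:
            means[c] = float(np.mean(vals))
        else:
            means[c] = math.nan
            absent.add(c)
    return RSCUTable(unit_id or tables[0].unit_id, means, frozenset(absent))


def cam(table: RSCUTable, include_unobserved_families: bool = True) -> frozenset[str]:
    """Codon aversion motif: the codons a gene never uses (RSCU = 0).

    Members of entirely unobserved families have usage count 0 and are
    included by default.
    """
    out = {c for c, v in table.rscu.items() if v == 0}
    if include_unobserved_families:
        out |= set(table.family_absent)
    return frozenset(out)


# ---------------------------------------------------------------------------
# interval summary (RSCU intervals x third-position nucleotide)
# ---------------------------------------------------------------------------

ENDINGS = ("A", "G", "U", "C")


@dataclass
class IntervalSummary:
    """Counts of (gene, codon) pairs per RSCU interval, by codon ending.

    Rows: unused (RSCU = 0), under (0–0.6), unbiased (0.6–1.6), over (>1.6);
    columns: A-, G-, U-, C-ending codons. Percentages are over the grand
    total (#genes × #codons) and printed round-half-up to 2 decimals.
    """

    counts: pd.DataFrame  # index CUP_CLASSES, columns ENDINGS

    @classmethod
    def from_counts(cls, matrix: list[list[int]]) -> "IntervalSummary":
        """Build from a 4×4 count matrix (rows unused/under/unbiased/over)."""
        df = pd.DataFrame(matrix, index=list(CUP_CLASSES), columns=list(ENDINGS))
        return cls(df.astype(int))

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_percentage(self, cup: str) -> float:
        return round_half_up(100 * self.row_totals[cup] / self.grand_total)

    @property
    def nonrandom_percentage(self) -> float:
        """Share of (gene, codon) pairs in the non-random classes."""
        n = self.row_totals[["unused", "under", "over"]].sum()
        return round_half_up(100 * n / self.grand_total)

    def ending_share(self, cup: str, endings: str | tuple[str, ...]) -> float:
        """Within-row share of codons with the given ending nucleotide(s)."""
        if isinstance(endings, str):
            endings = (endings,)
        n = self.counts.loc[cup, list(endings)].sum()
        return round_half_up(100 * n / self.row_totals[cup])

    def as_frame(self) -> pd.DataFrame:
        """The printed layout: counts per ending, row totals, percentages."""
        df = self.counts.copy()
        df["total"] = self.row_totals
        df["percentage"] = [self.row_percentage(cup) for cup in CUP_CLASSES]
        df.insert(0, "rscu_interval", ["0", "0~0.6", "0.6~1.6", ">1.6"])
        return df.reset_index(names="cup_class")


def interval_summary(mean_tables: list[RSCUTable]) -> IntervalSummary:
    """Tally per-gene mean-RSCU codons into interval × ending cells.

    Every codon of every gene is classified (family-absent = unused), so
    the grand total is #genes × #codons.
    """
    counts = pd.DataFrame(0, index=list(CUP_CLASSES), columns=list(ENDINGS))
    for t in mean_tables:
        for c in t.codons:
            counts.loc[t.cup_class[c], c[2]] += 1
    return IntervalSummary(counts)


# ---------------------------------------------------------------------------
# hierarchical clustering of per-gene RSCU profiles
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Agglomerative clustering of genes on their RSCU vectors."""

    labels: list[str]
    linkage_matrix: np.ndarray
    metric: str
    method: str

    def cut(self, k: int) -> dict[str, int]:
        """Cluster membership (1..k) at k clusters."""
        if k > len(self.labels):
            raise ValueError(f"k={k} exceeds number of units {len(self.labels)}")
        flat = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, flat)}

    def newick(self) -> str:
        """Dendrogram as Newick text with branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"


def rscu_matrix(tables: list[RSCUTable]) -> pd.DataFrame:
    """Codon × gene matrix of RSCU values (NaN preserved)."""
    data = {t.unit_id: [t.rscu[c] for c in t.codons] for t in tables}
    return pd.DataFrame(data, index=list(tables[0].codons))


def cluster_rscu(
    mean_tables: list[RSCUTable],
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of genes on their 64-dim RSCU vectors.

    Family-absent NaNs are imputed as 0 (usage count is genuinely zero)
    with a logged note. Deterministic given inputs; defaults (Euclidean
    distance, average linkage) chosen for robustness and reproducibility.
    """
    if len(mean_tables) < 2:
        raise ValueError("need at least two units to cluster")
    mat = rscu_matrix(mean_tables)
    n_missing = int(mat.isna().to_numpy().sum())
    if n_missing:
        logger.info("imputing %d family-absent RSCU values as 0 for clustering", n_missing)
        mat = mat.fillna(0.0)
    X = mat.to_numpy().T  # genes × codons
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    return ClusterResult(list(mat.columns), Z, metric, method)
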