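"""End-to-end orchestration: read genomes, run every statistic, write a
reproducible report bundle.

The bundle is a pure function of (inputs, config): per-genome composition,
per-gene skew points, mean-RSCU matrix, CAM matrix, the interval×ending
summary, ENC table with standard curve, PR2 table, a Newick dendrogram and
a JSON manifest carrying the run id (a digest of config + input checksums)
that is stamped on every table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import composition, skew_points
from .codon_usage import (
    cam,
    cluster_rscu,
    count_codons,
    interval_summary,
    mean_rscu,
    rscu,
    rscu_matrix,
)
from .enc_analysis import ENC_MODES, enc_plot_points, standard_curve
from .genetic_code import CODON_ORDER, load_code
from .pr2_analysis import pr2_point_from_codons, extract_fourfold
from .seq_io import (
    CANONICAL_GENES,
    GenomeRecord,
    codonize,
    read_fasta_with_table,
    read_genbank,
    write_table,
    CodonizationError,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    input_path: str
    out_dir: str
    coords_path: str | None = None  # FASTA+TSV mode when set
    code: str = "vertebrate-mito"
    stop_policy: str = "drop-partial"
    enc_mode: str = "code-derived"
    curve_step: float = 0.001
    linkage: str = "average"
    distance: str = "euclidean"
    cluster_k: int | None = None
    coordinate_convention: str = "one-based-inclusive"
    seed: int = 0

    def __post_init__(self) -> None:
        load_code(self.code)  # raises on unknown code
        if self.stop_policy not in ("drop-partial", "polyadenylate"):
            raise ValueError(f"unknown stop_policy {self.stop_policy!r}")
        if self.enc_mode not in ENC_MODES:
            raise ValueError(f"unknown enc_mode {self.enc_mode!r}")
        if not 0 < self.curve_step <= 0.1:
            raise ValueError("curve_step must be in (0, 0.1]")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _read_records(config: RunConfig) -> list[GenomeRecord]:
    if config.coords_path:
        return read_fasta_with_table(
            config.input_path, config.coords_path, config.coordinate_convention
        )
    return read_genbank(config.input_path)


def _run_id(config: RunConfig, records: list[GenomeRecord]) -> str:
    # path fields are excluded: the id identifies input content plus
    # analysis parameters, not where files happen to live
    params = {
        k: v
        for k, v in asdict(config).items()
        if k not in ("input_path", "out_dir", "coords_path")
    }
    h = hashlib.sha256()
    h.update(json.dumps(params, sort_keys=True).encode())
    for rec in records:
        h.update(rec.id.encode())
        h.update((rec.full_seq or "".join(g.seq for g in rec.genes)).encode())
    return h.hexdigest()[:12]


def validate_inputs(config: RunConfig) -> pd.DataFrame:
    """Dry-run diagnostics: gene coverage, length sanity, ambiguity content.

    Returns one row per finding with severity in {info, warning, error};
    never raises on data problems.
    """
    rows: list[dict] = []
    try:
        records = _read_records(config)
    except Exception as exc:
        return pd.DataFrame(
            [{"severity": "error", "unit": config.input_path, "message": str(exc)}]
        )
    code = load_code(config.code)
    for rec in records:
        present = {g.gene for g in rec.genes}
        for missing in set(CANONICAL_GENES) - present:
            rows.append(
                {
                    "severity": "warning",
                    "unit": f"{rec.id}/{missing}",
                    "message": "canonical PCG missing from annotation",
                }
            )
        for g in rec.genes:
            ambiguous = sum(1 for b in g.seq if b not in "ACGT")
            if ambiguous:
                rows.append(
                    {
                        "severity": "info",
                        "unit": f"{rec.id}/{g.gene}",
                        "message": f"{ambiguous} ambiguous bases",
                    }
                )
            if len(g.seq) % 3 and g.complete_stop:
                rows.append(
                    {
                        "severity": "warning",
                        "unit": f"{rec.id}/{g.gene}",
                        "message": "length not a multiple of 3 despite complete stop",
                    }
                )
            try:
                codonize(g, code, config.stop_policy)
            except CodonizationError as exc:
                rows.append(
                    {
                        "severity": "error",
                        "unit": f"{rec.id}/{g.gene}",
                        "message": str(exc),
                    }
                )
    if not rows:
        rows.append({"severity": "info", "unit": "-", "message": "no findings"})
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis battery and write the report bundle.

    Returns a name -> path map of everything written. Any stage failure
    aborts with :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    code = load_code(config.code)

    try:
        records = _read_records(config)
    except Exception as exc:
        raise StageError("read", str(exc)) from exc
    run_id = _run_id(config, records)
    paths: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        paths[name] = write_table(frame, out / f"{name}.tsv", run_id=run_id)

    # --- composition & skews ---------------------------------------------
    try:
        genome_rows = [
            composition(rec.full_seq or "".join(g.seq for g in rec.genes), rec.id).as_row()
            for rec in records
        ]
        emit("genome_composition", pd.DataFrame(genome_rows))

        gene_order = [g for g in CANONICAL_GENES if any(
            g in {x.gene for x in rec.genes} for rec in records
        )]
        skew_frames = []
        for rec in records:
            pts = skew_points(rec.genes)
            pts.insert(0, "genome", rec.id)
            skew_frames.append(pts)
        emit("gene_skew_points", pd.concat(skew_frames, ignore_index=True))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("composition", str(exc)) from exc

    # --- codon usage ------------------------------------------------------
    try:
        per_gene_rscu = {}
        per_gene_counts = {}
        for gene in gene_order:
            tables = []
            counts = []
            for rec in records:
                try:
                    cds = rec.gene(gene)
                except KeyError:
                    continue
                ct = count_codons(cds, code, config.stop_policy)
                counts.append(ct)
                tables.append(rscu(ct, code))
            per_gene_rscu[gene] = mean_rscu(tables, unit_id=gene)
            pooled = counts[0]
            for ct in counts[1:]:
                pooled = pooled + ct
            pooled.unit_id = gene
            per_gene_counts[gene] = pooled

        mean_tables = [per_gene_rscu[g] for g in gene_order]
        mat = rscu_matrix(mean_tables)
        emit("rscu_matrix", mat.reset_index(names="codon"))

        cam_rows = {
            g: [1 if c in cam(per_gene_rscu[g]) else 0 for c in CODON_ORDER]
            for g in gene_order
        }
        emit(
            "cam_matrix",
            pd.DataFrame(cam_rows, index=list(CODON_ORDER)).reset_index(names="codon"),
        )

        emit("interval_summary", interval_summary(mean_tables).as_frame())

        clust = cluster_rscu(mean_tables, metric=config.distance, method=config.linkage)
        newick_path = out / "rscu_dendrogram.nwk"
        newick_path.write_text(clust.newick() + "\n")
        paths["rscu_dendrogram"] = newick_path
        if config.cluster_k:
            emit(
                "cluster_labels",
                pd.DataFrame(
                    sorted(clust.cut(config.cluster_k).items()),
                    columns=["gene", "cluster"],
                ),
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("codon_usage", str(exc)) from exc

    # --- ENC --------------------------------------------------------------
    try:
        count_list = [per_gene_counts[g] for g in gene_order]
        emit("enc_table", enc_plot_points(count_list, code, mode=config.enc_mode))
        emit("enc_standard_curve", standard_curve(config.curve_step))
    except Exception as exc:
        raise StageError("enc", str(exc)) from exc

    # --- PR2 --------------------------------------------------------------
    try:
        pr2_rows = []
        for gene in gene_order:
            pooled = []
            for rec in records:
                try:
                    cds = rec.gene(gene)
                except KeyError:
                    continue
                pooled.extend(extract_fourfold(cds, code, config.stop_policy))
            pr2_rows.append(pr2_point_from_codons(pooled, gene).as_row())
        emit("pr2_table", pd.DataFrame(pr2_rows))
    except Exception as exc:
        raise StageError("pr2", str(exc)) from exc

    # --- manifest ---------------------------------------------------------
    manifest = {
        "run_id": run_id,
        "package_version": __version__,
        "config": asdict(config),
        "n_genomes": len(records),
        "genes": gene_order,
        "input_sha256": hashlib.sha256(
            Path(config.input_path).read_bytes()
        ).hexdigest(),
        "outputs": {k: str(v.name) for k, v in paths.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
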