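"""Quality-control filters and per-gene RPKM / relative translation efficiency.

Relative translation efficiency (RTE) for gene i is the ratio of ribosome
profiling RPKM to RNA-seq RPKM,

    RTE_i = RPKM_ribosome,i / RPKM_RNA,i

and downstream modelling operates on log-transformed RTE (base 10 by
default; the base cancels from every R^2 and model-selection statistic and
only rescales effect sizes, which are back-transformed with the same base).

The QC filters enrich for high-confidence measurements: a gene is kept iff
its CDS coverage fraction is at least 25% in BOTH the ribosome-profiling and
RNA-seq tracks, the CDS is at least 30 codons, and at least one ribosome
footprint maps to its first 10 coding bases (genes failing that last check
are likely misannotated starts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence_io import ContigSet, CoverageTrack, GeneModel

#: QC reason codes
LOW_COVERAGE_RIBO = "low_coverage_ribo"
LOW_COVERAGE_RNA = "low_coverage_rna"
SHORT_GENE = "short_gene"
ZERO_START_READS = "zero_start_reads"
EDGE_EXCLUDED = "edge_excluded"


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    rpkm_ribo: float
    rpkm_rna: float
    rte: float | None
    log_rte: float | None


@dataclass
class QCReport:
    """Per-gene pass/fail table; every input gene appears exactly once."""

    table: pd.DataFrame  # columns: gene_id, passed, reasons

    @property
    def survivors(self) -> list[str]:
        return list(self.table.loc[self.table["passed"], "gene_id"])

    def reasons_for(self, gene_id: str) -> list[str]:
        row = self.table.loc[self.table["gene_id"] == gene_id, "reasons"]
        if row.empty:
            raise KeyError(gene_id)
        r = row.iloc[0]
        return r.split(",") if r else []

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _cds_slice(track: CoverageTrack, gene: GeneModel) -> np.ndarray:
    return track.array(gene.contig_id)[gene.start - 1 : gene.end]


def coverage_fraction(track: CoverageTrack, gene: GeneModel) -> float:
    """Fraction of CDS positions with at least one mapped count."""
    counts = _cds_slice(track, gene)
    return float((counts >= 1).sum()) / gene.length_nt


def start_window_signal(track: CoverageTrack, gene: GeneModel, n: int = 10) -> float:
    """Summed counts over coding positions +1 ... +n (strand-aware)."""
    arr = track.array(gene.contig_id)
    if gene.strand == "+":
        return float(arr[gene.start - 1 : gene.start - 1 + n].sum())
    return float(arr[gene.end - n : gene.end].sum())


def apply_qc_filters(
    genes: list[GeneModel],
    ribo_track: CoverageTrack,
    rna_track: CoverageTrack,
    *,
    min_coverage: float = 0.25,
    min_length_nt: int = 90,
    start_window: int = 10,
    edge_excluded: set[str] | None = None,
) -> tuple[list[GeneModel], QCReport]:
    """Apply the inclusion filters; returns survivors and a full QC report.

    ``edge_excluded`` carries gene ids already flagged by sequence extraction
    (upstream window off the contig) so that every gene is accounted for in
    one place.  Thresholds are inclusive: coverage exactly at ``min_coverage``
    survives (it is genes *below* the threshold that are removed).
    """
    edge_excluded = edge_excluded or set()
    rows = []
    survivors = []
    for gene in genes:
        reasons = []
        if gene.gene_id in edge_excluded:
            reasons.append(EDGE_EXCLUDED)
        if gene.length_nt < min_length_nt:
            reasons.append(SHORT_GENE)
        if coverage_fraction(ribo_track, gene) < min_coverage:
            reasons.append(LOW_COVERAGE_RIBO)
        if coverage_fraction(rna_track, gene) < min_coverage:
            reasons.append(LOW_COVERAGE_RNA)
        if start_window_signal(ribo_track, gene, start_window) <= 0:
            reasons.append(ZERO_START_READS)
        if not reasons:
            survivors.append(gene)
        rows.append({"gene_id": gene.gene_id, "passed": not reasons,
                     "reasons": ",".join(reasons)})
    report = QCReport(pd.DataFrame(rows, columns=["gene_id", "passed", "reasons"]))
    return survivors, report


def rpkm(track: CoverageTrack, gene: GeneModel) -> float:
    """Reads per kilobase per million mapped reads.

    The per-base coverage sum over the CDS stands in for the read count; as a
    consistent linear functional of the reads it cancels from the RTE ratio.
    """
    total = track.total_signal
    if total <= 0:
        raise ValueError("empty library: track has zero total signal")
    signal = float(_cds_slice(track, gene).sum())
    return signal / ((gene.length_nt / 1e3) * (total / 1e6))


def compute_rte(rpkm_ribo: float, rpkm_rna: float,
                log_base: float = 10.0) -> tuple[float | None, float | None]:
    """(rte, log_rte); rte is None when RNA RPKM is zero, log_rte is None
    when rte is zero (log undefined; such genes are excluded from regression)."""
    if rpkm_rna <= 0:
        return None, None
    rte = rpkm_ribo / rpkm_rna
    if rte <= 0:
        return 0.0, None
    return rte, math.log(rte, log_base)


def expression_table(
    genes: list[GeneModel],
    ribo_track: CoverageTrack,
    rna_track: CoverageTrack,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Per-gene RPKM/RTE table for genes that already passed QC."""
    rows = []
    for gene in genes:
        r_ribo = rpkm(ribo_track, gene)
        r_rna = rpkm(rna_track, gene)
        rte, log_rte = compute_rte(r_ribo, r_rna, log_base)
        rows.append({
            "gene_id": gene.gene_id,
            "rpkm_ribo": r_ribo,
            "rpkm_rna": r_rna,
            "rte": np.nan if rte is None else rte,
            "log_rte": np.nan if log_rte is None else log_rte,
        })
    return pd.DataFrame(rows, columns=["gene_id", "rpkm_ribo", "rpkm_rna", "rte", "log_rte"])


def read_rte_table(path, log_base: float = 10.0) -> pd.DataFrame:
    """Read a precomputed RTE table (gene_id, rte, utr_sequence).

    This is the entry point for datasets where translation efficiency was
    measured by other means (e.g. single-cell protein distributions or
    reporter libraries); coverage-based RPKM computation is bypassed.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "rte", "utr_sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.copy()
    df["utr_sequence"] = df["utr_sequence"].str.upper().str.replace("T", "U")
    with np.errstate(divide="ignore"):
        df["log_rte"] = np.where(df["rte"] > 0,
                                 np.log(df["rte"].to_numpy(dtype=float))
                                 / np.log(log_base), np.nan)
    return df
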