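"""End-to-end orchestration: files in, landscape + best model + quintiles out.

The stages run in fixed order - sequence extraction, QC and RTE computation,
structure residualization, hybridization scanning, model selection, quintile
effect sizes and (optionally) operon stratification - with every excluded
gene logged with a reason, so that each annotated gene appears either in the
results or in the QC report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asd_scan, expression, sequence_io, structure_model

logger = logging.getLogger("sdscan")

#: E. coli 16S rRNA 3' tail (final bases, 5'->3'), the source of aSD
#: candidates; the conserved core is CCUCC.
DEFAULT_TAIL = "GGAUCACCUCCUUA"
DEFAULT_CORE = "CCUCC"
#: bases appended past the known rRNA terminus as a negative control
DEFAULT_CONTROL_3PRIME = "GCAU"


@dataclasses.dataclass
class PipelineConfig:
    fasta: str | None = None
    gff: str | None = None
    wig_ribo: str | None = None
    wig_rna: str | None = None
    rte_table: str | None = None
    operon_table: str | None = None
    tail: str = DEFAULT_TAIL
    core: str = DEFAULT_CORE
    control_3prime: str = DEFAULT_CONTROL_3PRIME
    max_5prime: int = 6
    max_3prime: int = 4
    d_max: int = 14
    utr_length: int = 40
    structure_correction: bool = True
    stratify_operons: bool = False
    log_base: float = 10.0
    min_n: int = 50
    min_genes_for_regression: int = 10
    tolerance: float = 0.005
    folding_engine: str = "builtin"
    duplex_engine: str = "builtin"
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        have_coverage = all([self.fasta, self.gff, self.wig_ribo, self.wig_rna])
        if not have_coverage and not self.rte_table:
            raise ValueError(
                "config needs either coverage inputs (fasta, gff, wig_ribo, "
                "wig_rna) or an rte_table"
            )
        if self.core not in self.tail:
            raise ValueError("core aSD must occur in the rRNA tail")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _collect_sequences(genes, contigs, utr_length):
    """Per-gene UTR and initiation region; edge-affected genes flagged."""
    utrs, init_regions, kept, edge = {}, {}, [], set()
    for gene in genes:
        try:
            utrs[gene.gene_id] = sequence_io.extract_upstream(gene, contigs, utr_length)
            init_regions[gene.gene_id] = sequence_io.extract_initiation_region(
                gene, contigs)
            kept.append(gene)
        except (sequence_io.EdgeExcludedError, ValueError) as exc:
            logger.info("edge-excluded %s: %s", gene.gene_id, exc)
            edge.add(gene.gene_id)
        else:
            if not sequence_io.is_canonical_start(gene, contigs):
                logger.warning("gene %s start codon %s not in {AUG, GUG, UUG}",
                               gene.gene_id,
                               sequence_io.start_codon(gene, contigs))
    return utrs, init_regions, edge


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a results bundle (and writes ``outdir``)."""
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")

    results: dict = {"config": dataclasses.asdict(config)}

    if config.rte_table:
        table = expression.read_rte_table(config.rte_table, config.log_base)
        table = table.dropna(subset=["log_rte"])
        utrs = dict(zip(table["gene_id"], table["utr_sequence"]))
        working = table[["gene_id", "log_rte"]].copy()
        # externally measured RTE: no coverage QC, no structure correction
        working["response"] = working["log_rte"]
        results["mode"] = "rte_table"
    else:
        contigs = sequence_io.read_fasta(config.fasta)
        genes = sequence_io.read_annotation(config.gff)
        ribo = sequence_io.read_wig(config.wig_ribo, contigs)
        rna = sequence_io.read_wig(config.wig_rna, contigs)
        utrs_all, init_regions, edge = _collect_sequences(
            genes, contigs, config.utr_length)
        survivors, qc = expression.apply_qc_filters(
            genes, ribo, rna, edge_excluded=edge)
        results["qc"] = qc
        if outdir:
            qc.to_tsv(outdir / "qc.tsv")
        if not survivors:
            raise ValueError("no genes survive quality control")
        table = expression.expression_table(survivors, ribo, rna, config.log_base)
        n_zero = int(table["log_rte"].isna().sum())
        if n_zero:
            logger.info("excluding %d genes with undefined log RTE", n_zero)
        table = table.dropna(subset=["log_rte"])
        if outdir:
            table.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        utrs = {g: utrs_all[g] for g in table["gene_id"]}

        if config.structure_correction:
            engine = structure_model.get_folding_engine(config.folding_engine)
            dg_fold = engine.fold_energies(
                [init_regions[g] for g in table["gene_id"]])
            fold_df = pd.DataFrame({"gene_id": table["gene_id"].to_numpy(),
                                    "log_rte": table["log_rte"].to_numpy(),
                                    "dg_fold": dg_fold})
            try:
                resid_df, fold_stats = structure_model.residualize(
                    fold_df, config.min_genes_for_regression)
            except ValueError as exc:
                if "degenerate" not in str(exc):
                    raise
                # constant folding energy carries no information: residuals
                # reduce to centred log RTE, equivalent up to a shift
                logger.warning("dg_fold constant across genes; falling back "
                               "to centred log RTE")
                resid_df = fold_df.copy()
                resid_df["predicted_log_rte"] = fold_df["log_rte"].mean()
                resid_df["residual"] = (fold_df["log_rte"]
                                        - fold_df["log_rte"].mean())
                fold_stats = {"n": len(fold_df), "slope": 0.0,
                              "intercept": float(fold_df["log_rte"].mean()),
                              "r2": 0.0, "p_value": 1.0}
            results["structure_fit"] = fold_stats
            results["folding_engine"] = engine.name
            if outdir:
                resid_df.to_csv(outdir / "residuals.tsv", sep="\t", index=False)
            working = resid_df[["gene_id"]].copy()
            working["response"] = resid_df["residual"].to_numpy()
        else:
            working = table[["gene_id"]].copy()
            working["response"] = (table["log_rte"]
                                   - table["log_rte"].mean()).to_numpy()
        results["mode"] = "coverage"

    gene_ids = list(working["gene_id"])
    utr_list = [utrs[g] for g in gene_ids]
    response = working["response"].to_numpy(dtype=float)

    scan_tail = config.tail + config.control_3prime
    candidates = asd_scan.enumerate_asd_candidates(
        scan_tail, config.core, config.max_5prime, config.max_3prime)
    distances = list(range(-1, -config.d_max - 1, -1))
    from .hybridization import get_duplex_engine
    duplex = get_duplex_engine(config.duplex_engine)
    landscape = asd_scan.scan_landscape(
        utr_list, response, candidates, distances, duplex, config.min_n)
    best_asd, best_d, best_fit = asd_scan.select_best(landscape, config.tolerance)
    results["landscape"] = landscape
    results["best"] = {
        "asd": best_asd, "distance": best_d, "n": best_fit.n,
        "r2": best_fit.r2, "r2_adj": best_fit.r2_adj, "aic": best_fit.aic,
        "f_pvalue": best_fit.f_pvalue, "tolerance": config.tolerance,
        "duplex_engine": duplex.name,
    }

    from .hybridization import binding_energy_matrix
    dg_best = binding_energy_matrix(
        asd_scan.encode_utrs(utr_list), best_asd, [best_d], duplex)[:, 0]
    quintiles = asd_scan.quintile_analysis(
        dg_best, response, gene_ids, config.log_base)
    results["quintiles"] = quintiles
    results["gene_ids"] = gene_ids
    results["response"] = response
    results["dg_best"] = dg_best

    if config.stratify_operons and config.operon_table:
        operons = pd.read_csv(config.operon_table, sep="\t")
        strata = asd_scan.stratify_by_operon(gene_ids, operons)
        results["strata"] = {}
        idx = {g: i for i, g in enumerate(gene_ids)}
        for name in ("first_in_TU", "internal"):
            members = strata[name]
            if len(members) <= 5:
                logger.info("stratum %s too small (%d genes)", name, len(members))
                continue
            sel = np.array([idx[g] for g in members])
            fit3 = asd_scan.fit_polynomial(dg_best[sel], response[sel], 3)
            results["strata"][name] = {
                "n": len(members), "r2_adj": fit3.r2_adj,
                "f_pvalue": fit3.f_pvalue,
            }
        if strata["unclassified"]:
            logger.info("%d genes absent from the operon table",
                        len(strata["unclassified"]))

    if outdir:
        landscape.to_frame().to_csv(outdir / "landscape.tsv", sep="\t", index=False)
        with open(outdir / "best_model.json", "w") as fh:
            json.dump(results["best"], fh, indent=2)
        qdf = pd.DataFrame({
            "bin": np.arange(1, len(quintiles.means) + 1),
            "mean_residual": quintiles.means,
            "sem": quintiles.sems,
            "n": quintiles.counts,
        })
        qdf.to_csv(outdir / "quintiles.tsv", sep="\t", index=False)
    return results
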