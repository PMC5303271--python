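"""Synthetic genomes with a planted aSD::translation-efficiency relationship.

The generator emulates the statistical structure the analysis assumes: a
fraction of genes carry a Shine-Dalgarno site at a fixed distance upstream
of the start codon.  Each planted site is an exact contiguous match to a
random portion of the reverse complement of the planted aSD sequence, with
the matched extent drawn per gene from a configurable distribution -
mirroring the way real 5' UTRs carry SD motifs of widely varying lengths
(GGAG through UAAGGAGGU), which is precisely the sequence diversity the
aSD-extension scan exploits.  The hybridization dose-response applies to
genes carrying a functional (planted) site; incidental background
complementarity carries no effect, so ``motif_fraction = 0`` is an exact
null for the scan.  True log RTE is a linear function of
initiation-region folding energy plus a peaked function of the aSD
hybridization energy at the planted distance, plus Gaussian noise.  RNA
abundances are log-normal, ribosome-profiling coverage is RNA coverage
scaled by true RTE, and both tracks receive independent per-base Poisson
noise.  Everything is rendered to the same FASTA/GFF3/wig formats the real
pipeline reads, alongside a ground-truth table sufficient to score recovery.

Folding and hybridization covariates are computed from the *realized*
sequences with the built-in engines, so the structure-residualization stage
faces genuine sequence-covariate coupling rather than an independent draw.

One seed governs every draw through named substreams, making generated
datasets byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .hybridization import BuiltinDuplexEngine, window_at_distance
from .sequence_io import (ContigSet, CoverageTrack, GeneModel,
                          reverse_complement, transcribe, write_annotation,
                          write_fasta, write_wig)
from .structure_model import BuiltinFoldingEngine, encode_rna

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
)
#: background 5' UTR base composition (A, C, G, T) - AU-rich, as bacterial
#: UTRs are
_UTR_COMPOSITION = {"A": 0.32, "C": 0.18, "G": 0.20, "T": 0.30}


@dataclass(frozen=True)
class ResponseParams:
    """Shape of the dG_binding -> log-RTE dose-response.

    ``peaked`` mode is a downward-opening quadratic through zero at
    dG_bind = 0 (no complementarity) with its interior maximum ``height``
    at ``dg_opt``; binding stronger than 2*dg_opt is detrimental.  The
    default height, log10(1.5), corresponds to a 50% boost in linear RTE at
    the optimum.  ``linear`` mode (contribution = slope * dG_bind) exists
    for null/contrast experiments.
    """

    mode: str = "peaked"
    dg_opt: float = -7.0
    height: float = math.log10(1.5)
    slope: float = -0.02

    def __post_init__(self):
        if self.mode not in ("peaked", "linear"):
            raise ValueError(f"unknown response mode {self.mode!r}")
        for v in (self.dg_opt, self.height, self.slope):
            if not np.isfinite(v):
                raise ValueError("non-finite response parameters")
        if self.mode == "peaked" and self.dg_opt >= 0:
            raise ValueError("peaked response needs dg_opt < 0")


def response_function(dg_bind, params: ResponseParams):
    """Contribution of aSD binding energy to true log RTE (vectorized)."""
    g = np.asarray(dg_bind, dtype=float)
    if params.mode == "linear":
        out = params.slope * g
    else:
        out = params.height * (1.0 - ((g - params.dg_opt) / params.dg_opt) ** 2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 2000
    utr_length: int = 40
    planted_asd: str = "ACCUCCUUA"
    planted_distance: int = -5
    motif_fraction: float = 0.6
    #: P(matched extent) for planted sites; extents are contiguous exact
    #: matches to the SD (reverse complement of the planted aSD), anchored
    #: uniformly at random within the planted register
    site_extent_probs: tuple = ((3, 0.10), (4, 0.15), (5, 0.20), (6, 0.20),
                                (7, 0.15), (8, 0.10), (9, 0.10))
    structure_slope: float = 0.03  # log-RTE per kcal/mol of dG_fold
    response: ResponseParams = field(default_factory=ResponseParams)
    noise_sigma: float = 0.3  # log-RTE units
    rna_log_sigma: float = 0.5  # sd of log10 RNA abundance
    coverage_depth: float = 25.0  # mean RNA-seq reads per base at abundance 1
    min_codons: int = 50
    max_codons: int = 250
    intergenic: int = 20
    contig_pad: int = 60
    qc_violators: bool = False  # append one gene violating each QC filter
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.utr_length < len(self.planted_asd) + 14:
            raise ValueError(
                "utr_length must be >= planted aSD length + 14 scan distances"
            )
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if not 0.0 <= self.motif_fraction <= 1.0:
            raise ValueError("motif_fraction must be in [0, 1]")
        probs = [p for _, p in self.site_extent_probs]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("site_extent_probs must be a probability distribution")
        if any(ext < 1 or ext > len(self.planted_asd)
               for ext, _ in self.site_extent_probs):
            raise ValueError("site extents must lie in 1 ... len(planted_asd)")
        if self.planted_distance >= 0:
            raise ValueError("planted_distance must be negative")


@dataclass
class SyntheticDataset:
    contigs: ContigSet
    genes: list[GeneModel]
    ribo_track: CoverageTrack
    rna_track: CoverageTrack
    truth: pd.DataFrame
    config: SyntheticConfig

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fasta",
            "gff": outdir / "annotation.gff3",
            "wig_ribo": outdir / "ribo.wig",
            "wig_rna": outdir / "rna.wig",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.contigs, paths["fasta"])
        write_annotation(self.genes, paths["gff"])
        write_wig(self.ribo_track, paths["wig_ribo"])
        write_wig(self.rna_track, paths["wig_rna"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_utr(rng: np.random.Generator, length: int) -> str:
    bases = np.array(list(_UTR_COMPOSITION))
    probs = np.array(list(_UTR_COMPOSITION.values()))
    return "".join(rng.choice(bases, size=length, p=probs))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(np.array(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _plant_site(utr_dna: str, sd_dna: str, d: int,
                extent_probs: tuple, rng: np.random.Generator) -> tuple[str, int]:
    """Write a contiguous partial SD match into the UTR; returns (utr, extent).

    A matched extent is drawn from ``extent_probs`` and anchored uniformly at
    random within the planted register; positions outside the matched
    segment keep the background base already in the UTR.
    """
    L, x = len(utr_dna), len(sd_dna)
    gap = -d
    extents = np.array([e for e, _ in extent_probs])
    probs = np.array([p for _, p in extent_probs])
    extent = int(rng.choice(extents, p=probs))
    offset = int(rng.integers(0, x - extent + 1))
    out = list(utr_dna)
    start = L - gap - x
    out[start + offset : start + offset + extent] = sd_dna[offset : offset + extent]
    return "".join(out), extent


def simulate_coverage(length_nt: int, mean_per_base: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Independent per-base Poisson counts with the given mean."""
    if mean_per_base < 0:
        raise ValueError("negative coverage depth")
    return rng.poisson(mean_per_base, size=length_nt).astype(float)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Build a complete synthetic dataset (in memory; ``.write`` renders files)."""
    seed = int(config.seed)
    seq_rng = np.random.default_rng([seed, 1])
    noise_rng = np.random.default_rng([seed, 2])
    abund_rng = np.random.default_rng([seed, 3])
    cov_rng = np.random.default_rng([seed, 4])

    asd_rna = config.planted_asd.upper().replace("T", "U")
    sd_dna = reverse_complement(asd_rna.replace("U", "T"))
    duplex = BuiltinDuplexEngine()
    folder = BuiltinFoldingEngine()

    utrs, cdss, strands, motif, extents = [], [], [], [], []
    for _ in range(config.n_genes):
        utr = _random_utr(seq_rng, config.utr_length)
        planted = seq_rng.random() < config.motif_fraction
        extent = 0
        if planted:
            utr, extent = _plant_site(utr, sd_dna, config.planted_distance,
                                      config.site_extent_probs, seq_rng)
        n_codons = int(seq_rng.integers(config.min_codons, config.max_codons + 1))
        utrs.append(utr)
        cdss.append(_random_cds(seq_rng, n_codons))
        strands.append("+" if seq_rng.random() < 0.5 else "-")
        motif.append(planted)
        extents.append(extent)

    # covariates from the realized sequences
    dg_bind = np.array([
        duplex.duplex_energy(asd_rna, window_at_distance(
            transcribe(u), config.planted_distance, len(asd_rna)))
        for u in utrs
    ])
    init_regions = [transcribe(u[-30:] + c[:30]) for u, c in zip(utrs, cdss)]
    dg_fold = folder.fold_energies(init_regions)

    # true log RTE, centred so typical RTE is near 1; the binding response
    # acts through functional (planted) sites only
    beta0 = -config.structure_slope * float(dg_fold.mean())
    functional = np.asarray(motif, dtype=float)
    log_rte = (beta0 + config.structure_slope * dg_fold
               + functional * response_function(dg_bind, config.response)
               + noise_rng.normal(0.0, config.noise_sigma, config.n_genes))

    # assemble the contig
    pieces, genes = [], []
    pos = 0
    pad = _random_utr(seq_rng, config.contig_pad)
    pieces.append(pad)
    pos += len(pad)
    spans = []  # (cds_start0, cds_len) per gene, 0-based on contig
    for i, (utr, cds, strand) in enumerate(zip(utrs, cdss, strands)):
        locus = utr + cds
        if strand == "+":
            pieces.append(locus)
            start = pos + len(utr) + 1
            end = pos + len(locus)
        else:
            pieces.append(reverse_complement(locus))
            start = pos + 1
            end = pos + len(cds)
        genes.append(GeneModel(f"g{i:04d}", "chr1", start, end, strand))
        spans.append((start - 1, len(cds)))
        pos += len(locus)
        gap = _random_utr(seq_rng, config.intergenic)
        pieces.append(gap)
        pos += len(gap)
    pieces.append(_random_utr(seq_rng, config.contig_pad))

    contigs = ContigSet({"chr1": "".join(pieces)})
    clen = contigs.length("chr1")
    rna_arr = np.zeros(clen)
    ribo_arr = np.zeros(clen)

    rna_rel = 10.0 ** abund_rng.normal(0.0, config.rna_log_sigma, config.n_genes)
    rte_true = 10.0 ** log_rte
    for (start0, length), rel, rte in zip(spans, rna_rel, rte_true):
        lam_rna = config.coverage_depth * rel
        rna_arr[start0 : start0 + length] += simulate_coverage(length, lam_rna, cov_rng)
        ribo_arr[start0 : start0 + length] += simulate_coverage(
            length, lam_rna * rte, cov_rng)

    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "strand": strands,
        "motif": motif,
        "site_extent": extents,
        "dg_bind": dg_bind,
        "dg_fold": dg_fold,
        "log_rte_true": log_rte,
        "rna_relative_abundance": rna_rel,
    })

    dataset = SyntheticDataset(contigs, genes, CoverageTrack({"chr1": ribo_arr}),
                               CoverageTrack({"chr1": rna_arr}), truth, config)
    if config.qc_violators:
        _append_qc_violators(dataset, seq_rng, cov_rng)
    return dataset


def _append_qc_violators(ds: SyntheticDataset, seq_rng, cov_rng) -> None:
    """Extend the contig with one gene violating each QC filter singly."""
    cfg = ds.config
    seq = ds.contigs["chr1"]
    extra_specs = [
        ("qc_short", 20, "full", "full"),       # < 30 codons
        ("qc_lowribo", 60, "sparse", "full"),   # ribo coverage < 25%
        ("qc_lowrna", 60, "full", "sparse"),    # rna coverage < 25%
        ("qc_nostart", 60, "nostart", "full"),  # zero ribo reads on +1..+10
    ]
    ribo = ds.ribo_track.array("chr1")
    rna = ds.rna_track.array("chr1")
    new_ribo, new_rna, pieces = [], [], []
    pos = len(seq)
    for gene_id, n_codons, ribo_mode, rna_mode in extra_specs:
        utr = _random_utr(seq_rng, cfg.utr_length)
        cds = _random_cds(seq_rng, n_codons)
        pieces.append(utr + cds)
        start = pos + len(utr) + 1
        end = pos + len(utr) + len(cds)
        ds.genes.append(GeneModel(gene_id, "chr1", start, end, "+"))
        length = len(cds)
        for mode, store in ((ribo_mode, new_ribo), (rna_mode, new_rna)):
            cov = simulate_coverage(length, cfg.coverage_depth, cov_rng) + 1.0
            if mode == "sparse":
                cov[int(length * 0.2):] = 0.0  # 20% of positions covered
            elif mode == "nostart":
                cov[:10] = 0.0
            store.append((start - 1, cov))
        pos = end
        gap = _random_utr(seq_rng, cfg.intergenic)
        pieces.append(gap)
        pos += len(gap)
    new_seq = seq + "".join(pieces)
    extra = len(new_seq) - len(seq)
    ribo = np.concatenate([ribo, np.zeros(extra)])
    rna = np.concatenate([rna, np.zeros(extra)])
    for start0, cov in new_ribo:
        ribo[start0 : start0 + len(cov)] = cov
    for start0, cov in new_rna:
        rna[start0 : start0 + len(cov)] = cov
    ds.contigs = ContigSet({"chr1": new_seq})
    ds.ribo_track = CoverageTrack({"chr1": ribo})
    ds.rna_track = CoverageTrack({"chr1": rna})


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
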