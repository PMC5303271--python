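"""Genome, annotation and coverage-track I/O with one fixed coordinate convention.

All genomic coordinates are 1-based and inclusive (GFF convention).  Positions
in 5' UTRs are numbered -1 (the base immediately 5' of the start codon) down to
-n; there is no position 0, and the first base of the start codon is +1.
Sequences handed to downstream thermodynamic code are RNA (T -> U),
always written 5' -> 3' on the coding strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

_DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file (FASTA/GFF3/wig)."""


class EdgeExcludedError(ValueError):
    """Requested upstream window runs off the end of the contig.

    Callers catch this and flag the gene ``edge-excluded`` rather than
    silently truncating the window.
    """


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def transcribe(seq: str) -> str:
    """DNA (coding strand) -> RNA."""
    return seq.replace("T", "U")


@dataclass(frozen=True)
class ContigSet:
    """Uppercase DNA sequences keyed by contig id."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, contig_id: str) -> str:
        try:
            return self.contigs[contig_id]
        except KeyError:
            raise KeyError(f"unknown contig id: {contig_id!r}") from None

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.contigs

    def length(self, contig_id: str) -> int:
        return len(self[contig_id])

    def ids(self) -> list[str]:
        return list(self.contigs)


@dataclass(frozen=True)
class GeneModel:
    """One annotated CDS. ``start``/``end`` are 1-based inclusive, start <= end."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class CoverageTrack:
    """Per-base non-negative counts for each contig (internally 0-based arrays)."""

    arrays: dict[str, np.ndarray]

    def array(self, contig_id: str) -> np.ndarray:
        try:
            return self.arrays[contig_id]
        except KeyError:
            raise KeyError(f"no coverage for contig {contig_id!r}") from None

    @property
    def total_signal(self) -> float:
        return float(sum(a.sum() for a in self.arrays.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack({c: a * factor for c, a in self.arrays.items()})

    @classmethod
    def zeros(cls, contigs: ContigSet) -> "CoverageTrack":
        return cls({c: np.zeros(len(s), dtype=float) for c, s in contigs.contigs.items()})


def read_fasta(path) -> ContigSet:
    """Read a FASTA file into a :class:`ContigSet`.

    Sequences are uppercased, U is converted to T, and any character outside
    A/C/G/T/N is a :class:`FormatError`.
    """
    contigs: dict[str, str] = {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or unparseable FASTA")
    for rec in records:
        if rec.id in contigs:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains illegal characters {sorted(bad)}"
            )
        contigs[rec.id] = seq
    return ContigSet(contigs)


def write_fasta(contigs: ContigSet, path) -> None:
    with open(path, "w") as fh:
        for cid, seq in contigs.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_annotation(path) -> list[GeneModel]:
    """Read CDS features from a GFF3 file.

    Only ``CDS`` lines are used; the identifier is taken from the ``ID`` or
    ``locus_tag`` attribute.  A CDS id occurring on more than one line (a
    spliced / multi-segment CDS) is rejected: the pipeline has no model for
    discontiguous coding sequences.
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            attr = _gff_attributes(attrs)
            gene_id = attr.get("ID") or attr.get("locus_tag")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: CDS without ID or locus_tag attribute")
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise FormatError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            if gene_id in genes:
                raise FormatError(
                    f"{path}:{lineno}: CDS id {gene_id!r} spans multiple segments; "
                    "multi-segment CDS are not supported"
                )
            genes[gene_id] = GeneModel(gene_id, contig, start_i, end_i, strand)
    return list(genes.values())


def write_annotation(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\tsdscan\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\tID={g.gene_id}\n"
            )


def read_wig(path, contigs: ContigSet) -> CoverageTrack:
    """Read a wiggle coverage file (fixedStep and variableStep dialects).

    Unspecified positions are zero; ``span`` repeats a value over consecutive
    bases.  ``track`` lines are ignored.  Values must be non-negative and
    positions must lie within the declared contig.
    """
    track = CoverageTrack.zeros(contigs)
    mode = None  # ("fixed", chrom, next_pos, step, span) | ("variable", chrom, span)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=", 1) for p in line.split()[1:])
                chrom = kv["chrom"]
                if chrom not in contigs:
                    raise FormatError(f"{path}:{lineno}: unknown chrom {chrom!r}")
                mode = ["fixed", chrom, int(kv["start"]), int(kv.get("step", 1)),
                        int(kv.get("span", 1))]
                continue
            if line.startswith("variableStep"):
                kv = dict(p.split("=", 1) for p in line.split()[1:])
                chrom = kv["chrom"]
                if chrom not in contigs:
                    raise FormatError(f"{path}:{lineno}: unknown chrom {chrom!r}")
                mode = ["variable", chrom, int(kv.get("span", 1))]
                continue
            if mode is None:
                raise FormatError(f"{path}:{lineno}: data before any step declaration")
            if mode[0] == "fixed":
                _, chrom, pos, step, span = mode
                value = float(line)
                _assign(track, contigs, chrom, pos, span, value, path, lineno)
                mode[2] = pos + step
            else:
                _, chrom, span = mode
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: expected 'pos value'")
                pos, value = int(parts[0]), float(parts[1])
                _assign(track, contigs, chrom, pos, span, value, path, lineno)
    return track


def _assign(track, contigs, chrom, pos, span, value, path, lineno):
    if value < 0:
        raise FormatError(f"{path}:{lineno}: negative coverage value {value}")
    clen = contigs.length(chrom)
    if pos < 1 or pos + span - 1 > clen:
        raise FormatError(
            f"{path}:{lineno}: position {pos} (span {span}) outside contig "
            f"{chrom!r} of length {clen}"
        )
    track.array(chrom)[pos - 1 : pos - 1 + span] = value


def write_wig(track: CoverageTrack, path) -> None:
    """Write a track as fixedStep wig (step 1 from position 1); exact round-trip."""
    with open(path, "w") as fh:
        for chrom, arr in track.arrays.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            buf = io.StringIO()
            for v in arr:
                buf.write(f"{v:g}\n")
            fh.write(buf.getvalue())


def extract_upstream(gene: GeneModel, contigs: ContigSet, n: int) -> str:
    """The ``n`` bases immediately 5' of the start codon, as RNA, 5'->3'.

    Returned positions are UTR coordinates -n ... -1.  Strand-aware: for a
    minus-strand gene the region lies 3' of ``end`` on the reference and is
    reverse-complemented.  Windows running off the contig raise
    :class:`EdgeExcludedError`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seq = contigs[gene.contig_id]
    if gene.strand == "+":
        lo, hi = gene.start - n, gene.start - 1  # 1-based inclusive
        if lo < 1:
            raise EdgeExcludedError(
                f"gene {gene.gene_id}: upstream window {lo}..{hi} off contig start"
            )
        region = seq[lo - 1 : hi]
    else:
        lo, hi = gene.end + 1, gene.end + n
        if hi > len(seq):
            raise EdgeExcludedError(
                f"gene {gene.gene_id}: upstream window {lo}..{hi} off contig end"
            )
        region = reverse_complement(seq[lo - 1 : hi])
    return transcribe(region)


def extract_cds_prefix(gene: GeneModel, contigs: ContigSet, n: int) -> str:
    """First ``n`` coding bases (positions +1 ... +n), as RNA, 5'->3'."""
    if n > gene.length_nt:
        raise ValueError(f"gene {gene.gene_id}: CDS shorter than {n} nt")
    seq = contigs[gene.contig_id]
    if gene.strand == "+":
        region = seq[gene.start - 1 : gene.start - 1 + n]
    else:
        region = reverse_complement(seq[gene.end - n : gene.end])
    return transcribe(region)


def extract_initiation_region(gene: GeneModel, contigs: ContigSet,
                              flank: int = 30) -> str:
    """The -flank ... +flank initiation region around the start codon (60 nt
    by default): ``flank`` upstream bases followed by the first ``flank``
    coding bases, strand-aware, RNA alphabet."""
    return extract_upstream(gene, contigs, flank) + extract_cds_prefix(gene, contigs, flank)


_START_CODONS = {"AUG", "GUG", "UUG"}


def start_codon(gene: GeneModel, contigs: ContigSet) -> str:
    return extract_cds_prefix(gene, contigs, 3)


def is_canonical_start(gene: GeneModel, contigs: ContigSet) -> bool:
    return start_codon(gene, contigs) in _START_CODONS
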