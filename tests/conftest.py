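import numpy as np
import pytest

from sdscan.sequence_io import ContigSet, CoverageTrack, GeneModel
from sdscan.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def qc_fixture():
    """Five genes on one contig: one violates each QC filter singly, one passes.

    All CDS are fully covered unless a filter requires otherwise; every gene
    has nonzero start-window reads unless that is the violated filter.
    """
    n = 5
    cds_len = 120  # 40 codons
    spacing = 200
    contig_len = spacing * (n + 1)
    seq = ("A" * 50 + "ATG" + "GCT" * ((spacing - 56) // 3))  # filler motif
    genome = (seq * (n + 2))[:contig_len]
    contigs = ContigSet({"c1": genome})
    genes = []
    starts = [spacing * i + 61 for i in range(n)]
    specs = [
        ("pass", cds_len), ("short", 60), ("lowribo", cds_len),
        ("lowrna", cds_len), ("nostart", cds_len),
    ]
    ribo = np.zeros(contig_len)
    rna = np.zeros(contig_len)
    for start, (name, length) in zip(starts, specs):
        end = start + length - 1
        genes.append(GeneModel(name, "c1", start, end, "+"))
        ribo_cov = np.full(length, 5.0)
        rna_cov = np.full(length, 5.0)
        if name == "lowribo":
            ribo_cov[int(length * 0.2):] = 0.0  # 20% coverage < 25%
        if name == "lowrna":
            rna_cov[int(length * 0.2):] = 0.0
        if name == "nostart":
            ribo_cov[:10] = 0.0
        ribo[start - 1 : end] = ribo_cov
        rna[start - 1 : end] = rna_cov
    return genes, CoverageTrack({"c1": ribo}), CoverageTrack({"c1": rna}), contigs


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene synthetic dataset at default (deep-coverage) settings."""
    return generate_dataset(SyntheticConfig(n_genes=300, seed=11))


@pytest.fixture(scope="session")
def small_dataset_files(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_ds")
    return small_dataset, small_dataset.write(outdir)
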