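# sdscan

Quantifying how anti-Shine–Dalgarno (aSD) sequence complementarity in 5′
UTRs predicts the translation efficiency of bacterial genes.

During translation initiation in prokaryotes, the 3′ tail of the 16S rRNA
(the aSD sequence, conserved core 5′-CCUCC-3′) base-pairs with
purine-rich Shine–Dalgarno motifs upstream of start codons. Three questions
about this interaction remain surprisingly open: *where* relative to the
start codon binding is most effective, *which* 16S bases actually
participate, and *what functional form* links binding strength to protein
output. `sdscan` implements a data-driven answer: it leverages the natural
sequence diversity of thousands of endogenous genes together with
genome-wide translation-efficiency estimates, scanning a grid of candidate
aSD definitions and binding distances for the cell that best predicts
translation efficiency.

## The method

1. **Relative translation efficiency.** From ribosome-profiling and RNA-seq
   coverage tracks, each gene *i* gets
   `RTE_i = RPKM_ribosome,i / RPKM_RNA,i`, after quality filters (≥25 % CDS
   coverage in both tracks, ≥30 codons, nonzero ribosome signal on the
   first 10 coding bases). A precomputed RTE table can be supplied instead
   for datasets measured by other means (single-cell protein distributions,
   reporter libraries).
2. **Structure residualization.** log RTE is regressed on the predicted
   folding energy ΔG_folding of the −30…+30 initiation region, and all
   further modelling uses the residuals — isolating the aSD signal from the
   dominant effect of mRNA structure around the start codon.
3. **The (aSD × distance) scan.** For every candidate aSD (5′/3′ extensions
   of CCUCC along the 16S tail, extended past the known terminus as a
   control) and every distance *d* = −1…−14 (bases strictly between the
   window's 3′ end and the start codon), residual RTE is regressed on the
   aSD::window hybridization energy ΔG_binding with first- and third-order
   polynomials. Fits are ranked by adjusted R²,
   `R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1)`, with AIC and F-tests
   reported; among near-equivalent cells the shortest candidate is
   selected.
4. **Effect size.** Genes are split into quintile bins of ΔG_binding; the
   percent increase in back-transformed mean residual RTE of the best bin
   over the weakest-binding bin gives a model-free effect size.

Hybridization energies come from a gapless antiparallel nearest-neighbor
engine (Turner 2004 stacking parameters, Watson–Crick + GU wobble, +4.09
kcal/mol initiation penalty); folding energies from a maximum
base-pairing dynamic program, with an optional ViennaRNA
(RNAfold/RNAcofold) adapter behind the same interfaces.

Because the original genome-wide datasets are external, the package ships a
first-class synthetic-data generator that renders planted ground truth
(an aSD motif at a chosen distance, a peaked dose–response, structure
effects, Poisson coverage noise) to the same FASTA/GFF3/wig formats the
real pipeline reads — so every stage is testable end to end, and recovery
of the planted parameters can be scored exactly.

## Worked example

Simulate a 2000-gene genome with the aSD 5′-ACCUCCUUA-3′ planted at
distance −5 (peaked response, 50 % boost at the optimum, σ = 0.3 log-RTE
noise), then scan it:

```bash
sdscan simulate --n-genes 2000 --asd ACCUCCUUA --distance -5 \
    --seed 1 --outdir sim/
sdscan scan --fasta sim/genome.fasta --gff sim/annotation.gff3 \
    --wig-ribo sim/ribo.wig --wig-rna sim/rna.wig --outdir scan/
```

prints

```json
{
  "asd": "ACCUCCUU",
  "distance": -5,
  "n": 2000,
  "r2": 0.05043143766933966,
  "r2_adj": 0.04900423041132773,
  "aic": 854.4804055207574,
  "f_pvalue": 3.011936202875187e-22,
  "tolerance": 0.005,
  "duplex_engine": "builtin-nearest-neighbor"
}
```

The scan finds the planted binding site exactly: the selected candidate
`ACCUCCUU` at *d* = −5 occupies the same genomic register as the planted
`ACCUCCUUA` at −5 (the conserved core CCUCC at core-register distance −6);
single-base extensions at the site boundaries differ by less than the
0.005 R²_adj selection tolerance, which is precisely why the shortest of
the near-equivalent candidates is reported. The quintile summary
(`sdscan quintiles`) shows the expected peaked dose–response — the
strongest-binding bin translates *worse* than intermediate binders — with
a 45.7 % increase of the best over the weakest-binding quintile, matching
the planted 50 % peak effect after bin averaging.

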