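# Methods

## Model and procedure

`sdscan` asks whether complementarity between a candidate anti-Shine–
Dalgarno (aSD) sequence and a fixed-length window of a gene's 5′ UTR
predicts that gene's translation efficiency, and uses the answer — scanned
over candidate definitions and window positions — to infer the functional
aSD sequence and its optimal distance to the start codon.

**Coordinates.** All genomic coordinates are 1-based inclusive. UTR
positions are numbered −1 (immediately 5′ of the start codon) to −n; there
is no position 0; the A, U, G of the start codon are +1, +2, +3. The
distance *d* of a scanning window is the number of bases strictly between
the window's 3′-most base and the start codon, written negative: a 5-mer
at *d* = −7 occupies −12…−8. Measuring from the window's 3′ end keeps *d*
invariant under 5′ extension of the aSD candidate; `core_register_distance`
converts a (candidate, *d*) pair back to the numbering of the conserved
CCUCC core, which is the coordinate in which two candidates "bind the same
genomic site".

**Relative translation efficiency.** `RTE_i = RPKM_ribo,i / RPKM_RNA,i`.
Wiggle tracks store per-base coverage rather than read starts, so the RPKM
"read count" is the per-base coverage sum over the CDS; since RTE is a
ratio, any consistent linear functional of the reads cancels the
library-specific constants. Genes are excluded (with logged reason codes)
when CDS coverage is below 25 % in either track, the CDS is shorter than
30 codons, or no ribosome signal maps to coding positions +1…+10 (a
strand-aware window; such genes are likely misannotated). Thresholds are
inclusive: coverage of exactly 0.25 survives. Genes with zero RNA signal
have no defined RTE; genes with RTE = 0 have no defined log and are
excluded from all regression stages (counted in the log). log base is 10
and configurable; it cancels from every R², AIC and p-value and only
rescales effect sizes, which are back-transformed in the same base.

**Structure residualization.** mRNA structure around the start codon is
the dominant sequence covariate of translation efficiency, so log RTE is
first regressed (OLS with intercept) on the folding energy ΔG_folding of
the −30…+30 initiation region and downstream modelling uses the
residuals. The stage is optional (`structure_correction: off` models
log RTE directly); if ΔG_folding is constant across genes the regression
is degenerate and the pipeline falls back to centred log RTE, which is the
same thing up to a shift.

**Hybridization scan.** For each candidate aSD (all 5′/3′ extensions of
CCUCC within the configured 16S 3′-tail string, default
`GGAUCACCUCCUUA` plus the control characters `GCAU` appended past the
known terminus; extensions up to 6 bases 5′ and 4 bases 3′) and each
distance −1…−14 (14 hybridization events per gene), residual RTE is
regressed on ΔG_binding with first- and third-order polynomials. Each
landscape cell records n, R², R²_adj, AIC (2k − 2 log L with k = order + 2
Gaussian parameters; only differences between orders matter) and the
F-test p-value against the intercept-only model. Cells with n below a
minimum (default 50), a constant predictor, or a rank-deficient cubic
design are marked invalid rather than dropped. No multiple-testing
correction is applied across the landscape; the permutation null
(`permutation_null_max_r2_adj`, which re-scans the full grid on shuffled
residuals using per-cell QR factorizations) is the principled alternative
and is what the tests use.

**Selection.** Among cells whose third-order R²_adj is within a tolerance
(default 0.005) of the landscape maximum, the shortest candidate is
selected; ties break by larger R²_adj, then by distance closer to the
start codon. The tolerance encodes a real statistical fact: single-base
additions or deletions at the boundaries of the aSD change the fit by far
less than the scan can resolve, so the extent boundary is reported
parsimoniously rather than over-confidently. The selection rule and
tolerance are recorded in the output.

**Quintile effect size.** Genes ranked from weakest (least negative
ΔG_binding) to strongest binding are split into five equal bins (sizes
differ by at most one, larger bins first; boundary ties break by stable
gene order). The effect is `(B^(m_best − m_weakest) − 1) × 100` with B the
log base, m_best the largest bin mean and m_weakest the first bin's mean.
The bin with the empirical maximum is used (and all five bins reported)
because which bin is optimal varies between datasets.

**Operon stratification.** Given a gene → (operon, position) table, genes
are split into first-in-transcription-unit versus internal, and the
already-selected (aSD, distance) model is re-fitted per stratum — the scan
is not re-run, since the question is whether the same signal holds in each
stratum.

## Energy engines

Two interchangeable engines exist for each thermodynamic step; engine
names are recorded in all outputs.

*Duplex (default `builtin-nearest-neighbor`).* Gapless antiparallel
hybridization of two equal-length strands at the full-overlap register,
scored with Turner 2004 nearest-neighbor stacking free energies (ΔG37,
Watson–Crick and GU wobble; shipped as a versioned TSV) plus a +4.09
kcal/mol duplex initiation penalty. Stacking accrues between consecutive
complementary positions, so isolated single pairs contribute nothing; a
non-negative optimum is reported as 0 (no stable duplex). Bulges and
internal loops are deliberately out of scope — the scan varies the
register, so fixed-register hybridization is the quantity of interest —
and the `viennarna-rnacofold` adapter provides full cofolding where the
bindings are available. The two engines agree in rank (Spearman ρ ≥ 0.9 on
graded duplex sets in the tests) though not in absolute value. Note one
consequence of wobble stacking: a GU-containing variant can bind
marginally *more* strongly than the perfect Watson–Crick complement for
some sequences, which is physically expected. The engine satisfies the
strand-exchange identity E(a, b) = E(b, a) — one duplex viewed from either
strand — but not mirror symmetry E(a, b) = E(reverse(b), reverse(a)),
because nearest-neighbor parameters are direction-dependent.

*Folding (default `builtin-maxpair`).* A maximum weighted base-pairing
dynamic program (GC = −3, AU = −2, GU = −1, minimum hairpin loop 3),
vectorized across sequences so that thousands of 60-mers fold in well
under a second. Its output is a pseudo-ΔG: it tracks thermodynamic
minimum free energies in rank only (ρ ≈ 0.55 against RNAfold on random
60-mers), which suffices for a covariate that enters only through a fitted
linear term. The `viennarna-rnafold` adapter substitutes true MFE folding.
Windows containing N are excluded from all energy computations and logged.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with planted ground truth written alongside every dataset.

* **Sequences.** Genes (default 2000) are laid out on one contig with
  random strand, 40-nt designed UTRs on an AU-rich background
  (A/C/G/U = 0.32/0.18/0.20/0.30), random CDS of 50–250 codons (ATG start,
  no internal stops), 20-nt intergenic gaps and 60-nt contig pads.
* **Planted sites.** A fraction of genes (default 0.6) carry a functional
  SD site at the planted distance (default: reverse complement of
  ACCUCCUUA at *d* = −5). Each site is an exact contiguous match to a
  random portion of the full SD, with extent drawn from a distribution
  over 3–9 bp (0.10/0.15/0.20/0.20/0.15/0.10/0.10) and anchored uniformly
  within the register. This mirrors the defining feature of real 5′ UTRs —
  SD motifs of widely varying extent — and is what makes aSD-extension
  scanning informative; an i.i.d. per-position mismatch model was
  considered and rejected as unrealistic (it makes every position equally
  and weakly informative).
* **Response.** True log RTE = β₀ + β_s·ΔG_fold + 1{site}·f(ΔG_bind) +
  N(0, σ), σ = 0.3. The dose–response f is a downward quadratic through
  zero at ΔG_bind = 0 with maximum at ΔG_opt = −7 kcal/mol and height
  log₁₀(1.5) — a 50 % boost at the optimum, decaying for binding stronger
  than the optimum (binding beyond 2·ΔG_opt is detrimental). A `linear`
  mode exists for null/contrast experiments. The response is gated on the
  planted-site indicator so that `motif_fraction = 0` is an exact null;
  incidental background complementarity carries no effect. ΔG_fold and
  ΔG_bind are computed from the *realized* sequences with the built-in
  engines, so the residualization stage faces genuine sequence–covariate
  coupling. β_s = 0.03 log-RTE per kcal/mol puts the structure fit at
  R² ≈ 0.06–0.08 on default data.
* **Coverage.** RNA abundance is log-normal (σ = 0.5 in log₁₀); expected
  ribosome coverage is RNA coverage × true RTE; per-base counts are
  independent Poisson at a default mean depth of 25 reads/base. At that
  depth estimated and true log RTE correlate at r > 0.99; the correlation
  degrades smoothly as depth falls.
* **Determinism.** One mandatory seed drives named substreams (sequence,
  noise, abundance, coverage); identical configurations produce
  byte-identical files.

What the generator does **not** emulate: operonic co-transcription,
variable UTR lengths/annotated TSSs, footprint size-selection biases,
elongation or termination effects, or ribosomal protein S1 binding.
Passing tests therefore demonstrate that the inference machinery recovers
a planted signal of realistic shape and size through realistic noise — not
that any particular real genome satisfies the generative assumptions.

## Numerical and design choices

* Problem sizes: the end-to-end recovery runs use 2000 genes, a 35 ×
  14-cell landscape and 100-permutation nulls; model-order discrimination
  uses 100 replicates at n = 1000. These sizes give stable statistics
  while keeping a full test-and-acceptance cycle to a couple of minutes.
* Boundary resolution: at σ = 0.3 and n = 2000, same-register candidates
  differing by one boundary base differ by ~0.001–0.003 R²_adj — below the
  0.005 selection tolerance. Recovery of the planted parameters is
  therefore asserted at the level of the binding *site* (core sequence and
  genomic register, plus the selected sequence lying within the planted
  aSD at that register); the exact extent boundary is not statistically
  identifiable at this noise level, and the selection rule's preference
  for the shortest near-equivalent candidate makes that explicit.
* AIC order selection: with a truly linear response, the cubic's two
  spurious parameters yield a 2·Δlog L that is asymptotically χ²₂, so AIC
  (penalty 4) picks the linear model with probability ≈ 1 − e⁻² ≈ 86.5 %.
  Observed rates across seeds are 83–88 %. This is an inherent property of
  AIC, not a defect of the implementation; with a peaked response the
  cubic wins in 100/100 replicates.
* The F-test p-value is computed against the intercept-only model; its
  type-I rate is verified by simulation (p > 0.01 in ≥ 95/100 null
  replicates).
* Quintile binning attenuates the planted peak effect (bin averaging
  mixes genes on and off the optimum): the noiseless quintile contrast for
  the default generator is ≈ 43 % against a planted 50 % peak, and
  measured values across seeds fall in ≈ 30–50 %.
* `min_n` for a landscape cell defaults to 50; below that, cubic fits on
  discrete energy values become unstable and cells are flagged invalid.

## Known limitations

* The built-in folding engine is a rank proxy, not a thermodynamic model;
  absolute ΔG_folding values are not comparable across engines.
* Gapless fixed-register hybridization underestimates binding for bulged
  duplexes; candidates longer than the true aSD partially compensate by
  scanning additional registers.
* Multi-segment (spliced) CDS records are rejected; only single-interval
  bacterial-style CDS are supported.
* The scan assumes equal-length UTR availability per gene; genes whose
  UTR window runs off the contig are excluded and logged, not truncated.
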