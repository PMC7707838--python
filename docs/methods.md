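# Methods

`dualqtl` implements bulk-segregant (X-QTL) mapping of *trans*-acting loci
that affect the mRNA production and the protein abundance of the same gene,
as read out by a dual fluorescent reporter (mCherry proportional to mRNA
production, GFP proportional to protein abundance) in single live yeast
cells. Pools of segregants sorted from the fluorescence extremes are
sequenced in bulk; loci reveal themselves as allele-frequency differences
(ΔAF) between the high and the low pool. This note records the model, the
defaults, and the design choices where the design was genuinely open.

## The contrast LOD model

Marker read counts are summed into fixed-width genomic bins (default 100 bp).
Within one pool, the unobserved pool allele frequency p is modeled as a
Markov chain along each chromosome. Over a gap of d bp the recombination
fraction is r = min(0.5, d / (bp_per_cM · 100)) with 2,200 bp/cM (the BY×RM
map scale); the transition has mean p + r(1 − 2p) — frequency relaxes toward
0.5 as linkage to any selected site decays — and variance r(1 − r)/N, where
N (default 1,000) is the effective number of segregants in the pool and sets
the drift of pool frequency along the genome. The chain is discretized on a
uniform frequency grid (default 201 points) with truncated-Gaussian cell
masses renormalized per row; gaps of r ≥ 0.5 reset the chain to its flat
prior, which also makes chromosomes independent. Emissions are
Binomial(n, p) in the reference (BY) read count, or beta-binomial with
overdispersion ρ when ρ > 0 (default ρ = 0). The prior at the first bin of a
chromosome is uniform. Scaled forward–backward recursions (normalized at
every step, so no underflow is possible) yield per-bin posteriors γ,
leave-one-out predictives, and the chain's no-data marginal m.

The per-bin LOD contrasts "the two pools have unconstrained frequencies"
against "the two pools have equal frequency at this bin". The likelihood
ratio reduces to a Savage–Dickey density ratio over the two pools' posterior
distributions at the bin:

    LOD(t) = −log10 Σ_p γ_high,t(p) · γ_low,t(p) / m_t(p)

Because each posterior aggregates the evidence of all linked bins through
the chain, the LOD grows with both read depth and the physical extent of a
frequency divergence. This is what gives 3% tail sorts mapping power at a
median coverage of only 13×: a locus with ΔAF ≈ 0.3 spreads its signal over
~100 kb of linked markers and reaches LOD 20–40, while any single 100-bp bin
holds only ~13 reads. A purely local single-bin contrast (available as the
`local_lod` diagnostic, built from leave-one-out predictive likelihoods of
the bin's own counts) is bounded by those ~13 reads at roughly LOD ≤ 1 for
realistic ΔAF, and is therefore not used for peak calling. Negative LOD
values — evidence *for* equality — are clipped to zero. Exchanging the pools
leaves the track unchanged, and inference runs only over informative bins
(nonzero depth in either pool), with gaps compounded into the transition.

Correctness of the recursions is checked against a brute-force oracle that
evaluates the same formula by direct summation over the full joint
hidden-state tensor on instances of up to 3 bins (agreement to < 1e-6;
observed ~1e-15).

## From counts to classified loci

1. **Allele frequencies.** BY-allele frequency per marker, missing at zero
   depth. Markers with AF strictly above 0.9 or below 0.1 in *either* pool
   of a pair are dropped from both (the bounds themselves are retained).
   Applying the filter per pair rather than per pool is an assumption; it is
   the stricter of the two readings.
2. **Smoothing.** Counting noise is smoothed per chromosome by a
   depth-weighted local-linear (loess-type) regression with tri-cube weights
   over a fixed 20 kb physical bandwidth, clipped to [0, 1]. A fixed
   physical bandwidth is robust to uneven marker density and is well below
   typical confidence-interval widths. Reported ΔAF (high − low) comes from
   these smoothed tracks; the HMM's posterior-mean difference is *not* used
   as an effect estimate because the chain's no-selection prior shrinks it
   toward zero.
3. **Peaks.** One peak per maximal contiguous run of bins with LOD ≥ the
   threshold (permissive 3.0); the peak is the run's highest bin (ties to
   the smallest coordinate), and the support interval extends to the outer
   edge of the first bin at or below peak − 2 LOD, clamped to the track
   extent. Runs with several local maxima deliberately yield a single peak;
   the replicate merge absorbs residual ambiguity.
4. **Replicate merging.** Peaks called per replicate at LOD > 3 are re-read
   in every replicate's track at each peak position (no per-replicate LOD
   filter), averaged, and collapsed by single-linkage when peaks lie within
   75 kb; merged position, LOD, ΔAF and interval bounds are member means. A
   strict-clique grouping mode exists for sensitivity analysis. Merged QTLs
   with mean LOD ≥ 4.5 are significant.
5. **FDR.** Contrasts of pools sorted into the same gate in different
   replicates (same sequencing batch) can contain only false positives.
   FDR(thr) = (N_nullQTL/N_null-comparisons) / (N_signalQTL/N_signal-
   comparisons) over a threshold grid; raw ratios are reported as computed
   and a non-increasing (running-minimum) version is also emitted because
   sparse-threshold ratios are noisy.
6. **Concordance.** Per gene, merged QTLs of the two channels pair when
   their confidence intervals overlap; a QTL overlapping several partners
   takes the highest-LOD one (a closest-peak mode is provided). Manual
   curation overrides (six ship with the package) are applied last. Loci in
   the chrXIV 350–550 kb region — which affects the mCherry reporter for
   every tagged gene, plausibly via the pleiotropic *MKT1* variant or
   reporter maturation — are excluded (inclusive bounds) before pairing.
   Pairs are kept when *either* member reaches LOD ≥ 4.5, so a pair whose
   weaker member narrowly misses significance is not misread as specific.
   Classes: concordant (both members, same ΔAF sign), discordant (opposite
   signs), mRNA-specific / protein-specific (single member). A ΔAF of
   exactly zero in a pair is flagged `undetermined`, never silently
   assigned. For effect comparisons that avoid thresholding the other
   channel, the other channel's smoothed ΔAF is read at the significant
   member's exact peak position and averaged over replicates; direction
   agreement is tested with an exact binomial test against 0.5 with an
   explicit denominator.

## The synthetic cross

The generator produces every input of the pipeline with known truth, at
realistic experimental conditions: haploid segregants from a two-parent cross
simulated marker-to-marker with switch probability r = min(0.5, d/(2,200·100))
(linear map, no interference, i.i.d. meiotic products — no tetrad or clonal
structure, which is second-order for pools drawn from large spore
populations); biological replicates are independent segregant populations.
Single-cell phenotypes follow

    R = t + γ·log FSC + ε_R,   G = κ·t + s + γ·log FSC + ε_G,

where t and s are additive genetic values of the transcription effects a_j
and the protein-specific effects b_j (genotype BY contributes +effect/2, so
positive effects mean the BY allele increases the trait, matching the ΔAF
sign convention), κ = 1 transmits mRNA effects to protein, σ_R = σ_G = 1,
γ = 1 couples both reporters to cell size (log FSC ~ Normal(4, 0.25)).
Sorting gates cells to the central 60% of FSC, then takes the top and bottom
q = 3% of the gated channel signal, capped at 10,000 cells (such sorts use
3–5% tails in practice, so q is overridable);
an unsorted control pool is a disjoint random gate sample. Sequencing draws
per-marker depth ~ Poisson(13) and BY reads ~ Binomial with error rate
0.001.

Defaults: 4 chromosomes × 500 kb with markers every 1 kb (2,000 markers,
a desk-scale stand-in for the 16-chromosome, 18,871-marker BY/RM marker set; any
layout, including full scale, is configurable), 50,000 segregants, and one
planted locus per class on its own chromosome: concordant a = 0.30,
protein-specific b = 0.35, mRNA-specific a = 0.35 with b = −κa (perfect
buffering), discordant a = 0.35 with b = −1.75κa (overcompensation, net
protein effect −0.26σ). These give expected |ΔAF| ≈ 0.25–0.4, the middle of the range real
trans-acting loci show in such crosses. One locus per chromosome keeps
super-threshold runs of distinct loci separate: the pool-frequency
divergence of a locus decays over ~110 kb, and two strong loci on one
chromosome can otherwise hold the LOD valley between them above the
permissive threshold and fuse into one called peak. Expected ΔAF per locus
and channel is computed from the Gaussian truncation-selection identity
(mixture cutoff solved numerically) and written to the truth table.

What the generator does not emulate: reporter maturation kinetics, mCherry
saturation, ribozyme cleavage, diploid/sporulation genetics, batch effects
between replicates, alignment or PCR-duplicate artifacts, and real marker
spacing heterogeneity. Passing recovery tests therefore demonstrates that
the statistical pipeline is correct and calibrated under its own model
assumptions — not that those assumptions capture every property of real
pooled sequencing.

## Numerical choices and degenerate inputs

* Frequency grid 201 points; transition matrices cached per unique gap;
  CDF-difference discretization handles kernels narrower than a grid cell.
* Overlap sums are floored at 1e-300 before the log, capping LOD at 300 and
  guaranteeing finite output; recursions raise on underflow rather than
  emit NaN.
* Loess: chromosomes with fewer than 5 informative markers pass through
  unsmoothed with a warning; constant-FSC event tables fall back to mean
  centering with a warning; the cytometry t-test is Welch's (pools carry no
  equal-variance guarantee).
* Pools with median depth below 2 are rejected on read (well below the ~5×
  practical minimum of pooled designs, ΔAF is noise-dominated).
* Ties in peak LOD break to the smallest coordinate; merged-QTL grouping is
  order-invariant.
* Event tables are read from TSV (columns FSC, SSC, GFP, mCherry); raw and
  natural-log fluorescence modes are provided for the loess size
  correction.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the desk-scale configuration:
50 no-QTL scans for null calibration, 8 two-replicate null studies for the
replicate-null FDR, and 10 seeded studies for detection/class recovery.
These sizes give Monte-Carlo resolution well inside the asserted margins
while keeping a full run in the low minutes on one CPU.

## Known limitations

* The LOD is a faithful re-implementation of the binned hidden-frequency
  contrast idea, validated against its own brute-force oracle and by
  simulation calibration; it does not reproduce any earlier tool's numerics
  bin-for-bin.
* Merged ΔAF is attenuated slightly by smoothing and by the extreme-AF
  filter at low depth; effect-size comparisons across channels are
  unaffected because both channels share the estimator.
* fraction_overlap and the FDR depend on the replicate pairing actually
  available; the number of null comparisons is an input (default 80), not
  derived from the manifest.
* With a single replicate, merging is a pass-through and reproducibility
  statistics are undefined by construction.
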