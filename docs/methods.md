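# Methods

This note records the models, parameter choices and numerical decisions
behind `barhrm`, and what the synthetic-data tests do and do not establish
about real instrument data.

## Thermodynamic model

Duplex melting temperatures use the unified oligonucleotide
nearest-neighbor parameter set: per-dinucleotide stacking ΔH/ΔS, terminal
initiation terms for G·C and A·T ends, and a symmetry entropy correction
(−1.4 cal/(mol·K)) for self-complementary strands, with

T_m(K) = 1000·ΔH / (ΔS + R·ln(C_T/x)),  R = 1.987 cal/(mol·K),

x = 4 for non-self-complementary duplexes and 1 for palindromes. Defaults
are C_T = 5·10⁻⁸ mol/L (50 nM total strands) and [Na⁺] = 0.05 mol/L,
matching typical HRM master-mix conditions. Salt is corrected additively in
Celsius, +16.6·log₁₀[Na⁺], the classic form consistent with treating the
sodium term as an additive empirical correction; an entropic alternative
(ΔS + 0.368·(N−1)·ln[Na⁺]) is selectable via `ThermoParams`. Two caveats
are deliberate: the parameter set is calibrated on short oligos and is here
extrapolated to 100–250 bp amplicons — the *ranking* of candidates, not the
absolute Tm, is load-bearing — and dye/Mg²⁺ stabilization is not modeled;
empirically, on-instrument Tm runs 0.7–1.5 °C above these predictions, and
the simulator's thermo-coupled mode adds the band midpoint (+1.1 °C) when
deriving group centers from sequences.

The hairpin screen is intentionally not a full minimum-free-energy fold: it
enumerates every perfect reverse-complement stem (stem ≥ 4 bp, loop ≥ 3 nt),
scores stems by nearest-neighbor stacking at the screening temperature
(37 °C) plus a fixed loop-size penalty {3: +5.6, 4: +5.6, 5: +5.7, 6: +5.4,
≥7: +6.0} kcal/mol, and flags structures below −2.0 kcal/mol. It answers
the single design question "could secondary structure distort this
amplicon's melt peak", for which perfect-stem enumeration suffices; bulges,
internal loops and multibranch structures are out of scope.

## Amplicon screening

Species barcodes are aligned globally (affine Needleman–Wunsch; match +1,
mismatch −1, gap open −2, extend −0.5; a gap of length L costs
open + (L−1)·extend; traceback ties resolve diagonal → up → left).
Discriminatory sites are isolated substitution columns (SNPs; IUPAC-
compatible columns are not variants) and maximal runs of gap columns merged
into single InDels. Candidate amplicons are alignment windows whose
degapped length in both species lies in [100, 250] bp by default, whose
first and last 20 columns are identical in both species (a primer-binding
surrogate — real primer design rules are instrument/software-specific and
not reproduced), and which contain at least one variant strictly inside the
flanks; windows carrying identical variant sets are deduplicated keeping
the shortest. Screening retains candidates with ΔTm strictly above 0.3 °C,
excludes single-SNP candidates below 0.4 °C, and ranks survivors by

rank = 1.0·min(ΔTm, 1.5) + 0.5·[length ∈ 100–200] + 0.5·[GC ∈ 40–60 %] +
0.5·[multi-variant],

an explicit codification of a verbal preference order; the weights are
package-defined and configurable. ΔTm may be predicted (design mode) or
measured from melt peaks (assay mode); the report records which.

## Melt-curve model and simulator

Each simulated curve is a mixture of two-state logistic melting domains on
linear baselines:

F(T) = scale·[Σ w_d·θ_d(T)]·L_pre(T) + scale·[1−Σ w_d·θ_d(T)]·L_post(T) + ε,
θ_d(T) = 1/(1+exp((T−Tm_d)/w_d)),

chosen as the minimal model whose −dF/dT apex sits exactly at Tm — the
quantity the analysis reads. Defaults emulate the acquisition protocol and
plausible instrument behavior: grid 65–94 °C at 0.1 °C (291 points),
transition width 0.45 °C, baselines 100 → 5 RFU with slopes −0.3/−0.05
RFU/°C, per-sample scale LogNormal(0, 0.05), fluorescence noise
σ = 0.95 RFU (1 % of the melt amplitude), within-group Tm jitter
σ = 0.05 °C. Noise magnitudes are package choices (no instrument values
are available) exposed in `CohortSpec`; the generator can produce both a
cleanly separable regime (ΔTm = 0.6 °C) and an unresolvable one
(ΔTm = 0.05 °C), and tests verify both. Cohort RNG substreams are derived
per sample from (seed, sample index), so enlarging a cohort never
reshuffles earlier samples; declared-label swaps change only the label as
sold, never the generating model. Fluorescence is floored at 0 RFU (melt
curves are non-negative by contract; at default noise the floor is never
reached in practice).

The default market cohort (`market_cohort_spec`) encodes the validation
study conditions: 24 samples with midpoints uniform in 87.8–88.0 °C, 6 in
88.4–88.6 °C, four of the latter declared "PG".

What passing these tests shows — and does not. The simulator reproduces the
statistical structure the analysis relies on (species-specific Tm, curve
shape, drift, scale, noise) but not PCR efficiency variation, dye
redistribution, heteroduplexes in mixed templates, probe-level spatial
calibration error, or inhibitor-degraded amplification. Perfect concordance
on synthetic cohorts therefore validates the *analysis chain*, not assay
performance on difficult real matrices.

## Melt-curve analysis

−dF/dT is estimated by Savitzky–Golay local quadratic least squares with
the window expressed in °C (±0.5 °C by default, 11 points at the default
grid; at least 7 points are required), making derivative estimates
grid-resolution-stable. Peaks are local maxima at or above 10 % of the
global derivative maximum (the software-style noise threshold; sub-
threshold bumps are never reported). The apex is refined by a least-squares
parabola over the points within ±0.5 °C of the discrete maximum rather
than a minimal 3-point interpolation: with 1 % fluorescence noise the
3-point form left mean |error| ≈ 0.045 °C (max 0.17 °C), while the widened
fit achieves ≈ 0.019 °C (max ≤ 0.09 °C) with unchanged noise-free bias
(0.003 °C).

Normalization fits straight lines in a pre-melt and a post-melt window and
rescales to 100 %/0 %: N(T) = 100·(F−L_post)/(L_pre−L_post). It is exactly
invariant to per-sample affine fluorescence transforms with positive gain.
Auto-placed windows are up to 1.5 °C wide and sit **adjacent to the melt
transition** (the contiguous region of |−dF/dT| above 5 % of its maximum
around the apex) — the package's own choice, matching how melt-analysis
cursors are placed in practice. The alternative of pinning windows at the
grid extremes is available (`window_mode="ends"`) but extrapolates the
fitted baselines across ~23 °C, amplifying slope noise roughly an order of
magnitude and destroying cluster separation at realistic noise; this was
measured, not assumed. A degenerate-curve error fires when the pre-melt
line fails to stay above the post-melt line by a margin scaled to the
trace's dynamic range.

Genotype calls compare each sample's normalized curve to per-genotype
centroids (means of verified reference samples) by RMS deviation over the
analysis range — between the normalization windows with a 0.2 °C margin —
so both a Tm shift and a shape change move a sample away from a centroid.
Temperature shifting is deliberately not applied by default: the species
are distinguished primarily by Tm, which shifting would erase. Confidence
is 100 × the positive part of the Pearson correlation between the sample
curve and its assigned centroid (mean-centered, analysis range only). This
is an analogue of the proprietary "percent confidence" of commercial melt
software, not a reproduction; it is calibrated only in the sense that
well-separated clusters at the default noise score ≥ 98. Distance ties
break toward the centroid with the nearest Tm, then lexicographically.
Reported percentages round to one decimal, half-even.

## Phylogenetic validation

Distances default to Kimura two-parameter (the barcoding convention;
p-distance available), with gap/ambiguity columns excluded pairwise and a
saturation error when the K2P logarithm leaves its domain. Neighbor
joining follows the Saitou–Nei Q-criterion with smallest-index tie-breaks;
negative branch lengths are clamped to zero with the deficit transferred
to the sister branch (the common MEGA-compatible behavior). Bootstrap
resamples alignment columns with replacement, rebuilds the tree per
replicate, and reports bipartition frequencies as integer percents;
replicates whose distances saturate are skipped and count against support.
ITS2 extraction from full ITS reads is out of scope; a coordinate-slice
helper accepts externally determined boundaries.

## Problem sizes and determinism

The shipped validation runs use ten 30-sample cohorts (291-point curves),
200-curve recovery sweeps, 100 random additive matrices (4–8 taxa) and
500–1000 bootstrap replicates on 10-taxon, 300-column alignments — sizes at
which every statistic of interest is stable while the whole suite runs in
well under a minute. All stochastic steps take explicit seeds;
`scripts/acceptance.py` derives every stream from its `--seed` argument.

## Known limitations

- Absolute Tm predictions inherit the oligo-calibration bias and carry no
  dye/Mg²⁺ correction; only predicted-vs-observed *deltas* are reported.
- The hairpin screen ignores non-canonical structure elements.
- Mixture deconvolution (quantifying adulteration fractions) and
  unsupervised genotype discovery are out of scope; calls require labeled
  reference samples.
- The confidence score is package-defined; values are not comparable to
  vendor-software confidence numbers.
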