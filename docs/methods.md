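# Methods

This note documents the models and procedures the package implements, the
choices made where more than one reasonable implementation exists, and what
the synthetic data used by the test suite does and does not emulate.

## The ancestry signal (StepPCO)

An admixed genome is modelled as a mosaic of chromosomal blocks inherited
from two parental populations P and Q.  Genotypes are unphased diploid
calls, coded −1/+1 for the two homozygotes and 0 for heterozygotes, on a
panel of SNPs with genetic-map positions in centimorgans (interpolated
piecewise-linearly from a recombination-rate table; SNPs outside the map
are clamped to the nearest endpoint, which is this package's policy, with a
warning).

The first principal axis (PA1) of the pooled parental samples is computed
after per-SNP mean centering with no variance scaling; missing calls are
mean-imputed for the axis estimation only.  The axis is oriented so Q
projects positively, and one axis is estimated per chromosome.  For a
window *w* of contiguous SNPs the measurement of a genotype vector *e* is

    M_w(e) = Σ_{i∈w} a_i e_i / Σ_{i∈w} |a_i|,

with missing calls excluded from both sums; it is invariant under positive
rescaling of the axis coefficients *a*.

K bin centers (K a power of two, default 1024, to suit the dyadic wavelet
analysis) are equispaced in genetic distance.  Each center receives the
smallest window in which the parental projections are λ-separated,

    |Eα − Eβ| ≥ λ(σ(α) + σ(β)),   λ = 3 by default,

where α, β are the per-sample window measurements of the two parental
panels (sample mean and sample SD, ddof = 1).  Windows grow by adding the
SNP nearest in genetic distance (ties toward the lower index); at the
chromosome ends growth continues one-sided.  A window that reaches the
whole chromosome without separating is flagged unusable.  After
construction the union of windows is audited to cover every SNP with no
gaps; a gap raises an error whose remedy is a larger K (with few, highly
informative SNPs per bin the minimal windows can be narrower than the bin
spacing).

The signal value of a bin rescales the measurement affinely so that the
parental mean projections sit at −1 (P) and +1 (Q).  Admixture proportion
is the mean over usable bins of (1 + S)/2 — deliberately without clamping
each bin into [−1, 1] first: the measurement noise around a pole is
symmetric, so the unclamped mean is unbiased whereas clamping pushes
pole-hugging cohorts toward 0.5 (measured bias ≈ +0.05 at a true
proportion of 0.2).  The final proportion is clipped into [0, 1].

Because the signal is a ratio involving the estimated parental pole gap,
hold-out parental samples land slightly beyond ±1 on average (a Jensen
effect of order a few percent at the default window sizes); this does not
affect the admixed midrange.

## Wavelet analysis

A length-2^L signal is decomposed onto Haar wavelets (rectangular waves of
amplitude 1 and zero mean; level l has 2^(l−1) positions and support
2^(L−l+1) samples).  The cascade keeps the averaging normalization: the
low-pass output is the pairwise mean and a detail coefficient is the mean
contrast of the two half-supports.  The analysis high-pass is signed
(γ_{2k−1} − γ_{2k})/2 so that the reconstruction

    γ = γ_average·1 + Σ_{l,k} wt_{l,k} ω_{l,k}

holds exactly with wavelets that are +1 on the first half of their support
(a widely printed variant signs the high-pass the other way, which swaps
sample pairs on reconstruction; summaries and centers use |wt| and are
unaffected by the choice).  The round trip is exact to 1e−12 relative
error.

The level summary is s_l = Σ_k |wt_{l,k}| / 2^(l−1) and the center

    C(γ) = Σ_l l·s_l / Σ_l s_l

is the dominant-frequency statistic: a square wave whose half-period is a
fraction p of the signal length has C = log2(1/p) exactly.  To compare
signals of different genetic lengths, centers are normalized by
subtracting log2(length / reference length); the package reports centers
on the scale of a 1-Morgan signal (so a chromosome-1-like signal of 2.78
Morgans is shifted down by log2 2.78 ≈ 1.475).

### Noise filtering

Three stages, in order, all calibrated on the parental individuals' own
signals (anything present in a non-admixed individual is noise):

1. **Amplitude threshold** — hard-threshold |wt| ≤ t_l per level.  The
   default t_l is the 90% quantile of the pooled parental |wt| at that
   level.  A per-level *maximum* is also available but is an extreme-value
   statistic: it grows with panel size and swallows genuine admixture
   coefficients of comparable size (measured center bias up to −0.6
   levels), which is why the quantile is the default; the noise that
   survives a quantile threshold is absorbed by stage 3 in expectation.
2. **Level cutoff** — levels above L−3 (level 7 at K=1024) are removed;
   wavelets narrower than that are below the resolution the SNP density
   supports.
3. **Baseline subtraction** — the parental mean of the post-threshold
   level summary is subtracted (floored at 0).  This removes the level
   profile shared by every individual, so internal admixture of a parental
   panel does not leak into the admixed cohort's center.

A signal whose residual summary total does not exceed the largest residual
left by any parental individual is reported as carrying no admixture
signal (center undefined) rather than being assigned a junk center.

## Forward simulation

Chromosomes are represented by their ancestry-switch coordinates on the
unit genetic map; a meiosis draws Poisson(R) crossovers (R = 2.78 per
chromosome per generation, human chromosome 1), placed uniformly on the
genetic map or through the inverse CDF of a generated hotspot map, and
alternates between the parental chromosomes from a fair start.  Crossovers
between same-ancestry segments are silent, so switch counts are true
ancestry switches; the expected count is

    N_bkpts = 2·T·R·(Eα(1 − Eα) − var α),

which the simulator matches within ~2% out to T ≈ 90 under pulse
admixture (the match degrades afterwards as block patterns become
population-correlated).

Demography: N0 = 1000 diploids; a pulse replaces a fraction m with pure-B
migrants at generation 0 (continuous mode replaces m/d per generation for
d generations); each generation the population splits into random
monogamous pairs and each pair draws Poisson offspring whose mean tracks
the geometric growth schedule toward N = 10,000 at generation 2000
(per-pair mean = target size / number of pairs).  Regulating the mean to
the schedule — rather than using a fixed mean 2g — keeps the census on the
stated trajectory; a free branching process at this scale drifts by
factors of 2–3 over a few hundred generations and can go extinct.

Sampling takes 100 chromosomes from distinct individuals at geometrically
spaced generations (ratio ≈ 1.41), pairs them randomly into 50 diploids to
mimic unphased data, and records per-chromosome admixture fraction and
switch counts plus per-diploid WT centers after the level cutoff and
length normalization.

The hotspot map is parameterized by hotspot count, width, intensity shape
and the fraction of recombination occurring in hotspots (default 0.8, the
human genome-wide figure); the spacing/intensity defaults are placeholders
to be overridden with literature values when fidelity to a particular
genome matters.

## Dating by reference curves

The mean WT center of a cohort grows with time since admixture and is
nearly independent of the admixture rate, but has no usable closed form,
so reference curves are simulated at the rate observed in the cohort
(default 100 replicates; the test suite and the acceptance script use 20).
The pooled mean curve is smoothed by isotonic regression on log-time and
inverted at the cohort mean center by linear interpolation in log-time;
flat stretches invert to their mean log-time.  The 95% CI takes the
2.5th–97.5th percentiles of the per-replicate curve inversions, evaluated
at the cohort mean and at its ±1.96·SE probes so that cohort sampling
noise widens the interval along with curve uncertainty.  Centers at or
beyond the curve range are flagged (below: admixture too recent to
register; above: older than the resolvable horizon — the level cutoff
makes the curve plateau, by default around level 7, so very old events
yield lower bounds only).  Generations convert to years at 30 years per
generation.

Two measurement models can stand behind a curve.  Exact-signal curves
compute each diploid's center from its true block structure — the right
reference for reasoning about the statistic itself.  When the cohorts to
be dated are measured through genotypes and a StepPCO frame, the window
smoothing attenuates the dominant wavelet levels and biases measured
centers low relative to exact signals (≈ −0.1 to −0.3 levels between
T = 20 and 100 at the default resolution); dating such cohorts against an
exact-signal curve therefore underestimates T.  `build_reference_curve`
accepts the cohort's own measurement function (`center_fn`) so curve and
cohort share one measurement model, which removes the bias; the recovery
experiments in the test suite use this, and it is the recommended usage.
A curve generation enters the reference only if at least 25% of its
diploids carry admixture signal at all (earliest generations consist
largely of unrecombined pure genomes whose filtered signals are empty).

## Artificial hybrids and switches per Morgan

Hybrid haploid genomes lay an exponential ancestry map over phased donor
haplotypes: resampling points at Exponential(λ) gaps, each drawing the
Q-side label with probability α (per genome, α ~ Beta with mean 0.20 and
SD 0.10, i.e. shape (3, 12)), so realized switches occur at rate
2λα(1 − α) per Morgan.  Donor haplotypes are never reused; haploids merge
pairwise into unphased diploids.  Over the grid λ ∈ {6, 10, 20, 40, 60,
100, 200, 400} the mean WT center is linear in log(realized switches per
Morgan); ordinary least squares of center on log rate gives an estimator
of switches per Morgan from an observed center.

Two deliberate departures from the dating pipeline: no level cutoff is
applied (the upper half of the λ grid lives above level 7 and the
calibration needs those frequencies), and the default conditions are
denser and more differentiated than the recovery experiment (16,384 SNPs,
frequency divergence 0.4, K = 2048 → windows of ~20 SNPs ≈ 0.003 Morgans)
because the λ = 400 blocks are ~0.009 Morgans wide and must be resolved by
the windows for the relation to stay linear across the grid; this emulates
the experiment's original setting of strongly differentiated parental
panels at full array density.

## Synthetic data: what it does and does not emulate

The generator draws, per SNP, an ancestral frequency a ~ U(0.1, 0.9) and
sets the parental frequencies to f_P = a(1 − d), f_Q = a + d(1 − a), so
the frequency gap equals the divergence parameter d exactly (d = 0:
exchangeable panels; d = 1: fixed opposite alleles); genotypes are
Hardy–Weinberg draws and haplotypes are i.i.d. Bernoulli draws from the
same frequencies.  The default study conditions — 8,192 SNPs over a
278-cM (chromosome-1-like) map, 40 samples per parental panel, d = 0.3 —
were chosen to give the window resolution typical of genotyping-array
data in admixed human cohorts (windows of ~40 of 8,192 SNPs ≈ 0.5% of the
chromosome; on real arrays, a few hundred of the ~40,000 chromosome-1
SNPs).

Not emulated: linkage disequilibrium between nearby SNPs (draws are
independent given the frequencies), ascertainment structure of array
panels, genotyping error and missingness patterns, drift between the
parental panels and the true ancestral populations, and multi-way or
sex-biased admixture.  Passing tests therefore demonstrate correctness of
the algorithms and calibration of the statistics under the stated
frequency model, not robustness to those real-data complications.  The
unit genetic map also means "physical" structure enters only through the
optional hotspot map.

## Numerical and degenerate-input policies

* Window denominators of zero (all calls missing, or all axis
  coefficients zero in a window) are errors at the single-measurement
  level and NaN bins at the signal level; unusable bins are NaN in signals,
  excluded from proportions, and set to the neutral value 0 before wavelet
  analysis.
* K is validated as a power of two in the library; the command-line layer
  raises a requested bin count to the next power of two and logs it.
* Isotonic smoothing ties are collapsed by averaging log-times; inversion
  at or beyond the curve range returns the boundary generation with a
  flag, and every dating result satisfies CI low ≤ point ≤ CI high by
  construction (the CI is widened to include the point if percentile
  rounding would exclude it).
* All stochastic entry points take either a NumPy `Generator` or a seed;
  replicate streams derive from one master `SeedSequence`.

## Known limitations

* The dating horizon is bounded by the level cutoff: curves plateau (by
  default near level 7 minus the length shift), so old events (around
  ≥200–400 generations at chromosome-1 scale) yield lower bounds, and
  inversions near the plateau are strongly seed-sensitive.
* Cohort centers measured at low SNP density are biased low against
  exact-signal curves (see above); dating should use measurement-matched
  curves unless SNP density is high relative to block widths.
* Continuous admixture biases dates toward the end of the influx; the
  package exposes continuous-migration simulation to quantify this but
  does not attempt multi-pulse inference.
* Curve confidence intervals reflect simulation-replicate spread and
  cohort sampling error, not uncertainty in the assumed demographic model
  (N0, growth, m).
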