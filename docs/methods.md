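# Methods

## Classifier

The conditional model is a Gaussian naive Bayes over absorbance: for class
*k* and grid wavelength λ, the calibration spectra define μ_k(λ) (arithmetic
mean) and σ_k(λ) (sample standard deviation, denominator n−1). Given a
wavelength subset S, ln P(x | k) = Σ_{λ∈S} ln 𝒩(x(λ); μ_k(λ), σ_k(λ)); the
sum-of-logs form replaces the density product so that models with hundreds
of wavelengths cannot overflow or underflow. The decision adds the class
log prior and takes the argmax; ties go to the smallest class label.

Choices that matter:

- **SD floor** (`sd_floor`, default 1e−6 AU). A zero-variance wavelength
  (e.g. constant synthetic data) would give an infinite density; σ is
  floored after estimation. Any value far below real absorbance noise
  (~1e−3–1e−2 AU) behaves identically.
- **Priors.** `proportional` (to calibration spectrum counts, default) or
  `equal`. With near-balanced calibration sets (120/120/120/120/117) the
  two rules almost never disagree. The decision rule can also drop the
  prior entirely (`include_prior=False`), which reduces to maximising the
  bare log conditional; both variants are exposed because the two
  formulations coexist in practice.
- **Classification unit** is the individual spectrum. A per-sample
  majority vote over the three replicates exists (`bayes.majority_vote`)
  but is off by default, so reported rates refer to spectra.
- **Sample SD convention.** RAR_SD and σ both use denominator n−1. For
  RAR_SD this is the convention that reproduces the published table
  arithmetic this package's metric tests pin down (one published row is
  only consistent with denominator K; the majority convention was kept and
  that row's SD is not asserted).

## Metrics and model selection

RAR_i = 100·M̃_i/M_i per class; RAR_Total = 100·ΣM̃_i/ΣM_i (identically the
class-size-weighted mean of RAR_i); RAR_SD = sd(RAR_1…RAR_K, ddof=1).
Models are compared on the **composite indicator RAR_Total − RAR_SD**
computed on unrounded values; one-decimal rounding happens only in report
rows. The composite penalises classifiers that buy overall accuracy with a
weak class — relevant here because the interference class is easiest to
sacrifice.

## Equidistant screening

`enumerate_specs` yields every canonical (I, N, G) with I on the grid,
1 ≤ N ≤ N_max, 1 ≤ G ≤ G_max and E = I + step·(N−1)·G on the grid; N = 1
models are emitted once (G canonicalised to 1). The only pruning is the
E-bound itself. Scoring fits the class statistics **once** on the full
grid, caches every per-(spectrum, class, wavelength) log density in a cube,
and evaluates each model as a subset sum. Cube, direct, and batched paths
all reduce a C-contiguous (…, s) array over its last axis, so their
floating-point sums are bit-identical — the test suite asserts exact
(not tolerance) agreement between the batched search and a naive
fit-and-predict per model. Ranking is a total order: composite descending,
then N, G, I ascending (simpler models win ties; no rule is inherited, so
the simplest deterministic one was chosen).

Desk-scale searches (~6·10⁴ models, 301-point grid) take ~1 s; the
1050-point grid with N_max = 1050, G_max = 50 enumerates ~2.5·10⁶ models
through the same streamed path, with `i_stride` and `budget` available to
subsample or cap a run, and a results CSV that can be fed back to resume
(`--ec-results`).

## Step-by-step phase-out

From a starting set, each step scores all single-wavelength removals
(calibration-fit statistics, prediction-set composite) and removes the best
one; ties remove the smallest wavelength. The path runs to a single
wavelength and `select_best` returns the best state seen (ties: fewer
wavelengths, then the later state), so the refined model never scores below
its EC parent and never has more wavelengths. The phase-out criterion
defaults to the composite for consistency with the EC ranking; a
`rar-total` switch reproduces the accuracy-only view of the elimination
trace. No refitting occurs anywhere after calibration: the pipeline records
a SHA-256 fingerprint of (μ, σ) at fit time and again at validation, and
the manifest asserts the validation set was scored exactly once, after all
selection.

## Synthetic spectra

`spectrum = Σ shared Gaussian peaks + Σ class band offsets · truncated
Gaussian profiles + bottle baseline offset + correlated noise`.

- **Shared peaks** emulate the dominant common chemistry (full-range
  presets place strong bands at 1450/1930 nm).
- **Informative bands** are truncated at ±4 widths, so outside their
  support class means are *exactly* equal and the informative wavelengths
  are known by construction.
- **Correlated noise**: white noise smoothed with a Gaussian kernel
  (sd = L/√2 in nm) and rescaled, giving per-point sd `noise_sd` and
  autocorrelation exp(−d²/(2L²)) at lag d — the independence violation
  that motivates wide equidistant gaps. L ≤ 0 degenerates to white noise.
- **Hierarchy**: every bottle draws one constant baseline offset shared by
  its samples and replicates, so only grouped splits are leak-free.
- **Interference class**: bottles of a class marked heterogeneous draw
  their own band amplitudes uniformly from a widened range, emulating a
  catch-all class of assorted products with elevated within-class spread.

The five-brand reference layout (`make_reference_dataset`) reproduces the
study-scale structure: 4 × (20 bottles × 5 samples × 3 replicates) plus an
interference class of 21 three-sample bottles and 48 single-sample bottles
(333 spectra; 1533 total), with the bottle-level 8/6/6, 7/7/7 and 18/15/15
allocation giving 597/468/468 spectra.

### Benchmark design (reduced grid)

`recovery_config` is the configuration used for wavelength-recovery
studies: 400–1000 nm at 2 nm (301 points), 5 classes, three bands at
600/700/800 nm (width 25 nm), 3σ class separation at band centre
(σ = √(noise_sd² + bottle_offset_sd²)), correlation length 4 nm, bottle
offset sd 0.002 AU, 8 bottles × 3 samples × 3 replicates per class. Class
band amplitudes follow the binary code (000, 100, 010, 001, 111): every
class pair differs on at least one band, and removing any band merges at
least one pair, so a model must cover all three bands to separate the
classes.

These numbers come from a design calculation rather than trial and error.
For a class pair differing on one band, the NB discriminant deflection over
a wavelength set is d = 3·Σg²ᵢ / √(Σᵢⱼ gᵢgⱼρᵢⱼ) (g the band profile, ρ the
noise autocorrelation, amplitude 3σ at centre). Two effects dominate the
design: (i) a bottle baseline offset of δ shifts the single-band
discriminant by ≈ 2.3·(δ/σ) of its sd — the offset aliases onto the class
contrast, so it must stay small (0.1·σ here); (ii) a lattice with gap
G·step samples only part of the band energy, so the bands must be wide
relative to the winning gaps. With 100 nm band spacing, models with
8–10 nm gaps span all three bands within N ≤ 30 and carry d ≈ 6–7,
at which per-spectrum error is ~10⁻³ and a 90-spectrum prediction set is
typically classified perfectly; models missing a band are stuck near 50%
on the merged pair and cannot win. The hierarchy counts keep one full
pipeline run (~6.4·10⁴ models plus ten phase-out paths) around one second,
so 20-seed replications are routine.

## What the synthetic tests do and do not show

Passing tests demonstrate that the machinery is correct (exhaustiveness,
bit-exact scoring, greedy-step optimality, leak-free splits) and that the
method recovers planted informative bands under the stated noise model.
They do not show that real wine spectra are this separable: the generator
is phenomenological (no Beer–Lambert chemistry, no scatter/pathlength
effects, no instrument drift between sessions), its class differences are
Gaussian bumps rather than broad correlated composition shifts, and its
validation sets are small (2 bottles/class in the benchmark), which makes
held-out rates noisy — the worked example's gap between 100% modeling and
93% validation is the expected optimism of selecting on a finite
prediction set.

## Numerical and degenerate-input conventions

- All subset sums run in ascending wavelength order over a contiguous
  axis; determinism is exact for fixed inputs, and every stochastic step
  (generation, splitting) is driven by an explicit integer seed.
- Wavelengths are physical nm everywhere in the API; the grid maps them to
  0-based indices with a 1e−6 relative snap tolerance, and off-grid values
  raise rather than round.
- Degenerate cases: classes with < 2 calibration spectra refuse to fit;
  empty wavelength subsets refuse to score; a phase-out from a single
  wavelength returns the trivial path; K = 1 evaluation defines RAR_SD = 0.
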