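# Methods

## The creator–evaluator map

The state of the dynamics is a beta distribution over a feature
frequency θ ∈ (0, 1), tracked interchangeably as shape parameters
(a, b) or moments (μ, σ) through

    μ = a/(a+b),    σ = sqrt(ab/(a+b+1))/(a+b),
    ν = μ(1−μ)/σ² − 1,   a = μν,   b = (1−μ)ν,

valid on the representable region σ² < μ(1−μ). One generation applies
the selection reweighting φ̃ = φ^(1+β_T) e^(−β_N φ) and moment-matches
the result back into the beta family. The implementation assumes:

* **β_T > −1** (the weight diverges otherwise), and integrability of
  φ̃ at both endpoints, i.e. boundary exponents (1+β_T)(a−1) > −1 and
  (1+β_T)(b−1) > −1. Violations raise an ill-defined-selection error.
* The map is the infinite-data limit: no finite-population sampling
  noise enters the update itself (sampling lives in the synthetic
  corpus layer).
* Orbits whose update would leave the representable region terminate
  with a flag; the state is never projected back, since that would
  fabricate dynamics outside the analysed regime.
* Negative β_N and β_T ∈ (−1, 0) are accepted but carry no tested
  guarantees; the analysed regime is β_T, β_N ≥ 0, μ < 1/2, σ < μ.

### Numerics of the update

Moments of φ̃ are computed as ratios of integrals, so the
normalisation constant never appears. When β_N = 0 the reweighted
density is exactly Beta(1+(1+β_T)(a−1), 1+(1+β_T)(b−1)) and the update
dispatches to that closed form (this is not an approximation — moment
matching of a beta density returns its own parameters). Otherwise a
hybrid quadrature evaluates everything in log space:

* both boundary exponents ≥ 1 (integrand vanishes at the endpoints,
  possibly sharply peaked inside): Gauss–Legendre on the quantile
  window [ppf(1e−18), isf(1e−18)] of the beta-envelope factor, with
  node counts doubled from 256 until the mean and sd agree to a
  relative 1e−9 (default; exposed as `rtol`);
* otherwise (an endpoint power singularity, necessarily a wide
  distribution): tanh–sinh (double-exponential) nodes with log-domain
  endpoint handling via `log_expit`, levels h = 2⁻⁶ … 2⁻⁹ with the same
  doubling test.

The variance is computed as the central second moment in a second pass
(∫(θ−m₁)² φ̃ / ∫φ̃) to avoid the cancellation of E[θ²] − E[θ]² for
narrow states. Non-convergence after the final refinement raises
rather than returning a degraded state. Selection peaks solve
φ(θ) = 1/β_N by bisection bracketing from the mode followed by Brent's
method to 1e−14.

### Observed fine structure of the dynamics

Two numerical facts worth knowing when interpreting diagnostics:

* Novelty-only orbits approach the slow manifold through a **damped
  2-cycle**: the ratio σ/μ (and the per-generation growth factor)
  alternates around its plateau value with residual amplitude of order
  1%. Plateau detection (`ratio_diagnostics`, default per-generation
  tolerance 1e−3) therefore only reports the late plateau at the
  default tolerance; transient-phase inspection needs a tolerance of a
  few 1e−2, and exponential-growth checks are best made on
  two-generation geometric-mean growth factors.
* Every novelty-only orbit ends at the **uniform fixed point**
  Beta(1, 1) (μ = 1/2, σ/μ = 1/√3 ≈ 0.577) regardless of β_N; the
  dependence of the near-constant ratio on β_N (smaller for larger
  β_N) is a property of the growth phase, measured here as the mean
  ratio over a decade of mean growth.

## Log-potential model

Operates purely in (μ̃, σ̃): σ̃ is invariant and μ̃ shifts by βσ̃² per
generation, both exact. The (μ, σ) view is derived on demand via
μ = exp(μ̃ + σ̃²/2), σ/μ = sqrt(exp(σ̃²) − 1). The log-normal treats θ
as a frequency only approximately — its support extends above 1 and no
truncation is applied, matching the closed form. This is a documented
caveat, not a bug: the model exists as the scale-invariant comparison
case.

## Feature extraction

Pitches are reduced mod 12; adjacent differences are taken mod 12 over
the *full* pitch-class stream and zeros are deleted afterwards.
Melodic and harmonic intervals are not distinguished. Decisions where
the procedure is underdetermined:

* **Note ordering.** Multi-track MIDI files are merged and sorted by
  onset, ties broken by track index then ascending pitch. Simultaneous
  notes therefore contribute harmonic intervals in a deterministic
  order; determinism was preferred over fidelity to an unknowable
  original ordering.
* **Percussion.** Channel-10 events carry no pitch-class meaning and
  are excluded.
* **Frequencies.** Interval-based frequencies (tritone, non-diatonic,
  bigrams) all use denominator |x|, so the 121 bigram entries sum to
  (|x|−1)/|x|. Rare-rhythm frequency defaults to the number of
  bigrams |v|−1 as denominator (configurable), with ratio membership
  decided in exact rational arithmetic — float ratios would
  misclassify 2/3-type values.
* **Note values from MIDI** are only approximations (quantised
  inter-onset intervals on an optional caller-supplied grid); exact
  values come from the note-list and MusicXML paths.
* Pieces under 100 notes are flagged at extraction and excluded by the
  corpus layer, not the reader.

The 20-element non-diatonic bigram set is stored as a constant *and*
re-derived by brute-force enumeration of three-note walks on
{0,2,4,5,7,9,11}; the two must agree (tested), and transposition
invariance of intervals makes one scale sufficient.

## Corpus statistics

Sliding windows are half-open [y, y+width), default width 100 years
stepped by 25, with the origin at the minimum year rounded down to a
step multiple (the windowing origin is not otherwise determined).
Zero-frequency pieces are excluded within each window; the sample
(n−1) sd is used throughout; windows with fewer than two surviving
pieces carry NaN sd. No smoothing or interpolation is applied to the
series — presentation-layer smoothing would fabricate data points.
Era beta fits additionally exclude frequencies exactly 1 (the open
support of the beta family; saturated pieces occur in synthetic
corpora near the uniform fixed point). `fit_beta` is maximum
likelihood with a moment-matched start and falls back to the
moment-matched parameters with a warning if the optimiser fails to
improve on them.

## Model fitting

The objective is Σ_series Σ_t [(μ_t^model − μ_t^data)² +
(σ_t^model − σ_t^data)²] with the model initialised from the earliest
window of each series and stepped one generation per data point
(`generations_per_step` exposes the mapping; nothing in the data fixes
it). Time points with missing sd contribute only their mean residual;
a missing sd at the earliest point is an error since the model cannot
be initialised. Orbits that leave the representable region inside the
data span score an infinite objective.

Optimisation is a deterministic grid — 21 values per coefficient by
default, 0 plus log-spaced points from 0.1 to β_max = 20 (symmetric
about 0 for the log-potential β) — followed by Nelder–Mead refinement
from the best grid point. Reproducibility was preferred over speed;
the objective can be non-smooth at the representability boundary, so
gradient-based refinement was avoided. Reported per-series RMSE is
sqrt(objective_series / 2T): one convention of several possible, so
fitted RMSEs are comparable within this package but not directly
against error figures computed under other aggregation conventions.

## Synthetic corpora

`simulate_corpus` implements the generative assumption of the model
itself: per piece, θ ~ Beta(a_t, b_t), note count N uniform on
[100, 1000] (the typical length scale of a musical piece), event count
~ Binomial(N, θ), observed frequency = count/N. Defaults used by the
law-reproduction and recovery experiments: initial (μ, σ) =
(0.02, 0.01) (a rare feature with σ < μ ≪ 1), 16 generations of 25
years from 1500, 300–500 pieces per generation, fixed seeds.

What this emulates — and what it does not: real per-piece frequencies
are weakly dependent bigram counts, not exchangeable Bernoulli events;
real corpora have uneven composer coverage, dating uncertainty, and
duplication; and the real selection process is not observed. Passing
tests therefore show that the pipeline recovers the model's own
dynamics from data generated under its assumptions — a consistency
check, not evidence about any historical corpus. One consequence
surfaces already at this level: the binomial layer inflates observed
window sds above the creator-model σ_t (by ~E[θ(1−θ)/N] in variance),
so sampled-corpus coefficient recovery carries a systematic bias of
order 10–20% that initialising from the earliest observed window only
partly absorbs. The recovery tolerance (25%) covers it; noiseless
moment fits recover coefficients to 1e−3.

## Problem sizes

Default experiment scales were chosen so the whole suite runs in
well under a minute of dynamics time: orbits of 200–600 generations
(each update costs ~0.1 ms on the Gauss–Legendre path), corpora of
300–500 pieces × 16 generations, and fitting grids of 7–9 points per
coefficient in tests (the library default stays 21). The brute-force
diatonic enumeration is 7³ walks and instantaneous.

## Known limitations

* Only a single creator/evaluator pair with identical models;
  decoupled or multi-agent variants are out of scope.
* No uncertainty quantification on fitted coefficients.
* MusicXML support is limited to monophonic note-value extraction.
* Duplicate-piece detection is a filename heuristic, off by default.
* The quadrature guarantees hold for β_T, β_N ≥ 0; extreme negative
  coefficients within the admissible range may need manual tolerance
  adjustment.
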