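# musevol

Tools for studying the statistical evolution of cultural styles —
concretely, of musical styles — through the lens of iterated statistical
learning under social selection. The package is aimed at researchers in
cultural evolution, computational musicology, and complex systems who
want to simulate the dynamics, extract the relevant symbolic-music
features from their own corpora, and fit the model's selection
coefficients to observed time series.

## The model

A creator (composer) at generation *t* is a probability model
φ_t(θ) over a feature frequency θ ∈ (0, 1) — say, the per-piece
frequency of tritones. φ_t is a beta distribution Beta(θ; a_t, b_t),
equivalently parameterised by its mean μ_t and standard deviation σ_t.
Generated data are socially selected with weight

    φ̃_t(θ) = φ_t(θ)^(1+β_T) · exp(−β_N φ_t(θ)),

where β_T rewards **typicality** (style conformity: a log-density
term) and β_N rewards **novelty** (penalising θ values already abundant
in the population: a density term). The next generation learns by
**moment matching**: φ_{t+1} is the beta distribution whose mean and sd
equal those of the normalised φ̃_t. The state (μ_t, σ_t) thus evolves
as a two-dimensional map, the *statistical creator–evaluator* (SCE)
dynamics. Closed-form facts built in and tested:

* typicality only (β_N = 0): a′−1 = (1+β_T)(a−1), b′−1 = (1+β_T)(b−1);
  the mode (a−1)/(a+b−2) is invariant, σ_t → 0, μ_t → mode;
* novelty only (β_T = 0): φ̃_t has two equal peaks of height 1/(e β_N)
  at the solutions of φ_t(θ) = 1/β_N; orbits collapse onto a slow
  manifold with σ/μ nearly constant (slightly below 1) and the mean
  grows near-exponentially toward a fixed point at μ = 1/2;
* the comparison **log-potential model** (log-normal creator, weight
  e^{β ln θ}) solves exactly: σ̃ constant, μ̃′ = μ̃ + β σ̃², so σ/μ is
  conserved and the mean grows geometrically with factor e^{β σ̃²}.

The symbolic-music layer implements the feature definitions this
programme analyses: pitch-class-interval sequences (pitches mod 12,
adjacent differences mod 12, zeros dropped), tritone frequency
\#{n | x_n = 6}/|x|, the 20-element set of non-diatonic interval
bigrams (independently derivable by brute-force enumeration on the
scale {0,2,4,5,7,9,11}), the full 121-element bigram frequency vector,
and rare-rhythm frequencies from exact rational note-value ratios.
Corpus statistics use 100-year windows shifted by 25 years with
zero-frequency pieces excluded, and per-era maximum-likelihood beta
fits. Model fitting minimises the summed squared error of predicted
means and sds over one or more series jointly, initialised from the
earliest window.

## Worked example

`python examples/synthetic_corpus_pipeline.py` generates a corpus of
500 pieces per 25-year generation (each piece: θ drawn from the current
creator model, 100–1000 notes, binomial event counts) along a
novelty-only orbit, windows it, and refits the model:

```
window series (first 5 rows):
 window_start  window_end   n     mean       sd    ratio
       1500.0      1525.0 489 0.019688 0.011985 0.608757
       1525.0      1550.0 500 0.050857 0.020278 0.398727
       1550.0      1575.0 500 0.079864 0.039922 0.499877
       1575.0      1600.0 500 0.150385 0.069530 0.462345
       1600.0      1625.0 500 0.231197 0.111345 0.481604

true coefficients      beta_T=0.0, beta_N=1.0
recovered coefficients beta_T=0.060, beta_N=1.123 (relative beta_N error 12.3%)
joint objective 0.002815, per-series RMSE 0.009099
forecast: mean 0.500 -> 0.500 over 8 more generations (novelty-only orbits settle at the fixed point 1/2)
```

The windows show the signature of novelty-driven evolution — mean and
sd both growing while their ratio stays near 0.5 — and the generating
novelty coefficient is recovered within the sampling noise of the
finite corpus. The other example scripts (`sce_orbits.py`,
`log_potential_comparison.py`, `extract_features.py`) each demonstrate
one capability and print what the numbers mean.

A `musevol` command-line tool wraps the same pipeline
(`simulate`, `synth`, `extract`, `stats`, `fit`, `forecast`); the
configs in `examples/configs/` reproduce the three selection regimes,
e.g.

```bash
musevol simulate --config examples/configs/novelty_only.cfg --out out/
```

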