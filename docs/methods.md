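# Methods

## The generalized multiscale entropy family

For a series {x_i}, 1 ≤ i ≤ N, and scale factor τ, the coarse-grained series
at scale τ is built from non-overlapping, left-aligned segments of τ points;
a trailing remainder shorter than τ is discarded, so the coarse-grained
series has ⌊N/τ⌋ points. The family MSE_n is indexed by the segment
statistic:

- mean (MSE_μ): the classical multiscale entropy; the coarse-grained series
  is a low-pass version of the signal;
- unbiased variance with denominator τ−1 (MSE_σ²): the coarse-grained series
  is the signal's volatility at resolution τ. For i.i.d. input with variance
  σ² these values are unbiased for σ² at every τ, and for Gaussian input
  (τ−1)s²/σ² follows a chi-square law with τ−1 degrees of freedom — both are
  enforced as tests;
- bias-adjusted sample skewness (third moment): provided as an extension
  hook with the `scipy.stats.skew(bias=False)` convention; it is not
  exercised by the shipped analyses.

A stride-1 moving-window variant (`rolling_moment`) exists purely for
visualizing volatility; the analysis pipeline never feeds it into entropy
estimation, because overlapping windows induce spurious short-range
correlations.

## Sample entropy

SampEn(m, r) = −ln(A/B). Both pair counts run over the same N−m template
start indices (so every length-m template considered has a length-(m+1)
extension), self-matches are excluded, pairs are unordered, the distance is
Chebyshev and the match criterion is strict (< r). The strictness matters
only at exact ties, but it is stated and tested because it changes counts on
quantized data. When A or B is zero — a real possibility for short
coarse-grained series at large τ — the estimate is returned as a flagged
undefined value, never an exception; the summing policy downstream decides
how to treat it.

The kernel builds a k-d tree on the m- and (m+1)-dimensional template
embeddings and counts neighbor pairs in the Chebyshev metric. The strict
inequality is realized exactly by querying at `nextafter(r, 0)`, the largest
float below r: the tree's d ≤ r' test is then equivalent to d < r in
float64, which is why the optimized kernel reproduces the brute-force
pair enumeration bit-for-bit (a standing test). A 10^5-point series at
m = 2 takes a few seconds on one core.

For i.i.d. Gaussian input, the conditional matching probability factorizes
and SampEn converges to −ln(2Φ(r/(σ√2)) − 1); the suite checks agreement
within 3 Monte-Carlo standard errors at N = 10^5 over 10 seeds.

Quadratic sample entropy QSE = SampEn + ln(2r) converts the conditional
probability into a density-like estimate, removing the leading dependence on
the tolerance; it shares the SampEn counts and propagates undefinedness.

## Tolerance resolution

The tolerance is resolved once and held constant across all scales:

- `percent_of_sd` (default): r = (p/100)·SD of the original, post-filter
  series, with sample SD (denominator n−1). Defaults p = 0.5 for variance
  coarse-graining and p = 15 for mean coarse-graining — variance-coarse-
  grained series have much smaller amplitudes than mean-coarse-grained ones.
- `fixed_absolute`: r given in the series' units (e.g. 0.0002 s² for RR
  volatility), an outlier-robust alternative.
- `percent_of_reference_series`: the caller designates the reference (for
  example one of the first variance coarse-grained series); the mechanism is
  exposed without fixing a particular scale or percentage.

A per-scale variant (`r_per_scale=True`), where each scale's tolerance is a
percentage of that coarse-grained series' own SD, is selectable but
non-default: it changes the meaning of the curve and is recorded per entry
when used. A reference series whose SD is ≤ 4·eps·max|x| is treated as
constant and rejected ("tolerance resolves to zero") — an exactly constant
series can still show an SD of order eps·|mean| in floating point.

## Complexity index

The index is the sum of entropies over an inclusive scale range, default
10–100 (91 scales). Undefined entries either abort the sum (`strict`, the
library default — silently dropping scales changes the index's meaning) or
are skipped and reported (`skip_undefined`, the CLI batch default, with a
warning). The index is additive over adjacent sub-ranges; feasibility
requires ⌊N/τ_max⌋ ≥ m + 2, and a warning is emitted below 100
coarse-grained points.

## RR artifact filter

The central point of a moving window of l points (default 41) is excluded
when it lies outside [(1−a)·m_c, (1+a)·m_c], where m_c is the mean of the
other l−1 window points and a = 0.2 by default. Decisions are taken against
the original series in a single deterministic pass and excluded points are
removed afterwards; `iterate=True` repeats passes to a fixed point, with
reported indices always referring to the original input. Edge points
without a full centered window are evaluated against a truncated window
(all available neighbors within (l−1)/2 on each side, at least (l−1)/2 of
them required), switchable to `edges="keep"` which never excludes edge
points. Excluded beats are removed and the survivors concatenated — no
interpolation — so segment boundaries shift accordingly. The criterion is
relative, hence invariant under positive rescaling of the series.

## Synthetic data

The generators define the conditions under which the method is validated:

- `white_gaussian`, `periodic` (pure sinusoid, default period 20 samples),
  `ar1` (stationary, marginal SD parameterization);
- `one_over_f`: spectral synthesis with amplitudes ∝ f^(−β/2), uniform
  random phases, zero DC component, sample SD normalized; the
  log-periodogram slope over the middle frequency band is checked to be ≈ −β;
- `rr_like`: baseline 0.8 s + slow sinusoidal trend (0.05 s amplitude, 500
  beats period) + 0.03 s Gaussian beat-to-beat noise, with ectopic events
  injected at a configurable rate as labeled (×0.5, ×1.5) interval pairs —
  the premature-beat/compensatory-pause signature the artifact filter
  targets. Labels give ground truth for sensitivity/specificity tests.
- `volatility_modulated_rr`: x_t = 0.8 + σ_t ε_t with log-volatility driven
  by 1/f noise, AR(1) or i.i.d. noise of equal marginal SD (0.7 in log
  units, mean volatility 0.05 s). The AR(1) coefficient defaults to
  φ = 0.6: its volatility memory (~2.5 beats) is short relative to the
  analyzed 10–100-beat scale band, which is what makes the AR(1) group
  genuinely intermediate between 1/f volatility (structure at every scale)
  and i.i.d. volatility (none). With long memory (φ close to 1) AR(1)
  volatility is as complex as 1/f over this band and the three-group
  construction would no longer have a known ordering.

These series emulate the amplitude range, slow trends and ectopy of real RR
data but not its full physiology (no circadian architecture, no respiratory
sinus arrhythmia, no nonstationary autonomic shifts). Passing tests
therefore demonstrate correctness of the estimators and the qualitative
multiscale signatures, not clinical performance on real Holter recordings.

## Cohort analysis

Per subject: read → filter (l=41, a=0.2) → resolve r → MSE curve →
complexity index. Individual failures are logged and skipped, since 24-h
Holter batches routinely contain unreadable records; only a fully failing
group raises. Groups are summarized as mean ± sample SD of the indices and
compared with the two-sided Mann–Whitney U test (exact enumeration when
both groups have ≤ 20 tie-free subjects, midrank normal approximation with
tie correction otherwise; all-constant input short-circuits to p = 1).

## Problem sizes and numerical choices

The test suite and acceptance script use 10^4–10^5-point series, 2^14-point
reference signals with 5–10 seeds, and cohorts of 20 subjects per group at
10^4 beats — sizes at which every qualitative property above is stable
across seeds while the whole suite runs in about a minute. Tolerances:
oracle comparisons are exact (same counts, same floats); Monte-Carlo
comparisons use 3–4 standard errors estimated from the data; distributional
checks use Kolmogorov–Smirnov at α = 0.01. Curve files store floats in
shortest round-trip representation so read→write→read is the identity.

## Known limitations

- SampEn at large scales of short series is undefined or unstable; the
  feasibility guard and the undefined-value policy make this explicit
  rather than preventing it.
- The fixed tolerance resolved from the original series' SD (in seconds) is
  applied to variance series (in s²); this deliberate convention makes
  indices comparable across subjects but means the tolerance is not
  dimensionless.
- No resampling harmonization is applied across recordings digitized at
  different ECG sampling rates; RR values are taken at face value in
  seconds.
- Refined/composite coarse-graining variants and short-series entropy
  corrections are out of scope.
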