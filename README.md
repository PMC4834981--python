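# gmse — generalized multiscale entropy for physiologic time series

`gmse` quantifies the complexity of physiologic signals — above all cardiac
interbeat (RR) interval series from Holter recordings — with the generalized
multiscale entropy family MSE_n. It is written for heart-rate-variability and
nonlinear-dynamics researchers who need the full pipeline: artifact filtering
of RR series, moment-based coarse-graining, sample-entropy estimation, a
scale-summed complexity index, and cohort-level group comparison.

## The method

Given a series {x_i}, 1 ≤ i ≤ N, and a scale factor τ, the series is divided
into non-overlapping segments of τ consecutive points and each segment is
replaced by one statistic, giving the coarse-grained series at scale τ:

- **MSE_μ** uses the segment mean — the classical multiscale entropy;
- **MSE_σ²** uses the unbiased segment variance, s² = 1/(τ−1) Σ (x_i − x̄)²,
  and therefore probes the *volatility* of the signal across time scales.

Sample entropy, SampEn = −ln(A/B), is computed for each coarse-grained
series: B counts pairs of length-m templates whose Chebyshev distance is
strictly below a tolerance r, and A counts the same pairs still matching at
length m+1. The tolerance is resolved once — by default r = 0.5% of the
original series' SD for variance coarse-graining and r = 15% for mean
coarse-graining — and held fixed across scales. The **complexity index** is
the sum of the entropies over an inclusive scale range (default 10–100, i.e.
91 scales). Complex signals with structure on many scales (1/f-like) score
high; both strictly periodic and uncorrelated random signals score low.

RR series are first cleaned with a moving-window filter: the central point
of a window of l = 41 beats is excluded when it deviates more than a = 20%
from the mean of its l−1 neighbors — removing ectopic beats (a premature
short interval plus compensatory pause) and missed detections without
interpolation.

## Worked example

```python
from gmse import MultiscaleEntropy, FilterParams
from gmse.synth import rr_like

rr = rr_like(20000, seed=1, ectopy_rate=0.01)   # RR-like series, seconds
res = MultiscaleEntropy(rr, moment="variance",
                        filter_params=FilterParams()).fit()
print(res.summary())
```

```
Generalized Multiscale Entropy Results
======================================================
Series:                     series
Coarse-graining moment:     variance
Scales:                     10..100 (91 scales)
Template length m:          2
Tolerance mode:             percent_of_sd
Resolved r:                 0.000230992
Filter (l, a):              (41, 0.2) excluded 200/20000
------------------------------------------------------
Complexity index:           51.8682 nats (scales 10..100)
Defined scales:             91
======================================================
gmse 0.1.0
```

The filter removed the 200 injected ectopic intervals (1% of beats, two
intervals per event); the tolerance resolved to 0.5% of the filtered series'
SD (≈0.23 ms); SampEn was defined at all 91 scales and summed to a
complexity index of 51.87 nats. Higher indices mean richer multiscale
volatility structure; in 24-h Holter data this index separates healthy young
subjects from older subjects and from patients with congestive heart
failure, in that descending order.

The same analysis is available from the shell:

```sh
gmse synth --kind rr_like --n 20000 --seed 1 --param ectopy_rate=0.01 rr.txt
gmse msen --moment variance --scales 10:100 --m 2 --r 0.5 \
     --r-mode percent_of_sd --filter rr.txt
```

which writes the per-scale curve (`rr.txt.msen.tsv`) and a JSON complexity
index with provenance (`rr.txt.index.json`). See also `gmse filter`,
`gmse coarsegrain`, `gmse entropy` and `gmse cohort --config cohort.yaml`
for batch group comparisons (means ± SD and two-tail Mann–Whitney tests).

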