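# Methods

## The entropy family

The core object is the sector-ring partition of a Poincaré plot. A series
is shifted by its minimum so the delayed-pair scatter `(x_i, x_{i+τ})` lives
in the first quadrant; the radial coordinate of a point is its Euclidean
norm (the partition's concentric circles are centered on the origin, which
implies the L2 distance). Ring `k` of `W` is the half-open annulus
`[(k−1)·dl, k·dl)` with `dl = L_max / W`; the outermost ring is closed at
`L_max` so the farthest point is always counted, and a point exactly at the
origin belongs to ring 1.

Distribution entropy (DE) is the Shannon entropy of the ring-occupancy
probabilities in natural log units. The logarithm base is a convention; we
use `ln` throughout so DE and the `q → 1` limit of the generalized form
coincide exactly, and DE is bounded by `ln W`.

The nonextensive distribution entropy (NDE) attaches to ring `k` the
parameter `q_k = 1 + L_max − (k−1)·dl − dl/2` — one plus the
reverse-subtracted distance of the ring's center from the origin — and sums
`(p_k − p_k^{q_k}) / (q_k − 1)`. Conventions and numerics:

* **Sign.** The summand is written so the measure is nonnegative and
  reduces to `−Σ p ln p` in the `q → 1` limit. (Written with the opposite
  sign, the same sum is ≤ 0 for all `q_k > 1` and cannot agree with its own
  Shannon limit; we regard the positive form as the intended one.)
* **`q` near 1.** When `|q_k − 1| < 1e−8` the term is evaluated by its
  limit `−p_k ln p_k` to avoid 0/0. Forcing all `q_k = 1 + 1e−6`
  reproduces DE to better than 1e−4 relative (tested).
* **Empty and full rings.** `p_k = 0` contributes exactly 0 (`0^q := 0`
  for `q > 1`), and `p_k = 1` contributes 0, so NDE = 0 iff one ring holds
  all points.
* **Degenerate input.** A constant series collapses the scatter to the
  origin (`L_max = 0`); both DE and NDE are defined as 0 there and the
  partition carries a degeneracy flag.
* **Units.** `q_k` is computed in the signal's native amplitude units with
  no normalization. NDE is therefore shift-invariant but intentionally
  scale-sensitive — amplitude is part of the information it encodes —
  whereas DE is exactly scale-invariant (rings rescale with `L_max`). Both
  behaviors are pinned by tests.
* **Delay.** The delay τ defaults to 1 (the standard-form plot) and is
  exposed as a parameter.

Defaults `W = 50`, window width 2500 and step 500 follow the
parameter-determination sweeps below; the analysis that motivated `W = 40`
for plain DE is also reproducible by passing `--rings 40`.

## Fractional Brownian motion simulator

Validation experiments need Gaussian self-similar paths with a prescribed
Hurst index. We generate fractional Gaussian noise exactly from its
autocovariance `γ(k) = (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})/2` by
Davies–Harte circulant embedding (O(n log n)), with an O(n³) Cholesky
factorization of the Toeplitz covariance as a fallback should an embedding
eigenvalue come out negative (it does not for H ∈ (0, 1) at the lengths
used), and cumulate to get fBm with `B_0 = 0` and `Var(B_t) = t^{2H}`.
The degenerate `H = 1` case is the analytic line `B_t = t·Z`. This is a
deliberate replacement for approximate wavelet-synthesis generators: every
claim made downstream is distributional (trends of entropy against H), so
an exact-covariance sampler is the stronger foundation. Seeded runs are
bit-reproducible; replicate `r` of grid entry `i` in a sweep uses seed
`seed + i·replicates + r`.

## Sliding-window analysis

Long nonstationary series are scored per window (offsets `0, step, 2·step,
…`; trailing samples that do not fill a window are dropped) and the series'
value is the arithmetic mean over windows. The ring partition — hence
`L_max` and the q-set — is computed inside each window independently, so a
window's score reflects its local amplitude and geometry. The Hurst sweep
at its defaults (length 20 000, width 2500, step 500, `W = 50`) reproduces
the qualitative findings used to fix the defaults: mean NDE decreases
strictly with H, its replicate spread shrinks as H grows, and NDE as a
function of `W` rises steeply up to roughly 40 rings and then plateaus.
The acceptance script runs a scaled-down sweep (length 2500, 10
replicates) chosen to show the same strict monotonicity in a few seconds.

## Sleep-EEG pipeline

Preprocessing has two stages:

* **Singular-spectrum detrending.** The signal is embedded in a Hankel
  trajectory matrix (window 200 samples = 2 s at 100 Hz), the leading
  `trend_rank = 1` eigentriple(s) of the lag-covariance decomposition —
  equivalent to the trajectory-matrix SVD — are reconstructed by diagonal
  averaging and subtracted. Embedding length and rank are configurable;
  rank 1–2 captures drift and baseline wander (a pure ramp is removed to
  <1% residual RMS, tested).
* **Band-pass 1–32 Hz, zero phase.** The contract is spectral: unity
  passband gain within ±5%, ≥20 dB stopband attenuation at 0.2 and 45 Hz,
  no phase shift at band center. The default realization is a 4th-order
  Butterworth applied forward-backward; a harmonic-wavelet variant — an
  ideal boxcar-in-frequency band limiter, which is what a harmonic wavelet
  filter bank implements — is available via `filter_mode="harmonic"`.

Scoring segments the cleaned signal into 30-s epochs (3000 samples at
100 Hz; a trailing remainder is dropped) and scores each epoch as the mean
NDE over 201 sliding windows of width 1000 and step 10, with `W = 50`
rings (the sweep recommendation; configurable).

Epochs are grouped by hypnogram code. NREM-1 epochs are excluded by default
(they are typically too few for a stable group), as are movement-time and
unscored codes; inclusion of NREM 1 is a flag. The hypothesized complexity
ordering is AWAKE > REM > stage 2 > stage 3 > stage 4 and is configurable.
The Jonckheere–Terpstra statistic sums, over ordered group pairs, the
Mann–Whitney counts `#(x < y) + ½·#(x = y)`; significance uses the normal
approximation with the tie-corrected null variance (the fully tied
degenerate case returns z = 0, p = 1). Post-hoc comparisons are two-group
JT statistics with standard error from the tie-corrected two-sample
variance; the reported raw significance is the upper-tail probability of
|z|, matching the convention of the statistical package whose pairwise
table layout we mirror (a standardized statistic of 1.980 maps to 0.024
raw and 0.239 after the ×10 Bonferroni adjustment for five groups), and
adjusted significance is `min(1, raw × number of comparisons)`. The
omnibus trend p-value is two-sided.

## Synthetic sleep records

`synth_sleep_record` emulates only the second-order structure that the
pipeline actually consumes: per-stage `1/f^β` colored Gaussian noise with
stage-dependent spectral slope and RMS amplitude, concatenated along the
hypnogram. Noise is band-limited to 0.5–40 Hz, mimicking acquisition
filtering, so the stated RMS is in-band amplitude — this matters, because
specifying full-band amplitude would let the 1–32 Hz preprocessing strip
most of a steep-spectrum stage's power and invert the physical amplitude
relation between wake and slow-wave sleep. Defaults (β, RMS in μV): AWAKE
(0.8, 15), REM (1.2, 20), N1 (1.4, 25), N2 (1.6, 30), N3 (2.0, 50), N4
(2.4, 75) — flatter spectrum and lower amplitude for wake/REM, steeper and
larger for deep sleep, consistent with typical stage spectra. The
generator produces no spindles, K-complexes, eye-movement or muscle
artifacts, no stage-transition dynamics, and stationary statistics within
a stage; a passing end-to-end test therefore shows that the pipeline
recovers a designed monotone complexity ordering from realistic spectra
and amplitudes, not that it stages real EEG. Real-recording analysis is
supported through the optional EDF reader plus an external hypnogram.

End-to-end, a record with 30 epochs per stage (the size the acceptance
script uses; 150 epochs ≈ 75 min of signal) yields group-mean NDE strictly
decreasing along the hypothesized order with a trend p-value far below
0.01.

## Known limitations

* NDE's amplitude sensitivity means values are comparable only across
  series in the same units and acquisition gain; the optional pre-scaling
  flag trades this information for comparability.
* The normal approximation of the trend test is asymptotic; very small
  groups (< ~5 epochs) deserve an exact or permutation test, which is not
  provided.
* The Davies–Harte sampler is exact in covariance but, like any Gaussian
  model, does not reproduce higher-order structure of real EEG.
* The harmonic-wavelet filter variant is an ideal band limiter and can
  ring at sharp signal edges; the Butterworth default is gentler.
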