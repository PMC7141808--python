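# Methods

## Fractional Brownian motion generation

Fractional Brownian motion `B_H(t)` is the zero-mean Gaussian process with
covariance `⟨B_H(t)B_H(s)⟩ ∝ t^{2H} + s^{2H} − |t−s|^{2H}`.  Its increment
process (fractional Gaussian noise, fGn) is stationary with autocovariance

    γ(k) = (σ²/2) (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}).

Tracks are generated by the Hosking method: the Durbin–Levinson recursion
draws each fGn value from its exact conditional distribution given all
previous values, so every finite sample has exactly the target covariance.
The recursion is O(N²) per track; the inner loop is numba-compiled and
batched over ensembles (one Hurst exponent per row), which generates
2×10⁵ hundred-point tracks in a couple of seconds on one CPU.  Unit
diffusion scale gives `Var[x(k·dt)] = (k·dt)^{2H}`; because the network
input is range-normalized the scale only matters for velocity statistics.
2D tracks are two independent components sharing `H` (isotropy).

The regime-switching generator alternates between an anti-persistent state
(`H` drawn uniformly from an interval inside (0, 0.5)) and a persistent
state (interval inside (0.5, 1)).  Residence times per state are
exponential or Pareto (`ψ(t) ∼ t^{-μ-1}`, survival `S(t) ∼ t^{-μ}`, scale =
the minimum dwell, optional hard cap emulating the finite observation
window — "truncated heavy tails").  Each dwell is an independent fBm
segment translated to continue from the previous endpoint; no correlation
crosses a state boundary.  The per-point label series and the exact dwell
table are returned with the trajectory.

Measurement noise is i.i.d. Gaussian per point with standard deviation
`NSR × std(coordinate values)`, per component (NSR = noise-to-signal
ratio).  Random subsampling retains `n_rand` uniformly chosen time points,
sorted, keeping their original time stamps.

## The network estimator

Input windows of `n` positions are differenced and divided by the window
range: `x → (x_{i+1} − x_i) / (max x − min x)`, which makes the input
stationary, scale-free and shift-free.  The network is a small dense
feedforward regressor with ReLU activations on every node including the
single output node, whose value (clamped to [0, 1]) is the Hurst estimate.
Three layouts are supported, counted in nodes including the input layer
(width `n`) and output: triangular `Σ_{l=0..L}(n−l) + 1`, rectangular
`nL + 1`, anti-triangular `Σ_{l=0..L}(n+l) + 1`.  Since differencing `n`
points yields `n−1` values, the realized input width is `n−1` and hidden
widths continue the same progression.  The three layouts measure within
~0.001 of each other in σ_H at equal `n` and `L`; the triangular layout is
the default because it is the cheapest.

Training regresses `H` on freshly simulated fBm windows with
`H ~ U(0, 1)`, mean-squared-error loss, RMSprop (lr 1e-3, ρ 0.9, ε 1e-8),
batch size 128.  Defaults: 2×10⁵ training windows, 10⁴ validation windows,
up to 40 epochs with early stopping (patience 4) on validation MAE and
best-epoch restore.  Weight init is He-normal with the output bias started
at 0.5 so the ReLU output node cannot be born dead.  Training is
deterministic for a fixed seed in a single-threaded run.  Optional
training-time noise augmentation (`noise_nsr_max`) corrupts each window
with `NSR ~ U(0, max)`; it costs ~0.03 of clean σ_H and buys large
robustness on noisy tracks (σ_H ≈ 0.09 at NSR 0.2 versus ≈ 0.24 for a
clean-trained model), so the headline model is clean-trained and a noisy
application should train with augmentation.

Measured accuracy (validation, triangular, L=3): σ_H ≈ 0.049 at n=100,
≈ 0.074 at n=41, ≈ 0.12 at n=15.  This follows the expected `c/√n`
statistical scaling with `c ≈ 0.5`; claims of length-independent accuracy
at very short windows are not consistent with that scaling, and we observe
none.  For randomly subsampled inputs (40 of 100 points) the estimator
uses the differences of the retained values only (time stamps discarded,
input width 40); it measures σ_H ≈ 0.078, essentially the same as a
consecutive 40-point window (0.073) — the subsampling itself costs little,
the shorter window costs the √n factor.  Alternative gap-aware encodings
(zero-filled full grid, difference+gap channels, linear interpolation)
were evaluated and none outperformed 0.070.

Models serialize to an npz container holding an architecture JSON, the
weight arrays, and predictions on a fixed probe set; loading verifies the
format version, the weight shapes, and the probe predictions bit-exactly.

## Estimator evaluation

For a labeled test set, `σ_H = mean |H_sim − H_est|`, the ΔH = H_sim −
H_est samples are retained, and bias `b = E[H_est] − H_sim`, variance and
MSE are computed on 20 equal H-bins; `MSE = Var + b²` holds per bin to
float precision by construction and is verified.  The classical baselines
are evaluated through the same report.  Two baseline details matter:

* Rescaled-range analysis is applied to the track's *increments* (the
  stationary sequence), block-averaged over a geometric window schedule
  (10 … N−1, factor 1.25) and fitted log-log.  Applied to raw positions it
  is uninformative (σ_H ≈ 0.44 at n=100 versus ≈ 0.12 on increments).
* The TAMSD fit is nonlinear least squares of `A·t^{2H}` over all lags,
  and the sequential-range fit is anchored at `M(δt)`; both choices follow
  the stated procedure of the original method even though log-log /
  free-intercept variants measure better.

## Segmentation

A symmetric window of `Nw` points (odd; default 15) slides one point at a
time; the estimate for a window starting at `i` is assigned to the center
`j = i + (Nw−1)/2`.  2D tracks are estimated per coordinate and averaged,
which reduces the estimator spread by √2 — a material gain: state
classification at window 15 is ~90% pointwise on 2D switching fixtures
versus ~80% on 1D ones.  The local series is cut at `H > 0.55`
(persistent) and `H < 0.45` (anti-persistent); the band in between absorbs
the estimator error (σ_H ≈ 0.05 at n=100 motivates the ±0.05 margin) and
stays unclassified.  Classified runs shorter than `Nw` are demoted to
unclassified as spurious.

**Gap bridging.**  Estimator noise makes the local estimate dip briefly
into the unclassified band at a roughly constant rate (measured: every
~285 points inside a pure `H = 0.85` track at window 41).  Under the plain
cutting rule every dip splits a dwell, which multiplies the observed
residence-time survival function by a spurious exponential factor and
steepens any fitted tail (µ̂ ≈ 2.2 for a true 1.5).  `segment_states`
therefore offers `bridge_gaps`: an unclassified gap shorter than the
minimum run length whose two neighbors are the *same* state is absorbed
into that state.  Genuine switches are never bridged (the far side is the
opposite state).  Residence-time analyses should enable it; the default
leaves the literal rule.

Directional classification of persistent segments uses
`cos θ_i = r_{0,i}·r_{i,i+1} / (|r_{0,i}||r_{i,i+1}|)` between the
centrosome→particle radial vector and the step vector, smoothed by a
centered moving average of the same window, thresholded at ±0.3:
anterograde above, retrograde below, unlabeled between.  Indices where the
radial or step vector has zero length are skipped.  Tracks enter the
directional statistics only if their maximum excursion from the start
exceeds 0.5 µm, they are longer than the window, and they switch state
more than twice (transitions counted between classified segments,
ignoring unclassified gaps).  Segment speed is net displacement over
duration (not path length).

## Residence-time statistics

Observed dwell durations per state feed an empirical survival function
`S(t) = P(T > t)` (strict inequality; binomial standard errors), and the
tail exponent is the negative slope of a least-squares line on
`(log t, log S)`.  Fit-window defaults: from the 20th percentile of the
support up to the 99th-percentile duration.  When a hard truncation scale
is known (the dwell cap / observation window), the upper limit should be
set explicitly a factor of ~3 below it, because survival plunges near a
hard cap.  Calibration on fixed-length dwells showed that with bridging
the segmentation erodes dwells by only ~0–20 points (window 41), so *no*
duration correction is applied; adding back a window length — the naive
correction — measurably over-inflates short dwells and biases µ̂ upward by
~0.1.  With a 41-point window, states at `H ≈ 0.2 / 0.85`, minimum dwell
100 and cap 3000, the full pipeline recovers µ = 1.5 (persistent) as
1.44–1.46 and µ = 0.6 (anti-persistent) as 0.59–0.65 across seeds.
The window is wider than the segmentation default because the band-dip
rate — the remaining fragmentation mechanism — falls steeply with window
size; at window 15 no heavy tail survives the pipeline.

Hurst-exponent distributions are fitted with 1D Gaussian mixtures
(scikit-learn EM, 10 restarts per candidate, seeds recorded) over k = 1…8,
selecting the BIC minimum.  Kernel density estimates are Gaussian with
Scott's-rule bandwidth (scipy) or an explicit absolute bandwidth.

## Synthetic fixtures versus real tracks

The generators produce exactly the model class the estimator is trained
on: Gaussian, exactly self-similar within a state, instantaneous state
switches, stationary noise, no localization error correlated in time, no
drift, no tracking gaps except the explicit subsampling fixture.  Passing
tests therefore demonstrate correctness of the method and pipeline *under
the fBm model*, not that any particular biological track is fBm.  In real
data, motion blur, vibrations, and tracking linkage errors add structure
the clean-trained network has not seen (the noise-augmented variant covers
the simplest of these).

## Numerical choices and limitations

* Durbin–Levinson prediction variance is floored at 1e-14 (relevant for
  H → 1); training H values are clipped to [1e-4, 1 − 1e-4].
* Constant windows (zero range) are degenerate: scalar estimation raises,
  vectorized paths return NaN and downstream treats NaN as unclassified.
* Problem sizes in tests and the acceptance script (2–4×10³ test tracks,
  10⁵–2×10⁵ training windows, 10⁴ dwells for tail recovery) are desk-scale
  choices that leave the measured quantities within their quoted
  tolerances; σ_H values move by well under 0.005 when scaled up.
* Tail fits by least squares on the survival log-log are simple and match
  how such plots are usually read, but are not maximum-likelihood
  (Clauset-style) estimates; formal power-law hypothesis testing is out of
  scope.
* The subsampled-input estimator discards gap lengths; this is the stated
  design and costs ~0.005 of σ_H versus the best gap-aware encoding tried.
* The bias of the network estimator is toward 0.5 near both ends of the H
  range (regression-to-the-prior under the uniform training prior); the
  per-bin bias curve in the evaluation report quantifies it.
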