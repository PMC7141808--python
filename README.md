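# hurstnet

Neural-network estimation of local Hurst exponents from short
particle-tracking trajectories.

## The problem

Organelles moving through a living cell (endosomes, lysosomes, other
cargo) rarely perform plain Brownian motion.  Their tracks alternate
between *persistent* runs — processive, motor-driven transport — and
*anti-persistent* jiggling in a crowded, tethering cytoplasm.  Modeling a
track as fractional Brownian motion (fBm) captures both regimes with a
single number, the Hurst exponent `H ∈ (0, 1)`: the mean squared
displacement scales as `⟨Δr²(t)⟩ ∼ t^{2H}`, with `H < 1/2` anti-persistent
(sub-diffusive), `H = 1/2` Brownian, and `H > 1/2` persistent
(super-diffusive).  Motion that switches state in time is described by a
*stochastic* local exponent `H(t)`.

Classical estimators of `H` — the time-averaged MSD power-law fit,
rescaled-range (R/S) analysis, sequential ranges — need hundreds of points
to be reliable, which makes them useless for resolving state switches that
last tens of frames.  `hurstnet` implements the alternative: a small dense
feedforward network (ReLU activations, RMSprop training) that regresses
`H` from a *differenced, range-normalized* window of as few as ~15
positions, trained entirely on exactly simulated fBm (Hosking method).
Because the input is normalized, the estimator is independent of the
diffusion coefficient and the spatial units of the track.

On 100-point tracks with `H ~ U(0,1)` the network reaches a mean absolute
error `σ_H ≈ 0.05`, two-and-a-half to three times better than the best of
the classical estimators on the same tracks.

On top of the estimator the package provides the full analysis pipeline
for heterogeneous transport:

* **fbm_sim** (`hurstnet.fbm`) — exact fBm via the Hosking / Durbin–Levinson
  recursion (jit-compiled, batched), regime-switching fBm with exponential
  or heavy-tailed (Pareto) residence times, measurement noise, random
  temporal subsampling.
* **classical** (`hurstnet.classical`) — TAMSD, rescaled-range and
  sequential-range baselines with their power-law fits.
* **dlfnn** (`hurstnet.network`, `hurstnet.evaluation`) — triangular /
  rectangular / anti-triangular architectures, training, estimation,
  save/load with integrity checks, and accuracy reports (σ_H, ΔH
  distribution, per-H bias/variance/MSE with `MSE = Var + b²`).
* **segmentation** (`hurstnet.segmentation`) — symmetric moving-window
  local `H(t)`, cutting tracks into persistent (`H > 0.55`) /
  anti-persistent (`H < 0.45`) segments, anterograde/retrograde
  classification relative to a user-supplied centrosome position, and
  per-segment displacement / duration / speed statistics.
* **stats** (`hurstnet.stats`) — Gaussian KDE, residence-time survival
  functions with power-law tail fits (`ψ(t) ∼ t^{-μ-1}`, so `S(t) ∼ t^{-μ}`),
  Gaussian-mixture fits of `H` distributions with BIC model selection, and
  estimator benchmark tables.
* **io / cli** (`hurstnet.io`, `hurstnet.cli`) — delimited track files
  (`track_id, t, x[, y]`; seconds and micrometres) and a `hurstnet`
  command with `simulate`, `train`, `estimate`, `segment`, `direction`,
  `stats` and `benchmark` subcommands.

## Worked example

```python
import numpy as np
from hurstnet import (
    NetworkSpec, TrainingConfig, train, estimate_hurst_many,
    simulate_fbm_ensemble, evaluate_estimates,
)

# train a 15-point-window estimator on freshly simulated fBm
spec = NetworkSpec("triangular", n_input=15, n_hidden_layers=3)
model = train(spec, TrainingConfig(n_train=150_000, max_epochs=20), seed=103)

# evaluate on fresh tracks
rng = np.random.default_rng(42)
h_true = rng.uniform(0.001, 0.999, 5000)
tracks = simulate_fbm_ensemble(h_true, 15, rng=rng)
report = evaluate_estimates(h_true, estimate_hurst_many(model, tracks))
print(f"sigma_H at 15 points: {report.sigma_h:.3f}")
```

prints

```
sigma_H at 15 points: 0.123
```

i.e. even from 15 positions the network pins the Hurst exponent to about
±0.12 on average — enough to tell persistent from anti-persistent
motion — where
rescaled-range analysis cannot run at all (it needs ≥ 21 points) and the
TAMSD fit is several times less accurate.

Segmenting a regime-switching track looks like:

```python
from hurstnet import SwitchingSpec, simulate_switching_fbm, windowed_hurst, segment_states

lab = simulate_switching_fbm(SwitchingSpec(n_points=3000, n_dim=2, seed=7))
hs = windowed_hurst(model, lab.trajectory, window=15)
segments = segment_states(hs, traj=lab.trajectory, bridge_gaps=True)
```

Each returned segment carries its state, trajectory index range, duration
(s), net displacement (µm), mean speed (µm/s) and mean local `H`.

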