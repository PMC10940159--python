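# lysomech

Quantitative analysis of lysosomal mechanosensation.

Lysosomes carry stretch-activated ion channels that release Ca²⁺ where the
organelle membrane is under tension. Testing that idea quantitatively
requires several distinct measurements, and `lysomech` packages all of them
as a tested, reusable pipeline:

* **Curvature–calcium coupling** — on two-channel time-lapse movies of a
  single organelle (a membrane marker such as mCherry plus a calcium
  indicator such as GCaMP6f), estimate the signed local curvature κ at every
  boundary sampling point, measure the local calcium signal normalized by
  the local membrane signal, and correlate the two across the sampling
  points of each frame. Per-frame Pearson coefficients are averaged over
  time into a per-lysosome statistic r̄.
* **Morphometrics** — lysosome area, circularity (4πA/P²), the fraction of
  lysosomes in a 5-µm peripheral shell of the cell outline, and Pearson
  colocalization of two channels.
* **Calcium responders** — background-subtracted F(t)/F(0) traces; a cell is
  a positive responder when its peak ratio rises by strictly more than 70 %.
* **Pressure-clamp electrophysiology** — per-step current amplitudes under
  a stepwise suction protocol, a Boltzmann dose–response
  I(P) = I_max / (1 + exp((P₅₀ − |P|)/s)) giving the half-activation
  pressure, reversal potentials from I–V relations, and non-stationary
  noise analysis (σ² = iI − I²/N) for the unitary current i, channel count
  N and single-channel conductance γ = i/(V_hold − E_rev).

Because no public dataset accompanies this kind of experiment, the package
includes a first-class synthetic-data module that generates every input
with analytically known ground truth: star-convex organelle shapes with
exact curvature from the polar-curve formula, rendered two-channel movies
whose calcium channel is linearly coupled to curvature, cell layouts with
designed peripheral fractions, calcium traces with known fold changes, and
binomial N-channel gating currents. Every analysis stage is validated
end-to-end against these oracles.

## Worked example

Generate a 10-frame movie of a five-lobed organelle whose calcium channel
is coupled to curvature with a designed point-wise correlation of 0.8, then
run the curvature pipeline on it:

```sh
$ lysomech simulate movie --seed 7 --n-frames 10 --rho 0.8 --out-dir demo
wrote movie.tif, labels.tif, ground_truth.csv to demo
$ lysomech curvcorr --movie demo/movie.tif --labels demo/labels.tif --out demo/results
lysosome 0: r_bar = 0.8109 over 10 frames
```

The frame-averaged coefficient r̄ = 0.81 recovers the designed coupling of
0.8: the pipeline detects the curvature–calcium relation built into the
fixture. `demo/results/` contains the per-sampling-point table, the
per-frame coefficients and the per-lysosome summary as CSV.

The same works for electrophysiology. Simulate 30 sweeps of a
100-channel patch (unitary current 0.1 pA, P₅₀ = 45 mmHg, slope 6 mmHg)
under the −10…−80 mmHg step protocol and fit the dose–response:

```sh
$ lysomech simulate sweeps --seed 7 --out-dir demo --n-sweeps 30 --noise-sd 0.5 --sample-rate 500
wrote sweeps.csv, protocol.yaml to demo
$ lysomech ephys dose --sweeps demo/sweeps.csv --protocol demo/protocol.yaml --out demo/dose.csv
P50 = 45.01 mmHg (slope 6.02, Imax 9.98 pA; interpolated P50 44.97)
```

The fitted half-activation pressure (45.01 mmHg), slope (6.02 mmHg) and
maximal current (9.98 pA ≈ N·i = 10 pA) match the generating parameters.

The same operations are available as library functions
(`lysomech.analyze_movie`, `lysomech.boltzmann_fit`,
`lysomech.nonstationary_noise`, …); see the docstrings and
`docs/methods.md` for the underlying models and parameter choices.

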