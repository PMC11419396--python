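# Methods

## Model

The package couples a conventionally trained feedforward classifier with
post-hoc rate dynamics. The two parts are deliberately separate: training
never sees the dynamics, and the dynamics never change the weights. The
scientific question is whether imposed oscillatory dynamics alone can turn a
converging architecture's mixed response to simultaneous stimuli into a
sequential, decodable code.

### Classifier

Images are 56×56, letters occupy one 28×28 quadrant each. Layer 1 shares one
28×28 kernel per node across the four quadrants (stride-28 "convolution",
summed), which (i) forces the quadrants to converge onto the same 64 nodes —
this convergence is what creates the bottleneck — and (ii) makes the layer-1
drive z1 exactly invariant to which quadrant a noiseless letter occupies.
Layer 2 is dense 64→32; the output is a 3-way softmax.

The hidden non-linearity is a shifted sigmoid σ(z) = 1/(1+e^{−a(z−b)}) with
a = 2 and b = 2.5 held fixed; no trainable biases exist anywhere. The shift
acts as a firing threshold: inputs near zero give h ≈ 0.007, inputs above
~4 give h ≈ 1, so trained hidden codes are near-binary (measured: ≥ 96 % of
hidden activations on training inputs fall outside (0.1, 0.9)). The same
σ later appears inside the dynamics, so keeping its constants fixed during
training keeps the static and dynamic operating points consistent.

Training is cross-entropy (natural log) with Adam at its standard defaults
(η = 10⁻³, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸), per-image updates in shuffled
order, 20 epochs. Batch mode is configurable (`TrainConfig.batch_size`);
per-image stochastic descent is the default. With two mini-batches per epoch
instead, the same schedule ends at a loss of ≈ 0.4–0.5 — soft weights that
classify perfectly but read out less confidently; the default's near-zero
final loss gives the confident burst read-outs that the temporal-code
analyses quantify. Gradients are hand-derived backpropagation (the model is
three matrix blocks; no autodiff framework is warranted) and are verified
against central finite differences in the test suite.

### Stimuli

The canonical training set is 132 images: 3 letters × 4 quadrants × 11 noise
standard deviations evenly spaced on [0.01, 0.25] — the only composition
consistent with a 132-image set spanning that noise range. Per image:
compose (gain × glyph per quadrant), add i.i.d. Gaussian pixel noise, clip
negatives at zero, divide by the maximum so luminance spans [0, 1] with max
exactly 1. The set is generated once per seed and reused every epoch
(fresh-noise-per-epoch is available but off by default); the test set is the
same composition under a disjoint seed.

Glyph bitmaps are procedural seven-segment-style block letters (stroke 4 px,
~20×22 px box centered in the quadrant), generated deterministically in
code, so all fixtures are bit-identical across runs without committing
binary files. Exact glyph geometry is not load-bearing: any three letter
shapes differing in a few dozen pixels train to the same phenomenology.

Competition images place two or three letters in distinct quadrants with
attention gains 1.2 (attended) / 0.8 (unattended) / 1.0 (neutral third),
then pass through the same noise + normalisation path. Their noise SD
defaults to 0.10, the midpoint of the training range (the exact value is not
specified by the protocol; any value in the range behaves equivalently).

### Node dynamics

Each hidden node carries an activation h and a refraction variable r:

    τ_h dh/dt = −h + σ((z − r − α(t) + h)/s)
    τ_r dr/dt = −r + c·h,      α(t) = m[1 + sin(2πft + φ)]

- τ_h = 0.01 s — how fast h chases its sigmoid target (membrane-like).
- τ_r = 0.1 s — afterhyperpolarisation-like timescale; sets the ~100 ms
  burst cadence. A fast-refraction variant (τ_r = 0.05 s) is a preset.
- c = 10 — refraction gain; r tracks c·h, so after a burst the node is
  suppressed until r decays. Larger c speeds the cycle (frequency is
  non-decreasing in c for moderate drive, verified in the tests).
- s = 0.1 — divides the whole sigmoid argument, effectively sharpening σ
  tenfold into a near-step response; this grouping (rather than scaling any
  single term) is the one consistent with the fixed-point expression below.
- m, f, φ — inhibition amplitude, frequency, phase per layer. α ∈ [0, 2m];
  m = 0.5 and f = 10 Hz are the working point, with φ expressing per-layer
  delays (phase = −2πf·delay).

Fixed points solve h\* = z/(c−1) + s/(c−1)·[log(1/h\*−1)/a − b] with
r\* = c·h\*. Because the right-hand side of h = σ((z−(c−1)h)/s) is strictly
decreasing in h for c > 1, the root is unique in (0, 1) and is found by
bracketed Brent root-finding (residuals < 10⁻⁸ enforced); the small-s
approximation h\* ≈ z/(c−1) is also returned and is used to initialise
network simulations at z = 2 (a quarter of the maximum input — on the
operating branch, so a temporal code forms within the first cycles).

Integration is explicit forward Euler at Δt = 1 ms, both state variables
updated from the pre-step state (synchronous update; layer 2's drive uses
layer 1's previous-step activations). Determinism is exact: same image,
weights and config give bit-identical trajectories.

Numerical accuracy: in the entrained regime (the one every full-network
experiment uses) Euler at Δt = 1 ms is phase-locked to the drive and agrees
with a 10× finer step to ≤ 2 ms in every peak time over 2 s. Free-running
(m = 0), Euler at 1 ms overestimates the limit-cycle period by ~5 %
(126 ms vs 119 ms for a high-accuracy RK45 reference at z = 8.5), and the
phase drift accumulates; free-running figures quoted by this package are
therefore reported at the canonical Δt = 1 ms with the period error
understood. The free-running frequency across the input grid spans
7.9–14.0 Hz with a maximum near z ≈ 4.5 and a decline toward stronger
drive (refraction saturates at r ≤ c while the drive grows).

### Full network

Both hidden layers get the dynamics; the output layer stays instantaneous
(softmax over h₂·W₃ at every step), since read-out is a decision rule, not a
neural population in this model. Inhibition is applied to hidden layers
only, each with its own α. The *bottleneck mode* — the network "without
dynamics" — is the same integrator with s = 1, c = 0 (r pinned at 0), m = 0
and zero initial state; it relaxes to the self-consistent equilibrium
h = σ(z + h), whose output on two-letter images is a mixture over both
letters' nodes. (The retained +h self-term means this equilibrium matches
the static forward pass only approximately — to within 0.05 for saturated
nodes — which is the designed behaviour, not an error.)

## Analysis conventions

- **Frequency**: mean inverse inter-peak interval after discarding a 0.5 s
  transient, peaks found with a prominence floor of 0.1 (robust on
  near-square bursts where a single Fourier bin can mislead); a spectral
  dominant-bin estimate serves as an independent cross-check in the tests.
  Traces with fewer than two qualifying peaks report 0 Hz (e.g. z ≤ 0.5).
- **Amplitude**: mean peak height above the post-transient minimum.
- **Events**: maximal runs where one output probability exceeds 0.5 — the
  natural "network prefers this letter" criterion for 3 classes
  (configurable). Events are grouped into inhibition cycles delimited by
  α maxima; the first cycle is excluded from steady-state statistics
  (initialisation transients routinely occupy cycles 1–2, and disrupted
  codes recover within about three cycles).
- **Similarity**: s_X(t) = h(t)·h^X / (h^X·h^X), projecting the
  instantaneous hidden state onto the static single-letter pattern h^X;
  equals 1 when the pattern is exactly reproduced and is scale-covariant.
- **Read-out accuracy**: a letter's maximum softmax probability after the
  transient.
- **Anti-phase locking** is assessed on burst midpoints (half-max
  crossings): raw peak positions of wide plateau bursts sit early in the
  burst and would misstate the phase by tens of ms at strong drive.

## What the simulations do and do not show

The synthetic stimuli emulate luminance-defined letter displays with
additive sensor noise and attention-as-gain. They do not model natural
image statistics, contrast normalisation, eccentricity, or feature overlap
between objects; "attention" is a fixed multiplicative gain, not a dynamic
process. Passing tests therefore demonstrate the mechanism — refraction
plus pulsed inhibition converting simultaneous inputs into a phase-ordered
code — in a controlled regime, not performance on natural scenes.

Quantitative phenomenology at the default (sharp) training endpoint, all
computed by the test suite or acceptance script: perfect train/test
classification; two read-out events per 10 Hz cycle on two-letter input
with the attended letter leading in ≥ 80 % (measured 100 %) of steady
cycles; attended-letter read-out ≈ 0.99; event durations ~25–40 ms;
layer 1 representing both letters in parallel while layer 2 sequences them;
the temporal code robust to layer-2 inhibition phase delays of tens of ms.
Slowing the inhibition to 5 Hz lengthens the excitable window and packs
more events per cycle (4–5 at the default training endpoint; 3 when the
network is trained to the softer two-mini-batch endpoint) — the item count
of the temporal code is set jointly by the inhibition period, the
refraction timescale, and the drive the trained weights deliver.

## Known limitations

- Explicit Euler's free-running period bias (~5 % at Δt = 1 ms) is accepted
  as part of the canonical numerical scheme rather than corrected.
- The softmax read-out renormalises during layer-wide silencing, so brief
  spurious preferences (~10–20 ms) can cross 0.5 on the rising-inhibition
  flank for some trained weights and input letters; inhibition always
  reduces spurious activation strongly relative to the free-running case,
  but does not eliminate threshold crossings for every seed.
- Three-letter temporal codes are fragile, as expected for this parameter
  regime: 10 Hz cycles fit at most two ~30 ms bursts plus refraction.
- No stochastic dynamics: noise enters only through the stimulus pixels.
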