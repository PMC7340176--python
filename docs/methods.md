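# Methods

## Hemodynamic model

Each of the 55 arterial segments is a linear lossy transmission line in
the frequency domain. Per unit length, the longitudinal impedance uses
Womersley theory,

    Z_long(ω) = (iωρ / πr²) · [1 − F₁₀(α)]⁻¹,
    F₁₀(α) = 2 J₁(αi^{3/2}) / (αi^{3/2} J₀(αi^{3/2})),   α = r√(ωρ/μ),

capturing the frequency-dependent viscous/inertial balance of oscillatory
pipe flow, and the transverse admittance is the thin-wall compliance
`Y_trans = iωC'` with `C' = 2πr³/(Eh)`. This compliance form is chosen so
the inviscid phase velocity reduces exactly to the Moens–Korteweg speed
`c = √(Eh/2ρr)`, which the tests use as a closed-form oracle. Blood is
ρ = 1.05 g cm⁻³, μ = 0.04 P.

The wall is viscoelastic: oscillatory harmonics see a complex modulus
`E(1 + iφ)` with a frequency-independent (structural) loss tangent,
default φ = 0.33. A purely elastic wall (φ = 0) leaves the tree so
underdamped that high-harmonic ringing dominates the timing features of
the distal pulse; structural damping of this size is within the range
reported for arterial wall tissue and restores realistically smooth
waveforms. φ is a solver parameter, so the elastic limit remains
available.

Square-root branches are fixed to Re γ ≥ 0 (waves attenuate) and
Re Z_C ≥ 0 (passive line). The steady (k = 0) component is computed
analytically as a Poiseuille resistor network — per-segment resistance
`8μl/πr⁴`, terminal resistances at the leaves, series/parallel assembly —
avoiding the 0/0 of the oscillatory formulas at ω → 0. An independent
nodal-analysis oracle checks this network on toy trees and the full tree.

Input impedances are assembled leaf-to-root (terminal load, single-child
chain, parallel bifurcation), then pressures and flows propagate
root-to-leaf: a child's inlet pressure is its parent's outlet pressure and
its inlet flow is that pressure divided by its own input impedance, which
makes flow conservation at junctions an algebraic identity — verified
numerically to 10⁻¹⁰ relative at every junction and harmonic.

The cardiac inflow is a parametric ejection pulse,
`q(t) = Q₀ sin²(πt/T_ej)` during ejection and zero in diastole, with
period 0.8 s (75 bpm), ejection duration 0.3 T, stroke volume 70 cm³,
K = 30 harmonics and N = 256 samples per period. The sin² profile is
continuously differentiable at the valve events, so the 30-harmonic
truncation reconstructs it to < 0.1% of peak; a plain half-sine has a
slope discontinuity whose Gibbs ringing exceeds 1%.

## The arterial tree and its calibration

The package ships its own literature-plausible 55-segment human tree (aortic trunk, coronary,
carotid/vertebral, upper-limb, visceral, lower-limb branches; 27 resistive
terminal loads distributed by regional flow fractions). Calibration was
done once and frozen into the shipped CSV, in this order of priority:
(1) the clinically documented severity trends of the distal pulse must
hold across the full 0–80% sweep; (2) the nominal patient should sit near
textbook pressures. The frozen tree gives brachial 131/80 mmHg, ankle
141/79 mmHg, ABI 1.074, mean pressure ≈ 95 mmHg at cardiac output
5.25 L min⁻¹. Two calibration choices deserve note:

* all radii and wall thicknesses carry a uniform ×1.3 relative to the
  initial draft table; this preserves every h/r ratio (hence every wave
  speed and all transit times) while lowering characteristic impedances,
  which brings pulse pressure down to a realistic value under purely
  resistive terminations (resistive loads reflect low-frequency energy
  completely, so an undersized tree otherwise overshoots pulse pressure);
* the posterior tibial segments are 38 cm × 0.286 cm radius, at the long
  end of the anatomical range, which places the ankle reflection timing
  where the severity trends are clean.

## Severity and its waveform signature

Severity s is fractional cross-sectional area occlusion of the infrarenal
abdominal aorta; the affected segment's radius becomes `r√(1−s)` over its
whole length (no turbulent/Bernoulli loss term — the stenosis acts through
its wave impedance `Z_C ∝ r^{−5/2}` and viscous resistance `∝ r^{−4}`).
On the nominal patient swept 0 → 80%, the package's morphology features
show: ankle pulse amplitude non-increasing, ankle crest time
(trough-to-peak) non-decreasing, ankle half-amplitude width
non-decreasing, brachial amplitude non-decreasing, ABI non-increasing with
a flat-then-drop profile (|ABI(0.4)−ABI(0)| ≪ |ABI(0.8)−ABI(0.5)|).

Timing features are defined on the waveform's native grid of 256 samples
per 0.8 s period (3.125 ms bins, equivalent to a 320 Hz recording — the
resolution class of clinical pulse instruments). The trough used for
crest time is found by walking back from the systolic peak to the first
local minimum, which is robust to secondary diastolic oscillations. At
much finer synthesis grids the continuous-time crest/width curves show
sub-millisecond wiggles (< 1% of the feature) at low severity, an
inherent property of a pure-diameter stenosis in a linear model whose
low-severity effect is carried by small reflection-phase shifts; the
monotone trends are therefore stated and tested at the native feature
resolution.

## Virtual cohorts

Inter-individual variability: the five parameters (length, diameter,
thickness, elasticity, peripheral resistance) take multiplicative levels
{0.8, 0.9, 1.0, 1.1, 1.2}, a 5⁵ = 3125 grid applied tree-wide.
Severity: 0–80% in 10% steps (train/validation basis, 28,125 patients) or
1% steps (test basis, 253,125 patients). Intra-individual variability:
each waveform sample re-draws the five factors from independent
log-normals with the patient's values as means and CV = 0.01
(σ² = ln(1+cv²), μ = ln m − σ²/2, so the mean and CV are exact); severity
itself is not perturbed, and cardiac parameters (stroke volume, ejection
timing, rate) are deliberately held fixed — variability is arterial only,
a stated limitation of the study design. RNG streams are derived per
(seed, patient, replicate) by hashing, so any sample regenerates in
isolation and full generation is order-independent and bit-reproducible.

The `mini` preset — 3³ grid over diameter/elasticity/peripheral
resistance, the same severity grids, 3/1/3 replicates (729 train, 243
validation, 6561 test samples) — is the problem size used by the test
suite and the acceptance script; it keeps the whole
simulate/train/evaluate study within minutes on one CPU while preserving
every structural feature of the full design. Generating the full 5.6M
samples is supported (`full` preset) but is a batch job.

## Network

Input: one cardiac period per sample, the brachial and ankle pressure
waveforms as two rows of a (2, 256) array, each z-scored with per-channel
training-set statistics. The rows are folded into the batch axis for the
convolutional stack, which is exactly "shared kernels of height 1": the
two pulses are convolved independently by identical kernels and never mix
before the fully connected layers (a weight-sharing test asserts the
row-swap symmetry). Five conv blocks (conv → batch-norm → LeakyReLU 0.01)
with kernel lengths {11, 7, 5, 3, 3} and counts {16, 32, 32, 64, 32},
stride-2 max-pooling after blocks 1, 2 and 5, and a global average pool
after block 5. The flattened latent vector is 32 channels × 2 rows = 64
features, deliberately equal to the 64-wide fully connected layers
(64 → 64 → 1, linear head). The final conv width is 32 rather than 64
precisely so that this latent/FC matching holds with two rows.

Training: mean-squared error on severity, Adam with β₁ = 0.9,
β₂ = 0.999, learning rate 2·10⁻⁴, batch 64, up to 100 epochs with
patience-40 early stopping on validation loss, best-validation weights
restored. The implementation is pure NumPy with hand-derived backward
passes (verified against finite differences), which buys exact
bit-reproducibility for a fixed seed and direct access to the
intermediate gradients Grad-CAM needs. On the mini cohort this reaches a
held-out severity MAE of ≈ 0.02 in well under ten minutes on one CPU.
Predictions are clipped to [0, 0.8]; classification labels PAD when the
predicted severity is ≥ the threshold (the tie goes to PAD — one
documented rule, immaterial at float resolution).

## ABI baseline

ABI = max(ankle BP) / max(brachial BP) over the period (the simulation is
periodic, so the global maximum is the systolic value). The calibration
simulates the nominal patient over a 17-point severity grid, fits
severity = P(ABI) with a cubic by least squares, evaluates the fit on a
dense grid, and projects it onto the nearest non-increasing function
(isotonic regression) before clipping to [0, 0.8] — a severity estimate
that rises with ABI is physiologically meaningless and would corrupt the
ROC construction. Degree 3 captures the flat-then-drop shape; the degree
is configurable.

## Evaluation protocols

Detection: for each labeling threshold (10–70% in 10% steps) draw equal
numbers of patients strictly below and at-or-above the threshold from the
test basis (1000 + 1000 at full scale, 100 + 100 at mini scale), classify
every stored waveform sample of those patients by thresholding the
predicted severity, and aggregate sensitivity, specificity and accuracy
over all samples; AUC is the rank (Mann–Whitney) statistic of the
continuous severity predictions, ties counting one half. Severity
assessment: a severity-uniform cohort (25 patients per 1% level at full
scale, 5 at mini scale) summarised by Bland–Altman bias and
bias ± 1.96·SD limits of agreement. Both protocols repeat 10 times with
independent draws; across-repeat means and coefficients of variation are
reported. At mini scale the Monte-Carlo error of the sampled
sensitivity/specificity (≈ 0.01 after averaging) exceeds the true
adjacent-threshold differences (≈ 0.006), so the monotone-trend assertion
for the ABI baseline is made on the exhaustive per-class rates over the
whole mini test set — the noise-free limit of the same estimator; the
sampled protocol is still what the reports contain.

## Interpretability

Latents are the 64 pooled last-conv features. t-SNE (perplexity 30, 1000
iterations, PCA init, fixed seed) embeds input and latent spaces for
inspection; the quantitative counterpart is a neighbour-coherence
statistic — the mean |severity difference| over each sample's 5 nearest
neighbours — which is smaller in latent space than in input space for a
properly trained model. Grad-CAM is adapted to regression by taking the
scalar severity output as the score: channel weights are the spatially
averaged gradients at the last conv layer, the weighted activation sum is
rectified, linearly upsampled to the input length and jointly normalised
to max 1. The planted-feature validation task puts a Gaussian bump
(amplitude = label) at samples 50–80 of one channel on silent background;
the localisation statistic is the saliency mass inside that window. Batch
norm is disabled in that experiment's network: its constant per-channel
offsets survive rectification as a spatially uniform saliency floor that
measures the normalisation rather than the attribution. The experiment
uses an otherwise identical five-conv architecture.

## Numerical and design notes

* Harmonic analysis/synthesis are exact FFT transcriptions; N = 256 ≥
  2K+2 prevents aliasing at K = 30.
* The impedance recursion and propagation are vectorised over harmonics;
  one patient simulates in ≈ 12 ms, the mini cohort in ≈ 2 minutes.
* `validate_tree` returns violations rather than raising, so a tree can
  be reported on in full; generation aborts only if > 1% of samples fail.
* Reproducibility contract: one master seed fans out to per-stage seeds
  by hashing; every stochastic stage (replicate noise, initialisation,
  shuffling, cohort draws, t-SNE) is bit-identical across runs.

## Limitations

Virtual patients only — the generator's realism is qualitative
(morphology trends), not patient-specific; segments are straight and
untapered, compliance is pressure-independent, terminations are purely
resistive (no windkessel), and venous return, autoregulation and cardiac
variability are absent. The stenosis is a single-site pure diameter
reduction without turbulent losses, so very high severities are likely
under-penalised. Passing the desk-scale tests shows the pipeline
recovers its own generator's severity signal under the stated variability
— it does not show clinical performance on measured waveforms.
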