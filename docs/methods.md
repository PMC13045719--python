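# Methods

`us2ct` reproduces, at desk scale, an in-silico study of ultrasound-to-CT
image translation: can a conditional adversarial network, fed ultrasound
data from different depths of the signal-processing chain, synthesise
CT-like images that make lesions easier to detect than the B-mode image
they came from?

## Phantoms

Phantoms are rectangular soft-tissue slabs (axial 40 mm × transverse
58.4 mm; a 10 mm elevation extent is recorded but only the elevational
mid-plane is rasterized) containing 0–3 non-overlapping spherical
inclusions with radii uniform in [1, 8] mm. Every pixel draws its density
and sound speed from a Gaussian with material-specific mean and relative
SD σ, truncated at ±4 σ to forbid non-physical values:

| material  | c₀ (m/s) | ρ₀ (kg/m³) | σ     |
|-----------|----------|-----------|-------|
| background (CT-invisible flavour) | 1540 | 1000 | 0.008 |
| background (CT-visible flavour)   | 1520 | 1030 | 0.008 |
| water     | 1480 | 1000 | 0     |
| muscle    | 1575 | 1065 | 0.08  |
| kidney    | 1570 | 1050 | 0.05  |

Water (σ = 0) is perfectly homogeneous, hence anechoic — the cyst-like
case. In the *CT-invisible* flavour the background mean density equals
water's, so anechoic inclusions carry no CT contrast at all; the
*CT-visible* flavour (background 1030 kg/m³) gives every inclusion CT
contrast. This pair of conditions is what makes the translation study
interesting: one modality can see what the other cannot.

Open choices made here: the inclusion count is uniform over {0,…,3}; the
raster pitch defaults to 0.1 mm/pixel (400 × 584) with a 0.4 mm coarse
preset for desk experiments; non-overlap is enforced by rejection sampling
with 1000 retries.

## Ultrasound simulation (stand-in physics)

The RF simulator deliberately replaces pseudospectral wave propagation
with convolutional linear scattering along ray paths — the single largest
simplification in the package. Per pixel, reflectivity is the fractional
fluctuation of acoustic impedance ρc about its local (5-pixel) spatial
mean, so homogeneous regions scatter nothing and material interfaces keep
a thin specular rim. Per scan line the echo signal is

  s(t) = Σ_pixels w(x, z) · T(x, z) · A(z) · r(x, z) · p(t − 2z/c̄),

with p a Hanning-windowed tone burst (4 cycles, 6 MHz), c̄ the flavour's
background sound speed, A(z) the two-way global attenuation
(0.75 dB cm⁻¹ MHz⁻¹·⁵ by default), w a Hann-apodized lateral beam profile
narrowest at the 20 mm transmit focus (a small residual defocus term
models the fixed transmit focus; dynamic receive focusing keeps the
round-trip beam near the diffraction limit elsewhere), and T the
accumulated scattering loss exp(−2κ∫r²dz) with κ = 3.5 mm⁻¹ — this term
produces the acoustic shadows distal to strongly scattering inclusions
that the translation model later learns to see through. Transmit
feedthrough is added at the top of each line and sensor noise at 1% of
the peak echo amplitude.

What this preserves: fully developed Rayleigh speckle, anechoic/
hyperechoic contrast, depth-dependent attenuation and resolution, and
distal shadowing — the image statistics the downstream model trains on.
What it does not: nonlinear propagation, reverberation, multiple
scattering, elevational effects, aberration. Conclusions from passing
tests therefore concern the translation methodology, not wave physics.

The record duration is derived from the background sound speed as the
round trip of the phantom depth plus a 3.995 mm margin, which reproduces
the two flavour-specific durations (57.1364 µs and 57.8882 µs) used at
full scale; sampling interval is duration / 2934 (fs ≈ 51 MHz).

## The 7-stage signal chain

Raw scan lines pass, in fixed order, through: input signal removal
(muting samples earlier than the tone-burst duration + 1 µs guard), time
gain compensation (exactly cancelling the modelled attenuation law, gain
10^(α f^1.5 · 2z_cm/20)), zero-phase Butterworth band-pass (6 MHz ± 50%
fractional bandwidth, order 4, forward-backward), analytic-signal envelope
detection, log compression (60 dB dynamic range mapped to [0, 1]) and
2× lateral linear upsampling, yielding the B-mode image. Each stage's
output is a training input in its own right: 7 matrices per phantom, six
of shape (lines × samples) and the upsampled B-mode at (2·lines × samples).
The chain is deterministic; all randomness lives in the simulator.

## CT simulation

The density map is windowed to [0, 1] by a linear window
(ρ − G_min)/(G_max − G_min); the default window is the dataset-global
attainable range (material means ± 4 relative SDs, matching the sampling
truncation), so windowing is identical for every phantom of a flavour.
The windowed image is zero-padded to a centred square and projected over
100 uniform angles in [0, π) by an explicit sparse parallel-beam operator
(rays sampled at 1-pixel steps with bilinear weights; ⌈√2·n⌉ detectors at
1-pixel pitch). Gaussian noise (1% of the maximum projection value) is
added per detector bin. Reconstruction is SIRT:

  x ← clamp₊(x + C Aᵀ R (b − A x)),   R, C = inverse row/column sums of A,

initialised at zero, 100 iterations by default (40 in desk runs). Because
A is an explicit matrix, the iteration is verified against a dense-matrix
oracle using the same operator, and the residual ‖b − Ax‖ is checked to be
non-increasing. Beam geometry (parallel), projector kernel (bilinear/
Joseph) and iteration count are package choices; beam-hardening and
Hounsfield calibration are out of scope.

## Paired dataset

The CT image is cropped to the probe's field of view (full 40 mm depth,
38.4 mm lateral span centred), the stage matrix is cropped to the
round-trip time of the phantom depth and transposed to axial × lateral,
and both are bilinearly resampled to a square raster (256² at full scale,
64² desk). The ultrasound input is mapped per-image from min/max to
[−1, 1] (its units are arbitrary; constant images map to 0); the CT
target is mapped by the *fixed* affine [0, 1] → [−1, 1] because the
windowed density scale is absolute — per-image normalization of targets
would stretch background noise to full scale (worst for inclusion-free
phantoms, whose intensity range is pure noise) and cap the achievable
SSIM between any translation and its target at ≈ 0.3–0.5, well below
what a consistent translator can reach on a shared scale (≈ 0.9, the
noise-realization ceiling). Splits are uniform random partitions at a 4:1 ratio (800/200
at full scale, 96/24 desk), drawn once per experiment; augmentation —
resize by 286/256, shared random crop, 50% joint horizontal flip — is
applied per training draw only, after split assignment, so no information
crosses the split.

## Translator

The translator is pix2pix: a UNet generator (encoder halving resolution
per level down to a 1×1 bottleneck, mirrored decoder with skip
connections, tanh output) and a patch discriminator over the concatenated
(input, candidate) pair, trained alternately with Adam (lr 2·10⁻⁴,
β₁ = 0.5, β₂ = 0.999), batch size 1, generator loss
BCE(D(x, G(x)), 1) + λ·L1 with λ = 100. The `full_256` preset is the
canonical topology (C64–C128–C256–C512×5 encoder, dropout 0.5 in the
first three decoder blocks, 70×70-receptive-field discriminator emitting
a 30×30 patch map). The `desk_64` preset — 6-level UNet with channels
16–128 on 64×64 images, 3-layer discriminator — is the configuration used
by the scaled-down experiments; its narrower channels keep a CPU training
run in minutes while retaining enough capacity to fit the task.

The networks and their gradients are implemented directly in NumPy
(im2col convolutions, instance normalization as the batch-size-1 analogue
of batch norm, hand-written backward passes, verified against numerical
differentiation). Inference runs with dropout off, so translation is
deterministic; a flag can re-enable sampling. Normalization is omitted at
the 1×1 bottleneck where per-channel statistics are degenerate.

## Metrics and statistics

* **gCNR** = 1 − Σ_bin min(p_ROI, p_BG) over 256 shared histogram bins
  spanning the pooled intensity range; exactly invariant under joint
  monotone affine remapping. The background region is the imaging field
  minus all inclusions dilated by 2 pixels. A degenerate pooled range
  (constant image) scores 0. Computed separately for anechoic and
  hyperechoic ROIs; only phantoms with at least one inclusion contribute.
* **SSIM** uses the scikit-image implementation with a uniform 7×7 window,
  K₁ = 0.01, K₂ = 0.03, data range 1.0 on [0, 1]-scaled images.
* **Jaccard** |A∩B|/|A∪B| compares binary masks (reader masks importable
  as PNG); undefined and rejected when both masks are empty.
* The statistical harness runs Anderson-Darling and Levene as reported
  preliminaries, Kruskal-Wallis as the omnibus, Dunn's rank-based
  post-hoc (tie-corrected z statistics; p-values reported without
  additional multiplicity adjustment) and a dependent t-test for paired
  Jaccard vectors; α = 0.05. For two tie-free groups Dunn's z reduces to
  the rank-sum normal approximation, which the tests use as an
  independent cross-check.

## Scaled-down replication

The acceptance script runs the whole chain at the desk preset: per
flavour, 120 phantoms at 0.4 mm pitch, 64-line probe at 3 MHz (734 time
samples), 96/24 split, 2500 training steps on the B-mode stage, SIRT at
40 iterations. It reports the mean gCNR of generated test images over
hyperechoic ROIs and the mean SSIM against ground-truth CT (CT-visible
flavour), plus the mean anechoic-ROI gCNR in the CT-invisible flavour —
the "inverse effect" where the translator, faithfully reproducing CT,
erases cyst-like inclusions that only ultrasound can see. The test suite
exercises the same pipeline at a further reduced size (40 phantoms, 800
steps per flavour) so the full suite stays fast; problem sizes are the
package's own scaling choices and are recorded in the experiment
manifests.

## Known limitations

* Stand-in acoustics (above): no wave-equation effects; shadow strength
  κ is a phenomenological constant.
* The desk preset changes probe frequency, sampling and network width
  relative to the full-scale configuration, so absolute metric values are
  not comparable to full-scale runs — only directions and orderings.
* The human reader study is out of scope: Jaccard utilities evaluate
  supplied masks but nothing here replaces radiologists.
* Per-image min/max normalization of pairs (a documented choice; the
  alternative dataset-global normalization is untested).
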