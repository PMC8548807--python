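# Methods

## The optical model

The rhabdom is modelled as a one-dimensional stack of absorbing slabs: no
distal optics, diffraction, waveguide modes or birefringence, no angular
or spatial structure, and no pupil mechanism. Light enters at the cornea,
attenuates slab by slab (Beer–Lambert), is fully reflected at the tapetum
(reflectance 1.0, spectrally flat, configurable) and attenuates again on
the way out; what leaves the distal face is the eyeshine. The default
grids are 300–700 nm at 1 nm and 450 µm of rhabdom at dz = 5 µm
(90 slabs). Absorption coefficients are in mm⁻¹ and dz is converted to mm
inside the propagation, so κ·dz is dimensionless.

Within each slab the flux used for photoconversion and quantum catch is
the *path-averaged* flux Ī = (I_in − I_out)/(c·dz), which is exact for
exponential attenuation. This choice makes the photon bookkeeping
(absorbed + exiting = source) hold to machine precision and gives clean
first-order convergence in dz: halving dz changes every normalized
sensitivity spectrum by well under 1% (tested).

Visual pigments follow the A1 nomogram (α-band plus, by default, the UV
β-band; a flag disables it — the measured opponent spectra show a small
UV sideband, so the band is on by default). Metarhodopsin uses the same
template family at its own peak wavelength, since only peak wavelengths
are known for the metarhodopsins. Pigment pairs: R515/M495 in R1/2,
R545/M505 in R3–9; α_R = 6 mm⁻¹, α_M = 7.5 mm⁻¹.

The red screening pigment has no tabulated spectrum, so a surrogate
logistic long-pass absorbance is used: 0.5 at λ_half = 600 nm with
steepness 0.05 nm⁻¹ (≈1 below, →0 above). It is implemented as a
non-bleaching absorber outside the receptor count — it attenuates the
flux but no photochemical rate ever changes its state — present between
230 and 420 µm.

### Morphology profile

The true depth profile of microvillar cross-sections is not published for
these species, so the package ships a documented default: R1&2 contribute
15% each for z < 250 µm and nothing below; R3&4 contribute 20% each
distally, rising to 25% where R1&2 vacate; R5–8 share the remainder
equally; R9 fills the cross-section in its 400–450 µm window. A helper
(`perturb_geometry`) scales each receptor's profile by random factors
within ±10% for robustness checks; all headline quantities reported by
the acceptance script move by well under their tolerances when the
profile is perturbed (tested).

### Solvers

* Fixed point: iterate {flux → per-unit-fraction rates →
  f_R = k_M/(k_R + k_M)} from the dark-adapted state (f_R = 1) until
  max |Δf_R| < 10⁻³ (default). On the default configuration this
  converges in 4 iterations; slabs a receptor does not occupy keep the
  dark state.
* ODE: df_R/dt = k_M f_M − k_R f_R with the flux recomputed as the state
  evolves, integrated with an explicit Runge–Kutta scheme. There is no
  absolute photon-to-rate constant in the model, so time is normalized:
  rates are scaled so the largest initial conversion rate is 1 per time
  unit; the default duration of 400 time units is far past the slowest
  slab's equilibration. The two routes agree to max |Δf_R| < 10⁻⁵ on the
  default configuration (the test asserts < 0.01).

Equilibria are invariant to scaling the source intensity (rates scale
jointly), which is also tested.

### Calibration of the screening-pigment density

The screening pigment's peak absorption coefficient α_S is the one free
optical parameter. It was calibrated once, and frozen in the default
configuration, so that the modelled R9 sensitivity peaks at 620 nm — the
measured peak of the red opponent unit and the model's central spectral
prediction. That gives α_S = 20 mm⁻¹. An eyeshine-based calibration was
considered and rejected: the visual pigments alone absorb essentially all
light below ~570 nm over the doubled path, so the modelled eyeshine
half-rise sits at 624–645 nm for any α_S between 5 and 60 mm⁻¹ and cannot
be steered to a target wavelength.

### Distal/basal summaries

Self-screening shifts the local quantum-catch spectrum continuously with
depth, so "the distal peak" depends on how thick a distal window one
integrates. Two window sets are used, exposed as module constants:

* equilibrium fractions are averaged (ρ-weighted) over thick regions —
  distal = 0–230 µm (above the screening pigment), basal = 350–450 µm
  (including the R9 zone);
* partial quantum catches use thin end-windows — distal = 0–50 µm,
  basal = 350–400 µm — because a thick distal sum mixes depths and
  displaces the peak (the 0–230 µm sum peaks near 560 nm, the top slabs
  at 545 nm).

### The printed catch formula

The catch is computed as Q_r(λ) = Σ_z Ī_z κ_zrR Γ_rR dz, the photons
absorbed by the rhodopsin isoform per unit corneal flux. A form that
multiplies by ρ_zr a second time (ρ already enters through κ) and omits
Γ appears in some descriptions of this model class; the absorbed-photon
form is the physically consistent one. Normalized spectra are identical
under any per-receptor constant, and the R1:R9 log ratio reported here
uses the absorbed-photon form.

### Known limitation: the R1:R9 sensitivity ratio

The model puts R9's peak catch about 0.9 log₁₀ units below R1's. The
ratio depends jointly on α_S and on the morphology profile, in particular
on R9's cross-section (100% of the basal 50 µm in the default profile)
— anatomically R9 is a minute cell, and a smaller effective cross-section
or a denser screening pigment (α_S ≥ 40 mm⁻¹) both push the ratio toward
2 log units, at the cost of displacing the modelled R9 peak beyond
630 nm. With the documented defaults the package reports the ~0.9 value
rather than tuning for the larger deficit.

## The electrophysiological analysis

Amplitudes are voltages relative to the dark resting potential
(depolarizations positive). The intensity–response sigmoid
V = V₀Iⁿ/(Iⁿ + Rⁿ) is fitted by least squares on voltage (additive
voltage noise is the physiological convention); the fit is evaluated
through log₁₀ intensity for conditioning, which is algebraically
identical. An optional exclusion window on log intensity drops
supersaturating flashes. Reverse transformation inverts the fitted
sigmoid: I_eq = R·(V/(V₀−V))^(1/n); for isoquantal flashes of one common
intensity the sensitivity is proportional to I_eq. Amplitudes at or above
0.98·V₀ are excluded with a warning (the inversion diverges at V₀);
amplitudes at or above V₀ raise an error.

Opponent decomposition follows the selective-adaptation logic: G+ is the
depolarizing sensitivity under red adaptation (opponent unit silenced),
normalized to +1; R− is the hyperpolarizing amplitudes under green
adaptation (G+ suppressed) reverse-transformed through the
*hyperpolarizing* pathway's own sigmoid, reported negative; the combined
spectrum is re-normalized so the larger-magnitude peak is +1. The output
is invariant to the overall gain of the recording (tested).

Polarization runs are fitted on the voltage oscillation itself — a
squared cosine is exactly a second-harmonic cosine, so the fit is a
closed-form harmonic regression — and the fitted extreme voltages are
then reverse-transformed to give Ψ = S_max/S_min; Φ is reported modulo
180°. Fitting voltages first is deliberate: inverse-transformed
sensitivities have strongly heteroscedastic noise, while the voltage
noise is additive. A flat run is flagged degenerate (Ψ = 1, Φ undefined)
rather than fabricated.

Peak and bandwidth reporting: λ_max by parabolic interpolation around the
grid maximum (optionally a least-squares quadratic over all contiguous
points above 75% of the maximum, which is what the noisy 21-wavelength
LED grid needs), FWHM by linear interpolation of the two half-maximum
crossings, computed on the magnitude of the spectrum so opponent
components report positive bandwidths; dual peaks are reported when a
second local maximum exceeds half the main one beyond a trough. For
single-pigment cells the pipeline assigns λ_max by fitting the nomogram
template itself (free peak and amplitude, all 21 points), and for the
band-shaped R− components by fitting a Gaussian — both standard practice
and far more precise on coarse grids than three-point interpolation
(noiseless biases ≤ 1.6 nm across the species presets, tested).

## The synthetic-recording generator

The generator emulates what the analysis assumes, with the measured
values as defaults: a depolarizing green unit (sigmoid half-max at
−2.51 log, slope 0.86) and a delayed hyperpolarizing opponent input
driven by a red unit's own sigmoid (half-max −1.21 log, slope 1.05),
scaled by the driving force (V_hold − E_rev)/(V_rest − E_rev) with
E_rev = −70 mV — so depolarizing current amplifies the hyperpolarization
and current that drives the cell below −70 mV reverses its sign, crossing
zero exactly at the reversal potential (asserted in tests). Defaults not
printed anywhere and chosen once as realistic study conditions: V₀ =
25 mV (green) and 10 mV (opponent pathway, the smaller dynamic range),
resting potential −60 mV, input resistance 20 MΩ for nA→mV conversion,
synaptic delay 20 ms (visible in the optional step time course), additive
Gaussian noise of 0.5 mV.

Chromatic adaptation is divisive: a steady background at λ_a with
intensity I_a multiplies each unit's catch by 1/(1 + S_u(λ_a)·I_a/R_u) —
the simplest mechanism that lets a green background isolate the
hyperpolarizing responses and a red background silence them. The standard
protocol set uses a strong green background (log I_a = 1) and a moderate
red one (log I_a = 0), as an experimenter would choose them: the red
background must silence the less-sensitive red unit without acting on the
green unit through its long-wavelength template tail. Stimuli default to
the 21 LED peak wavelengths (365–685 nm); spectral series run at
sub-saturating intensities (−2.0 dark, −1.0 green-adapted, −1.5
red-adapted, 3–5 repeats), intensity series span −4…0 log in 17 steps,
and polarizer runs make 5 full rotations in 18° steps with cos²-modulated
catches per unit.

Species presets carry the measured opponent-cell parameters of the eight
species with red ommatidia (R− peak 610–620 nm, FWHM 40–60 nm; G+ peaks
440–545 nm) plus two negative controls without an R− unit. Dual-peaked
green units (opsin co-expression) are weighted sums of two templates; the
R− spectra are Gaussians with the preset peak/FWHM (the default for a
single synthetic cell can also be the model's own R9 spectrum).

What the generator does *not* emulate: photon shot noise, spikelets,
conductance dynamics, receptive-field structure, and — because the green
unit uses a raw pigment template — the measured cells' sharp red cutoff.
A consequence is that dark-adapted red flashes produce a small net
depolarization in the synthetic cells, where real G+R− cells
hyperpolarize; the adaptation-isolated components, which are what the
analysis quantifies, are unaffected. Passing recovery tests therefore
demonstrate that the analysis chain inverts data with the assumed
structure at realistic noise, not that it is robust to every artefact of
real recordings.

## Problem sizes and determinism

The default model run is 401 wavelengths × 90 slabs × 9 receptors and
converges in 4 fixed-point iterations (< 1 s); the ODE route integrates
810 state variables for 400 normalized time units (~15 s). The
parameter-recovery studies use 100 synthetic cells (sampled peak
wavelengths 450–545 nm) and the species table 3–5 cells per preset, with
recovered values averaged over cells, never pooled before fitting. Every
stochastic component is driven by an explicit seed; identical seeds give
bit-identical run tables and pipeline outputs (tested).
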