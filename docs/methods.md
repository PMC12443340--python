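# Methods

`pabreast` simulates photoacoustic breast imaging at desk scale to study how
skin tone affects the detectability of small blood targets, and how the
choice of transmit wavelength and image formation method (FFT/k-space
reconstruction, delay-and-sum, short-lag spatial coherence) mitigates the
skin tone bias. This note documents the models, their assumptions, the
parameters that matter, and the deliberate simplifications.

## Phantom

The tissue model is a layered breast slab immersed in water: a 1.4 mm water
standoff between the transducer face (z = 0) and the skin surface, a skin
layer of configurable thickness (default 1.4 mm), and a breast interior of
fibroglandular tissue (optionally with seeded fat blobs) below. A spherical
blood target of diameter 0.5–3 mm is centered laterally with its center
10 mm below the volume top, i.e. 8.6 mm below the skin surface. Voxel
membership uses a voxel-center test. The full-scale study geometry
(45 × 15 × 20 mm at 100 µm voxels) is expressible; the desk-scale default is
the 2D imaging-plane slice at 150 µm pixels, which keeps a full sweep in the
minutes range on one CPU without changing any physical constant.

The skin thickness is a modeling choice: the quantity that drives the
skin-tone mechanism is the total optical absorption of the skin layer, and
1.4 mm — matching the water standoff so the breast interior starts at
2.8 mm — is within the anatomical range for breast skin. The interior
composition default is uniform fibroglandular ("extremely dense" breast);
heterogeneity relevant to the clutter mechanism is injected downstream by
the binary absorber map, not by the fat/fibroglandular layout.

Skin optical absorption follows the empirical individual-typology-angle
(ITA) melanin model

    mu_a(lambda, ITA) = 45.4 · 10^(−0.004·lambda) · 10^(−0.014·ITA)  [mm^-1]

with wavelength in nm and ITA in degrees: darker skin (lower ITA) absorbs
more at every wavelength. Eighteen ITA values spanning −54° to 60° (three
per skin tone category from Very Light to Dark) define the simulated
population. All other optical coefficients (water, fat, fibroglandular,
blood) and all acoustic properties (sound speed, density, attenuation) are
tabulated per tissue at 757, 800, and 1064 nm; anisotropy g = 0.9 and
refractive index n = 1.37 are uniform across media, including water.
Other wavelengths raise by default; an opt-in log-linear interpolation of
the tabulated coefficients is available.

Vessel phantoms (a splayed vessel and a claw structure, benign- and
malignant-lesion features) are generated parametrically as tapered tubes
along polyline centerlines and voxelized by a point-in-tube test; an
optional binary-STL path (via `trimesh`) voxelizes externally authored
meshes by a point-in-mesh test.

## Optical transport

Fluence is computed by a weighted-photon voxel Monte Carlo: collimated
Gaussian beam (waist radius 4 mm, read as the 1/e² intensity radius — the
convention is not fixed by the source material, so each transverse offset
component is N(0, (w/2)²)), exponential free paths against
µ_t = µ_a + µ_s, survival (albedo) weighting at collisions,
Henyey–Greenstein scattering sampled by the closed-form inverse CDF, Russian
roulette below weight 1e-4 with survival factor 10, and a path cap of 10
volume diagonals. Fluence uses a track-length estimator (lower variance
than a collision estimator in low-µ_a voxels); the energy ledger uses
collision-based absorption so that launched weight equals
absorbed + escaped + terminated weight exactly when roulette is off.

Because the refractive index is uniform, there are no refraction or Fresnel
events, and the surface is treated as matched for the normally incident
collimated source. In 2D mode the label map is extruded along elevation:
photons move in 3D, but lookup and deposition use the in-plane voxel only.
This preserves 3D attenuation physics (e.g. the Beer–Lambert limit) while
keeping the grid two-dimensional; it ignores elevation-dependent structure,
which the layered phantom does not have anyway.

The desk-scale photon budget is 1e5 per condition (the full-scale budget of
1e8 is a config knob); Monte Carlo error scales as expected with photon
count, and the detectability metrics operate on peak-normalized images, so
the absolute fluence scale is irrelevant.

## Initial pressure and channel data

Initial pressure is p0 = Φ·µ_a·Γ with the Grüneisen parameter Γ = 1 for all
tissues, thinned by an i.i.d. Bernoulli(0.5) binary absorber map — the
absorber map, together with the skin layer, is the clutter source of
interest. A 128-element linear array (0.3 mm pitch, 7 MHz center frequency,
4.9 MHz bandwidth, 40 MHz sampling) records one-way spherical-wave
superposition at an effective homogeneous sound speed of 1540 m/s: each
nonzero voxel contributes an impulse at delay d/c with amplitude p0/√d (2D)
or p0/d (3D), scaled by a hard-baffle sinc element directivity (toggleable,
element width = pitch) and optionally by single-frequency path attenuation
10^(−ᾱ·f_c·d/20) using the mean tabulated attenuation coefficient sampled
along the straight path (off by default). Traces are convolved with a
Gaussian-modulated cosine whose −6 dB two-sided spectral width equals the
bandwidth.

This analytic forward operator replaces a full-wave heterogeneous solver.
It preserves the mechanism the study attributes clutter to — skin-origin
initial pressure and absorber-map speckle overlying the target — and is
linear, exactly superposable, and oracle-friendly. Speed-of-sound
aberration, multiple scattering of acoustic waves, and dispersive power-law
attenuation are documented as unmodeled.

Channel noise is zero-mean i.i.d. Gaussian at a 20 dB channel SNR defined
on full-record RMS (the SNR convention is a package choice; the source
material does not define one).

## Image formation

* **DAS**: per pixel, the unapodized sum of one-way-delayed samples over
  all elements, linear interpolation between samples; envelope detection by
  axial Hilbert magnitude.
* **SLSC**: per pixel, the sum over lags m = 1..M (M = 10) of the
  normalized spatial coherence R̂(m) of 7-sample axial kernel windows
  (0.270 mm at 1540 m/s and 40 MHz) extracted at the same delays;
  zero-energy window pairs are skipped with pair-count renormalization to
  avoid 0/0 without biasing coherent regions. Raw values lie in [−M, M];
  negative values are clamped to zero. No Hilbert envelope is applied to
  the SLSC image: the lag-summed coherence map carries no RF carrier, and
  applying an analytic-signal envelope to it measurably blurs the axial
  profile and biases the peak (0.3 mm on the point fixture) without
  changing its information content.
* **FFT**: planar-geometry k-space reconstruction — 2D spectrum over
  (time, lateral), Stolt remapping of temporal frequency onto axial
  wavenumber via ω = c·√(k_x² + k_z²) with linear interpolation and the
  associated Jacobian weighting, zeroing of evanescent components, inverse
  transform, then bilinear resampling onto the image grid. The k-space
  image is rectified by absolute value for metrics and display (it receives
  no envelope detection).

Every image is normalized by its brightest pixel. For display, FFT and DAS
images are log compressed (20·log10) with a repository-default 40 dB dynamic
range (the study's display range is not printed); SLSC images are displayed
linearly. All detectability metrics are computed on the normalized linear
stage, prior to any log compression.

## Metrics

The target ROI is a disk the size of the target, concentric with it at the
ground-truth center; the background ROI is an annulus with inner radius 2r
and outer radius chosen so the two ROIs have equal areas (√5·r in continuous
geometry; under rasterization the outer radius is found by a fine search
minimizing the pixel-count mismatch). Since the simulation ground truth is
available, ROIs are centered at the true target center and one ROI pair per
diameter is replicated across wavelengths, skin tones, and methods; an
optional mode re-centers on a reference image peak instead.

* **SNR** = µ_i/σ_o: target-ROI mean amplitude over background-ROI sample
  standard deviation. A numerically constant background (e.g. a clamped
  SLSC annulus that is entirely zero — fully suppressed clutter) makes SNR
  undefined; it is signalled as an error, recorded as NaN in sweep tables,
  and never returned as infinity.
* **gCNR** = 1 − Σ_k min(h_i(x_k), h_o(x_k)) over N = 32 shared equal-width
  bins spanning the combined amplitude range of the two ROIs, histograms
  normalized to unit mass. Bounded in [0, 1]; invariant under affine
  amplitude rescaling (bin edges recompute from the data range); with the
  smallest targets the ROIs hold few pixels and the sparse histograms bias
  gCNR upward — a resolution artifact shared by all conditions at a given
  diameter, so cross-condition comparisons remain meaningful.
* **FWHM**: average of the three rows (or columns) centered on the target
  line, half-maximum crossings located by linear interpolation on both
  sides of the peak.

## Sweeps, seeds, and trend checks

A sweep is the cartesian product of wavelengths × ITA values × diameters,
each condition running phantom → fluence → p0 → channels → noise → three
reconstructions → metrics. One master seed expands deterministically
(CRC32-tagged SeedSequence) into per-stage, per-condition seeds, so repeat
runs are byte-identical. Condition failures are logged as table rows with
an error message and excluded from aggregation; they never abort the sweep.
Aggregation reports mean ± standard deviation of SNR and gCNR per skin tone
category, diameter, method, and wavelength, with the category's ITA values
as the replicate axis.

The desk-scale sweep uses one ITA per category (60, 47, 35, 20, −10, −54)
and four diameters (0.5, 1.5, 2.25, 3 mm). `trend_report` evaluates the
directional claims this reduced design can support: (a) DAS SNR at 757 and
800 nm increases with ITA (Spearman ρ > 0 of per-ITA mean SNR — the skin
tone bias of amplitude beamforming), and (b) the across-category coefficient
of variation of mean gCNR with SLSC is smaller at 1064 nm than at 757 nm
(the long wavelength equalizes skin tones because water, not melanin,
dominates proximal absorption there). Each check reports pass / fail /
inconclusive (exact tie) / insufficient (missing coverage) rather than
raising.

Absolute SNR/gCNR magnitudes from the full-scale study (3D anatomical
phantom, 1e8 photons, full-wave acoustics) are not reproduced by this
desk-scale pipeline and are not asserted anywhere; the test suite instead
verifies the forward models against closed forms and brute-force oracles
(Beer–Lambert limit, energy conservation, exact DAS/SLSC equivalence on
small instances, gCNR reference cases, FWHM of a discrete Gaussian,
point-source localization) and the directional trends above.

## Numerical choices and limitations

* Delay and Stolt interpolation are linear (deterministic and
  oracle-friendly); voxel indices use floor so that points marginally
  outside the grid escape rather than alias into edge voxels.
* The photon path cap (10 diagonals) guards against non-terminating paths
  in transparent media; roulette keeps the deep-weight tail unbiased.
* A sub-voxel sphere labels at least the voxel nearest its center.
* Known limitations: no acoustic heterogeneity or aberration; no Fresnel
  physics; 2D extruded optics ignores elevation structure; small-ROI gCNR
  inflation at the 0.5 mm diameter; the SLSC axial response is plateau-like
  over roughly the pulse length, so its axial FWHM is kernel- and
  pulse-limited rather than target-limited.
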