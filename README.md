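# pabreast

Desk-scale simulation of photoacoustic breast imaging for studying **skin
tone bias in target detectability**. Illumination through skin deposits
optical energy in the melanin-rich epidermis; the resulting skin-origin
acoustic waves become clutter that can mask small blood targets — and the
effect grows as skin tone darkens. This package simulates that mechanism
end to end and quantifies how transmit wavelength (757, 800, 1064 nm) and
image formation method trade off against it, for spherical blood targets of
0.5–3 mm diameter and vessel-like structures under skin tones spanning
individual typology angles (ITA) from 60° (very light) to −54° (dark).

It is aimed at researchers in photoacoustic image formation and imaging
fairness who want a fully scripted, seed-reproducible pipeline — no
downloads, no MATLAB — whose every stage is testable against closed forms
and brute-force oracles.

## Models at the core

* **Skin optical absorption** (melanin/ITA model):
  `mu_a(lambda, ITA) = 45.4 · 10^(−0.004 lambda) · 10^(−0.014 ITA)` mm⁻¹ —
  e.g. 0.0144 mm⁻¹ at 1064 nm for ITA = −54° versus 0.0004 mm⁻¹ for
  ITA = 60°.
* **Fluence** Φ by weighted-photon voxel Monte Carlo (Henyey–Greenstein
  scattering, g = 0.9; track-length estimator) from a collimated Gaussian
  beam of 4 mm waist radius (50.3 mm² illumination area).
* **Initial pressure** `p0 = Φ · mu_a · Γ` (Γ = 1), thinned by a 50% binary
  absorber map.
* **Channel data** at a 128-element, 0.3 mm pitch, 7 MHz linear array
  (40 MHz sampling): one-way spherical-wave superposition at 1540 m/s,
  band-limited to 4.9 MHz, plus 20 dB Gaussian channel noise.
* **Reconstruction**: FFT/k-space (Stolt regridding via ω = c·|k|),
  delay-and-sum (DAS), and short-lag spatial coherence (SLSC) beamforming
  with maximum lag M = 10 and a 0.270 mm (7-sample) axial kernel:
  `SLSC(pixel) = Σ_{m=1..M} R̂(m)`, the lag-averaged normalized
  cross-correlation of delayed element signals.
* **Detectability**: `SNR = mu_i / sigma_o` (target-disk mean over
  background-annulus standard deviation; annulus inner radius 2r, equal
  areas) and `gCNR = 1 − Σ_k min(h_i(x_k), h_o(x_k))` over N = 32 shared
  bins, plus FWHM resolution measurements.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

A 2.25 mm blood target under dark skin (ITA = −54°) imaged at 1064 nm:

```python
from pabreast import (
    GridSpec, SkinToneSpec, build_sphere_phantom, PhotonSource,
    simulate_fluence, make_absorber_mask, initial_pressure,
    simulate_channels, add_channel_noise, ImageGrid, das, slsc, fft_recon,
    postprocess, make_rois, compute_snr, compute_gcnr,
)
from pabreast.phantom import property_arrays

grid = GridSpec.breast_2d()                 # 15 x 45 mm plane, 150 um pixels
vol = build_sphere_phantom(2.25, grid)      # target centered 10 mm deep
props = property_arrays(1064, SkinToneSpec(ita=-54))

flu = simulate_fluence(vol, props, PhotonSource(n_photons=100_000, seed=1))
mask = make_absorber_mask(vol.labels.shape, density=0.5, seed=2)
p0 = initial_pressure(flu, props["mua"][vol.labels], gamma=1.0, mask=mask)
rf = add_channel_noise(simulate_channels(p0), snr_db=20.0, seed=3)

img_grid = ImageGrid.from_grid_spec(grid)
rois = make_rois(vol.target_center, 2.25, img_grid)
for recon_fn in (fft_recon, das, slsc):
    img = postprocess(recon_fn(rf, img_grid))
    print(f"{img.method:4s}  SNR = {compute_snr(img, rois):6.2f}   "
          f"gCNR = {compute_gcnr(img, rois):.3f}")
```

prints

```
FFT   SNR =  28.24   gCNR = 0.878
DAS   SNR =  16.46   gCNR = 0.930
SLSC  SNR = 681.47   gCNR = 0.988
```

All three methods see this relatively large target at 1064 nm even under
the darkest simulated skin tone — at this wavelength the water standoff,
not melanin, dominates proximal absorption. SLSC gives the best histogram
separation (gCNR); its very large SNR reflects near-total clutter
suppression in the background annulus (the coherence there clamps to almost
zero, so the SNR denominator collapses — when it reaches exactly zero the
package reports SNR as undefined rather than infinite). Repeating at
757 nm and sweeping skin tones reverses the picture for amplitude-based
methods: `pabreast sweep` (or `pabreast.experiments.run_sweep`) runs the
wavelength × skin tone × diameter grid, writes tidy `metrics.csv` /
`aggregate.csv` tables, and `trend_report` checks the directional claims
(DAS SNR at 757 nm rises with ITA; SLSC gCNR varies less across skin tone
categories at 1064 nm than at 757 nm).

A CLI mirrors the pipeline stages:

```sh
pabreast phantom --kind sphere --diameter 2.25 --out vol.h5
pabreast optics --volume vol.h5 --wavelength 1064 --ita -54 --photons 1e5 --seed 7 --out phi.h5
pabreast acoustics --volume vol.h5 --phi phi.h5 --wavelength 1064 --ita -54 --out rf.h5
pabreast recon --rf rf.h5 --method slsc --out img.tif
pabreast sweep --out results/
```

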