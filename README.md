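# fluordepth

**Ratiometric dual-wavelength fluorescence depth estimation of
photosensitizers in turbid tissue.**

Photodynamic therapy (PDT) with chlorin-e6-type photosensitizers (PS) is
monitored by wide-field fluorescence imaging. These drugs absorb at two
wavelengths — the Soret band (~405 nm) and the Q band (~660 nm) — and emit
near 760 nm. Blue excitation light penetrates tissue far less than red, so
the intensity-normalized ratio of red- to blue-excited fluorescence

```
R = (F(660 nm) / I_660) / (F(405 nm) / I_405)
```

encodes the depth at which the PS sits: superficial PS gives small R, deep
PS gives large R. `fluordepth` implements the full chain from this idea to
numbers, for physicists and biomedical-optics researchers who analyze
dual-wavelength PDT monitoring data:

* **Forward model** — the diffusion-approximation fluorescence flux

  `F = φ I_ex k_ex sinh(q) e⁻ᑫ/q ∫ μ_a,PS(z) e^(−(μ_ex+μ_em) z) dz`

  with closed-form ratios R(d), R(d_b), R(d_1e) for a uniform surface layer,
  a buried uniform layer, an exponential concentration profile, and a
  bleached (buried) exponential profile.
* **Inverse estimators** — depth from a measured ratio for each profile, and
  the PDT-induced photobleaching shift Δd_b = ln(R_after/R_before)/(μ_ex1−μ_ex2).
* **Dual-step photon Monte Carlo** — an independent numerical verification
  of the model (weighted photons, Henyey–Greenstein scattering, Woodcock
  delta tracking, Fresnel boundary, isotropic re-emission from the
  PS-absorbed dose).
* **Image pipeline** — dark subtraction, shared ROIs, excitation-intensity
  normalization and reference-object calibration turning 16-bit image pairs
  into calibrated ratios and depth reports.
* **Synthetic fixtures** — noisy image pairs with exact ground truth, and
  two-layer phantom profile series.

A human-dermis optical-property preset at 405/660/760 nm
(`dermis_table1`) ships with matching chlorin-e6 absorption amplitudes.

## Worked example

```python
from fluordepth import (preset_triple, preset_amplitudes, ratio_limits,
                        ratio_bottom, invert_bottom, bleach_depth)

triple = preset_triple("dermis_table1")
amps = preset_amplitudes("dermis_table1")

r0, rinf = ratio_limits(triple, amps)
print(f"R0 = {r0:.4f}, Rinf = {rinf:.4f}")
# R0 = 0.2393, Rinf = 0.6645

R = ratio_bottom(triple, 0.3, amps)       # PS buried under 0.3 mm of tissue
print(f"R(d_b = 0.3 mm) = {R:.4f}")
# R(d_b = 0.3 mm) = 2.0860

print(f"reconstructed d_b = {invert_bottom(R, triple, amps):.4f} mm")
# reconstructed d_b = 0.3000 mm

print(f"bleach shift = {bleach_depth(2.5, 2.0, triple):.4f} mm")
# bleach shift = 0.0585 mm
```

The first two numbers are the thin- and thick-layer asymptotes of the ratio
on the dermis preset: every surface-profile ratio lies between 0.239 and
0.664, and ratios above 0.664 indicate PS buried under a PS-free cover —
here 0.3 mm of dermis triples the ratio to 2.09, and the closed-form inverse
recovers the cover thickness exactly. The last line converts a post/pre-PDT
ratio increase (2.0 → 2.5) into a 0.06 mm downward shift of the PS layer,
the signature of superficial photobleaching.

The `examples/` directory holds one short script per capability
(forward curves, inversion, Monte Carlo verification, image pipeline,
sensitivity analysis); each prints the numbers it computes and what they
mean. A thin CLI mirrors the same stages:

```bash
fluordepth forward --preset dermis_table1 --profile bottom_uniform --grid 0:1.5:0.05
fluordepth invert --kind exp -R 0.45
fluordepth mc --profile top_uniform --depth 1.0 --photons 200000 --seed 7
fluordepth ratio --blue b.tif --red r.tif --dark d.tif --roi roi.json --administration topical
```

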