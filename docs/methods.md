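# Methods

## The physical problem

Chlorin-type photosensitizers (PS) used in photodynamic therapy (PDT) have
two absorption peaks — the Soret band near 405 nm and the Q band near
660 nm — and emit fluorescence near 760 nm. Blue excitation light is
attenuated in tissue much faster than red, so the ratio of red-excited to
blue-excited fluorescence, each normalized by its excitation intensity,

    R = (F(660) / I_660) / (F(405) / I_405),

increases monotonically with the depth at which the PS sits. `fluordepth`
turns this into a quantitative depth estimator: a forward model R(depth), its
inverses depth(R), a photon Monte Carlo to verify the model, and an image
pipeline that produces R from wide-field camera frames.

## Forward model

The escaping fluorescence flux for plane-wave excitation of a semi-infinite
turbid medium with a depth profile mu_a_ps(z) of PS absorption is modeled in
a hybrid way: excitation propagation follows the semi-empirical beam model of
Jacques (exponential decay at the diffusion attenuation rate
mu_diff = sqrt(3 mu_a mu_t'), enhanced by the backscattering factor
k_ex = 3 + 5.4 p' − 2 e^(−17 p'), p' = exp(−(8/3) mu_diff/mu_t')), and the
isotropically emitted fluorescence escapes per the diffusion approximation
with the boundary factor sinh(q) e^(−q)/q, q = 2 mu_diff(λ_em) m / (3
mu_t'(λ_em)):

    F = phi I_ex k_ex sinh(q) e^(−q)/q ∫ mu_a_ps(z) e^(−(mu_ex + mu_em) z) dz.

The model assumes mu_a_ps ≪ mu_a of the base tissue (a warning is emitted
when the ratio exceeds 0.25 — the threshold is a package convention; the
underlying theory states only "small").

Four canonical profiles have closed-form ratios: a uniform surface layer of
thickness d (saturating in d), a uniform half-space under a PS-free cover
d_b (exponential in d_b), an exponential concentration profile with 1/e
depth d_1e (saturating, with exactly twice the initial slope of the uniform
layer), and the exponential profile buried under a cover (the product of the
last two forms). All ratios are independent of the absolute PS concentration
and lie between the thin-layer limit R0 = (phi2 a2/phi1 a1)(k_ex2/k_ex1) and
the thick-layer limit Rinf = R0 (mu_ex1+mu_em)/(mu_ex2+mu_em) (the buried
layer starts at Rinf and grows beyond it).

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| mu_a, mu_s, g, n | base-tissue optical properties per wavelength, 1/mm, – | `dermis_table1` preset | human dermis at 405/660/760 nm |
| m | internal-reflection factor of diffuse emission | 2.76 | value for n = 1.37; user-settable, not computed from n (the defining formula lives outside this model family); it cancels in every ratio |
| phi1, phi2 | fluorescence quantum yields | 1, 1 | only their ratio matters; it is absorbed by calibration in practice |
| mu_a_ps | PS absorption amplitudes | 0.1 / 0.02 mm⁻¹ (405/660) | chlorin e6 at ~1 µg/g in vivo |
| M0 | integrated exponential-profile amplitudes | 0.02 / 0.004 mm | same total amount redistributed in depth (surface value M0/d_1e) |

Units are 1/mm for coefficients, mm for depths, nm for wavelengths
throughout.

## Inverse estimators

The buried-layer and exponential inverses are closed forms
(d_b = ln(R/Rinf)/(mu_ex1−mu_ex2); d_1e = (R−R0)/(R0(mu_ex1+mu_em) −
R(mu_ex2+mu_em))); the uniform-layer inverse is a bracketed Brent search on
the strictly monotone forward ratio, bracketed on [0, 10·3/(mu_ex2+mu_em)]
because the ratio saturates beyond z* = 3/(mu_ex2+mu_em) and deeper layers
are indistinguishable. Out-of-range ratios raise an error naming the
admissible interval; for Monte Carlo or measurement noise just below R0 the
exponential inverse can clamp to R0 with a warning instead. The
photobleaching shift between two measurements is
Δd_b = ln(R_after/R_before)/(mu_ex1−mu_ex2); negative values mean the PS
localization became shallower.

The sensitivity harness perturbs mu_a and mu_s (not the derived
coefficients) and recomputes everything downstream, matching how an
uncertainty in published tissue properties propagates in practice. With
both coefficients scaled by a common factor s, mu_diff scales by s while
k_ex and the attenuation ratios are invariant, so the buried-layer inversion
returns exactly d_b/s: ×1.3 gives a 23% underestimate and ×0.7 a 43%
overestimate before any Monte Carlo effects are added.

## Monte Carlo verification

The dual-step simulator follows the standard weighted-photon scheme for
layered tissue: Henyey–Greenstein scattering, implicit capture, Russian
roulette (threshold 1e−4 of the launch weight, survival 0.1), Fresnel
treatment of the index-mismatched top boundary, with depth-dependent
absorption handled by Woodcock delta tracking (exact for arbitrary
mu_t(z), so discretized exponential PS profiles cost nothing extra). The
PS-absorbed fraction mu_a_ps/(mu_a_ps + mu_a) of the absorbed excitation
dose forms an isotropic distributed source for a second transport pass at
the emission wavelength; the response F is the total weight escaping the top
boundary per launched excitation photon. One seed determines both passes
bit-reproducibly.

Choices where the method description is genuinely open:

* **Lateral boundary: absorbing by default, periodic as an option.** The
  default simulates a finite 30×30 mm medium with open edges: photons
  crossing a lateral face are terminated as lost. This discards a measurable
  fraction of the deep-diffusing weight (5.8% red-excited, 1.4% blue on the
  dermis preset) and depresses the buried-layer ratio by several percent at
  sub-millimetre covers — but it is the geometry under which the model
  family's published verification bounds hold, and the saturation-thickness
  comparisons reproduce them (≤3%). `lateral_boundary="periodic"` instead
  wraps photons across the faces, which represents laterally infinite
  wide-field irradiation exactly (translation invariance); it restores the
  deep red dose and shifts saturation-scale ratios up by ~3–4%, trading the
  finite-box artifact for a larger visible near-field discrepancy of the
  diffusion model itself. Both are physically meaningful; the choice should
  follow the experiment being emulated.
* **Emission source placement.** Absorbed dose is tallied per 10 µm depth
  voxel together with its depth-weighted first moment; re-emission photons
  launch from the dose-weighted mean depth of each voxel. Launching from
  voxel centers instead leaves a first-order discretization bias (measured
  ≈ −2% in R at d_1e = 0.1 mm, halving/doubling the voxel size confirms the
  scaling) that would otherwise have to be bought back with finer grids.
* **Fresnel splitting.** At each internal boundary hit the transmitted
  fraction of the weight escapes and the reflected fraction continues —
  unbiased and lower-variance than sampling reflect/transmit. The specular
  reflection of the entering beam, ((n−1)/(n+1))², is deducted at launch;
  it is common to both wavelengths and cancels in R.
* **Detection.** F counts all escaping weight regardless of exit angle,
  while the analytic F is a normal flux; the angular factors are common to
  both excitation wavelengths and cancel in the ratio to the level probed
  here.
* **Stratified emission.** Per batch, k photons launch from every source
  voxel with weight dose/k (k set by the emission photon budget), rather
  than sampling voxels proportionally — lower variance, same expectation.

Validation inside the test suite: Beer–Lambert absorption profiles in the
scattering-free limit; exact weight conservation with roulette disabled
(closure to <1e−3); an end-to-end closed-form check of the full dual-step
chain in a purely absorbing index-matched medium (dose Beer–Lambert, escape
probability E2(mu_em z)/2); batch standard errors scaling as n^(−1/2); and
bit-identical reruns under a fixed seed.

## Known model discrepancy in the buried-layer geometry

With exact optical properties, inverting Monte Carlo ratios of buried
uniform layers returns depths a few hundredths of a millimetre shallow —
an offset of roughly −0.02 to −0.03 mm, i.e. ≈ −17% at d_b = 0.15 mm
shrinking to ≈ −5% at 0.45 mm on the dermis preset with the default
absorbing lateral boundary (about half that with the periodic boundary).
Two effects combine: the finite-box lateral loss preferentially removes
deep-diffusing red-excited photons, and the diffusion-model exponentials
carry a near-field error over the first transport mean free path (0.34 mm
at 660 nm) where the true fluence and escape functions decay more slowly
than e^(−mu_diff z). The buried-layer ratio — exponentially sensitive to
the cover attenuation — inherits both. The effect is not a transport bug:
the simulator reproduces closed-form answers exactly in the absorbing
limit, matches asymptotic attenuation rates (including PS self-shielding)
to well under a percent, and agrees with the closed forms to ≤1.5% for
surface profiles. It propagates into the sensitivity biases: the
down-scaled-properties overestimation lands near +30% rather than the
+43% pure parameter propagation would give, while the up-scaled
underestimation moves from 23% to ≈30%.

## Ratiometric image pipeline

ROI responses are dark-subtracted means (negative pixels clipped at zero —
deterministic and documented; unbiasedness near zero signal is impossible
either way), the same pixel set is applied to both channels, and
R = (S_red/I_red)/(S_blue/I_blue). Calibration divides by the ratio
R_ref of a reference object (a thin PS layer on an absorbing substrate),
which carries the source/quantum-yield/absorption-amplitude factors but no
depth dependence; the proportionality constant is fixed to 1, since any
fixed constant cancels in all depth changes and relative comparisons. Depth
reports invert the exponential profile for topical administration and the
buried layer for intravenous injection, flagging out-of-range ratios rather
than failing. When the PS amplitudes are unknown, the thin-layer limit R0
can optionally be replaced by the back-reflectance estimate k_ex2/k_ex1.

## Synthetic fixtures

The image generator emulates the imaging setup: mean counts are
F × I_ex × counts_scale + dark (defaults: counts_scale 2e4, dark 100,
intensities 1.4/2.2 mW/cm², 16-bit range), with Poisson shot noise and
Gaussian read noise (sd 2). It does **not** emulate illumination
non-uniformity, autofluorescence, spectral bleed-through, or pixel-to-pixel
gain variation, so pipeline tests demonstrate correctness of the ratio
arithmetic and noise handling, not robustness to those real-world artifacts.
The `phantom_like` optical preset is qualitative (strong blue, weak red
absorption, as in agarose/lipofundin/ink phantoms); quantitative tests use
the dermis preset. Quantitative phantom layer properties are not published
in tabular form, hence the qualitative stand-in.

## Problem sizes and numerics

The verification scripts use 4–6 × 10⁵ excitation and 2–4 × 10⁵ emission
photons per wavelength with a roulette threshold of 1e−3 — sizes chosen so
each quantity's Monte Carlo standard error sits well below the effect being
measured (stderr of R ≈ 0.5–0.8%; the batch estimate was validated against
the empirical seed-to-seed spread). Depth voxels are 10 µm, the grid
extends to 20 mm, and exponential profiles are discretized with exact slab
averages (preserving the integrated amount to <0.5%) down to 16 decay
depths. Closed-form ratios evaluate limits analytically at d = 0 and d = ∞;
the quadrature route truncates the kernel at 1e−12 of its surface value.

## Limitations

* The analytic model is 1-D in depth: no lateral heterogeneity, no finite
  beam effects, no curved anatomy.
* No polarization, time resolution, or wavelength interpolation of optical
  properties; exactly three working wavelengths.
* The inverse estimators assume the profile family is known (from the
  administration route); they do not select among profiles.
* In vivo depth values depend on the optical-property preset chosen; the
  sensitivity harness quantifies, but does not remove, that dependence.
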