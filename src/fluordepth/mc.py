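"""Dual-step fluorescence Monte Carlo for layered semi-infinite turbid media.

The simulator provides an independent numerical check of the
diffusion-approximation forward model.  It follows the classical weighted
photon-transport scheme for layered tissue:

* **Step 1 (excitation).**  A plane wave enters the medium at normal
  incidence (specular reflection deducted), photons random-walk with
  exponential free paths, Henyey--Greenstein scattering and implicit capture,
  and the absorbed weight is tallied on a 1-D depth grid (lateral dimensions
  marginalized).  Depth-varying absorption (layers, discretized exponential
  photosensitizer profiles) is handled by Woodcock delta tracking against the
  majorant interaction coefficient, which is exact for arbitrary mu_t(z).
* **Step 2 (emission).**  The photosensitizer-absorbed dose -- the absorption
  map times mu_a_ps / (mu_a_ps + mu_a_base) in PS-containing voxels -- becomes
  an isotropic distributed source.  Emission photons are launched per source
  voxel with weight equal to the voxel dose (stratified) and transported at
  the emission-wavelength properties; the fluorescence response F is the
  total weight escaping through the top boundary per launched excitation
  photon, regardless of exit angle.

The refractive-index mismatch at the top boundary is treated by
deterministic Fresnel splitting: at every boundary hit the transmitted part
of the weight escapes and the reflected part continues, which is unbiased
and lower-variance than probabilistic reflection.  Photons crossing the
lateral faces of the simulation box are terminated as lost (the default,
mimicking a finite 30x30 mm medium with open edges); a periodic lateral
boundary is available instead, which represents laterally infinite
plane-wave irradiation exactly (see the methods note for the trade-off).
Photons crossing the bottom of the grid are terminated and tallied, and
Russian roulette (threshold relative to the launch weight) bounds the path
length.

The ratio R = F(red) / F(blue) from paired runs is the quantity compared
against the closed-form model; common factors (specular loss, emission
escape physics) cancel in the ratio.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .optics import OpticalProperties, SpectralTriple
from .profiles import DepthProfile

__all__ = [
    "MCConfig",
    "Layer",
    "MediumStack",
    "AbsorptionMap",
    "MCResult",
    "build_stack",
    "excitation_absorption_map",
    "fluorescence_response",
    "mc_ratio",
    "fresnel_reflectance",
]


@dataclass(frozen=True)
class MCConfig:
    """Photon counts, grid and variance-reduction settings.

    ``n_photons`` is the number of excitation photons per wavelength (split
    into ``n_batches`` batches for the standard-error estimate).
    ``n_emission`` is the total number of emission photons per wavelength
    (default ``n_photons // 10``), distributed evenly over the source voxels
    of each batch.  ``seed`` fully determines both transport steps.
    """

    n_photons: int = 10_000_000
    seed: int = 0
    voxel_dz: float = 0.01
    lateral_size: float = 30.0
    max_depth: float = 20.0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    n_batches: int = 10
    n_emission: int | None = None
    ambient_n: float = 1.0
    lateral_boundary: str = "absorbing"

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if self.voxel_dz <= 0:
            raise ValueError("voxel_dz must be > 0")
        if not (0 < self.roulette_survival < 1):
            raise ValueError("roulette_survival must lie in (0, 1)")
        if self.roulette_threshold < 0:
            raise ValueError("roulette_threshold must be >= 0")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.lateral_boundary not in ("absorbing", "periodic"):
            raise ValueError("lateral_boundary must be 'absorbing' or 'periodic'")

    @property
    def emission_photons(self) -> int:
        return self.n_emission if self.n_emission is not None else max(self.n_photons // 10, 1000)


@dataclass(frozen=True)
class Layer:
    """One homogeneous slab: thickness (mm, inf allowed for the bottom layer),
    base optical properties per wavelength, and the photosensitizer absorption
    coefficient per excitation wavelength (uniform within the slab)."""

    thickness: float
    props: Mapping[float, OpticalProperties]
    mu_a_ps: Mapping[float, float]

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError("layer thickness must be > 0")
        object.__setattr__(self, "props", dict(self.props))
        object.__setattr__(self, "mu_a_ps", dict(self.mu_a_ps))


@dataclass(frozen=True)
class MediumStack:
    """Ordered layers from the surface down; the last layer may be
    semi-infinite (capped at the grid depth).  ``excitation_wavelengths``
    names the wavelengths at which mu_a_ps entries are defined."""

    layers: Sequence[Layer]
    lambda_em: float
    excitation_wavelengths: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))
        for lay in self.layers[:-1]:
            if lay.thickness == math.inf:
                raise ValueError("only the bottom layer may be semi-infinite")

    @property
    def surface_n(self) -> float:
        first = self.layers[0]
        return next(iter(first.props.values())).n


@dataclass
class AbsorptionMap:
    """Depth-resolved absorbed excitation weight per launched photon."""

    z: np.ndarray  # voxel centers, mm
    absorbed: np.ndarray  # total absorbed weight per voxel per launched photon
    ps_dose: np.ndarray  # photosensitizer-absorbed fraction of the above
    specular: float
    escaped: float
    transmitted: float
    lost_lateral: float

    @property
    def total_accounted(self) -> float:
        return (
            self.specular
            + self.escaped
            + self.transmitted
            + self.lost_lateral
            + float(self.absorbed.sum())
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"z": self.z, "absorbed": self.absorbed, "ps_dose": self.ps_dose})


@dataclass
class MCResult:
    """Fluorescence responses, their ratio and Monte Carlo diagnostics."""

    F: dict[float, float]
    R_lambda: float
    stderr_R: float
    F_batches: dict[float, np.ndarray]
    absorption_maps: dict[float, AbsorptionMap]
    n_photons: int
    seed: int

    def to_json(self, path=None):
        payload = {
            "F": {str(k): v for k, v in self.F.items()},
            "R_lambda": self.R_lambda,
            "stderr_R": self.stderr_R,
            "n_photons": self.n_photons,
            "seed": self.seed,
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def fresnel_reflectance(cos_i: float, n_in: float, n_out: float) -> float:
    """Unpolarized Fresnel reflectance for light hitting the boundary from inside."""
    return float(_fresnel(cos_i, n_in / n_out))


# ---------------------------------------------------------------------------
# Transport kernel (Woodcock delta tracking, implicit capture, HG scattering)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _fresnel(cos_i, n_rel):
    if n_rel == 1.0:
        return 0.0
    if cos_i > 0.999999:
        r = (n_rel - 1.0) / (n_rel + 1.0)
        return r * r
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_rel * sin_i
    if sin_t >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _transport(
    seed,
    z0,
    w0,
    isotropic,
    mu_t_v,
    mu_a_v,
    g_v,
    dz,
    max_depth,
    half_lat,
    n_rel,
    periodic,
    roulette_threshold,
    roulette_survival,
    deposit,
    deposit_z,
):
    """Trace photons through a depth-voxelized medium.

    Returns (escaped, transmitted, lost_lateral); absorbed weight accumulates
    into ``deposit`` and its depth-weighted first moment into ``deposit_z``
    (used to place re-emission sources at the dose-weighted mean depth of
    each voxel).  Photons launched at depth z0[i] with weight w0[i];
    direction is straight down unless ``isotropic``.
    """
    np.random.seed(seed)
    n_vox = mu_t_v.size
    mu_maj = mu_t_v.max()
    escaped = 0.0
    transmitted = 0.0
    lost = 0.0
    floor = roulette_threshold if roulette_threshold > 0.0 else 1e-12
    for i in range(z0.size):
        z = z0[i]
        w = w0[i]
        w_launch = w
        if w <= 0.0:
            continue
        if isotropic:
            x = 0.0
            y = 0.0
            uz = 2.0 * np.random.random() - 1.0
            phi = 2.0 * math.pi * np.random.random()
            sint = math.sqrt(max(0.0, 1.0 - uz * uz))
            ux = sint * math.cos(phi)
            uy = sint * math.sin(phi)
        else:
            x = (np.random.random() - 0.5) * 2.0 * half_lat
            y = (np.random.random() - 0.5) * 2.0 * half_lat
            ux = 0.0
            uy = 0.0
            uz = 1.0
        alive = True
        while alive:
            s = -math.log(np.random.random()) / mu_maj
            if uz < 0.0 and z + uz * s < 0.0:
                # reach the top boundary: Fresnel split, reflect, resample
                t = -z / uz
                x += ux * t
                y += uy * t
                z = 0.0
                if abs(x) > half_lat or abs(y) > half_lat:
                    if periodic:
                        x = (x + half_lat) % (2.0 * half_lat) - half_lat
                        y = (y + half_lat) % (2.0 * half_lat) - half_lat
                    else:
                        lost += w
                        break
                rf = _fresnel(-uz, n_rel)
                escaped += w * (1.0 - rf)
                w *= rf
                uz = -uz
            else:
                x += ux * s
                y += uy * s
                z += uz * s
                if z >= max_depth:
                    transmitted += w
                    break
                if abs(x) > half_lat or abs(y) > half_lat:
                    if periodic:
                        # plane-wave illumination of a laterally uniform medium
                        # is translation-invariant: weight leaving a face is
                        # exactly replaced by weight entering the opposite one
                        x = (x + half_lat) % (2.0 * half_lat) - half_lat
                        y = (y + half_lat) % (2.0 * half_lat) - half_lat
                    else:
                        lost += w
                        break
                v = int(z / dz)
                if v >= n_vox:
                    v = n_vox - 1
                mt = mu_t_v[v]
                if np.random.random() * mu_maj < mt:
                    # real collision: implicit capture + HG scatter
                    aw = w * mu_a_v[v] / mt
                    deposit[v] += aw
                    deposit_z[v] += aw * z
                    w -= aw
                    g = g_v[v]
                    if g == 0.0:
                        cost = 2.0 * np.random.random() - 1.0
                    else:
                        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                        cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                        if cost > 1.0:
                            cost = 1.0
                        elif cost < -1.0:
                            cost = -1.0
                    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
                    phi = 2.0 * math.pi * np.random.random()
                    cosp = math.cos(phi)
                    sinp = math.sin(phi)
                    if abs(uz) > 0.99999:
                        ux = sint * cosp
                        uy = sint * sinp
                        uz = cost if uz > 0.0 else -cost
                    else:
                        den = math.sqrt(1.0 - uz * uz)
                        uxn = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                        uyn = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                        uzn = -den * sint * cosp + uz * cost
                        norm = math.sqrt(uxn * uxn + uyn * uyn + uzn * uzn)
                        ux = uxn / norm
                        uy = uyn / norm
                        uz = uzn / norm
                # null collision: direction and weight unchanged
            if alive and w < floor * w_launch:
                if roulette_threshold > 0.0:
                    if np.random.random() < roulette_survival:
                        w /= roulette_survival
                    else:
                        break
                else:
                    # roulette disabled: deposit the residual weight locally so
                    # the weight budget stays closed
                    v = int(z / dz)
                    if v >= n_vox:
                        v = n_vox - 1
                    if v < 0:
                        v = 0
                    deposit[v] += w
                    deposit_z[v] += w * z
                    break
    return escaped, transmitted, lost


# ---------------------------------------------------------------------------
# Stack construction and grid compilation
# ---------------------------------------------------------------------------


def build_stack(profile: DepthProfile, base: SpectralTriple, cfg: MCConfig) -> MediumStack:
    """Discretize a canonical depth profile over the base medium into layers.

    Uniform profiles become two-layer stacks; exponential profiles are
    discretized into voxel-thick slabs whose mu_a_ps is the exact slab average
    (which preserves the depth-integrated amount).
    """
    ex = (base.lambda_blue, base.lambda_red)
    props = {lam: base.at(lam) for lam in (*ex, base.lambda_em)}
    zero = {lam: 0.0 for lam in ex}

    def uniform_amp():
        return {lam: profile.amplitude[lam] for lam in ex}

    layers: list[Layer] = []
    if profile.kind == "top_uniform":
        d = min(profile.d, cfg.max_depth)
        if d > 0:
            layers.append(Layer(d, props, uniform_amp()))
        if d < cfg.max_depth:
            layers.append(Layer(math.inf, props, zero))
    elif profile.kind == "bottom_uniform":
        if profile.d_b > 0:
            layers.append(Layer(min(profile.d_b, cfg.max_depth), props, zero))
        if profile.d_b < cfg.max_depth:
            layers.append(Layer(math.inf, props, uniform_amp()))
    elif profile.kind in ("exponential", "shifted_exponential"):
        if profile.d_1e < cfg.voxel_dz:
            raise ValueError(
                f"d_1e = {profile.d_1e} mm is below the voxel resolution {cfg.voxel_dz} mm"
            )
        if profile.d_b > 0:
            layers.append(Layer(profile.d_b, props, zero))
        z_cut = min(cfg.max_depth, profile.d_b + 16.0 * profile.d_1e)
        edges = np.arange(profile.d_b, z_cut + cfg.voxel_dz * 0.5, cfg.voxel_dz)
        d1e = profile.d_1e
        for z0, z1 in zip(edges[:-1], edges[1:]):
            # exact slab average of the exponential
            frac = d1e / (z1 - z0) * (
                math.exp(-(z0 - profile.d_b) / d1e) - math.exp(-(z1 - profile.d_b) / d1e)
            )
            amp = {lam: profile.surface_amplitude(lam) * frac for lam in ex}
            layers.append(Layer(z1 - z0, props, amp))
        if edges[-1] < cfg.max_depth:
            layers.append(Layer(math.inf, props, zero))
    else:  # pragma: no cover
        raise ValueError(f"unknown profile kind {profile.kind!r}")
    return MediumStack(layers=layers, lambda_em=base.lambda_em, excitation_wavelengths=ex)


def _compile_grid(stack: MediumStack, lam: float, cfg: MCConfig, excitation: bool):
    """Per-voxel (mu_t, mu_a_total, g, mu_a_ps) arrays over [0, max_depth]."""
    n_vox = int(round(cfg.max_depth / cfg.voxel_dz))
    z_edges = np.arange(n_vox + 1) * cfg.voxel_dz
    z_cent = 0.5 * (z_edges[:-1] + z_edges[1:])
    mu_a = np.empty(n_vox)
    mu_s = np.empty(n_vox)
    g = np.empty(n_vox)
    mu_ps = np.zeros(n_vox)
    top = 0.0
    idx0 = 0
    for lay in stack.layers:
        bottom = cfg.max_depth if lay.thickness == math.inf else top + lay.thickness
        idx1 = min(n_vox, int(round(bottom / cfg.voxel_dz)))
        p = lay.props[lam]
        mu_a[idx0:idx1] = p.mu_a
        mu_s[idx0:idx1] = p.mu_s
        g[idx0:idx1] = p.g
        if excitation:
            mu_ps[idx0:idx1] = lay.mu_a_ps.get(lam, 0.0)
        top = bottom
        idx0 = idx1
        if idx0 >= n_vox:
            break
    if idx0 < n_vox:  # pad with the last layer
        mu_a[idx0:] = p.mu_a
        mu_s[idx0:] = p.mu_s
        g[idx0:] = p.g
        if excitation:
            mu_ps[idx0:] = lay.mu_a_ps.get(lam, 0.0)
    mu_a_tot = mu_a + mu_ps
    mu_t = mu_a_tot + mu_s
    return z_cent, mu_t, mu_a_tot, g, mu_ps


def _kernel_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def excitation_absorption_map(
    stack: MediumStack, lambda_ex: float, cfg: MCConfig, seed: int | None = None
) -> AbsorptionMap:
    """Depth-resolved absorbed excitation weight per launched photon (step 1)."""
    z, mu_t, mu_a_tot, g, mu_ps = _compile_grid(stack, lambda_ex, cfg, excitation=True)
    n_med = stack.surface_n
    r_spec = ((n_med - cfg.ambient_n) / (n_med + cfg.ambient_n)) ** 2
    n = cfg.n_photons
    deposit = np.zeros_like(mu_t)
    deposit_z = np.zeros_like(mu_t)
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    esc, trans, lost = _transport(
        _kernel_seed(ss),
        np.zeros(n),
        np.full(n, 1.0 - r_spec),
        False,
        mu_t,
        mu_a_tot,
        g,
        cfg.voxel_dz,
        cfg.max_depth,
        cfg.lateral_size / 2.0,
        n_med / cfg.ambient_n,
        cfg.lateral_boundary == "periodic",
        cfg.roulette_threshold,
        cfg.roulette_survival,
        deposit,
        deposit_z,
    )
    absorbed = deposit / n
    with np.errstate(invalid="ignore"):
        ps_frac = np.where(mu_a_tot > 0, mu_ps / mu_a_tot, 0.0)
    return AbsorptionMap(
        z=z,
        absorbed=absorbed,
        ps_dose=absorbed * ps_frac,
        specular=r_spec,
        escaped=esc / n,
        transmitted=trans / n,
        lost_lateral=lost / n,
    )


def _emission_run(
    stack: MediumStack,
    cfg: MCConfig,
    dose: np.ndarray,
    z_src: np.ndarray,
    k_per_voxel: int,
    seed: int,
) -> float:
    """Step 2: launch k photons per source voxel, weight = voxel dose / k.

    Sources sit at the dose-weighted mean depth of each voxel, which removes
    the first-order voxelization bias of the re-emission position.
    """
    _, mu_t, mu_a_tot, g, _ = _compile_grid(stack, stack.lambda_em, cfg, excitation=False)
    src = np.nonzero(dose > 0)[0]
    if src.size == 0:
        return 0.0
    n_med = stack.surface_n
    z0 = np.repeat(z_src[src], k_per_voxel)
    w0 = np.repeat(dose[src] / k_per_voxel, k_per_voxel)
    sink = np.zeros_like(mu_t)
    sink_z = np.zeros_like(mu_t)
    esc, _, _ = _transport(
        seed,
        z0,
        w0,
        True,
        mu_t,
        mu_a_tot,
        g,
        cfg.voxel_dz,
        cfg.max_depth,
        cfg.lateral_size / 2.0,
        n_med / cfg.ambient_n,
        cfg.lateral_boundary == "periodic",
        cfg.roulette_threshold,
        cfg.roulette_survival,
        sink,
        sink_z,
    )
    return float(esc)


def fluorescence_response(
    stack: MediumStack,
    lambda_ex: float,
    cfg: MCConfig,
    seed_sequence: np.random.SeedSequence | None = None,
) -> tuple[float, np.ndarray, AbsorptionMap]:
    """Dual-step fluorescence response F at one excitation wavelength.

    Returns ``(F, per-batch F values, absorption map)``; F is the escaped
    fluorescence weight per launched excitation photon.
    """
    ss = seed_sequence or np.random.SeedSequence(cfg.seed)
    n_b = cfg.n_batches
    n_per = max(cfg.n_photons // n_b, 1)
    z, mu_t, mu_a_tot, g, mu_ps = _compile_grid(stack, lambda_ex, cfg, excitation=True)
    if not np.any(mu_ps > 0):
        warnings.warn("stack carries no photosensitizer at this wavelength; F = 0", stacklevel=2)
    n_med = stack.surface_n
    r_spec = ((n_med - cfg.ambient_n) / (n_med + cfg.ambient_n)) ** 2
    with np.errstate(invalid="ignore"):
        ps_frac = np.where(mu_a_tot > 0, mu_ps / mu_a_tot, 0.0)

    children = ss.spawn(2 * n_b)
    F_batches = np.zeros(n_b)
    total_deposit = np.zeros_like(mu_t)
    agg = {"escaped": 0.0, "transmitted": 0.0, "lost": 0.0}
    for b in range(n_b):
        deposit = np.zeros_like(mu_t)
        deposit_z = np.zeros_like(mu_t)
        esc, trans, lost = _transport(
            _kernel_seed(children[2 * b]),
            np.zeros(n_per),
            np.full(n_per, 1.0 - r_spec),
            False,
            mu_t,
            mu_a_tot,
            g,
            cfg.voxel_dz,
            cfg.max_depth,
            cfg.lateral_size / 2.0,
            n_med / cfg.ambient_n,
            cfg.lateral_boundary == "periodic",
            cfg.roulette_threshold,
            cfg.roulette_survival,
            deposit,
            deposit_z,
        )
        agg["escaped"] += esc
        agg["transmitted"] += trans
        agg["lost"] += lost
        total_deposit += deposit
        dose = deposit / n_per * ps_frac
        n_src = int(np.count_nonzero(dose > 0))
        if n_src == 0:
            continue
        with np.errstate(invalid="ignore"):
            z_src = np.where(deposit > 0, deposit_z / np.where(deposit > 0, deposit, 1.0), z)
        k = max(1, int(round(cfg.emission_photons / (n_b * n_src))))
        F_batches[b] = _emission_run(
            stack, cfg, dose, z_src, k, _kernel_seed(children[2 * b + 1])
        )
    n_tot = n_per * n_b
    absorbed = total_deposit / n_tot
    amap = AbsorptionMap(
        z=z,
        absorbed=absorbed,
        ps_dose=absorbed * ps_frac,
        specular=r_spec,
        escaped=agg["escaped"] / n_tot,
        transmitted=agg["transmitted"] / n_tot,
        lost_lateral=agg["lost"] / n_tot,
    )
    return float(F_batches.mean()), F_batches, amap


def mc_ratio(stack: MediumStack, cfg: MCConfig) -> MCResult:
    """Fluorescence ratio R = F(red)/F(blue) with a batch standard error."""
    ss = np.random.SeedSequence(cfg.seed)
    blue_ss, red_ss = ss.spawn(2)
    lam_b, lam_r = stack.excitation_wavelengths
    F_b, batches_b, map_b = fluorescence_response(stack, lam_b, cfg, blue_ss)
    F_r, batches_r, map_r = fluorescence_response(stack, lam_r, cfg, red_ss)
    if F_b == 0:
        raise ZeroDivisionError("blue-excited fluorescence response is zero; ratio undefined")
    R = F_r / F_b
    with np.errstate(divide="ignore", invalid="ignore"):
        Rb = np.where(batches_b > 0, batches_r / batches_b, np.nan)
    good = np.isfinite(Rb)
    stderr = float(np.std(Rb[good], ddof=1) / math.sqrt(good.sum())) if good.sum() > 1 else math.nan
    return MCResult(
        F={lam_b: F_b, lam_r: F_r},
        R_lambda=float(R),
        stderr_R=stderr,
        F_batches={lam_b: batches_b, lam_r: batches_r},
        absorption_maps={lam_b: map_b, lam_r: map_r},
        n_photons=cfg.n_photons,
        seed=cfg.seed,
    )
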