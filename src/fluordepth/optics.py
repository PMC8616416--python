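"""Wavelength-resolved optical properties of turbid tissue and derived transport coefficients.

The analytic fluorescence model works with four primary optical properties per
wavelength -- absorption coefficient ``mu_a``, scattering coefficient ``mu_s``,
scattering anisotropy ``g`` and refractive index ``n`` -- and a handful of
derived quantities used throughout:

* reduced scattering ``mu_s' = mu_s (1 - g)``,
* transport coefficient ``mu_t' = mu_a + mu_s'``,
* diffusion attenuation coefficient ``mu_diff = sqrt(3 mu_a mu_t')``,
* the semi-empirical backscattering enhancement factor ``k_ex`` of the
  Jacques model for a unidirectional beam entering a diffusive half-space,
* the dimensionless emission escape parameter
  ``q_em = 2 mu_diff(lambda_em) m / (3 mu_t'(lambda_em))``, where ``m``
  accounts for total internal reflection of diffuse fluorescence light at the
  tissue--air boundary (``m ~ 2.76`` for tissue refractive index 1.37).

Units: all coefficients are in 1/mm, depths in mm, wavelengths in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import yaml

__all__ = [
    "OpticalProperties",
    "DerivedCoefficients",
    "SpectralTriple",
    "M_DEFAULT",
    "reduced_scattering",
    "diffusion_attenuation",
    "backscatter_factor",
    "q_em_factor",
    "derived_coefficients",
    "preset_triple",
    "preset_amplitudes",
    "load_triple",
    "dump_triple",
    "PRESETS",
]

#: Total-internal-reflectance factor for diffuse light at a tissue--air
#: boundary with tissue refractive index n = 1.37.  Treated as a settable
#: configuration constant rather than computed from n.
M_DEFAULT = 2.76


class DiffusionModelError(ValueError):
    """The diffusion approximation is not applicable to the given medium."""


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of a homogeneous medium at one wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, 1/mm.  Must be >= 0.
    mu_s : float
        Scattering coefficient, 1/mm.  Must be >= 0.
    g : float
        Scattering anisotropy factor (mean cosine), 0 <= g < 1.
    n : float
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s: float
    g: float = 0.8
    n: float = 1.37

    def __post_init__(self) -> None:
        if not (self.mu_a >= 0):
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if not (self.mu_s >= 0):
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not (0 <= self.g < 1):
            raise ValueError(f"g must lie in [0, 1), got {self.g}")
        if not (self.n >= 1):
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s (1 - g), 1/mm."""
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_t_prime(self) -> float:
        """Transport coefficient mu_a + mu_s', 1/mm."""
        return self.mu_a + self.mu_s_prime

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, 1/mm (Monte Carlo step scale)."""
        return self.mu_a + self.mu_s

    def scaled(self, mu_a_scale: float = 1.0, mu_s_scale: float = 1.0) -> "OpticalProperties":
        """Return a copy with mu_a and mu_s multiplied by the given factors."""
        return replace(self, mu_a=self.mu_a * mu_a_scale, mu_s=self.mu_s * mu_s_scale)


def reduced_scattering(p: OpticalProperties) -> float:
    """Reduced scattering coefficient mu_s' = mu_s (1 - g), 1/mm."""
    return p.mu_s_prime


def diffusion_attenuation(p: OpticalProperties) -> float:
    """Diffusion attenuation coefficient sqrt(3 mu_a mu_t'), 1/mm.

    Raises
    ------
    DiffusionModelError
        If ``mu_a == 0`` -- diffuse light then does not decay and the
        diffusion attenuation coefficient is not defined.
    """
    if p.mu_a <= 0:
        raise DiffusionModelError(
            "diffusion attenuation requires mu_a > 0; the diffusion "
            "approximation is invalid for a non-absorbing medium"
        )
    return math.sqrt(3.0 * p.mu_a * p.mu_t_prime)


def backscatter_factor(p: OpticalProperties) -> float:
    """Backscattering enhancement factor k_ex of the Jacques beam model.

    ``k_ex = 3 + 5.4 p' - 2 exp(-17 p')`` with
    ``p' = exp(-(8/3) mu_diff / mu_t')``.  In the diffusive regime
    (``mu_s' >> mu_a``) ``p'`` approaches 1 and k_ex >= 3; the factor
    accounts for the subsurface fluence enhancement by diffusely
    backscattered excitation light.
    """
    mu_diff = diffusion_attenuation(p)
    pp = math.exp(-(8.0 / 3.0) * mu_diff / p.mu_t_prime)
    return 3.0 + 5.4 * pp - 2.0 * math.exp(-17.0 * pp)


def q_em_factor(p_em: OpticalProperties, m: float = M_DEFAULT) -> float:
    """Dimensionless emission parameter q_em = 2 mu_diff m / (3 mu_t').

    Evaluated at the emission wavelength; ``m`` is the total-internal-
    reflectance factor of diffuse light at the boundary.
    """
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    if m == 0:
        return 0.0
    return 2.0 * diffusion_attenuation(p_em) * m / (3.0 * p_em.mu_t_prime)


@dataclass(frozen=True)
class DerivedCoefficients:
    """Every derived coefficient the analytic model consumes, at one wavelength."""

    mu_s_prime: float
    mu_t_prime: float
    mu_diff: float
    k_ex: float
    q_em: float
    m: float

    @classmethod
    def from_properties(cls, p: OpticalProperties, m: float = M_DEFAULT) -> "DerivedCoefficients":
        return cls(
            mu_s_prime=p.mu_s_prime,
            mu_t_prime=p.mu_t_prime,
            mu_diff=diffusion_attenuation(p),
            k_ex=backscatter_factor(p),
            q_em=q_em_factor(p, m),
            m=m,
        )


def derived_coefficients(p: OpticalProperties, m: float = M_DEFAULT) -> DerivedCoefficients:
    """Bundle mu_s', mu_t', mu_diff, k_ex and q_em for one wavelength."""
    return DerivedCoefficients.from_properties(p, m)


@dataclass(frozen=True)
class SpectralTriple:
    """Base-medium optical properties at the three working wavelengths.

    The dual-wavelength scheme excites chlorin-type photosensitizers at the
    Soret band (blue, default 405 nm) and the Q band (red, default 660 nm)
    and detects emission in a band around 760 nm.

    Parameters
    ----------
    props : mapping wavelength (nm) -> OpticalProperties
        Must contain entries for all three wavelengths.
    lambda_blue, lambda_red, lambda_em : float
        Working wavelengths in nm; ``lambda_red > lambda_blue``.
    m : float
        Total-internal-reflectance factor for the emission escape term.
    """

    props: Mapping[float, OpticalProperties]
    lambda_blue: float = 405.0
    lambda_red: float = 660.0
    lambda_em: float = 760.0
    m: float = M_DEFAULT

    def __post_init__(self) -> None:
        if not self.lambda_red > self.lambda_blue:
            raise ValueError("lambda_red must exceed lambda_blue")
        for lam in (self.lambda_blue, self.lambda_red, self.lambda_em):
            if lam not in self.props:
                raise ValueError(f"optical properties missing for {lam} nm")
        object.__setattr__(self, "props", dict(self.props))

    @property
    def blue(self) -> OpticalProperties:
        return self.props[self.lambda_blue]

    @property
    def red(self) -> OpticalProperties:
        return self.props[self.lambda_red]

    @property
    def emission(self) -> OpticalProperties:
        return self.props[self.lambda_em]

    def at(self, lam: float) -> OpticalProperties:
        return self.props[lam]

    # -- derived attenuation shorthands used by every ratio formula ------

    @property
    def mu_ex_blue(self) -> float:
        """Diffusion attenuation at the blue excitation wavelength, 1/mm."""
        return diffusion_attenuation(self.blue)

    @property
    def mu_ex_red(self) -> float:
        """Diffusion attenuation at the red excitation wavelength, 1/mm."""
        return diffusion_attenuation(self.red)

    @property
    def mu_em(self) -> float:
        """Diffusion attenuation at the emission wavelength, 1/mm."""
        return diffusion_attenuation(self.emission)

    @property
    def kappa_blue(self) -> float:
        """Round-trip attenuation mu_ex(blue) + mu_em, 1/mm."""
        return self.mu_ex_blue + self.mu_em

    @property
    def kappa_red(self) -> float:
        """Round-trip attenuation mu_ex(red) + mu_em, 1/mm."""
        return self.mu_ex_red + self.mu_em

    @property
    def delta_mu(self) -> float:
        """mu_ex(blue) - mu_ex(red), the log-slope of the buried-layer ratio, 1/mm."""
        return self.mu_ex_blue - self.mu_ex_red

    @property
    def k_ex_blue(self) -> float:
        return backscatter_factor(self.blue)

    @property
    def k_ex_red(self) -> float:
        return backscatter_factor(self.red)

    @property
    def q_em(self) -> float:
        return q_em_factor(self.emission, self.m)

    def kappa(self, lam: float) -> float:
        """Round-trip attenuation mu_ex(lam) + mu_em for an excitation wavelength."""
        return diffusion_attenuation(self.at(lam)) + self.mu_em

    def scaled(self, mu_a_scale: float = 1.0, mu_s_scale: float = 1.0) -> "SpectralTriple":
        """Scale mu_a and mu_s at every wavelength and recompute everything derived.

        This is the perturbation used in optical-property sensitivity studies:
        the primary coefficients are scaled, and all derived coefficients
        (mu_diff, k_ex, q_em) follow from the scaled values.
        """
        return replace(
            self,
            props={lam: p.scaled(mu_a_scale, mu_s_scale) for lam, p in self.props.items()},
        )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Human-dermis base tissue at 405/660/760 nm, with the photosensitizer
#: absorption amplitudes used alongside it (chlorin e6 at ~1 ug/g in vivo):
#: mu_a_ps for uniform profiles and M0 for total-amount-conserving
#: exponential profiles.
_DERMIS_TABLE1 = {
    "n": 1.37,
    "wavelengths": {
        405.0: {"mu_a": 0.96, "mu_s": 38.0, "g": 0.8},
        660.0: {"mu_a": 0.15, "mu_s": 14.0, "g": 0.8},
        760.0: {"mu_a": 0.13, "mu_s": 12.0, "g": 0.8},
    },
    "amplitudes": {405.0: 0.1, 660.0: 0.02},
    "m0": {405.0: 0.02, 660.0: 0.004},
}

#: Qualitative stand-in for agarose/lipofundin/ink phantoms: strong blue
#: absorption, weak red absorption.  Approximate -- the quantitative presets
#: are the dermis values above; use this only where the blue/red absorption
#: contrast, not the exact numbers, matters.
_PHANTOM_LIKE = {
    "n": 1.35,
    "wavelengths": {
        405.0: {"mu_a": 0.5, "mu_s": 25.0, "g": 0.7},
        660.0: {"mu_a": 0.05, "mu_s": 10.0, "g": 0.7},
        760.0: {"mu_a": 0.04, "mu_s": 9.0, "g": 0.7},
    },
    "amplitudes": {405.0: 0.08, 660.0: 0.016},
    "m0": {405.0: 0.016, 660.0: 0.0032},
}

PRESETS: dict[str, dict] = {
    "dermis_table1": _DERMIS_TABLE1,
    "phantom_like": _PHANTOM_LIKE,
}


def _triple_from_dict(cfg: dict) -> SpectralTriple:
    n = float(cfg.get("n", 1.37))
    m = float(cfg.get("m", M_DEFAULT))
    props = {
        float(lam): OpticalProperties(
            mu_a=float(rec["mu_a"]), mu_s=float(rec["mu_s"]), g=float(rec.get("g", 0.8)), n=n
        )
        for lam, rec in cfg["wavelengths"].items()
    }
    lams = sorted(props)
    if len(lams) != 3:
        raise ValueError(f"expected exactly three wavelengths, got {lams}")
    return SpectralTriple(props=props, lambda_blue=lams[0], lambda_red=lams[1], lambda_em=lams[2], m=m)


def preset_triple(name: str = "dermis_table1") -> SpectralTriple:
    """Return a named optical-property preset as a :class:`SpectralTriple`."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return _triple_from_dict(cfg)


def preset_amplitudes(name: str = "dermis_table1", conserve_total: bool = False) -> dict[float, float]:
    """Photosensitizer absorption amplitudes that ship with a preset.

    ``conserve_total=False`` returns the uniform-profile absorption
    coefficients mu_a_ps(lambda_i); ``conserve_total=True`` returns the
    integrated amplitudes M0(lambda_i) of a total-amount-conserving
    exponential profile (surface amplitude M0/d_1e).
    """
    cfg = PRESETS[name]
    key = "m0" if conserve_total else "amplitudes"
    return dict(cfg[key])


def load_triple(path) -> tuple[SpectralTriple, dict[float, float]]:
    """Load a spectral triple and PS amplitudes from a YAML config file.

    Expected layout::

        n: 1.37
        m: 2.76           # optional
        wavelengths:
          405: {mu_a: 0.96, mu_s: 38, g: 0.8}
          660: {mu_a: 0.15, mu_s: 14, g: 0.8}
          760: {mu_a: 0.13, mu_s: 12, g: 0.8}
        amplitudes: {405: 0.1, 660: 0.02}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    triple = _triple_from_dict(cfg)
    amps = {float(k): float(v) for k, v in cfg.get("amplitudes", {}).items()}
    return triple, amps


def dump_triple(triple: SpectralTriple, amplitudes: Mapping[float, float], path) -> None:
    """Write a spectral triple plus amplitudes to a YAML config file."""
    cfg = {
        "n": triple.blue.n,
        "m": triple.m,
        "wavelengths": {
            float(lam): {"mu_a": p.mu_a, "mu_s": p.mu_s, "g": p.g}
            for lam, p in triple.props.items()
        },
        "amplitudes": {float(k): float(v) for k, v in amplitudes.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
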