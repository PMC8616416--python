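"""In-depth photosensitizer distribution profiles.

Four canonical profiles cover the administration routes relevant to PDT
monitoring, with z = 0 at the tissue surface and z increasing downward:

* ``top_uniform``      -- constant concentration in a surface layer of
  thickness ``d`` (topical application, short accumulation);
* ``bottom_uniform``   -- constant concentration in the half-space below a
  PS-free cover of thickness ``d_b`` (intravenous injection, PS delivered by
  deep vessels);
* ``exponential``      -- concentration decaying as exp(-z / d_1e)
  (topical application with diffusive penetration);
* ``shifted_exponential`` -- the exponential profile pushed down below a
  PS-free cover of thickness ``d_b`` (surface photobleaching after PDT).

The amplitude carried by a profile is the photosensitizer absorption
coefficient mu_a_ps at each excitation wavelength (1/mm).  For exponential
profiles the flag ``conserve_total`` switches the meaning of the amplitude to
the depth-integrated amount M0 (the surface value is then M0 / d_1e), which
keeps the total amount of photosensitizer fixed while it redistributes in
depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["DepthProfile", "PROFILE_KINDS"]

PROFILE_KINDS = ("top_uniform", "bottom_uniform", "exponential", "shifted_exponential")


@dataclass(frozen=True)
class DepthProfile:
    """Tagged in-depth photosensitizer distribution.

    Use the constructors :meth:`top_uniform`, :meth:`bottom_uniform`,
    :meth:`exponential` and :meth:`shifted_exponential` rather than the bare
    dataclass.
    """

    kind: str
    amplitude: Mapping[float, float]
    d: float = 0.0
    d_b: float = 0.0
    d_1e: float = 0.0
    conserve_total: bool = False

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}; expected one of {PROFILE_KINDS}")
        for name in ("d", "d_b", "d_1e"):
            v = getattr(self, name)
            if not np.isfinite(v) and not (name == "d" and v == np.inf):
                raise ValueError(f"{name} must be finite (or d may be inf), got {v}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not self.amplitude:
            raise ValueError("amplitude map must not be empty")
        for lam, a in self.amplitude.items():
            if not (a > 0) or not np.isfinite(a):
                raise ValueError(f"amplitude at {lam} nm must be finite and > 0, got {a}")
        object.__setattr__(self, "amplitude", dict(self.amplitude))

    # -- constructors ----------------------------------------------------

    @classmethod
    def top_uniform(cls, d: float, amplitude: Mapping[float, float]) -> "DepthProfile":
        """Uniform PS layer of thickness ``d`` mm at the surface."""
        return cls(kind="top_uniform", amplitude=amplitude, d=d)

    @classmethod
    def bottom_uniform(cls, d_b: float, amplitude: Mapping[float, float]) -> "DepthProfile":
        """Uniform PS half-space below a PS-free cover of thickness ``d_b`` mm."""
        return cls(kind="bottom_uniform", amplitude=amplitude, d_b=d_b)

    @classmethod
    def exponential(
        cls, d_1e: float, amplitude: Mapping[float, float], conserve_total: bool = False
    ) -> "DepthProfile":
        """Exponentially decaying PS concentration with 1/e depth ``d_1e`` mm."""
        return cls(kind="exponential", amplitude=amplitude, d_1e=d_1e, conserve_total=conserve_total)

    @classmethod
    def shifted_exponential(
        cls,
        d_1e: float,
        d_b: float,
        amplitude: Mapping[float, float],
        conserve_total: bool = False,
    ) -> "DepthProfile":
        """Exponential profile (1/e depth ``d_1e``) below a PS-free cover ``d_b``."""
        return cls(
            kind="shifted_exponential",
            amplitude=amplitude,
            d_1e=d_1e,
            d_b=d_b,
            conserve_total=conserve_total,
        )

    # -- evaluation ------------------------------------------------------

    def surface_amplitude(self, lam: float) -> float:
        """Amplitude of mu_a_ps at the top of the PS-containing region, 1/mm."""
        a = self.amplitude[lam]
        if self.kind in ("exponential", "shifted_exponential") and self.conserve_total:
            if self.d_1e == 0:
                raise ZeroDivisionError("conserve_total surface amplitude undefined at d_1e = 0")
            return a / self.d_1e
        return a

    def mu_a_ps(self, z, lam: float):
        """Photosensitizer absorption coefficient at depth(s) ``z`` (mm), 1/mm."""
        z = np.asarray(z, dtype=float)
        if np.any(z < 0):
            raise ValueError("depths must be >= 0")
        if self.kind == "top_uniform":
            out = np.where(z < self.d, self.amplitude[lam], 0.0)
        elif self.kind == "bottom_uniform":
            out = np.where(z >= self.d_b, self.amplitude[lam], 0.0)
        else:
            a0 = self.surface_amplitude(lam)
            zz = z - self.d_b
            with np.errstate(over="ignore"):
                out = np.where(zz >= 0, a0 * np.exp(-np.maximum(zz, 0.0) / self.d_1e), 0.0)
        return out if out.ndim else float(out)

    @property
    def depth_parameter(self) -> float:
        """The scalar depth parameter of the profile (d, d_b or d_1e)."""
        if self.kind == "top_uniform":
            return self.d
        if self.kind == "bottom_uniform":
            return self.d_b
        return self.d_1e
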