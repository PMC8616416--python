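"""Synthetic inputs emulating the dual-wavelength imaging experiment.

The generators here produce every test input the package needs: noisy
dual-wavelength image pairs with a known ground-truth ratio (emulating a
wide-field imager with 405/660 nm LED excitation, a 760 nm detection band, a
dark level, shot noise and Gaussian read noise) and series of two-layer
phantom-like depth profiles.

Mean pixel counts are built directly from the analytic forward model:

    counts_i = F_i * I_ex_i * counts_scale + dark_level,

then Poisson shot noise and Gaussian read noise are added and the result is
quantized to the 16-bit detector range.  The ground-truth ratio stored with
each fixture is the exact analytic value, so pipeline tests can close the
loop measurement -> ratio -> depth against a known truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import analytic
from .optics import preset_triple, preset_amplitudes
from .profiles import DepthProfile

__all__ = ["FixtureSpec", "ImagePair", "make_image_pair", "phantom_series", "write_fixture", "read_fixture"]

_U16_MAX = np.iinfo(np.uint16).max


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic dual-wavelength image pair."""

    profile: DepthProfile
    preset: str = "dermis_table1"
    image_shape: tuple[int, int] = (64, 64)
    counts_scale: float = 20_000.0  # detector counts per unit flux per unit intensity
    dark_level: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    I_ex1: float = 1.4  # blue excitation intensity, mW/cm^2
    I_ex2: float = 2.2  # red excitation intensity, mW/cm^2
    phis: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.counts_scale > 0:
            raise ValueError("counts_scale must be > 0")
        if self.dark_level < 0:
            raise ValueError("dark_level must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass
class ImagePair:
    """Synthetic images plus the ground truth they were generated from."""

    img_blue: np.ndarray
    img_red: np.ndarray
    dark: np.ndarray
    truth: dict


def make_image_pair(spec: FixtureSpec) -> ImagePair:
    """Generate a noisy dual-wavelength image pair with known ground-truth R."""
    triple = preset_triple(spec.preset)
    res = analytic.profile_ratio(triple, spec.profile, spec.phis)
    rng = np.random.default_rng(spec.seed)

    def channel(F: float, I_ex: float) -> np.ndarray:
        mean = F * I_ex * spec.counts_scale + spec.dark_level
        img = np.full(spec.image_shape, mean, dtype=np.float64)
        if spec.shot_noise:
            img = rng.poisson(img).astype(np.float64)
        if spec.read_noise_sd > 0:
            img += rng.normal(0.0, spec.read_noise_sd, spec.image_shape)
        if mean > _U16_MAX:
            warnings.warn(
                f"mean count {mean:.0f} saturates the 16-bit detector range", stacklevel=3
            )
        return np.clip(np.round(img), 0, _U16_MAX).astype(np.uint16)

    img_blue = channel(res.F_blue, spec.I_ex1)
    img_red = channel(res.F_red, spec.I_ex2)
    dark = np.full(spec.image_shape, spec.dark_level, dtype=np.float64)
    if spec.read_noise_sd > 0:
        dark += rng.normal(0.0, spec.read_noise_sd, spec.image_shape)
    dark = np.clip(np.round(dark), 0, _U16_MAX).astype(np.uint16)

    truth = {
        "R_lambda": res.R_lambda,
        "F_blue": res.F_blue,
        "F_red": res.F_red,
        "profile_kind": spec.profile.kind,
        "depth_parameter": spec.profile.depth_parameter,
        "preset": spec.preset,
        "I_ex1": spec.I_ex1,
        "I_ex2": spec.I_ex2,
        "counts_scale": spec.counts_scale,
        "dark_level": spec.dark_level,
        "seed": spec.seed,
    }
    return ImagePair(img_blue=img_blue, img_red=img_red, dark=dark, truth=truth)


def phantom_series(
    kind: str,
    thickness_grid: Sequence[float],
    preset: str = "dermis_table1",
) -> list[DepthProfile]:
    """Two-layer phantom-mimicking profiles over a grid of layer thicknesses.

    ``kind="top_layer"`` gives uniform PS layers of the listed thicknesses at
    the surface; ``kind="bottom_layer"`` gives uniform PS half-spaces under
    PS-free covers of the listed thicknesses (0 = uniform semispace).  Grids
    are sorted and deduplicated; thicknesses must lie within [0.1, 5] mm
    (a zero cover is allowed for the bottom case).
    """
    if kind not in ("top_layer", "bottom_layer"):
        raise ValueError("kind must be 'top_layer' or 'bottom_layer'")
    amps = preset_amplitudes(preset)
    grid = sorted(set(float(t) for t in thickness_grid))
    out = []
    for t in grid:
        if not (0.1 <= t <= 5.0 or (kind == "bottom_layer" and t == 0.0)):
            raise ValueError(f"thickness {t} mm outside the supported range [0.1, 5] mm")
        if kind == "top_layer":
            out.append(DepthProfile.top_uniform(t, amps))
        else:
            out.append(DepthProfile.bottom_uniform(t, amps))
    return out


def write_fixture(pair: ImagePair, directory, stem: str = "fixture") -> dict[str, Path]:
    """Write an image pair as 16-bit TIFFs plus a JSON truth sidecar."""
    from .pipeline import save_image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "blue": directory / f"{stem}_blue.tif",
        "red": directory / f"{stem}_red.tif",
        "dark": directory / f"{stem}_dark.tif",
        "truth": directory / f"{stem}_truth.json",
    }
    save_image(paths["blue"], pair.img_blue)
    save_image(paths["red"], pair.img_red)
    save_image(paths["dark"], pair.dark)
    with open(paths["truth"], "w") as fh:
        json.dump(pair.truth, fh, indent=2)
    return paths


def read_fixture(directory, stem: str = "fixture") -> ImagePair:
    """Read back an image pair written by :func:`write_fixture`."""
    from .pipeline import load_image

    directory = Path(directory)
    with open(directory / f"{stem}_truth.json") as fh:
        truth = json.load(fh)
    return ImagePair(
        img_blue=load_image(directory / f"{stem}_blue.tif"),
        img_red=load_image(directory / f"{stem}_red.tif"),
        dark=load_image(directory / f"{stem}_dark.tif"),
        truth=truth,
    )
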