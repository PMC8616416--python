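"""Ratiometric processing of dual-wavelength fluorescence image pairs.

A measurement consists of two monochrome fluorescence images (blue- and
red-excited, registered by the same detector), a dark frame, a shared region
of interest, the two excitation intensities and a calibration ratio from a
reference object (a thin photosensitizer layer on an absorbing substrate,
whose ratio carries the source/quantum-yield/absorption-amplitude factors
but no depth dependence).  The pipeline computes

    R_lambda = (mean ROI signal, red / I_ex_red) / (mean ROI signal, blue / I_ex_blue)
    R_c      = R_lambda / R_ref

and feeds the calibrated ratio to the closed-form depth inverses: the
exponential-profile inverse for topical administration, the buried-layer
inverse for intravenous injection, and the pre/post-PDT photobleaching depth
shift when both measurements are available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .inverse import DepthRangeError, bleach_depth, estimate_depth
from .optics import SpectralTriple

__all__ = [
    "ROI",
    "RatioMeasurement",
    "CalibratedRatio",
    "roi_response",
    "measured_ratio",
    "depth_report",
    "load_image",
    "save_image",
]


@dataclass(frozen=True)
class ROI:
    """Region of interest in pixel coordinates (origin top-left, 0-based).

    Either a rectangle ``(x, y, w, h)`` or a polygon vertex list
    ``[(x0, y0), (x1, y1), ...]``; the same pixel set is applied to both
    channels.
    """

    rect: tuple[int, int, int, int] | None = None
    polygon: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.polygon is None):
            raise ValueError("specify exactly one of rect or polygon")
        if self.polygon is not None:
            object.__setattr__(self, "polygon", tuple(tuple(p) for p in self.polygon))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.rect is not None:
            x, y, w, h = self.rect
            if x < 0 or y < 0 or x + w > shape[1] or y + h > shape[0]:
                raise ValueError(f"ROI rectangle {self.rect} outside image of shape {shape}")
            m = np.zeros(shape, dtype=bool)
            m[y : y + h, x : x + w] = True
            return m
        from skimage.draw import polygon2mask

        # polygon vertices are (x, y); polygon2mask expects (row, col)
        verts = np.array([(y, x) for x, y in self.polygon])
        if verts.min() < 0 or (verts[:, 0] > shape[0]).any() or (verts[:, 1] > shape[1]).any():
            raise ValueError("ROI polygon outside image bounds")
        return polygon2mask(shape, verts)

    def to_json(self, path=None):
        payload = (
            {"rect": list(self.rect)}
            if self.rect is not None
            else {"polygon": [list(p) for p in self.polygon]}
        )
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, src) -> "ROI":
        if isinstance(src, (str, Path)) and Path(src).exists():
            with open(src) as fh:
                payload = json.load(fh)
        elif isinstance(src, (str, bytes)):
            payload = json.loads(src)
        else:
            payload = src
        if "rect" in payload:
            return cls(rect=tuple(payload["rect"]))
        return cls(polygon=tuple(tuple(p) for p in payload["polygon"]))


@dataclass(frozen=True)
class RatioMeasurement:
    """Raw dual-wavelength responses plus normalization/calibration inputs."""

    img_blue: np.ndarray
    img_red: np.ndarray
    dark: np.ndarray
    roi: ROI
    I_ex1: float  # blue excitation intensity, mW/cm^2
    I_ex2: float  # red excitation intensity, mW/cm^2
    R_ref: float = 1.0

    def __post_init__(self) -> None:
        if not (self.img_blue.shape == self.img_red.shape == self.dark.shape):
            raise ValueError("images and dark frame must share one shape")
        if not (self.I_ex1 > 0 and self.I_ex2 > 0):
            raise ValueError("excitation intensities must be > 0")
        if not self.R_ref > 0:
            raise ValueError("R_ref must be > 0")


@dataclass(frozen=True)
class CalibratedRatio:
    """R_lambda, its calibrated value R_c = R_lambda / R_ref and ROI statistics."""

    R_lambda: float
    R_c: float
    roi_stats: dict


def roi_response(img: np.ndarray, dark: np.ndarray, roi: ROI) -> float:
    """Mean dark-subtracted signal over the ROI (negative pixels clipped at 0)."""
    if img.shape != dark.shape:
        raise ValueError("image and dark frame shapes differ")
    m = roi.mask(img.shape)
    if not m.any():
        raise ValueError("empty ROI")
    diff = np.clip(img.astype(np.float64) - dark.astype(np.float64), 0.0, None)
    return float(diff[m].mean())


def measured_ratio(meas: RatioMeasurement) -> CalibratedRatio:
    """Excitation-intensity-normalized ratio of ROI responses, calibrated."""
    s_blue = roi_response(meas.img_blue, meas.dark, meas.roi)
    s_red = roi_response(meas.img_red, meas.dark, meas.roi)
    if s_blue == 0:
        raise ZeroDivisionError("blue-channel ROI response is zero; ratio undefined")
    r = (s_red / meas.I_ex2) / (s_blue / meas.I_ex1)
    m = meas.roi.mask(meas.img_blue.shape)

    def stats(img):
        diff = np.clip(img.astype(np.float64) - meas.dark.astype(np.float64), 0.0, None)[m]
        return {"mean": float(diff.mean()), "sd": float(diff.std()), "n_pixels": int(m.sum())}

    return CalibratedRatio(
        R_lambda=r,
        R_c=r / meas.R_ref,
        roi_stats={"blue": stats(meas.img_blue), "red": stats(meas.img_red)},
    )


def depth_report(
    pre: CalibratedRatio,
    triple: SpectralTriple,
    amplitudes,
    post: CalibratedRatio | None = None,
    administration: str = "topical",
    phis: tuple[float, float] = (1.0, 1.0),
    use_backreflectance_r0: bool = False,
) -> dict:
    """Depth estimate (and PDT-induced depth change) from calibrated ratios.

    Topical administration inverts the exponential-profile formula for the
    penetration depth d_1e; intravenous injection inverts the buried-layer
    formula for the PS-free cover d_b.  When a post-PDT ratio is supplied,
    the bleaching depth shift Delta d_b = ln(R_after/R_before)/(mu_ex1-mu_ex2)
    is added.  ``use_backreflectance_r0`` replaces the quantum-yield/amplitude
    factor in the thin-layer limit by 1, i.e. takes R0 = k_ex2/k_ex1 as
    estimated from back-reflectance measurements of the bare medium.

    Out-of-range ratios are flagged in the report rather than raised.
    """
    if administration not in ("topical", "intravenous"):
        raise ValueError("administration must be 'topical' or 'intravenous'")
    amps = (1.0, 1.0) if use_backreflectance_r0 else amplitudes
    kind = "exponential" if administration == "topical" else "bottom_uniform"
    report: dict = {
        "administration": administration,
        "profile_kind": kind,
        "R_c_pre": pre.R_c,
    }
    try:
        est = estimate_depth(kind, pre.R_c, triple, amps, phis)
        report["depth_mm"] = est.value
        report["valid_range"] = list(est.valid_range)
        report["in_range"] = True
    except DepthRangeError as err:
        report["depth_mm"] = None
        report["valid_range"] = list(err.interval)
        report["in_range"] = False
        report["note"] = str(err)
    if post is not None:
        report["R_c_post"] = post.R_c
        report["delta_d_b_mm"] = bleach_depth(post.R_c, pre.R_c, triple)
        try:
            est_post = estimate_depth(kind, post.R_c, triple, amps, phis)
            report["depth_post_mm"] = est_post.value
        except DepthRangeError:
            report["depth_post_mm"] = None
    return report


def render_report(report: Mapping) -> str:
    """Human-readable rendering of a depth report."""
    lines = [
        f"administration : {report['administration']} ({report['profile_kind']} profile)",
        f"R_c (pre-PDT)  : {report['R_c_pre']:.6g}",
    ]
    if report.get("depth_mm") is not None:
        lines.append(f"depth estimate : {report['depth_mm']:.4g} mm")
    else:
        lines.append(f"depth estimate : out of range ({report.get('note', '')})")
    if "R_c_post" in report:
        lines.append(f"R_c (post-PDT) : {report['R_c_post']:.6g}")
        lines.append(f"bleach shift   : {report['delta_d_b_mm']:.4g} mm")
    return "\n".join(lines)


def load_image(path) -> np.ndarray:
    """Read a monochrome 16-bit TIFF or PNG raster."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def save_image(path, img: np.ndarray) -> None:
    """Write a monochrome image as 16-bit TIFF or PNG."""
    path = Path(path)
    data = np.asarray(img)
    if data.dtype != np.uint16:
        if data.max(initial=0) > np.iinfo(np.uint16).max:
            warnings.warn("image saturates the 16-bit range; clipping", stacklevel=2)
        data = np.clip(np.round(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)
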