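"""Automated measurements on bright-field-like frames and confocal stacks.

These are deterministic counterparts of the manual ImageJ procedures used in
the lab: tracing film contours (here: threshold + largest connected
component + hole filling), measuring the aureole width as the difference of
the equivalent-circle radii of the contours with and without the dark
annulus, thresholding the particle carpet for the surface fraction, and
summing per-slice thresholded areas x z-step for Z-stack volumes.

Intended for the synthetic frames produced by :mod:`aureole.synth` or for
comparable user images; real micrographs with debris or uneven illumination
are outside the warranty of the simple global thresholds used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .synth import ImageFrame, ZStack

__all__ = [
    "EmptySegmentationError",
    "AureoleMeasurement",
    "measure_film_area",
    "measure_aureole_width",
    "measure_surface_fraction",
    "zstack_volume_fractions",
    "radial_darkness_profile",
]


class EmptySegmentationError(RuntimeError):
    """No foreground object was found in the frame."""


@dataclass
class AureoleMeasurement:
    """Aureole geometry from one frame.

    ``R_outer``/``R_inner`` are equivalent-circle radii (sqrt(A/pi)) of the
    spread region with and without the dark annulus; their difference is the
    mean aureole width.  ``found`` is False when no annulus was detectable
    (Delta reported as 0 with low confidence).
    """

    t_s: float
    R_outer_um: float
    R_inner_um: float
    found: bool = True

    @property
    def delta_um(self) -> float:
        return self.R_outer_um - self.R_inner_um

    @property
    def delta_over_R(self) -> float:
        return self.delta_um / self.R_outer_um if self.R_outer_um > 0 else 0.0


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        raise EmptySegmentationError("no foreground found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _segment(frame: ImageFrame) -> tuple[np.ndarray, np.ndarray]:
    """(outer, inner) masks of the spread region.

    Three-class Otsu separates dark structures (aggregate, aureole, and any
    speckle), the mid-gray carpet background, and the bright cleared film.
    The inner region is the filled bright film (the aggregate sits as a dark
    hole inside it); the outer region additionally annexes the dark annulus.
    Isolated carpet speckle falls away with the largest-component step.
    """
    img = frame.data
    if img.max() == img.min():
        raise EmptySegmentationError("uniform frame: nothing to segment")
    try:
        t_dark, t_bright = threshold_multiotsu(img, classes=3)
    except ValueError as exc:  # fewer than 3 gray levels
        raise EmptySegmentationError(f"cannot threshold frame: {exc}") from exc
    bright = img > t_bright
    dark = img <= t_dark
    if not bright.any():
        raise EmptySegmentationError("no bright film region found")
    inner = ndimage.binary_fill_holes(_largest_component(bright))
    outer = ndimage.binary_fill_holes(_largest_component(bright | dark))
    return outer, inner


def measure_film_area(frame: ImageFrame) -> float:
    """Area of the spread region (film + aureole) in um^2.

    Equivalent radius is sqrt(A/pi); invariant under translation of the
    object within the field of view.
    """
    outer, _ = _segment(frame)
    return float(outer.sum()) * frame.pixel_size_um**2


def measure_aureole_width(frame: ImageFrame) -> AureoleMeasurement:
    """Aureole width as the difference of outer and inner equivalent radii."""
    outer, inner = _segment(frame)
    px = frame.pixel_size_um
    area_out = float(outer.sum()) * px**2
    # the annulus must touch the film boundary; its pixels are outer & ~inner
    annulus = outer & ~inner
    area_in = float(inner.sum()) * px**2
    R_out = math.sqrt(area_out / math.pi)
    R_in = math.sqrt(area_in / math.pi)
    t = float(frame.ground_truth.get("t_s", math.nan)) if frame.ground_truth else math.nan
    if annulus.sum() * px**2 < math.pi * (R_out + px) ** 2 - math.pi * R_out**2:
        # less than ~one pixel ring of dark area: no detectable aureole
        return AureoleMeasurement(t_s=t, R_outer_um=R_out, R_inner_um=R_out, found=False)
    return AureoleMeasurement(t_s=t, R_outer_um=R_out, R_inner_um=R_in, found=True)


def measure_surface_fraction(frame: ImageFrame, region: np.ndarray | None = None) -> float:
    """Optical surface fraction of the particle carpet.

    ``region`` selects the carpet pixels; by default everything outside the
    outer film contour (or the whole frame if no film is present).  A global
    Otsu threshold on the carpet pixels separates particle speckle from
    background; the returned value is the dark-pixel fraction.  Multilayer
    coatings (phi_S > 1) cannot be resolved optically — the estimate
    saturates below 1.
    """
    img = frame.data
    if region is None:
        try:
            outer, _ = _segment(frame)
            region = ~outer
        except EmptySegmentationError:
            region = np.ones_like(img, dtype=bool)
    if not region.any():
        raise EmptySegmentationError("empty carpet region")
    carpet = img[region]
    if carpet.max() == carpet.min():
        return 0.0
    t = threshold_otsu(carpet)
    # skimage convention: foreground is img > t, so particles are <= t
    return float(np.mean(carpet <= t))


def zstack_volume_fractions(stack: ZStack) -> tuple[float, float]:
    """(bead, nucleus) volume fractions of the cell from a confocal stack.

    Each channel is thresholded (Otsu over the whole stack); per-slice areas
    are summed as area x z-step — the elementary-volume rule with the lower
    slice's area — and fractions are V_beads/V_cell and V_nucleus/V_cell.
    """
    for name in ("cell", "nucleus", "beads"):
        if name not in stack.channels:
            raise KeyError(f"stack is missing the {name!r} channel")

    def volume(channel: np.ndarray) -> float:
        if channel.max() == channel.min():
            return 0.0
        t = threshold_otsu(channel)
        mask = channel > t
        if mask.mean() > 0.5:  # degenerate split on a nearly-empty channel
            return 0.0
        per_slice_area = mask.sum(axis=(1, 2)) * stack.pixel_size_um**2
        return float(per_slice_area.sum() * stack.z_step_um)

    v_cell = volume(stack.channels["cell"])
    if v_cell == 0:
        raise EmptySegmentationError("no cell found in stack")
    return volume(stack.channels["beads"]) / v_cell, volume(stack.channels["nucleus"]) / v_cell


def radial_darkness_profile(
    frame: ImageFrame, bin_um: float = 22.0
) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthal mean intensity versus radius, in bins of one cell diameter.

    The center is the image center (frames are rendered centered).  Returns
    (bin center radii [um], mean intensity); intensities are relative —
    uncalibrated grayscale, as in the source micrographs.
    """
    img = frame.data.astype(float)
    ny, nx = img.shape
    px = frame.pixel_size_um
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.indices(img.shape)
    r_um = np.hypot(yy - cy, xx - cx) * px
    half_fov = min(ny, nx) / 2.0 * px
    n_bins = int(math.ceil(half_fov / bin_um))
    idx = np.minimum((r_um / bin_um).astype(int), n_bins - 1)
    keep = r_um < n_bins * bin_um
    sums = np.bincount(idx[keep], weights=img[keep], minlength=n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    profile = sums / np.maximum(counts, 1)
    radii = (np.arange(n_bins) + 0.5) * bin_um
    return radii, profile
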