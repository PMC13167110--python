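"""Spectral z-stack processing: background subtraction, flattening, ROI spectra.

Each excitation laser yields a (z, bin, y, x) stack.  Per-plane rolling-ball
background subtraction suppresses neuropil signal, summation along z flattens
the chromatic focal shift, and averaging pixels within a co-registered ROI mask
yields the 204-channel fingerprint fed to the unmixer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from skimage.restoration import rolling_ball

from .spectral import Fingerprint, SpectralGrid

__all__ = [
    "SpectralStack",
    "ROIMask",
    "rolling_ball_subtract",
    "flatten_stack",
    "extract_roi_spectrum",
    "masks_from_label_image",
    "read_stack_tiff",
    "write_stack_tiff",
]


@dataclass
class SpectralStack:
    """One excitation laser's spectral z-stack, indexed (z, bin, y, x)."""

    values: np.ndarray
    laser: float
    pixel_size: float = 1.0  # um per pixel
    z_step: float = 5.0  # um between planes

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("stack must be 4-D (z, bin, y, x)")
        if np.any(self.values < 0):
            raise ValueError("stack intensities must be >= 0")
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ValueError("pixel_size and z_step must be positive")

    @property
    def n_z(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class ROIMask:
    """Pixel footprint of one ROI as (y, x) coordinate arrays."""

    rows: np.ndarray
    cols: np.ndarray
    roi_id: str

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        if self.rows.size == 0:
            raise ValueError(f"ROI {self.roi_id}: empty mask")
        if self.rows.shape != self.cols.shape:
            raise ValueError("rows and cols must have equal length")

    @property
    def n_pixels(self) -> int:
        return self.rows.size

    def to_label_image(self, shape, value: int = 1) -> np.ndarray:
        img = np.zeros(shape, dtype=np.uint16)
        img[self.rows, self.cols] = value
        return img

    @classmethod
    def from_boolean(cls, mask: np.ndarray, roi_id: str) -> "ROIMask":
        rows, cols = np.nonzero(mask)
        return cls(rows, cols, roi_id)


def masks_from_label_image(labels: np.ndarray) -> list[ROIMask]:
    """Split a 16-bit label image into per-ROI masks (label 0 = background)."""
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        out.append(ROIMask(rows, cols, str(int(lab))))
    return out


def rolling_ball_subtract(
    plane: np.ndarray, radius_um: float, pixel_size: float
) -> np.ndarray:
    """Subtract a rolling-ball background estimate from one image plane.

    The ball radius in pixels is ``round(radius_um / pixel_size)`` (30 um in
    the reference protocol); output is clipped at zero.
    """
    if radius_um <= 0 or pixel_size <= 0:
        raise ValueError("radius_um and pixel_size must be positive")
    radius_px = round(radius_um / pixel_size)
    if radius_px < 1:
        raise ValueError(
            f"rolling-ball radius {radius_um} um is below one pixel "
            f"at {pixel_size} um/px"
        )
    plane = np.asarray(plane, dtype=float)
    background = rolling_ball(plane, radius=radius_px)
    return np.clip(plane - background, 0.0, None)


def flatten_stack(
    stack: SpectralStack,
    z_crop: tuple[int, int] | None = None,
    background_radius_um: float | None = 30.0,
) -> np.ndarray:
    """Sum a spectral stack along z after per-plane background subtraction.

    ``z_crop`` is a half-open (start, stop) plane range dropping high-noise end
    planes; it must be applied identically to every laser of a subject.  The
    summed projection flattens the wavelength-dependent focal shift.  Returns a
    (bin, y, x) array.
    """
    start, stop = z_crop if z_crop is not None else (0, stack.n_z)
    if not (0 <= start < stop <= stack.n_z):
        raise ValueError(f"z_crop {z_crop} out of bounds for {stack.n_z} planes")
    planes = stack.values[start:stop]
    if background_radius_um is None:
        return planes.sum(axis=0)
    out = np.zeros(planes.shape[1:], dtype=float)
    for z in range(planes.shape[0]):
        for b in range(planes.shape[1]):
            out[b] += rolling_ball_subtract(
                planes[z, b], background_radius_um, stack.pixel_size
            )
    return out


def extract_roi_spectrum(
    flattened_per_laser: dict[float, np.ndarray],
    mask: ROIMask,
    grid: SpectralGrid,
) -> Fingerprint:
    """Average flattened intensities over a mask into one fingerprint.

    ``flattened_per_laser`` maps laser wavelength -> (bin, y, x) array from
    :func:`flatten_stack`.  The value of channel (laser, bin) is the mean over
    mask pixels, so ROI area does not scale the fingerprint.
    """
    missing = [l for l in grid.laser_wavelengths if l not in flattened_per_laser]
    if missing:
        raise KeyError(f"flattened images missing for lasers: {missing}")
    vals = np.zeros((grid.n_lasers, grid.n_bins))
    for i, laser in enumerate(grid.laser_wavelengths):
        img = flattened_per_laser[laser]
        if img.shape[0] != grid.n_bins:
            raise ValueError(
                f"laser {laser}: {img.shape[0]} bins, grid expects {grid.n_bins}"
            )
        if mask.rows.max() >= img.shape[1] or mask.cols.max() >= img.shape[2]:
            raise ValueError(f"ROI {mask.roi_id} exceeds image bounds")
        vals[i] = img[:, mask.rows, mask.cols].mean(axis=1)
    return Fingerprint(np.clip(vals, 0.0, None), mask.roi_id)


def write_stack_tiff(path, stack: SpectralStack) -> None:
    """Write a stack as a multi-page TIFF, pages ordered z-major then bin."""
    z, b, y, x = stack.values.shape
    tifffile.imwrite(
        path,
        stack.values.reshape(z * b, y, x).astype(np.float32),
        metadata={
            "laser_nm": stack.laser,
            "n_z": z,
            "n_bins": b,
            "pixel_size_um": stack.pixel_size,
            "z_step_um": stack.z_step,
        },
    )


def read_stack_tiff(
    path, laser: float, n_z: int, pixel_size: float = 1.0, z_step: float = 5.0
) -> SpectralStack:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    total, y, x = pages.shape
    if total % n_z:
        raise ValueError(f"{total} pages not divisible by n_z={n_z}")
    vals = pages.reshape(n_z, total // n_z, y, x)
    return SpectralStack(vals, laser, pixel_size, z_step)
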