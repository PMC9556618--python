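"""In-memory containers and PNG I/O for circle-scan B-scans and RNFL masks.

A circumpapillary OCT scan sweeps a circle around the optic nerve head; the
unrolled image has one column per A-scan (angular position) and one row per
axial depth sample. Intensities are stored as floats in [0, 1]; the axial
pixel pitch in micrometres is carried alongside the pixel grid so that
thickness in physical units can be recovered downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ContractError

EYES = ("OD", "OS")

#: Spectralis nominal axial pixel pitch in micrometres per pixel.
DEFAULT_AXIAL_SPACING_UM = 3.87


@dataclass
class BScanImage:
    """A 2-D grayscale circle-scan B-scan with calibration metadata.

    Parameters
    ----------
    pixels : ndarray of float, shape (height_px, width_ascans)
        Intensities in [0, 1]; columns sweep the scan circle in TSNIT order.
    axial_spacing_um : float
        Micrometres of tissue depth per axial pixel.
    eye : {"OD", "OS"}
        Laterality; controls the angular mapping of TSNIT sectors.
    scan_id : str
        Free-form identifier used in reports and error messages.
    """

    pixels: np.ndarray
    axial_spacing_um: float = DEFAULT_AXIAL_SPACING_UM
    eye: str = "OD"
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ContractError("B-scan pixels must be a non-empty 2-D grid")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ContractError(
                f"B-scan intensities must lie in [0, 1]; got [{lo:.4g}, {hi:.4g}]"
            )
        if self.axial_spacing_um <= 0:
            raise ContractError("axial_spacing_um must be positive")
        if self.eye not in EYES:
            raise ContractError(f"eye must be one of {EYES}, got {self.eye!r}")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_ascans(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "BScanImage":
        """Return a copy with new pixel data and unchanged calibration."""
        return replace(self, pixels=pixels)


@dataclass
class RNFLMask:
    """Binary per-pixel label of the RNFL band on the same grid as its image."""

    pixels: np.ndarray
    axial_spacing_um: float = DEFAULT_AXIAL_SPACING_UM
    eye: str = "OD"
    scan_id: str = field(default="")

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ContractError("mask must be a non-empty 2-D grid")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ContractError(f"mask values must be in {{0, 1}}; got {uniq[:6]}")
        self.pixels = arr.astype(bool)
        if self.axial_spacing_um <= 0:
            raise ContractError("axial_spacing_um must be positive")
        if self.eye not in EYES:
            raise ContractError(f"eye must be one of {EYES}, got {self.eye!r}")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_ascans(self) -> int:
        return self.pixels.shape[1]


def load_bscan(
    path: str | Path,
    axial_spacing_um: float = DEFAULT_AXIAL_SPACING_UM,
    eye: str = "OD",
    scan_id: str | None = None,
) -> BScanImage:
    """Read an 8- or 16-bit grayscale PNG/TIFF and normalise to [0, 1].

    Integer images are divided by the maximum of their dtype (255 or 65535),
    so a saturated pixel maps to exactly 1.0 regardless of bit depth.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.mode not in ("L", "I;16", "I", "F"):
            im = im.convert("L")
        arr = np.asarray(im)
    if np.issubdtype(arr.dtype, np.integer):
        denom = float(np.iinfo(arr.dtype).max) if arr.dtype != np.int32 else 65535.0
        arr = arr.astype(np.float64) / denom
    arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return BScanImage(
        pixels=arr,
        axial_spacing_um=axial_spacing_um,
        eye=eye,
        scan_id=scan_id if scan_id is not None else path.stem,
    )


def save_bscan(image: BScanImage, path: str | Path) -> None:
    """Write a B-scan as an 8-bit grayscale PNG."""
    arr = np.round(np.clip(image.pixels, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def load_mask(
    path: str | Path,
    axial_spacing_um: float = DEFAULT_AXIAL_SPACING_UM,
    eye: str = "OD",
    scan_id: str | None = None,
) -> RNFLMask:
    """Read a binary mask PNG; any non-zero pixel counts as foreground."""
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return RNFLMask(
        pixels=(arr > 0).astype(np.uint8),
        axial_spacing_um=axial_spacing_um,
        eye=eye,
        scan_id=scan_id if scan_id is not None else path.stem,
    )


def save_mask(mask: RNFLMask, path: str | Path) -> None:
    """Write a mask PNG with values {0, 255}."""
    arr = (mask.pixels.astype(np.uint8) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))
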