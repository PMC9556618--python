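"""Speckle denoising and network-input preparation.

Speckle — the multiplicative interference noise of coherent imaging — is
suppressed with grayscale morphology: an opening (removes bright speckle,
the dominant OCT artifact) followed by a closing (removes dark pits), both
with a small square structuring element. The denoised scan is then brought
to the fixed network grid: images already at or below the target size are
zero-padded symmetrically; larger images are first downscaled isotropically
so the longer side matches the target, then padded. The exact transform is
recorded in a ScaleInfo so predicted masks can be mapped back to the
original grid losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology, transform

from .errors import ContractError, ParameterError
from .images import BScanImage, RNFLMask


def denoise_morphological(image: BScanImage, kernel_px: int = 3) -> BScanImage:
    """Grayscale morphological opening then closing with a square kernel.

    The composite is idempotent in practice on speckle-dominated scans and
    never widens the intensity range. Calibration metadata is untouched.
    """
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ParameterError(f"kernel_px must be odd and >= 1, got {kernel_px}")
    if kernel_px == 1:
        return image.with_pixels(image.pixels.copy())
    footprint = np.ones((kernel_px, kernel_px), dtype=bool)
    opened = morphology.opening(image.pixels, footprint)
    closed = morphology.closing(opened, footprint)
    return image.with_pixels(np.clip(closed, 0.0, 1.0))


@dataclass(frozen=True)
class ScaleInfo:
    """Record of the original→network-grid transform, sufficient to invert it.

    scale_factor is the isotropic resampling factor applied before padding
    (1 when no resampling was needed); pad_top/pad_left are the zero-padding
    offsets of the (possibly resampled) image inside the square network grid.
    """

    scale_factor: float
    pad_top: int
    pad_left: int
    original_height: int
    original_width: int
    target: int = 256

    def scaled_dims(self) -> tuple[int, int]:
        """Dimensions after resampling, recomputed by the padding rule."""
        if self.scale_factor == 1.0:
            return self.original_height, self.original_width
        m = max(self.original_height, self.original_width)
        # integer ceiling of dim * target / m — exact, no float rounding
        return (
            min(self.target, -((-self.original_height * self.target) // m)),
            min(self.target, -((-self.original_width * self.target) // m)),
        )


def _scaled_size(height: int, width: int, target: int) -> tuple[float, int, int]:
    m = max(height, width)
    scale = target / m
    new_h = min(target, -((-height * target) // m))
    new_w = min(target, -((-width * target) // m))
    return scale, int(new_h), int(new_w)


def prepare_input(image: BScanImage, target: int = 256) -> tuple[np.ndarray, ScaleInfo]:
    """Resample/zero-pad a B-scan to the square network grid.

    If both dimensions are at or below ``target`` the image is zero-padded
    symmetrically (any odd leftover pixel goes to the bottom/right). If
    either dimension exceeds ``target`` the image is first downscaled
    isotropically (bilinear) so the larger dimension equals ``target``, the
    smaller one rounding up, and then padded. Returns the float32 network
    input and the ScaleInfo that inverts the transform.
    """
    h, w = image.pixels.shape
    if h <= target and w <= target:
        scale = 1.0
        resampled = image.pixels
        new_h, new_w = h, w
    else:
        scale, new_h, new_w = _scaled_size(h, w, target)
        resampled = transform.resize(
            image.pixels,
            (new_h, new_w),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    pad_top = (target - new_h) // 2
    pad_left = (target - new_w) // 2
    out = np.zeros((target, target), dtype=np.float32)
    out[pad_top : pad_top + new_h, pad_left : pad_left + new_w] = resampled
    info = ScaleInfo(
        scale_factor=scale,
        pad_top=pad_top,
        pad_left=pad_left,
        original_height=h,
        original_width=w,
        target=target,
    )
    return out, info


def prepare_mask(mask: RNFLMask, target: int = 256) -> np.ndarray:
    """Bring a binary mask to the network grid with the same rule as its image.

    Resampling, when needed, is nearest-neighbour so the result stays binary.
    """
    h, w = mask.pixels.shape
    if h <= target and w <= target:
        resampled = mask.pixels
        new_h, new_w = h, w
    else:
        _, new_h, new_w = _scaled_size(h, w, target)
        resampled = (
            transform.resize(
                mask.pixels.astype(np.float32),
                (new_h, new_w),
                order=0,
                mode="edge",
                anti_aliasing=False,
                preserve_range=True,
            )
            > 0.5
        )
    pad_top = (target - new_h) // 2
    pad_left = (target - new_w) // 2
    out = np.zeros((target, target), dtype=np.float32)
    out[pad_top : pad_top + new_h, pad_left : pad_left + new_w] = resampled
    return out


def restore_mask(grid_mask: np.ndarray, info: ScaleInfo) -> np.ndarray:
    """Invert prepare_input on a binary network-grid mask.

    Crops the padding, then (if the original was larger than the grid)
    upsamples with nearest-neighbour back to the original dimensions.
    Returns a boolean array of the original shape.
    """
    if grid_mask.shape != (info.target, info.target):
        raise ContractError(
            f"mask shape {grid_mask.shape} does not match network grid "
            f"({info.target}×{info.target})"
        )
    sh, sw = info.scaled_dims()
    core = grid_mask[info.pad_top : info.pad_top + sh, info.pad_left : info.pad_left + sw]
    if info.scale_factor == 1.0:
        return core.astype(bool)
    restored = transform.resize(
        core.astype(np.float32),
        (info.original_height, info.original_width),
        order=0,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return restored > 0.5
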