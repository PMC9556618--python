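"""Mask post-processing and conversion to calibrated RNFL thickness.

The predicted binary mask is first cleaned (holes filled, speckle components
removed), then converted to a per-A-scan thickness profile in micrometres,
and finally summarised into the seven clinical read-outs: the circle average
plus the six TSNIT sectors (temporal, temporal-superior, nasal-superior,
nasal, nasal-inferior, temporal-inferior).

Two thickness estimators are provided. The column estimator counts mask
pixels per A-scan and multiplies by the axial pixel pitch. The Euclidean
distance transform (EDT) estimator takes, per A-scan, twice the maximum
distance-to-background over the column's mask pixels; for a band that is one
contiguous vertical run per column the two agree to within one axial pixel,
so the EDT serves as an internal cross-check of the default column method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import ConfigurationError, ContractError
from .images import RNFLMask


@dataclass
class ThicknessProfile:
    """Per-A-scan RNFL thickness in µm along the unrolled scan circle.

    A-scan 0 sits on the temporal meridian and the columns proceed in TSNIT
    order (temporal → superior → nasal → inferior → temporal).
    """

    values_um: np.ndarray
    start_meridian: str = "temporal"
    direction: str = "TSNIT"

    def __post_init__(self) -> None:
        self.values_um = np.asarray(self.values_um, dtype=np.float64)
        if self.values_um.ndim != 1 or self.values_um.size == 0:
            raise ContractError("thickness profile must be a non-empty 1-D sequence")
        if np.any(self.values_um < 0):
            raise ContractError("thickness values must be non-negative")

    @property
    def n_ascans(self) -> int:
        return int(self.values_um.size)

    @property
    def average_um(self) -> float:
        return float(self.values_um.mean())


# Spectralis-convention sector spans on the unrolled TSNIT axis, degrees.
# Temporal is centred on the temporal horizontal meridian (angle 0) and spans
# 90 degrees; nasal mirrors it; the four oblique sectors take 45 degrees each.
DEFAULT_SECTOR_SPANS: tuple[tuple[str, float, float], ...] = (
    ("temporal", 315.0, 45.0),
    ("temporal_superior", 45.0, 90.0),
    ("nasal_superior", 90.0, 135.0),
    ("nasal", 135.0, 225.0),
    ("nasal_inferior", 225.0, 270.0),
    ("temporal_inferior", 270.0, 315.0),
)

SECTOR_NAMES = tuple(name for name, _, _ in DEFAULT_SECTOR_SPANS)


@dataclass
class SectorLayout:
    """Angular spans of the six TSNIT sectors on the unrolled circle.

    Spans are half-open ``[start, end)`` for right eyes; start > end denotes a
    span wrapping through 0°/360° (the default temporal sector). Spans must be
    disjoint and cover the full circle.
    """

    sectors: tuple[tuple[str, float, float], ...] = DEFAULT_SECTOR_SPANS

    def __post_init__(self) -> None:
        widths = {}
        for name, start, end in self.sectors:
            w = (end - start) % 360.0
            if w == 0:
                raise ConfigurationError(f"sector {name!r} has zero angular width")
            widths[name] = w
        if abs(sum(widths.values()) - 360.0) > 1e-9:
            raise ConfigurationError(
                "sector spans must cover the circle: widths sum to "
                f"{sum(widths.values())}, expected 360"
            )
        # disjointness: probe a fine angular grid, every angle in exactly one span
        probe = np.arange(0.0, 360.0, 0.25)
        hits = np.zeros(probe.size, dtype=int)
        for _, start, end in self.sectors:
            hits += _in_span(probe, start, end, mirrored=False)
        if not np.all(hits == 1):
            raise ConfigurationError("sector spans overlap or leave gaps")
        self.widths_deg = widths

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.sectors)


@dataclass
class SectorThickness:
    """The seven reported thickness values (µm): circle average + 6 sectors."""

    average_um: float
    nasal_um: float
    temporal_um: float
    nasal_inferior_um: float
    temporal_inferior_um: float
    nasal_superior_um: float
    temporal_superior_um: float

    _BY_SECTOR = {
        "nasal": "nasal_um",
        "temporal": "temporal_um",
        "nasal_inferior": "nasal_inferior_um",
        "temporal_inferior": "temporal_inferior_um",
        "nasal_superior": "nasal_superior_um",
        "temporal_superior": "temporal_superior_um",
    }

    def as_dict(self) -> dict[str, float]:
        return {
            "average_um": self.average_um,
            "nasal_um": self.nasal_um,
            "temporal_um": self.temporal_um,
            "nasal_inferior_um": self.nasal_inferior_um,
            "temporal_inferior_um": self.temporal_inferior_um,
            "nasal_superior_um": self.nasal_superior_um,
            "temporal_superior_um": self.temporal_superior_um,
        }

    def __getitem__(self, sector: str) -> float:
        return getattr(self, self._BY_SECTOR[sector])


def clean_mask(
    mask: RNFLMask, min_component_px: int = 25, fill_holes: bool = True
) -> RNFLMask:
    """Fill interior holes and drop small speckle components.

    Holes (background regions not connected to the image border) are filled
    first; then 8-connected foreground components with area strictly below
    ``min_component_px`` are removed.
    """
    pix = mask.pixels
    if fill_holes:
        pix = ndimage.binary_fill_holes(pix)
    if min_component_px > 1:
        # remove components with area strictly below min_component_px
        pix = morphology.remove_small_objects(
            pix, max_size=min_component_px - 1, connectivity=2
        )
    return RNFLMask(
        pixels=pix.astype(np.uint8),
        axial_spacing_um=mask.axial_spacing_um,
        eye=mask.eye,
        scan_id=mask.scan_id,
    )


def thickness_profile(mask: RNFLMask, method: str = "column") -> ThicknessProfile:
    """Convert a cleaned binary mask to a per-A-scan thickness profile.

    method="column": per A-scan, thickness = (number of mask pixels in that
    column) × axial pixel pitch.
    method="edt": per A-scan, thickness = 2 × (maximum Euclidean distance to
    the nearest background pixel over that column's mask pixels) × pitch.
    Columns without any mask pixel report 0 under both methods.
    """
    if method not in ("column", "edt"):
        raise ContractError(f"unknown thickness method {method!r}")
    pix = mask.pixels
    if method == "column":
        values = pix.sum(axis=0).astype(np.float64) * mask.axial_spacing_um
    else:
        if not pix.any():
            values = np.zeros(pix.shape[1], dtype=np.float64)
        else:
            dist = ndimage.distance_transform_edt(pix)
            values = 2.0 * dist.max(axis=0) * mask.axial_spacing_um
    return ThicknessProfile(values_um=values)


def _in_span(
    angles_deg: np.ndarray, start: float, end: float, mirrored: bool
) -> np.ndarray:
    """Membership of angles in a circular span.

    Right eyes use half-open [start, end); mirrored (left-eye) angles were
    produced by a reflection, which reverses orientation, so membership flips
    to (start, end] to keep the sectors a partition of the circle.
    """
    a = np.mod(angles_deg, 360.0)
    s, e = start % 360.0, end % 360.0
    if mirrored:
        if s < e:
            return (a > s) & (a <= e)
        return (a > s) | (a <= e)
    if s < e:
        return (a >= s) & (a < e)
    return (a >= s) | (a < e)


def sector_angles(n_ascans: int, eye: str) -> tuple[np.ndarray, bool]:
    """Anatomical angle of each A-scan plus whether the mapping is mirrored.

    Column i sits at i·360/n on the unrolled axis. For left eyes (OS) the
    anatomical angle is the reflection about the vertical (superior–inferior)
    axis, (180 − a) mod 360, which swaps nasal and temporal labels while
    keeping superior sectors superior.
    """
    raw = np.arange(n_ascans) * (360.0 / n_ascans)
    if eye == "OS":
        return np.mod(180.0 - raw, 360.0), True
    return raw, False


def sector_thickness(
    profile: ThicknessProfile, layout: SectorLayout | None = None, eye: str = "OD"
) -> SectorThickness:
    """Summarise a profile into the circle average and six TSNIT sector means.

    The average is the plain mean over all A-scans; each sector is the mean
    over the A-scans whose anatomical angle falls in its span. When the
    profile length is a multiple of 8 the sectors partition the columns
    exactly, and the average equals the angular-width-weighted mean of the
    six sector values.
    """
    if layout is None:
        layout = SectorLayout()
    if profile.n_ascans < 6:
        raise ContractError("profile must have at least 6 A-scans")
    if eye not in ("OD", "OS"):
        raise ContractError(f"eye must be 'OD' or 'OS', got {eye!r}")
    angles, mirrored = sector_angles(profile.n_ascans, eye)
    values: dict[str, float] = {"average_um": profile.average_um}
    for name, start, end in layout.sectors:
        member = _in_span(angles, start, end, mirrored)
        values[name] = (
            float(profile.values_um[member].mean()) if member.any() else float("nan")
        )
    return SectorThickness(
        average_um=values["average_um"],
        nasal_um=values["nasal"],
        temporal_um=values["temporal"],
        nasal_inferior_um=values["nasal_inferior"],
        temporal_inferior_um=values["temporal_inferior"],
        nasal_superior_um=values["nasal_superior"],
        temporal_superior_um=values["temporal_superior"],
    )
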