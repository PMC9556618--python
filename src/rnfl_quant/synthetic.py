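"""Seeded circumpapillary B-scan phantoms with exact ground truth.

The phantom emulates the geometry of an unrolled circle scan: a vitreous
region on top, an RNFL band whose thickness follows the classic TSNIT
double-hump curve (thick superior-temporal and inferior-temporal bundles,
thinner temporal and nasal meridians), deeper retina below, multiplicative
gamma speckle, and optional epiretinal-membrane (ERM) / posterior-vitreous-
detachment (PVD) artifacts drawn above the band.

Group presets are calibrated so the expected circle-average thickness
matches published cohort means for healthy controls (≈100.3 µm), NAION
(≈69.7 µm) and optic neuritis (≈76.1 µm). Per-phantom variability is a
global profile scale drawn from a symmetrically truncated normal (so the
Monte-Carlo mean stays on target) plus smooth zero-mean angular jitter built
from low-order Fourier modes (whose discrete circle mean is exactly zero).

Everything is driven by a single integer seed; per-phantom child seeds are
derived with a splitmix64 mix so datasets of any size are reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .images import BScanImage, RNFLMask, save_bscan, save_mask
from .thickness import (
    SECTOR_NAMES,
    SectorLayout,
    ThicknessProfile,
    sector_thickness,
)

#: Hump centres: the superior-temporal and inferior-temporal bundle peaks sit
#: at the centres of the TS (45–90°) and TI (270–315°) sectors.
HUMP_CENTERS_DEG = (67.5, 292.5)

#: Published cohort means of the manually segmented circle-average thickness
#: used as calibration targets for the group presets (µm).
GROUP_TARGET_AVG_UM = {"control": 100.3, "NAION": 69.7, "ON": 76.1}

# Hump height above baseline per preset; chosen so the sector pattern is
# qualitatively right (temporal/nasal low, TS/TI high) while the baseline is
# solved numerically from the circle-average target.
_GROUP_HUMP_UM = {"control": 60.0, "NAION": 35.0, "ON": 40.0}


def splitmix64(seed: int, index: int) -> int:
    """Deterministic child-seed derivation (splitmix64 finalizer).

    Returns a value in [0, 2^31) suitable for numpy Generators.
    """
    mask = 0xFFFFFFFFFFFFFFFF
    z = (int(seed) + (index + 1) * 0x9E3779B97F4A7C15) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z = z ^ (z >> 31)
    return z % 2**31


@dataclass
class PhantomSpec:
    """Generative parameters for one family of synthetic circle-scan B-scans.

    Parameters
    ----------
    width_ascans, height_px : int
        Grid size: A-scans per circle and axial samples. The 256×256 default
        matches the network input natively; use 496×768 for a
        Spectralis-like grid that exercises the resize path.
    axial_spacing_um : float
        Micrometres per axial pixel (Spectralis nominal 3.87).
    baseline_um : float
        Sector-independent thickness floor of the RNFL band.
    hump_amplitude_um : float
        Peak height of the superior- and inferior-temporal humps above the
        baseline.
    hump_width_deg : float
        Gaussian sigma of each hump, in degrees.
    ilm_depth_px, ilm_undulation_px : mean inner-limiting-membrane depth and
        amplitude of its slow sinusoidal undulation.
    speckle_shape : float
        Gamma shape of the multiplicative speckle (mean 1); lower is
        noisier; 0 disables speckle.
    scale_sd : float
        SD of the per-phantom global profile scale (truncated at ±3 SD).
    jitter_um : float
        Amplitude scale of the smooth zero-mean angular jitter; 0 disables.
    background_level, band_level, deep_level : float
        Intensities of vitreous, RNFL band and deeper retina in [0, 1].
    erm, pvd : bool
        Draw an epiretinal membrane / posterior vitreous detachment artifact.
    eye : {"OD", "OS"}; group_preset : {"control", "NAION", "ON", "custom"}.
    """

    width_ascans: int = 256
    height_px: int = 256
    axial_spacing_um: float = 3.87
    baseline_um: float = 80.0
    hump_amplitude_um: float = 60.0
    hump_width_deg: float = 26.0
    ilm_depth_px: int = 60
    ilm_undulation_px: float = 6.0
    speckle_shape: float = 4.0
    scale_sd: float = 0.10
    jitter_um: float = 2.0
    background_level: float = 0.08
    band_level: float = 0.85
    deep_level: float = 0.45
    erm: bool = False
    pvd: bool = False
    eye: str = "OD"
    group_preset: str = "custom"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.width_ascans < 8 or self.height_px < 8:
            raise ConfigurationError("grid must be at least 8×8 (invariant: non-degenerate grid)")
        for name in (
            "axial_spacing_um",
            "hump_width_deg",
            "baseline_um",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"invariant violated: {name} must be positive")
        for name in ("hump_amplitude_um", "ilm_undulation_px", "scale_sd", "jitter_um"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"invariant violated: {name} must be non-negative")
        if self.speckle_shape < 0:
            raise ConfigurationError("invariant violated: speckle_shape must be >= 0")
        for name in ("background_level", "band_level", "deep_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"invariant violated: {name} must be in [0, 1]")
        if self.eye not in ("OD", "OS"):
            raise ConfigurationError("invariant violated: eye must be 'OD' or 'OS'")
        if self.baseline_um + self.hump_amplitude_um >= self.height_px * self.axial_spacing_um:
            raise ConfigurationError(
                "invariant violated: baseline_um + hump_amplitude_um must be below "
                f"the frame depth ({self.height_px * self.axial_spacing_um:.1f} µm)"
            )

    @classmethod
    def for_group(cls, group: str, **overrides) -> "PhantomSpec":
        """Build a preset calibrated to a cohort's mean circle-average thickness.

        The baseline is solved so that the noise-free double-hump profile has
        exactly the target circle average on the preset's discrete grid.
        """
        if group == "custom":
            return cls(group_preset="custom", **overrides)
        if group not in GROUP_TARGET_AVG_UM:
            raise ConfigurationError(
                f"unknown group preset {group!r}; expected control/NAION/ON/custom"
            )
        amp = overrides.pop("hump_amplitude_um", _GROUP_HUMP_UM[group])
        width = overrides.pop("hump_width_deg", 26.0)
        n = overrides.get("width_ascans", 256)
        hump_mean = float(_hump_sum(np.arange(n) * (360.0 / n), width).mean()) * amp
        baseline = GROUP_TARGET_AVG_UM[group] - hump_mean
        return cls(
            baseline_um=baseline,
            hump_amplitude_um=amp,
            hump_width_deg=width,
            group_preset=group,
            **overrides,
        )


@dataclass
class GroundTruth:
    """Exact labels for one phantom: mask, continuous profile, ILM rows."""

    mask: RNFLMask
    profile_um: ThicknessProfile
    ilm_row_per_column: np.ndarray = field(repr=False)


def _wrapped_angle_dist(angles_deg: np.ndarray, center_deg: float) -> np.ndarray:
    d = np.abs(np.mod(angles_deg - center_deg + 180.0, 360.0) - 180.0)
    return d


def _hump_sum(angles_deg: np.ndarray, sigma_deg: float) -> np.ndarray:
    """Unit-amplitude sum of the two Gaussian humps at the bundle peaks."""
    total = np.zeros_like(angles_deg, dtype=np.float64)
    for center in HUMP_CENTERS_DEG:
        d = _wrapped_angle_dist(angles_deg, center)
        total += np.exp(-0.5 * (d / sigma_deg) ** 2)
    return total


def noise_free_profile(spec: PhantomSpec) -> np.ndarray:
    """The deterministic double-hump TSNIT curve for a spec, in µm."""
    angles = np.arange(spec.width_ascans) * (360.0 / spec.width_ascans)
    return spec.baseline_um + spec.hump_amplitude_um * _hump_sum(
        angles, spec.hump_width_deg
    )


def tsnit_profile(spec: PhantomSpec, seed: int) -> ThicknessProfile:
    """Draw one per-A-scan ground-truth thickness profile.

    profile = s · (baseline + humps) + jitter, where s is a global scale from
    a normal truncated symmetrically at ±3 SD (mean exactly 1) and the jitter
    is a sum of Fourier modes k = 1..4 with seeded Gaussian coefficients —
    its discrete mean over the circle is exactly zero, so the expected circle
    average equals the noise-free average.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    base = noise_free_profile(spec)
    scale = 1.0
    if spec.scale_sd > 0:
        while True:
            s = rng.normal(1.0, spec.scale_sd)
            if abs(s - 1.0) <= 3.0 * spec.scale_sd:
                scale = s
                break
    values = scale * base
    if spec.jitter_um > 0:
        theta = np.arange(spec.width_ascans) * (2.0 * np.pi / spec.width_ascans)
        jitter = np.zeros_like(values)
        for k in range(1, 5):
            c, d = rng.normal(0.0, spec.jitter_um, size=2)
            jitter += c * np.cos(k * theta) + d * np.sin(k * theta)
        values = values + jitter
    values = np.clip(values, 1.0, None)
    return ThicknessProfile(values_um=values)


def render_bscan(
    spec: PhantomSpec, profile: ThicknessProfile, seed: int, scan_id: str = ""
) -> tuple[BScanImage, GroundTruth]:
    """Render one B-scan image and its exact ground truth from a profile.

    The noise-free template is piecewise constant (vitreous / band / deeper
    retina) warped by a slow sinusoidal ILM curve; the ground-truth mask is
    taken from the template before speckle, so each column holds a single
    contiguous run of round(thickness / pitch) pixels starting at the ILM.
    """
    spec.validate()
    if profile.n_ascans != spec.width_ascans:
        raise ConfigurationError(
            f"profile length {profile.n_ascans} != spec width {spec.width_ascans}"
        )
    rng = np.random.default_rng(seed)
    n, h = spec.width_ascans, spec.height_px
    cols = np.arange(n)

    phase = rng.uniform(0.0, 2.0 * np.pi)
    ilm = np.round(
        spec.ilm_depth_px
        + spec.ilm_undulation_px * np.sin(2.0 * np.pi * cols / n + phase)
    ).astype(int)

    thick_px = np.round(profile.values_um / spec.axial_spacing_um).astype(int)
    bottom = ilm + thick_px
    if np.any(ilm < 0) or np.any(bottom >= h):
        raise ConfigurationError(
            "RNFL band exceeds the frame: increase height_px or reduce "
            "ilm_depth_px / profile thickness"
        )

    rows = np.arange(h)[:, None]
    band = (rows >= ilm[None, :]) & (rows < bottom[None, :])
    below = rows >= bottom[None, :]
    img = np.full((h, n), spec.background_level, dtype=np.float64)
    img[band] = spec.band_level
    img[below] = spec.deep_level

    if spec.erm:
        arc_w = int(rng.uniform(0.2, 0.4) * n)
        start = int(rng.integers(0, n))
        gap = int(rng.integers(5, 11))
        arc = (cols - start) % n < arc_w
        for dr in (0, 1):
            r = np.clip(ilm - gap + dr, 0, h - 1)
            img[r[arc], cols[arc]] = 0.9
    if spec.pvd:
        start_row = int(rng.integers(5, max(6, spec.ilm_depth_px // 2)))
        slope = rng.uniform(-0.05, 0.05)
        r = np.clip(np.round(start_row + slope * cols).astype(int), 0, h - 1)
        above = r < ilm - 2
        img[r[above], cols[above]] = min(1.0, spec.background_level + 0.18)

    if spec.speckle_shape > 0:
        speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, size=img.shape)
        img = img * speckle
    img = np.clip(img, 0.0, 1.0)

    image = BScanImage(
        pixels=img, axial_spacing_um=spec.axial_spacing_um, eye=spec.eye, scan_id=scan_id
    )
    mask = RNFLMask(
        pixels=band.astype(np.uint8),
        axial_spacing_um=spec.axial_spacing_um,
        eye=spec.eye,
        scan_id=scan_id,
    )
    truth = GroundTruth(mask=mask, profile_um=profile, ilm_row_per_column=ilm)
    return image, truth


@dataclass
class DatasetManifest:
    """Index of a generated phantom dataset on disk."""

    frame: pd.DataFrame
    root: Path

    def __len__(self) -> int:
        return len(self.frame)

    def image_path(self, scan_id: str) -> Path:
        row = self.frame.loc[self.frame.scan_id == scan_id].iloc[0]
        return self.root / row.image

    def mask_path(self, scan_id: str) -> Path:
        row = self.frame.loc[self.frame.scan_id == scan_id].iloc[0]
        return self.root / row.mask

    @classmethod
    def read(cls, manifest_csv: str | Path) -> "DatasetManifest":
        path = Path(manifest_csv)
        return cls(frame=pd.read_csv(path), root=path.parent)


def make_dataset(
    n: int,
    spec: PhantomSpec,
    seed: int,
    out_dir: str | Path,
    layout: SectorLayout | None = None,
) -> DatasetManifest:
    """Write ``n`` image/mask PNG pairs plus a CSV manifest of true thicknesses.

    Child seeds for the profile and the renderer of scan ``i`` are derived
    from the master seed via splitmix64 at indices 2i and 2i+1, so the same
    (spec, seed) always reproduces the same dataset, independent of ``n`` for
    the common prefix.
    """
    if n < 1:
        raise DataError("dataset size must be >= 1")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out} is not writable: {exc}") from exc

    if layout is None:
        layout = SectorLayout()
    rows = []
    for i in range(n):
        scan_id = f"{spec.group_preset}_{i:04d}"
        profile = tsnit_profile(spec, splitmix64(seed, 2 * i))
        image, truth = render_bscan(spec, profile, splitmix64(seed, 2 * i + 1), scan_id)
        img_name = f"{scan_id}_image.png"
        mask_name = f"{scan_id}_mask.png"
        save_bscan(image, out / img_name)
        save_mask(truth.mask, out / mask_name)
        sectors = sector_thickness(profile, layout, spec.eye)
        row = {
            "scan_id": scan_id,
            "eye": spec.eye,
            "group": spec.group_preset,
            "image": img_name,
            "mask": mask_name,
            "true_avg_um": sectors.average_um,
        }
        for name in SECTOR_NAMES:
            row[f"true_{name}_um"] = sectors[name]
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "manifest.csv", index=False, quoting=csv.QUOTE_MINIMAL)
    return DatasetManifest(frame=frame, root=out)


def corrupt_mask(mask: RNFLMask, seed: int, arc_fraction: float = 0.25) -> RNFLMask:
    """Simulated segmentation-failure operator: truncate the band over an arc.

    Removes all band pixels over a random contiguous arc covering
    ``arc_fraction`` of the circle — a stylised stand-in for the gross
    layer-tracing failures automated segmentation exhibits on atrophic or
    artifact-laden scans.
    """
    if not 0.0 < arc_fraction < 1.0:
        raise ConfigurationError("arc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = mask.width_ascans
    width = max(1, int(round(arc_fraction * n)))
    start = int(rng.integers(0, n))
    arc = (np.arange(n) - start) % n < width
    pix = mask.pixels.copy()
    pix[:, arc] = False
    return RNFLMask(
        pixels=pix.astype(np.uint8),
        axial_spacing_um=mask.axial_spacing_um,
        eye=mask.eye,
        scan_id=mask.scan_id,
    )
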