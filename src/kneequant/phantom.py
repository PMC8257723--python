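"""Synthetic 3D knee phantoms with known ground truth.

The phantoms are deliberately stylised: two overlapping discs stand in for
the femoral condyles, a rectangle for the tibial plateau, and each bone
carries a narrow shaft so its principal axis is unambiguously the joint's
long axis.  Articular interfaces are flat planes normal to the projection
axis, which makes the cartilage thickness of every surface column known in
closed form — that is what lets every downstream operator be tested against
exact expectations without real MRI data.

Cartilage is laid down in voxel columns.  The distance-transform thickness
of an ``n``-voxel column is ``(n + 1) * dz`` (centre-to-centre distances
overshoot each interface by half a voxel), so the generator fills
``n = round(t / dz) - 1`` voxels to realise a requested thickness ``t``
within half a voxel.

Longitudinal cohorts add a focal medial lesion whose radius grows linearly
in time, duplicate-scan noise jitters the outer cartilage boundary, and
clinical-score tables emulate bounded patient-reported outcomes with a
post-treatment improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .volume import (
    BACKGROUND,
    FEMORAL_CARTILAGE,
    FEMUR_BONE,
    TIBIAL_CARTILAGE,
    TIBIA_BONE,
    LabelVolume,
)

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "LesionDistribution",
    "CohortTruth",
    "SizingError",
    "REGION_NAMES",
    "INSTRUMENTS",
    "make_knee_phantom",
    "apply_lesion",
    "add_scan_noise",
    "truth_metrics",
    "simulate_cohort",
    "simulate_scores",
    "measured_thickness_mm",
]

REGION_NAMES = (
    "femoral_posteromedial",
    "femoral_posterolateral",
    "femoral_anteromedial",
    "femoral_anterolateral",
    "tibial_medial",
    "tibial_lateral",
)


class SizingError(ValueError):
    """Raised when the requested geometry does not fit the voxel grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic knee.

    Spacing defaults to the acquisition geometry the pipeline targets:
    0.31 x 0.31 mm in-plane with 0.36 mm partitions.  The grid is cropped
    around the joint; sizes are validated against the geometry.
    """

    knee_side: str = "right"
    volume_shape: tuple[int, int, int] = (128, 128, 200)
    spacing_mm: tuple[float, float, float] = (0.31, 0.31, 0.36)
    condyle_radius_mm: float = 10.0
    plateau_extent_mm: float = 24.0
    base_thickness_mm: float = 2.0
    #: optional spatially varying thickness: f(r_mm, c_mm) -> mm, coordinates
    #: relative to the grid centre; overrides base_thickness_mm where given
    base_thickness_field: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    seed: int = 0

    # fractions of the slice extent where the articular surfaces sit
    _fem_surface_frac: float = 0.47
    _tib_surface_frac: float = 0.57

    def __post_init__(self) -> None:
        if self.knee_side not in ("left", "right"):
            raise ValueError(f"knee_side must be 'left' or 'right', got {self.knee_side!r}")
        if len(self.volume_shape) != 3 or any(int(n) <= 0 for n in self.volume_shape):
            raise ValueError(f"volume_shape must be three positive ints, got {self.volume_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be three positive reals, got {self.spacing_mm}")
        if self.condyle_radius_mm <= 0:
            raise ValueError("condyle_radius_mm must be positive")
        if self.plateau_extent_mm <= 0:
            raise ValueError("plateau_extent_mm must be positive")


@dataclass(frozen=True)
class LesionSpec:
    """A focal cartilage lesion on the projected surface.

    ``center_mm`` is (row, col) in mm relative to the grid centre in the
    volume's own orientation.  The effective radius after ``w`` weeks is
    ``radius_mm + growth_rate_mm_per_week * w``.
    """

    target_region: str = "femoral_posteromedial"
    center_mm: tuple[float, float] = (4.0, -5.5)
    radius_mm: float = 3.0
    residual_thickness_mm: float = 1.0
    growth_rate_mm_per_week: float = 0.0

    def __post_init__(self) -> None:
        if self.target_region not in REGION_NAMES:
            raise ValueError(
                f"unknown target region {self.target_region!r}; expected one of {REGION_NAMES}"
            )
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.residual_thickness_mm < 0:
            raise ValueError("residual_thickness_mm must be >= 0")

    def radius_at(self, weeks_elapsed: float) -> float:
        return max(0.0, self.radius_mm + self.growth_rate_mm_per_week * weeks_elapsed)


def measured_thickness_mm(target_mm: float, dz: float) -> float:
    """Thickness the distance-transform metric reports for a column built
    to target ``target_mm`` (see module docstring)."""
    n = _column_voxels(target_mm, dz)
    return (n + 1) * dz if n > 0 else 0.0


def _column_voxels(t_mm, dz: float):
    """Voxels to fill so the measured column thickness is closest to t."""
    n = np.round(np.asarray(t_mm, float) / dz).astype(int) - 1
    return np.maximum(n, 0) if np.ndim(n) else int(max(n, 0))


# ---------------------------------------------------------------------------
# geometry layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Layout:
    """Derived voxel-index geometry of a phantom (right-knee orientation)."""

    spec: PhantomSpec
    r_mm: np.ndarray  # (nr,) in-plane row coords relative to centre
    c_mm: np.ndarray  # (nc,)
    fem_footprint: np.ndarray
    shaft_fem: np.ndarray
    tib_footprint: np.ndarray
    shaft_tib: np.ndarray
    k_condyle_top: int
    k_fem_surface: int  # last femoral bone slice; cartilage below
    k_tib_surface: int  # first tibial bone slice; cartilage above
    k_plateau_end: int
    fem_thickness_vox: np.ndarray
    tib_thickness_vox: np.ndarray


def _thickness_field(spec: PhantomSpec, R: np.ndarray, C: np.ndarray) -> np.ndarray:
    if spec.base_thickness_field is not None:
        t = np.asarray(spec.base_thickness_field(R, C), float)
    else:
        t = np.full(R.shape, float(spec.base_thickness_mm))
    if np.any(t < 0):
        raise ValueError("base thickness field must be >= 0 everywhere")
    return t


def _layout(spec: PhantomSpec) -> _Layout:
    nr, nc, nz = (int(n) for n in spec.volume_shape)
    sr, sc, dz = spec.spacing_mm
    r_mm = (np.arange(nr) - (nr - 1) / 2.0) * sr
    c_mm = (np.arange(nc) - (nc - 1) / 2.0) * sc
    R, C = np.meshgrid(r_mm, c_mm, indexing="ij")

    rad = spec.condyle_radius_mm
    sep = 1.1 * rad  # centre-to-centre condyle separation
    half_width = sep / 2.0 + rad
    margin = 2.0 * max(sr, sc)

    if half_width + margin > abs(c_mm[0]):
        raise SizingError(
            f"volume_shape[1] (cols) too small: condylar footprint half-width "
            f"{half_width:.1f} mm exceeds available {abs(c_mm[0]) - margin:.1f} mm"
        )
    if rad + margin > abs(r_mm[0]):
        raise SizingError(
            f"volume_shape[0] (rows) too small: condyle radius {rad:.1f} mm "
            f"exceeds available {abs(r_mm[0]) - margin:.1f} mm"
        )
    if spec.plateau_extent_mm / 2.0 + margin > abs(r_mm[0]):
        raise SizingError(
            f"volume_shape[0] (rows) too small: plateau extent "
            f"{spec.plateau_extent_mm:.1f} mm does not fit"
        )

    medial = (R**2 + (C + sep / 2.0) ** 2) <= rad**2
    lateral = (R**2 + (C - sep / 2.0) ** 2) <= rad**2
    fem_footprint = medial | lateral
    shaft_fem = (R**2 + C**2) <= (0.55 * rad) ** 2
    tib_footprint = (np.abs(R) <= spec.plateau_extent_mm / 2.0) & (np.abs(C) <= half_width)
    shaft_tib = (R**2 + C**2) <= (0.45 * half_width) ** 2

    k_fem_surface = int(round(spec._fem_surface_frac * nz))
    k_tib_surface = int(round(spec._tib_surface_frac * nz))
    k_condyle_top = k_fem_surface - max(1, int(round(8.0 / dz)))
    k_plateau_end = k_tib_surface + max(1, int(round(6.0 / dz)))
    if k_condyle_top < 2:
        raise SizingError("volume_shape[2] (slices) too small for the femoral bone stack")
    if k_plateau_end >= nz - 2:
        raise SizingError("volume_shape[2] (slices) too small for the tibial bone stack")

    t = _thickness_field(spec, R, C)
    fem_n = _column_voxels(t, dz)
    tib_n = _column_voxels(t, dz)
    nmax = int(max(fem_n[fem_footprint].max(initial=0), tib_n[tib_footprint].max(initial=0)))
    if k_fem_surface + nmax >= k_tib_surface - tib_n[tib_footprint].max(initial=0) - 2:
        raise SizingError(
            "volume_shape[2] (slices) too small: cartilage shells would close the joint space"
        )
    return _Layout(
        spec=spec, r_mm=r_mm, c_mm=c_mm,
        fem_footprint=fem_footprint, shaft_fem=shaft_fem,
        tib_footprint=tib_footprint, shaft_tib=shaft_tib,
        k_condyle_top=k_condyle_top, k_fem_surface=k_fem_surface,
        k_tib_surface=k_tib_surface, k_plateau_end=k_plateau_end,
        fem_thickness_vox=fem_n, tib_thickness_vox=tib_n,
    )


def make_knee_phantom(spec: PhantomSpec) -> LabelVolume:
    """Build a labelled knee phantom from a spec (deterministic)."""
    lay = _layout(spec)
    nr, nc, nz = (int(n) for n in spec.volume_shape)
    vol = np.zeros((nr, nc, nz), np.int16)
    K = np.arange(nz)[None, None, :]

    vol[lay.shaft_fem, : lay.k_condyle_top] = FEMUR_BONE
    vol[lay.fem_footprint, lay.k_condyle_top : lay.k_fem_surface + 1] = FEMUR_BONE
    fem_cart = (
        lay.fem_footprint[:, :, None]
        & (K > lay.k_fem_surface)
        & (K <= lay.k_fem_surface + lay.fem_thickness_vox[:, :, None])
    )
    vol[fem_cart] = FEMORAL_CARTILAGE

    vol[lay.tib_footprint, lay.k_tib_surface : lay.k_plateau_end + 1] = TIBIA_BONE
    vol[lay.shaft_tib, lay.k_plateau_end + 1 :] = TIBIA_BONE
    tib_cart = (
        lay.tib_footprint[:, :, None]
        & (K < lay.k_tib_surface)
        & (K >= lay.k_tib_surface - lay.tib_thickness_vox[:, :, None])
    )
    vol[tib_cart] = TIBIAL_CARTILAGE

    out = LabelVolume(data=vol, spacing_mm=spec.spacing_mm, knee_side="right")
    if spec.knee_side == "left":
        out = out.mirrored()
    return out


# ---------------------------------------------------------------------------
# lesions and scan noise
# ---------------------------------------------------------------------------

def _lesion_columns(volume: LabelVolume, lesion: LesionSpec, radius_mm: float) -> np.ndarray:
    nr, nc = volume.shape[:2]
    sr, sc = volume.spacing_mm[:2]
    r_mm = (np.arange(nr) - (nr - 1) / 2.0) * sr
    c_mm = (np.arange(nc) - (nc - 1) / 2.0) * sc
    R, C = np.meshgrid(r_mm, c_mm, indexing="ij")
    rc, cc = lesion.center_mm
    return (R - rc) ** 2 + (C - cc) ** 2 <= radius_mm**2


def apply_lesion(
    volume: LabelVolume, lesion: LesionSpec, weeks_elapsed: float = 0.0
) -> LabelVolume:
    """Thin cartilage within the lesion footprint to the residual thickness.

    Voxels outside the lesion columns are untouched; thinning only removes
    cartilage (never adds), keeping the voxels adjacent to the bone surface.
    """
    cart_label = (
        FEMORAL_CARTILAGE if lesion.target_region.startswith("femoral") else TIBIAL_CARTILAGE
    )
    if volume.count(cart_label) == 0:
        raise ValueError(
            f"target region {lesion.target_region!r}: cartilage label {cart_label} "
            "is empty in this volume"
        )
    radius = lesion.radius_at(weeks_elapsed)
    cols = _lesion_columns(volume, lesion, radius)
    n_res = _column_voxels(lesion.residual_thickness_mm, volume.spacing_mm[2])

    data = volume.data.copy()
    cart = data == cart_label
    # rank of each cartilage voxel within its column, counted from the bone
    # surface outward (femoral cartilage hangs below the femur: rank by
    # ascending slice; tibial cartilage sits above the tibia: descending)
    if cart_label == FEMORAL_CARTILAGE:
        rank = np.cumsum(cart, axis=2) - 1
    else:
        rank = np.cumsum(cart[:, :, ::-1], axis=2)[:, :, ::-1] - 1
    remove = cart & cols[:, :, None] & (rank >= n_res)
    data[remove] = BACKGROUND
    out = LabelVolume(data=data, spacing_mm=volume.spacing_mm, knee_side=volume.knee_side)
    out.canonical = volume.canonical
    out.alignment = dict(volume.alignment)
    return out


def add_scan_noise(
    volume: LabelVolume, sd_mm: float, rng: np.random.Generator
) -> LabelVolume:
    """Duplicate-scan noise: jitter the outer cartilage boundary per column.

    Each surface column's cartilage depth changes by round(N(0, sd)/dz)
    voxels, independently per scan, emulating the small inter-scan
    differences attributed to patient repositioning.  Columns only grow into
    background voxels.
    """
    if sd_mm < 0:
        raise ValueError("sd_mm must be >= 0")
    if sd_mm == 0:
        return volume.copy()
    dz = volume.spacing_mm[2]
    data = volume.data.copy()
    for cart_label, outward in ((FEMORAL_CARTILAGE, +1), (TIBIAL_CARTILAGE, -1)):
        cart = data == cart_label
        if not cart.any():
            continue
        has = cart.any(axis=2)
        delta = np.round(rng.normal(0.0, sd_mm, size=has.shape) / dz).astype(int)
        delta[~has] = 0
        K = np.arange(data.shape[2])[None, None, :]
        if outward > 0:
            rank = np.cumsum(cart, axis=2) - 1
            outer = np.where(has, np.max(np.where(cart, K, -1), axis=2), -1)
        else:
            rank = np.cumsum(cart[:, :, ::-1], axis=2)[:, :, ::-1] - 1
            outer = np.where(has, np.min(np.where(cart, K, data.shape[2]), axis=2), data.shape[2])
        n_col = cart.sum(axis=2)
        n_new = np.maximum(n_col + delta, 0)
        shrink = cart & ((rank) >= n_new[:, :, None])
        data[shrink] = BACKGROUND
        grow = np.maximum(delta, 0)
        for step in range(1, int(grow.max(initial=0)) + 1):
            sel = grow >= step
            target = outer + outward * step
            ok = sel & (target >= 0) & (target < data.shape[2])
            rr, cc = np.nonzero(ok)
            tt = target[ok]
            bg = data[rr, cc, tt] == BACKGROUND
            data[rr[bg], cc[bg], tt[bg]] = cart_label
    out = LabelVolume(data=data, spacing_mm=volume.spacing_mm, knee_side=volume.knee_side)
    out.canonical = volume.canonical
    return out


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _quadrant_masks(footprint: np.ndarray) -> dict[str, np.ndarray]:
    """Bounding-box midline quadrants, mirroring the ROI construction rule."""
    rows, cols = np.nonzero(footprint)
    rmin, rmax = rows.min(), rows.max()
    cmin, cmax = cols.min(), cols.max()
    r_split = rmin + (rmax - rmin + 1) // 2
    c_split = cmin + (cmax - cmin + 1) // 2
    rr = np.arange(footprint.shape[0])[:, None]
    cc = np.arange(footprint.shape[1])[None, :]
    ant, med = rr < r_split, cc < c_split
    return {
        "anteromedial": footprint & ant & med,
        "anterolateral": footprint & ant & ~med,
        "posteromedial": footprint & ~ant & med,
        "posterolateral": footprint & ~ant & ~med,
    }


def truth_metrics(
    spec: PhantomSpec,
    lesion: Optional[LesionSpec] = None,
    weeks_elapsed: float = 0.0,
    threshold_mm: float = 1.5,
) -> pd.DataFrame:
    """Noiseless region metrics computed from the 2D generative geometry.

    Independent of the 3D measurement pipeline: works entirely on planar
    footprint masks and the closed-form column thicknesses.  Used as ground
    truth for parameter-recovery tests.  Right-knee orientation (metrics are
    mirror-invariant by construction).
    """
    lay = _layout(spec)
    dz = spec.spacing_mm[2]
    R, C = np.meshgrid(lay.r_mm, lay.c_mm, indexing="ij")

    rows = []
    for bone, footprint, n_vox in (
        ("femur", lay.fem_footprint, lay.fem_thickness_vox),
        ("tibia", lay.tib_footprint, lay.tib_thickness_vox),
    ):
        measured = np.where(n_vox > 0, (n_vox + 1) * dz, 0.0)
        if lesion is not None and lesion.target_region.startswith(bone[:3]):
            radius = lesion.radius_at(weeks_elapsed)
            rc, cc = lesion.center_mm
            inside = (R - rc) ** 2 + (C - cc) ** 2 <= radius**2
            n_res = _column_voxels(lesion.residual_thickness_mm, dz)
            n_eff = np.where(inside, np.minimum(n_vox, n_res), n_vox)
            measured = np.where(n_eff > 0, (n_eff + 1) * dz, 0.0)
        measured = np.where(footprint, measured, 0.0)
        if bone == "femur":
            masks = _quadrant_masks(lay.fem_footprint)
            regions = {name: masks[name] for name in masks}
        else:
            cols = np.nonzero(lay.tib_footprint)[1]
            c_split = cols.min() + (cols.max() - cols.min() + 1) // 2
            ccg = np.arange(lay.tib_footprint.shape[1])[None, :]
            regions = {
                "medial": lay.tib_footprint & (ccg < c_split),
                "lateral": lay.tib_footprint & (ccg >= c_split),
            }
        for region, mask in regions.items():
            vals = measured[mask]
            rows.append((bone, region, "area_ratio", float((vals >= threshold_mm).mean())))
            rows.append((bone, region, "mean_thickness_mm", float(vals.mean())))
    return pd.DataFrame(rows, columns=["bone", "region", "metric", "value"])


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionDistribution:
    """Population distribution of lesion parameters for cohort simulation."""

    target_region: str = "femoral_posteromedial"
    center_mm: tuple[float, float] = (4.0, -5.5)
    center_jitter_sd_mm: float = 1.0
    radius_range_mm: tuple[float, float] = (2.5, 4.0)
    growth_rate_mm_per_week: tuple[float, float] = (0.04, 0.06)
    residual_thickness_mm: float = 1.0

    def draw(self, rng: np.random.Generator) -> LesionSpec:
        dr, dc = rng.normal(0.0, self.center_jitter_sd_mm, size=2)
        return LesionSpec(
            target_region=self.target_region,
            center_mm=(self.center_mm[0] + dr, self.center_mm[1] + dc),
            radius_mm=float(rng.uniform(*self.radius_range_mm)),
            residual_thickness_mm=self.residual_thickness_mm,
            growth_rate_mm_per_week=float(rng.uniform(*self.growth_rate_mm_per_week)),
        )


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort: noiseless region metrics and the
    per-patient lesion parameters that generated them."""

    table: pd.DataFrame  # patient_id, timepoint_weeks, bone, region, metric, value
    lesions: dict[str, LesionSpec]
    timepoints_weeks: tuple[float, ...]
    growth_stop_week: Optional[float]


def simulate_cohort(
    n_patients: int = 8,
    timepoints_weeks: Sequence[float] = (-30.0, -15.0, -1.0, 30.0),
    progression: Optional[LesionDistribution] = None,
    scan_noise_sd_mm: float = 0.0,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
    growth_stop_week: Optional[float] = None,
    threshold_mm: float = 1.5,
) -> tuple[dict[tuple[str, float], LabelVolume], CohortTruth]:
    """Simulate a longitudinal cohort of lesioned knee phantoms.

    Lesion radii grow linearly from the first timepoint; if
    ``growth_stop_week`` is set, growth halts there (emulating a treatment
    that arrests progression).  Scan noise perturbs each scan independently;
    the truth table is always noiseless.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    tps = [float(w) for w in timepoints_weeks]
    if tps != sorted(tps):
        raise ValueError("timepoints_weeks must be sorted ascending")
    spec = base_spec or PhantomSpec()
    dist = progression or LesionDistribution()
    base = make_knee_phantom(spec)
    streams = np.random.SeedSequence(seed).spawn(n_patients)

    volumes: dict[tuple[str, float], LabelVolume] = {}
    truth_rows = []
    lesions: dict[str, LesionSpec] = {}
    w0 = tps[0]
    for i, ss in enumerate(streams):
        pid = f"{i + 1:02d}"
        rng = np.random.default_rng(ss)
        lesion = dist.draw(rng)
        lesions[pid] = lesion
        for w in tps:
            w_eff = min(w, growth_stop_week) if growth_stop_week is not None else w
            elapsed = max(0.0, w_eff - w0)
            vol = apply_lesion(base, lesion, weeks_elapsed=elapsed)
            if scan_noise_sd_mm > 0:
                vol = add_scan_noise(vol, scan_noise_sd_mm, rng)
            volumes[(pid, w)] = vol
            tm = truth_metrics(spec, lesion, weeks_elapsed=elapsed, threshold_mm=threshold_mm)
            for _, row in tm.iterrows():
                truth_rows.append((pid, w, row.bone, row.region, row.metric, row.value))
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "timepoint_weeks", "bone", "region", "metric", "value"],
    )
    return volumes, CohortTruth(
        table=truth, lesions=lesions, timepoints_weeks=tuple(tps),
        growth_stop_week=growth_stop_week,
    )


# ---------------------------------------------------------------------------
# clinical scores
# ---------------------------------------------------------------------------

#: instrument -> (lo, hi, direction, baseline mean, baseline sd, visit sd)
#: direction +1: higher is better (improvement raises the score); -1: pain
#: scale where improvement lowers it
INSTRUMENTS = {
    "lysholm_total": (0.0, 100.0, +1, 45.0, 12.0, 5.0),
    "koos_pain": (0.0, 100.0, +1, 55.0, 12.0, 5.0),
    "koos_adl": (0.0, 100.0, +1, 60.0, 12.0, 5.0),
    "nrs_walking": (0.0, 10.0, -1, 5.0, 1.5, 0.8),
}


def simulate_scores(
    n_patients: int = 8,
    visits_weeks: Sequence[float] = (-30, -15, -5, -2, 0, 5, 10, 15, 20, 25, 30),
    effect_onset_week: float = 0.0,
    effect_size: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate bounded clinical-score trajectories.

    Visits at or before the onset week fluctuate around a stable per-patient
    baseline; later visits shift by ``effect_size`` (in 0-100 scale units;
    scaled to the instrument range, signed by its direction).  Scores are
    evaluated before any treatment given at the onset visit, so the shift
    applies strictly after it.  Values are rounded to instrument resolution
    and clipped to the instrument range.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    rows = []
    for i, ss in enumerate(streams):
        pid = f"{i + 1:02d}"
        rng = np.random.default_rng(ss)
        for name, (lo, hi, direction, bmean, bsd, vsd) in INSTRUMENTS.items():
            baseline = np.clip(rng.normal(bmean, bsd), lo, hi)
            shift = direction * effect_size * (hi - lo) / 100.0
            for w in visits_weeks:
                val = baseline + rng.normal(0.0, vsd)
                if w > effect_onset_week:
                    val += shift
                if hi <= 10:  # NRS-style scale: half-point resolution
                    val = round(val * 2.0) / 2.0
                else:
                    val = round(val)
                rows.append((pid, float(w), name, float(np.clip(val, lo, hi))))
    return pd.DataFrame(rows, columns=["patient_id", "visit_week", "instrument", "value"])
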