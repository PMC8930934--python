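"""Voxel-based 3D morphometry of meniscus segmentations.

Quantitative measures of meniscus *position* (extrusion distances, tibial
plateau coverage, extrusion area) and *morphology* (volume, height, width)
are computed from a voxelized binary segmentation of one femorotibial
compartment (medial or lateral) on a coronal slice stack.

Conventions
-----------
The meniscus mask is a 3D boolean array with axes

    ``(y, z, x)`` = (coronal slice, anterior -> posterior;
                     inferior -> superior;
                     internal -> external medio-lateral)

"external" means away from the knee's midline for the given compartment, so
increasing ``x`` always points in the direction in which the meniscus can
extrude.  The tibial plateau is represented by its 2D footprint over
``(y, x)`` — the total area of subchondral bone (cartilage surface including
denuded areas, ACdAB) projected onto the tibial plane.

Extrusion is measured per coronal slice along the in-slice medio-lateral
axis as the signed distance between the external margin of the tibial
plateau and the external margin of the tibial surface of the meniscus;
positive values mean the meniscus protrudes beyond the plateau margin.
Negative values are meaningful (the meniscus margin can sit internal to the
plateau margin, typical laterally) and are never truncated.

Margins are the external-most occupied cell; no sub-voxel contour fitting
is attempted, so every measure is exactly reproducible by voxel/cell
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "MorphometryError",
    "EmptyStructureError",
    "UndefinedSliceError",
    "UndefinedMeasureError",
    "SegmentedCompartment",
    "SliceMeasures",
    "MeniscusMeasures",
    "MEASURE_FIELDS",
    "meniscus_tibial_footprint",
    "extrusion_distance_slice",
    "central_window",
    "mean_extrusion",
    "max_extrusion",
    "coverage_pct",
    "extrusion_area_pct",
    "height_stats",
    "width_mean",
    "volume_ml",
    "restrict_to_slices",
    "compute_all_measures",
    "slice_measures",
]

DEFAULT_SPACING = (1.5, 0.37, 0.37)  # (slice thickness, z, x) in mm — DESS coronal

Window = Literal["all", "central5", "central1"]


class MorphometryError(ValueError):
    """Base class for morphometry failures."""


class EmptyStructureError(MorphometryError):
    """A required structure (meniscus or plateau) has no voxels/cells."""


class UndefinedSliceError(MorphometryError):
    """A per-slice measure was requested on a slice lacking a structure."""


class UndefinedMeasureError(MorphometryError):
    """An aggregate measure has no eligible slices to average over."""


@dataclass(frozen=True)
class MeniscusMeasures:
    """The aggregate position and size measures of one meniscus.

    Units: mm for distances/heights/widths, ml for volume, percent for the
    area fractions.  Extrusion values are signed.
    """

    extrusion_area_pct: float
    mean_extrusion_mm: float
    max_extrusion_mm: float
    mean_extrusion_central5_mm: float
    mean_extrusion_central1_mm: float
    coverage_pct: float
    width_mean_mm: float
    height_mean_mm: float
    height_max_mm: float
    volume_ml: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Canonical field order of :class:`MeniscusMeasures`.
MEASURE_FIELDS: tuple[str, ...] = tuple(f.name for f in fields(MeniscusMeasures))


@dataclass(frozen=True)
class SliceMeasures:
    """Per-coronal-slice decomposition underlying the aggregate measures."""

    slice_index: int
    extrusion_mm: float | None
    width_mm: float
    plateau_present: bool
    meniscus_present: bool


@dataclass
class SegmentedCompartment:
    """Voxel grid of one femorotibial compartment.

    Parameters
    ----------
    meniscus_mask
        3D boolean array, axes ``(y, z, x)`` (see module docstring).
    plateau_footprint
        2D boolean array over ``(y, x)``: the tibial plateau area (ACdAB)
        projected onto the tibial plane.  Must share the (y, x) extent of
        the meniscus mask.
    spacing
        ``(slice_thickness_mm, z_mm, x_mm)``; all components > 0.
    compartment
        ``"medial"`` or ``"lateral"`` — metadata only; the external
        direction is already encoded in the x axis orientation.
    """

    meniscus_mask: np.ndarray
    plateau_footprint: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    compartment: str = "medial"

    def __post_init__(self) -> None:
        self.meniscus_mask = np.asarray(self.meniscus_mask, dtype=bool)
        self.plateau_footprint = np.asarray(self.plateau_footprint, dtype=bool)
        if self.meniscus_mask.ndim != 3:
            raise MorphometryError(
                f"meniscus_mask must be 3D (y, z, x), got ndim={self.meniscus_mask.ndim}"
            )
        if self.plateau_footprint.ndim != 2:
            raise MorphometryError(
                f"plateau_footprint must be 2D (y, x), got ndim={self.plateau_footprint.ndim}"
            )
        ny, _, nx = self.meniscus_mask.shape
        if self.plateau_footprint.shape != (ny, nx):
            raise MorphometryError(
                "plateau_footprint shape "
                f"{self.plateau_footprint.shape} does not match meniscus (y, x) "
                f"extent {(ny, nx)}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MorphometryError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.compartment not in ("medial", "lateral"):
            raise MorphometryError(f"compartment must be medial|lateral, got {self.compartment!r}")

    @property
    def n_slices(self) -> int:
        return self.meniscus_mask.shape[0]

    @property
    def slice_thickness_mm(self) -> float:
        return self.spacing[0]

    @property
    def z_spacing_mm(self) -> float:
        return self.spacing[1]

    @property
    def x_spacing_mm(self) -> float:
        return self.spacing[2]

    def meniscus_slices(self) -> np.ndarray:
        """Indices of coronal slices containing at least one meniscus voxel."""
        return np.flatnonzero(self.meniscus_mask.any(axis=(1, 2)))


# ---------------------------------------------------------------------------
# Footprints and per-slice primitives
# ---------------------------------------------------------------------------

def meniscus_tibial_footprint(seg: SegmentedCompartment) -> np.ndarray:
    """Tibial-surface footprint of the meniscus: per-(y, x) column occupancy.

    A footprint cell is set iff the column holds at least one meniscus
    voxel; the z extent collapses.  Raises :class:`EmptyStructureError` on
    an empty mask.
    """
    if not seg.meniscus_mask.any():
        raise EmptyStructureError("no meniscus voxels in mask")
    return seg.meniscus_mask.any(axis=1)


def extrusion_distance_slice(seg: SegmentedCompartment, y: int) -> float:
    """Signed extrusion distance (mm) in coronal slice ``y``.

    ``(x_max_meniscus − x_max_plateau) × x_spacing`` where ``x_max`` is the
    external-most occupied cell index of each footprint in that slice.
    """
    men_row = seg.meniscus_mask[y].any(axis=0)
    plat_row = seg.plateau_footprint[y]
    if not men_row.any() or not plat_row.any():
        raise UndefinedSliceError(
            f"slice {y} lacks {'meniscus' if not men_row.any() else 'plateau'}; "
            "extrusion undefined"
        )
    x_men = int(np.flatnonzero(men_row)[-1])
    x_plat = int(np.flatnonzero(plat_row)[-1])
    return (x_men - x_plat) * seg.x_spacing_mm


def slice_measures(seg: SegmentedCompartment, y: int) -> SliceMeasures:
    """Per-slice measures for slice ``y`` (extrusion None when undefined)."""
    men_row = seg.meniscus_mask[y].any(axis=0)
    plat_present = bool(seg.plateau_footprint[y].any())
    men_present = bool(men_row.any())
    width = 0.0
    if men_present:
        xs = np.flatnonzero(men_row)
        width = (int(xs[-1]) - int(xs[0]) + 1) * seg.x_spacing_mm
    extrusion = (
        extrusion_distance_slice(seg, y) if (men_present and plat_present) else None
    )
    return SliceMeasures(
        slice_index=int(y),
        extrusion_mm=extrusion,
        width_mm=width,
        plateau_present=plat_present,
        meniscus_present=men_present,
    )


def central_window(seg: SegmentedCompartment, n_slices: int) -> list[int]:
    """Indices of the central ``n_slices`` coronal slices of the meniscus.

    The central index is ``floor((y_first + y_last) / 2)`` over the slices
    containing meniscus; for an even occupied-slice count this picks the
    anterior of the two middle slices.  The symmetric window is intersected
    with the slices that actually contain meniscus.
    """
    if n_slices not in (1, 5):
        raise MorphometryError(f"n_slices must be 1 or 5, got {n_slices}")
    occ = seg.meniscus_slices()
    if occ.size == 0:
        raise EmptyStructureError("no meniscus voxels; central window undefined")
    c = (int(occ[0]) + int(occ[-1])) // 2
    half = (n_slices - 1) // 2
    occupied = set(int(i) for i in occ)
    return [y for y in range(c - half, c + half + 1) if y in occupied]


# ---------------------------------------------------------------------------
# Aggregate position measures
# ---------------------------------------------------------------------------

def _eligible_extrusions(seg: SegmentedCompartment, ys: Iterator[int]) -> list[float]:
    vals = []
    for y in ys:
        try:
            vals.append(extrusion_distance_slice(seg, y))
        except UndefinedSliceError:
            continue  # excluded from aggregation, never zero-imputed
    return vals


def mean_extrusion(seg: SegmentedCompartment, window: Window = "all") -> float:
    """Mean signed extrusion (mm) over eligible slices of the given window.

    Eligible slices are those where both plateau and meniscus are present;
    slices lacking either are excluded from the average.  ``window`` is
    ``"all"`` (entire meniscus), ``"central5"`` or ``"central1"``.
    """
    if window == "all":
        ys = seg.meniscus_slices().tolist()
    elif window == "central5":
        ys = central_window(seg, 5)
    elif window == "central1":
        ys = central_window(seg, 1)
    else:
        raise MorphometryError(f"unknown window {window!r}")
    vals = _eligible_extrusions(seg, iter(ys))
    if not vals:
        raise UndefinedMeasureError(f"no slice in window {window!r} has both structures")
    return float(np.mean(vals))


def max_extrusion(seg: SegmentedCompartment) -> float:
    """Maximum signed per-slice extrusion (mm) over all eligible slices."""
    vals = _eligible_extrusions(seg, iter(seg.meniscus_slices().tolist()))
    if not vals:
        raise UndefinedMeasureError("no slice has both structures")
    return float(np.max(vals))


def coverage_pct(seg: SegmentedCompartment) -> float:
    """Percentage of the tibial plateau covered by the meniscus footprint."""
    if not seg.plateau_footprint.any():
        raise EmptyStructureError("empty plateau footprint")
    men_fp = meniscus_tibial_footprint(seg)
    n_plat = int(seg.plateau_footprint.sum())
    n_cov = int((seg.plateau_footprint & men_fp).sum())
    return 100.0 * n_cov / n_plat


def extrusion_area_pct(seg: SegmentedCompartment) -> float:
    """Percent of the tibial meniscus surface not covering the plateau."""
    men_fp = meniscus_tibial_footprint(seg)
    n_men = int(men_fp.sum())
    n_out = int((men_fp & ~seg.plateau_footprint).sum())
    return 100.0 * n_out / n_men


# ---------------------------------------------------------------------------
# Morphology measures
# ---------------------------------------------------------------------------

def height_stats(seg: SegmentedCompartment) -> tuple[float, float]:
    """(mean, max) meniscus height (thickness) in mm over occupied columns.

    Column height is the voxel count along z times the z spacing — robust
    to where the meniscus sits in z and to internal representation.
    """
    counts = seg.meniscus_mask.sum(axis=1)  # (y, x) voxel counts
    occupied = counts[counts > 0]
    if occupied.size == 0:
        raise EmptyStructureError("no meniscus voxels")
    heights = occupied * seg.z_spacing_mm
    return float(heights.mean()), float(heights.max())


def width_mean(seg: SegmentedCompartment) -> float:
    """Mean meniscus width (mm): per-slice medio-lateral extent, averaged."""
    occ = seg.meniscus_slices()
    if occ.size == 0:
        raise EmptyStructureError("no meniscus voxels")
    widths = [slice_measures(seg, int(y)).width_mm for y in occ]
    return float(np.mean(widths))


def volume_ml(seg: SegmentedCompartment) -> float:
    """Meniscus volume in ml (voxel count × voxel volume; empty mask → 0)."""
    voxel_mm3 = seg.spacing[0] * seg.spacing[1] * seg.spacing[2]
    return float(seg.meniscus_mask.sum()) * voxel_mm3 / 1000.0


# ---------------------------------------------------------------------------
# Windowing and the full measure set
# ---------------------------------------------------------------------------

def restrict_to_slices(seg: SegmentedCompartment, ys: Sequence[int]) -> SegmentedCompartment:
    """Sub-compartment containing only the given coronal slices (in order)."""
    idx = np.asarray(sorted(int(y) for y in ys), dtype=int)
    if idx.size == 0:
        raise MorphometryError("cannot restrict to an empty slice set")
    return SegmentedCompartment(
        meniscus_mask=seg.meniscus_mask[idx],
        plateau_footprint=seg.plateau_footprint[idx],
        spacing=seg.spacing,
        compartment=seg.compartment,
    )


def compute_all_measures(seg: SegmentedCompartment) -> MeniscusMeasures:
    """All aggregate measures of one compartment, deterministically.

    Component errors propagate: a compartment for which any measure is
    undefined yields no partial result.
    """
    h_mean, h_max = height_stats(seg)
    return MeniscusMeasures(
        extrusion_area_pct=extrusion_area_pct(seg),
        mean_extrusion_mm=mean_extrusion(seg, "all"),
        max_extrusion_mm=max_extrusion(seg),
        mean_extrusion_central5_mm=mean_extrusion(seg, "central5"),
        mean_extrusion_central1_mm=mean_extrusion(seg, "central1"),
        coverage_pct=coverage_pct(seg),
        width_mean_mm=width_mean(seg),
        height_mean_mm=h_mean,
        height_max_mm=h_max,
        volume_ml=volume_ml(seg),
    )
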