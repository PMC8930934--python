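"""File formats and configuration.

Masks travel as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) label
volumes with array axes ``(y, z, x)`` matching the in-memory convention.
One label volume encodes both structures: label 1 = meniscus only,
2 = tibial plateau footprint only (stored at the inferior z layer),
3 = both (meniscus voxel at the inferior layer of a plateau column) — so a
write → read round trip is exact.  Voxel spacing comes from the image
header and can be overridden from the config.

Cohort tables are UTF-8 comma-separated CSV with a mandatory header row
and "." decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .morphometry import DEFAULT_SPACING, MEASURE_FIELDS, SegmentedCompartment

__all__ = [
    "IOError_",
    "ConfigError",
    "PipelineConfig",
    "DEFAULT_LABEL_MAP",
    "read_mask",
    "write_mask",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_measures_csv",
]

DEFAULT_LABEL_MAP = {"meniscus": 1, "plateau": 2, "both": 3}

NIFTI_SUFFIXES = (".nii", ".nii.gz")
METAIMAGE_SUFFIXES = (".mha", ".mhd")


class IOError_(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated run configuration for the command-line pipeline."""

    spacing: tuple[float, float, float] | None = None  # override header spacing
    label_map: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    sdc_mftc_um: float = 102.0
    sdc_lftc_um: float = 92.0
    sdc_minjsw_um: float = 328.0
    height_caliper_cm: float = 3.0
    bmi_caliper: float = 5.0
    womac_caliper: float = 5.0
    seed: int = 0
    n_pairs: int = 37
    out_dir: str = "."

    def __post_init__(self) -> None:
        errors = []
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
            if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
                errors.append(f"spacing: must be 3 positive lengths, got {self.spacing}")
        for name in ("sdc_mftc_um", "sdc_lftc_um", "sdc_minjsw_um",
                     "height_caliper_cm", "bmi_caliper", "womac_caliper"):
            if getattr(self, name) <= 0:
                errors.append(f"{name}: must be > 0, got {getattr(self, name)}")
        required = set(DEFAULT_LABEL_MAP)
        if set(self.label_map) != required:
            errors.append(f"label_map: keys must be {sorted(required)}")
        elif len(set(self.label_map.values())) != 3:
            errors.append("label_map: labels must be distinct")
        if self.n_pairs < 1:
            errors.append(f"n_pairs: must be >= 1, got {self.n_pairs}")
        if errors:
            raise ConfigError("invalid configuration: " + "; ".join(errors))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} does not hold a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }


# ---------------------------------------------------------------------------
# Mask I/O
# ---------------------------------------------------------------------------

def _encode_labels(seg: SegmentedCompartment, label_map: dict) -> np.ndarray:
    vol = np.zeros(seg.meniscus_mask.shape, dtype=np.uint8)
    vol[seg.meniscus_mask] = label_map["meniscus"]
    # plateau footprint lives at the inferior (z=0) layer; columns where a
    # meniscus voxel already occupies that cell get the combined label
    plate = seg.plateau_footprint
    bottom = vol[:, 0, :]
    both = plate & (bottom == label_map["meniscus"])
    only = plate & ~both
    bottom[only] = label_map["plateau"]
    bottom[both] = label_map["both"]
    return vol


def _decode_labels(
    vol: np.ndarray,
    spacing: tuple[float, float, float],
    label_map: dict,
    compartment: str,
) -> SegmentedCompartment:
    if vol.ndim != 3:
        raise IOError_(f"label volume must be 3D, got ndim={vol.ndim}")
    meniscus = (vol == label_map["meniscus"]) | (vol == label_map["both"])
    plateau = ((vol == label_map["plateau"]) | (vol == label_map["both"])).any(axis=1)
    if not plateau.any():
        raise IOError_(
            f"no plateau voxels (label {label_map['plateau']}/{label_map['both']}) in volume"
        )
    if not meniscus.any():
        raise IOError_(f"no meniscus voxels (label {label_map['meniscus']}) in volume")
    return SegmentedCompartment(meniscus, plateau, spacing=spacing, compartment=compartment)


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def write_mask(
    seg: SegmentedCompartment,
    path: str | Path,
    label_map: dict = DEFAULT_LABEL_MAP,
) -> None:
    """Write one compartment as a label volume (format from the suffix)."""
    path = Path(path)
    vol = _encode_labels(seg, label_map)
    suffix = _suffix(path)
    if suffix in NIFTI_SUFFIXES:
        affine = np.diag([seg.spacing[0], seg.spacing[1], seg.spacing[2], 1.0])
        nib.save(nib.Nifti1Image(vol, affine), str(path))
    elif suffix in METAIMAGE_SUFFIXES:
        # SimpleITK reverses index order: array (y, z, x) -> image size (x, z, y)
        img = sitk.GetImageFromArray(vol)
        img.SetSpacing((seg.spacing[2], seg.spacing[1], seg.spacing[0]))
        sitk.WriteImage(img, str(path))
    else:
        raise IOError_(f"unsupported mask format {suffix!r} for {path}")


def read_mask(
    path: str | Path,
    label_map: dict = DEFAULT_LABEL_MAP,
    spacing_override: tuple[float, float, float] | None = None,
    compartment: str = "medial",
) -> SegmentedCompartment:
    """Read a label volume into a SegmentedCompartment.

    Spacing is taken from the header unless ``spacing_override`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise IOError_(f"mask file not found: {path}")
    suffix = _suffix(path)
    if suffix in NIFTI_SUFFIXES:
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[0]), float(zooms[1]), float(zooms[2]))
    elif suffix in METAIMAGE_SUFFIXES:
        img = sitk.ReadImage(str(path))
        vol = sitk.GetArrayFromImage(img)  # (y, z, x) given our write convention
        sp = img.GetSpacing()  # (x, z, y)
        spacing = (float(sp[2]), float(sp[1]), float(sp[0]))
    else:
        raise IOError_(f"unsupported mask format {suffix!r} for {path}")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)  # type: ignore[assignment]
    return _decode_labels(np.asarray(vol), spacing, label_map, compartment)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "knee_id" not in df.columns:
        raise IOError_(f"cohort CSV {path} lacks a knee_id column")
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_measures_csv(rows: list[dict], path: str | Path) -> None:
    """One row per (knee, compartment); measures at 3 decimal places."""
    lead = ["source", "compartment"]
    df = pd.DataFrame(rows, columns=lead + list(MEASURE_FIELDS))
    df.to_csv(path, index=False, float_format="%.3f")
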