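"""Synthetic data: voxel phantoms with analytic ground truth and cohort tables.

Two phantom families exercise the morphometry code without any imaging
data:

* **Box phantoms** — rectangular plateau and meniscus footprints with a
  per-slice external offset.  Every measure has a pencil-and-paper closed
  form, so morphometry output can be checked exactly.
* **C phantoms** — a C-shaped wedge meniscus (annulus sector whose height
  grows linearly from the inner to the outer rim) over a disc-shaped
  plateau, rasterized at a requested voxel spacing.  Reference values come
  from rasterizing the same continuous geometry on a several-fold finer
  grid; the phantom is a geometric idealization, not an anatomical model.

The **cohort simulator** draws matched case-control tables whose group
means/SDs follow the published summary statistics of a 37-pair structural
progression study: covariates (age, height, BMI, WOMAC pain, sex, KLG),
baseline and 12-month cartilage-thickness / minJSW values, and the per-knee
meniscus measures for both compartments, including central-slice surrogate
variants correlated with the entire-meniscus values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import (
    DEFAULT_SPACING,
    MeniscusMeasures,
    SegmentedCompartment,
    compute_all_measures,
)

__all__ = [
    "PhantomError",
    "BoxPhantomSpec",
    "CPhantomSpec",
    "CohortSimSpec",
    "SimulatedCohort",
    "make_box_phantom",
    "make_c_phantom",
    "c_phantom_analytic_volume_ml",
    "simulate_cohort",
    "simulate_test_retest_differences",
    "measures_frame",
    "central_surrogate_frames",
    "MEDIAL_MEASURE_PARAMS",
    "LATERAL_MEASURE_PARAMS",
    "BASELINE_PARAMS_MM",
    "CHANGE_PARAMS_UM",
    "COVARIATE_PARAMS",
]


class PhantomError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Box phantom — exact closed forms
# ---------------------------------------------------------------------------

@dataclass
class BoxPhantomSpec:
    """Rectangular phantom: plateau cells x ∈ [0, plateau_extent_x),
    meniscus of ``meniscus_extent_x`` cells whose external margin sits
    ``external_offset`` cells beyond the plateau margin (may vary per
    slice, may be negative)."""

    n_slices: int = 11
    plateau_extent_x: int = 20
    meniscus_extent_x: int = 8
    external_offset: int | Sequence[int] = 2
    meniscus_height: int = 4
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def offsets(self) -> list[int]:
        off = self.external_offset
        if np.isscalar(off):
            return [int(off)] * self.n_slices
        off = [int(o) for o in off]
        if len(off) != self.n_slices:
            raise PhantomError(
                f"external_offset length {len(off)} != n_slices {self.n_slices}"
            )
        return off

    def validate(self) -> None:
        if self.n_slices < 1 or self.plateau_extent_x < 1 or self.meniscus_extent_x < 1:
            raise PhantomError("extents and slice count must be >= 1")
        if self.meniscus_height < 1:
            raise PhantomError("meniscus_height must be >= 1 voxel")
        for off in self.offsets():
            if self.plateau_extent_x + off - self.meniscus_extent_x < 0:
                raise PhantomError(
                    "meniscus extends past the internal grid edge "
                    f"(offset {off})"
                )


def make_box_phantom(
    spec: BoxPhantomSpec,
) -> tuple[SegmentedCompartment, MeniscusMeasures]:
    """Build the box phantom and its closed-form ground-truth measures."""
    spec.validate()
    offs = spec.offsets()
    P, E, H = spec.plateau_extent_x, spec.meniscus_extent_x, spec.meniscus_height
    dy, dz, dx = spec.spacing
    nx = P + max(max(offs), 0) + 2
    ny = spec.n_slices
    nz = H + 1

    meniscus = np.zeros((ny, nz, nx), dtype=bool)
    plateau = np.zeros((ny, nx), dtype=bool)
    for y, off in enumerate(offs):
        plateau[y, :P] = True
        x_hi = P - 1 + off  # external meniscus margin
        meniscus[y, :H, x_hi - E + 1: x_hi + 1] = True
    seg = SegmentedCompartment(meniscus, plateau, spacing=spec.spacing)

    # closed forms
    extrusions = [off * dx for off in offs]
    c = (ny - 1) // 2  # occupied slices are 0..ny-1
    win5 = [y for y in range(c - 2, c + 3) if 0 <= y < ny]
    overlap = 0
    for off in offs:
        a, b = P + off - E, P - 1 + off
        overlap += max(0, min(b, P - 1) - max(a, 0) + 1)
    men_cells = ny * E
    truth = MeniscusMeasures(
        extrusion_area_pct=100.0 * (men_cells - overlap) / men_cells,
        mean_extrusion_mm=float(np.mean(extrusions)),
        max_extrusion_mm=float(np.max(extrusions)),
        mean_extrusion_central5_mm=float(np.mean([extrusions[y] for y in win5])),
        mean_extrusion_central1_mm=extrusions[c],
        coverage_pct=100.0 * overlap / (ny * P),
        width_mean_mm=E * dx,
        height_mean_mm=H * dz,
        height_max_mm=H * dz,
        volume_ml=men_cells * H * dy * dz * dx / 1000.0,
    )
    return seg, truth


# ---------------------------------------------------------------------------
# C phantom — continuous geometry rasterized at two resolutions
# ---------------------------------------------------------------------------

@dataclass
class CPhantomSpec:
    """C-shaped wedge meniscus over a disc plateau.

    The meniscus is the annulus sector ``inner_radius <= r <= outer_radius``
    of arc span ``arc_span_deg`` centred on the external (+x) direction,
    displaced externally by ``extrusion_shift_mm``; its height rises
    linearly from 0 at the inner rim to ``wedge_height_outer_mm`` at the
    outer rim.  The plateau footprint is the disc of ``plateau_radius_mm``
    centred at the origin.  With ``outer_radius == plateau_radius`` the
    central-slice extrusion equals ``extrusion_shift_mm`` exactly in the
    continuum.
    """

    inner_radius_mm: float = 8.0
    outer_radius_mm: float = 18.0
    arc_span_deg: float = 160.0
    wedge_height_outer_mm: float = 5.0
    extrusion_shift_mm: float = 0.0
    plateau_radius_mm: float = 18.0
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def validate(self) -> None:
        if not (self.outer_radius_mm > self.inner_radius_mm > 0):
            raise PhantomError("need outer_radius > inner_radius > 0")
        if not (0 < self.arc_span_deg <= 360):
            raise PhantomError("arc_span_deg must be in (0, 360]")
        if self.wedge_height_outer_mm <= 0 or self.plateau_radius_mm <= 0:
            raise PhantomError("heights and radii must be > 0")


def _rasterize_c(spec: CPhantomSpec, spacing: tuple[float, float, float]) -> SegmentedCompartment:
    dy, dz, dx = spacing
    L = max(spec.outer_radius_mm + spec.extrusion_shift_mm, spec.plateau_radius_mm) + 1.0
    ny = int(np.ceil(2 * L / dy))
    nx = int(np.ceil(2 * L / dx))
    nz = int(np.ceil(spec.wedge_height_outer_mm / dz)) + 1
    yc = (np.arange(ny) + 0.5) * dy - L  # cell centres in mm
    xc = (np.arange(nx) + 0.5) * dx - L
    zc = (np.arange(nz) + 0.5) * dz

    Y, X = np.meshgrid(yc, xc, indexing="ij")
    plateau = (X ** 2 + Y ** 2) <= spec.plateau_radius_mm ** 2

    Xs = X - spec.extrusion_shift_mm
    r = np.hypot(Xs, Y)
    half_span = np.deg2rad(spec.arc_span_deg) / 2.0
    theta = np.abs(np.arctan2(Y, Xs))  # 0 along +x (external)
    in_annulus = (
        (r >= spec.inner_radius_mm)
        & (r <= spec.outer_radius_mm)
        & (theta <= half_span)
    )
    frac = np.clip(
        (r - spec.inner_radius_mm) / (spec.outer_radius_mm - spec.inner_radius_mm),
        0.0, 1.0,
    )
    h = np.where(in_annulus, frac * spec.wedge_height_outer_mm, -1.0)  # (y, x)
    meniscus = zc[None, :, None] <= h[:, None, :]  # (y, z, x)
    return SegmentedCompartment(meniscus, plateau, spacing=spacing)


def make_c_phantom(
    spec: CPhantomSpec, oracle_refine: int = 4
) -> tuple[SegmentedCompartment, MeniscusMeasures]:
    """Rasterize the C phantom; reference measures from an
    ``oracle_refine``-fold finer grid of the same continuous geometry."""
    spec.validate()
    if oracle_refine < 2:
        raise PhantomError("oracle_refine must be >= 2")
    seg = _rasterize_c(spec, spec.spacing)
    fine_spacing = tuple(s / oracle_refine for s in spec.spacing)
    fine = _rasterize_c(spec, fine_spacing)  # type: ignore[arg-type]
    return seg, compute_all_measures(fine)


def c_phantom_analytic_volume_ml(spec: CPhantomSpec) -> float:
    """Closed-form continuum volume of the wedge: ∫∫ h(r) · r dr dθ."""
    a, b = spec.inner_radius_mm, spec.outer_radius_mm
    span = np.deg2rad(spec.arc_span_deg)
    # h(r) = H (r-a)/(b-a);  ∫_a^b h(r) r dr = H/(b-a) · (b³/3 − a b²/2 + a³/6)
    radial = (b ** 3 / 3 - a * b ** 2 / 2 + a ** 3 / 6) / (b - a)
    return span * spec.wedge_height_outer_mm * radial / 1000.0


# ---------------------------------------------------------------------------
# Cohort simulation — group parameters of the 37-pair progression study
# ---------------------------------------------------------------------------

#: (case (mean, sd), control (mean, sd)) per medial measure.
MEDIAL_MEASURE_PARAMS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "extrusion_area_pct": ((30.4, 13.4), (26.7, 17.3)),
    "mean_extrusion_mm": ((2.6, 1.1), (2.2, 1.2)),
    "max_extrusion_mm": ((4.8, 1.3), (4.0, 1.1)),
    "mean_extrusion_central5_mm": ((3.3, 1.4), (2.5, 1.5)),
    "mean_extrusion_central1_mm": ((3.4, 1.5), (2.4, 1.6)),
    "coverage_pct": ((34.6, 12.5), (36.8, 13.5)),
    "width_mean_mm": ((7.9, 1.7), (8.2, 1.8)),
    "height_mean_mm": ((2.8, 0.4), (2.6, 0.4)),
    "volume_ml": ((1.9, 0.7), (1.8, 0.7)),
}

LATERAL_MEASURE_PARAMS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "extrusion_area_pct": ((7.8, 7.3), (8.6, 10.6)),
    "mean_extrusion_mm": ((-0.3, 1.2), (-0.4, 1.2)),
    "max_extrusion_mm": ((2.0, 1.5), (1.8, 1.3)),
    "mean_extrusion_central5_mm": ((0.1, 1.4), (-0.2, 1.2)),
    "mean_extrusion_central1_mm": ((0.0, 1.4), (-0.2, 1.2)),
    "coverage_pct": ((54.1, 8.3), (51.7, 11.6)),
    "width_mean_mm": ((8.4, 1.1), (8.0, 1.3)),
    "height_mean_mm": ((2.7, 0.3), (2.4, 0.3)),
    "volume_ml": ((1.8, 0.4), (1.6, 0.5)),
}

#: Baseline cartilage thickness / minJSW in mm: (case, control) (mean, sd).
BASELINE_PARAMS_MM = {
    "minjsw": ((3.9, 1.4), (3.8, 1.3)),
    "mftc": ((3.2, 0.6), (3.3, 0.6)),
    "lftc": ((3.8, 0.5), (3.6, 0.5)),
}

#: 12-month change in µm (negative = loss): (case, control) (mean, sd).
CHANGE_PARAMS_UM = {
    "minjsw": ((-1052.0, 788.0), (88.0, 259.0)),
    "mftc": ((-254.0, 165.0), (21.0, 78.0)),
    "lftc": ((-39.0, 144.0), (19.0, 59.0)),
}

COVARIATE_PARAMS = {
    "age_years": ((64.7, 8.0), (64.6, 9.8)),
    "height_cm": ((165.6, 7.9), (165.6, 7.7)),
    "bmi_kg_m2": ((30.2, 4.6), (30.2, 4.4)),
    "womac_pain": ((3.5, 3.8), (2.8, 3.3)),
}

MALE_FRACTION = 13 / 37
KLG2_FRACTION = 21 / 37

#: Physical clipping bounds applied to simulated measures.
_MEASURE_BOUNDS = {
    "extrusion_area_pct": (0.0, 100.0),
    "coverage_pct": (0.0, 100.0),
    "width_mean_mm": (0.0, None),
    "height_mean_mm": (0.0, None),
    "volume_ml": (0.0, None),
}

_CENTRAL_MORPH_FIELDS = ("coverage_pct", "volume_ml", "height_mean_mm", "width_mean_mm")


@dataclass
class CohortSimSpec:
    """Parameters of the simulated matched cohort.

    Defaults reproduce the published group summary statistics: measure
    means/SDs per group and compartment, 12-month change distributions,
    covariate distributions, and the entire-vs-central correlations of the
    medial surrogate analysis (0.93 central 5 / 0.88 central slice for
    mean extrusion; 0.84 / 0.85 / 0.73 / 0.90 for coverage, volume, height
    and width vs the central 5).  Unprinted cross-measure correlations
    default to 0.
    """

    n_pairs: int = 37
    medial_params: dict = field(default_factory=lambda: dict(MEDIAL_MEASURE_PARAMS))
    lateral_params: dict = field(default_factory=lambda: dict(LATERAL_MEASURE_PARAMS))
    baseline_params: dict = field(default_factory=lambda: dict(BASELINE_PARAMS_MM))
    change_params: dict = field(default_factory=lambda: dict(CHANGE_PARAMS_UM))
    covariate_params: dict = field(default_factory=lambda: dict(COVARIATE_PARAMS))
    extrusion_corr_central5: float = 0.93
    extrusion_corr_central1: float = 0.88
    extrusion_corr_c5_c1: float = 0.95
    morph_corr_central5: dict = field(
        default_factory=lambda: {
            "coverage_pct": 0.84, "volume_ml": 0.85,
            "height_mean_mm": 0.73, "width_mean_mm": 0.90,
        }
    )
    change_corr_mftc_minjsw: float = 0.8

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise PhantomError("n_pairs must be >= 1")
        corrs = [
            self.extrusion_corr_central5, self.extrusion_corr_central1,
            self.extrusion_corr_c5_c1, self.change_corr_mftc_minjsw,
            *self.morph_corr_central5.values(),
        ]
        if any(abs(c) > 1 for c in corrs):
            raise PhantomError("correlations must lie in [-1, 1]")
        if min(np.linalg.eigvalsh(self._extrusion_corr_matrix())) < -1e-12:
            raise PhantomError("extrusion correlation matrix is not PSD")

    def _extrusion_corr_matrix(self) -> np.ndarray:
        r5, r1, r51 = (
            self.extrusion_corr_central5,
            self.extrusion_corr_central1,
            self.extrusion_corr_c5_c1,
        )
        return np.array([[1, r5, r1], [r5, 1, r51], [r1, r51, 1]])


@dataclass
class SimulatedCohort:
    cases: pd.DataFrame
    controls: pd.DataFrame
    truncation_rate: float
    spec: CohortSimSpec


def _mvn(rng, means, sds, corr, n):
    cov = np.outer(sds, sds) * corr
    return rng.multivariate_normal(np.asarray(means, dtype=float), cov, size=n)


def _truncnorm(rng, mu, sd, lo, hi, n):
    return sps.truncnorm.rvs((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd,
                             size=n, random_state=rng)


def _draw_measures(rng, params, spec: CohortSimSpec, group: int, n: int,
                   prefix: str, medial: bool, clip_count: list[int]) -> dict[str, np.ndarray]:
    """Draw one group's measure columns for one compartment."""
    cols: dict[str, np.ndarray] = {}
    ext_fields = ("mean_extrusion_mm", "mean_extrusion_central5_mm",
                  "mean_extrusion_central1_mm")
    means = [params[f][group][0] for f in ext_fields]
    sds = [params[f][group][1] for f in ext_fields]
    trio = _mvn(rng, means, sds, spec._extrusion_corr_matrix(), n)
    for k, f in enumerate(ext_fields):
        cols[prefix + f] = trio[:, k]

    for f in ("extrusion_area_pct", "max_extrusion_mm"):
        mu, sd = params[f][group]
        cols[prefix + f] = rng.normal(mu, sd, n)

    for f in _CENTRAL_MORPH_FIELDS:
        mu, sd = params[f][group]
        if medial:
            r = spec.morph_corr_central5[f]
            pair = _mvn(rng, [mu, mu], [sd, sd], np.array([[1, r], [r, 1]]), n)
            cols[prefix + f] = pair[:, 0]
            cols[f"{prefix}{f}_central5"] = pair[:, 1]
        else:
            cols[prefix + f] = rng.normal(mu, sd, n)

    # Maximal height is not among the published summary cells; it is the
    # mean height plus a positive peripheral-rim offset.
    cols[prefix + "height_max_mm"] = (
        cols[prefix + "height_mean_mm"] + _truncnorm(rng, 1.2, 0.4, 0.1, 3.0, n)
    )

    for f, (lo, hi) in _MEASURE_BOUNDS.items():
        for key in (prefix + f, f"{prefix}{f}_central5"):
            if key in cols:
                v = cols[key]
                clipped = np.clip(v, lo if lo is not None else -np.inf,
                                  hi if hi is not None else np.inf)
                clip_count[0] += int(np.sum(clipped != v))
                cols[key] = clipped
    return cols


def simulate_cohort(spec: CohortSimSpec = CohortSimSpec(), seed: int = 0) -> SimulatedCohort:
    """Draw a matched case-control cohort with the specified group moments.

    Covariates of each control are drawn relative to its matched case so
    the matching calipers (±3 cm height, ±5 BMI, ±5 WOMAC; same sex/KLG)
    hold by construction.  Identical spec + seed give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_pairs
    clip_count = [0]
    n_values = [0]

    sex = np.where(rng.random(n) < MALE_FRACTION, "M", "F")
    klg = np.where(rng.random(n) < KLG2_FRACTION, 2, 3)

    frames = []
    for group, tag in ((0, "case"), (1, "control")):
        cols: dict[str, np.ndarray] = {
            "knee_id": np.array([f"{tag}_{i:04d}" for i in range(n)]),
            "sex": sex.copy(),
            "klg": klg.copy(),
        }
        for cov, pars in spec.covariate_params.items():
            mu, sd = pars[group]
            cols[cov] = rng.normal(mu, sd, n)
        frames.append(cols)
    cases, controls = frames

    # matched covariates: control = case + within-caliper perturbation
    controls["height_cm"] = cases["height_cm"] + _truncnorm(rng, 0.0, 1.0, -3, 3, n)
    controls["bmi_kg_m2"] = cases["bmi_kg_m2"] + _truncnorm(rng, 0.0, 1.5, -5, 5, n)
    cases["womac_pain"] = np.clip(cases["womac_pain"], 0, 20)
    delta = _truncnorm(rng, -0.7, 1.5, -5, 5, n)
    controls["womac_pain"] = np.clip(cases["womac_pain"] + delta, 0, 20)

    for group, cols in ((0, cases), (1, controls)):
        for structure in ("minjsw", "mftc", "lftc"):
            mu, sd = spec.baseline_params[structure][group]
            cols[f"{structure}_mm_baseline"] = np.clip(rng.normal(mu, sd, n), 0.5, None)
        mu_m, sd_m = spec.change_params["mftc"][group]
        mu_j, sd_j = spec.change_params["minjsw"][group]
        r = spec.change_corr_mftc_minjsw
        ch = _mvn(rng, [mu_m, mu_j], [sd_m, sd_j], np.array([[1, r], [r, 1]]), n)
        ch_lftc = rng.normal(*spec.change_params["lftc"][group], n)
        cols["mftc_mm_y1"] = np.clip(cols["mftc_mm_baseline"] + ch[:, 0] / 1000.0, 0.05, None)
        cols["minjsw_mm_y1"] = np.clip(cols["minjsw_mm_baseline"] + ch[:, 1] / 1000.0, 0.05, None)
        cols["lftc_mm_y1"] = np.clip(cols["lftc_mm_baseline"] + ch_lftc / 1000.0, 0.05, None)

        med = _draw_measures(rng, spec.medial_params, spec, group, n, "med_",
                             medial=True, clip_count=clip_count)
        lat = _draw_measures(rng, spec.lateral_params, spec, group, n, "lat_",
                             medial=False, clip_count=clip_count)
        cols.update(med)
        cols.update(lat)
        n_values[0] += sum(v.size for k, v in med.items()) + sum(v.size for k, v in lat.items())

    return SimulatedCohort(
        cases=pd.DataFrame(cases),
        controls=pd.DataFrame(controls),
        truncation_rate=clip_count[0] / max(n_values[0], 1),
        spec=spec,
    )


def simulate_test_retest_differences(
    n: int, sd_um: float = 52.0, seed: int = 0
) -> np.ndarray:
    """Zero-mean test–retest change differences (µm) for SDC estimation.

    The default SD of 52 µm is the test–retest variability implied by a
    102 µm smallest detectable change (102 / 1.96).
    """
    if n < 2:
        raise PhantomError("need n >= 2 differences")
    return np.random.default_rng(seed).normal(0.0, sd_um, n)


# ---------------------------------------------------------------------------
# Frame helpers
# ---------------------------------------------------------------------------

def measures_frame(df: pd.DataFrame, compartment: str = "med") -> pd.DataFrame:
    """Extract one compartment's measure columns with canonical names."""
    prefix = compartment + "_"
    cols = {c[len(prefix):]: df[c] for c in df.columns
            if c.startswith(prefix) and not c.endswith("_central5")}
    return pd.DataFrame(cols)


def central_surrogate_frames(
    df: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(entire, central5, central1) medial frames for the surrogate analysis.

    The central frames carry each measure *as measured in that window*
    under the canonical field name, so that correlating ``entire[f]`` with
    ``central5[f]`` compares entire-meniscus vs central-window values.
    """
    entire = measures_frame(df, "med")
    central5 = pd.DataFrame({
        "mean_extrusion_mm": df["med_mean_extrusion_central5_mm"],
        **{f: df[f"med_{f}_central5"] for f in _CENTRAL_MORPH_FIELDS},
    })
    central1 = pd.DataFrame({
        "mean_extrusion_mm": df["med_mean_extrusion_central1_mm"],
    })
    return entire, central5, central1
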