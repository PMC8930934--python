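"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive: pure-Python loops over voxels and
cells with exact rational arithmetic where possible, and exhaustive
dynamic-programming search for the matching optimum.  Nothing imports the
implementation paths it checks.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


class OracleUndefined(Exception):
    """The brute-force enumeration found the measure undefined."""


def oracle_footprint(men: np.ndarray) -> list[list[bool]]:
    ny, nz, nx = men.shape
    return [
        [any(men[y, z, x] for z in range(nz)) for x in range(nx)]
        for y in range(ny)
    ]


def _row_xmax(row) -> int | None:
    xs = [x for x, v in enumerate(row) if v]
    return max(xs) if xs else None


def oracle_measures(men: np.ndarray, plat: np.ndarray, spacing) -> dict[str, float]:
    """All aggregate measures by exhaustive voxel/cell enumeration.

    Raises OracleUndefined when a required structure or window is empty.
    """
    dy, dz, dx = (Fraction(str(s)) for s in spacing)
    ny, nz, nx = men.shape
    fp = oracle_footprint(men)

    men_slices = [y for y in range(ny) if any(fp[y])]
    if not men_slices:
        raise OracleUndefined("empty meniscus")
    if not plat.any():
        raise OracleUndefined("empty plateau")

    # per-slice signed extrusion in cells, only where both structures exist
    extr_cells: dict[int, int] = {}
    for y in range(ny):
        xm = _row_xmax(fp[y])
        xp = _row_xmax(list(plat[y]))
        if xm is not None and xp is not None:
            extr_cells[y] = xm - xp

    def window_mean(ys) -> Fraction:
        vals = [extr_cells[y] for y in ys if y in extr_cells]
        if not vals:
            raise OracleUndefined("no eligible slice in window")
        return Fraction(sum(vals), len(vals)) * dx

    c = (men_slices[0] + men_slices[-1]) // 2
    win5 = [y for y in range(c - 2, c + 3) if y in men_slices]
    win1 = [y for y in [c] if y in men_slices]

    all_eligible = [extr_cells[y] for y in men_slices if y in extr_cells]
    if not all_eligible:
        raise OracleUndefined("no eligible slice")

    n_plat = sum(1 for y in range(ny) for x in range(nx) if plat[y, x])
    n_men_fp = sum(1 for y in range(ny) for x in range(nx) if fp[y][x])
    n_cov = sum(1 for y in range(ny) for x in range(nx) if plat[y, x] and fp[y][x])
    n_out = n_men_fp - n_cov

    heights = []
    for y in range(ny):
        for x in range(nx):
            cnt = sum(1 for z in range(nz) if men[y, z, x])
            if cnt:
                heights.append(cnt)
    widths = []
    for y in men_slices:
        xs = [x for x, v in enumerate(fp[y]) if v]
        widths.append(xs[-1] - xs[0] + 1)
    n_vox = sum(
        1 for y in range(ny) for z in range(nz) for x in range(nx) if men[y, z, x]
    )

    return {
        "extrusion_area_pct": float(Fraction(100 * n_out, n_men_fp)),
        "mean_extrusion_mm": float(
            Fraction(sum(all_eligible), len(all_eligible)) * dx
        ),
        "max_extrusion_mm": float(max(all_eligible) * dx),
        "mean_extrusion_central5_mm": float(window_mean(win5)),
        "mean_extrusion_central1_mm": float(window_mean(win1)),
        "coverage_pct": float(Fraction(100 * n_cov, n_plat)),
        "width_mean_mm": float(Fraction(sum(widths), len(widths)) * dx),
        "height_mean_mm": float(Fraction(sum(heights), len(heights)) * dz),
        "height_max_mm": float(max(heights) * dz),
        "volume_ml": float(n_vox * dy * dz * dx / 1000),
    }


def random_compartment(rng: np.random.Generator, max_extent: int = 16):
    """Random mask pair guaranteed to have ≥1 slice with both structures."""
    ny = int(rng.integers(1, max_extent + 1))
    nz = int(rng.integers(1, max_extent + 1))
    nx = int(rng.integers(2, max_extent + 1))
    while True:
        men = rng.random((ny, nz, nx)) < rng.uniform(0.05, 0.5)
        plat = rng.random((ny, nx)) < rng.uniform(0.1, 0.8)
        both = men.any(axis=(1, 2)) & plat.any(axis=1)
        if men.any() and plat.any() and both.any():
            return men, plat


def oracle_best_matching(eligible: np.ndarray, dist: np.ndarray) -> tuple[int, float]:
    """Exhaustive (max cardinality, then min total distance) 1:1 matching.

    DP over (case index, used-control bitmask); feasible up to ~10x10.
    """
    n, m = eligible.shape
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def go(i: int, used: int) -> tuple[int, float]:
        if i == n:
            return (0, 0.0)
        best = go(i + 1, used)  # leave case i unmatched
        for j in range(m):
            if eligible[i, j] and not used & (1 << j):
                pairs, cost = go(i + 1, used | (1 << j))
                cand = (pairs + 1, cost + float(dist[i, j]))
                if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
        return best

    return go(0, 0)
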