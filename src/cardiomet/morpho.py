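"""Stereological and geometric morphometry.

Point-counting volume densities (Vv) with the classical test systems (82
points for atrial electron micrographs, 140 for left-ventricular fields,
200 for aortic sections), numerical densities (Nv), ANP-granule metrics,
vessel-ring geometry (lumen diameter, intima-media thickness and area
with fixation-shrinkage correction), elastic-lamellae counting, Laplace
circumferential wall tension, and percent-change reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from cardiomet.synthio import (
    COLLAGEN_LABEL,
    LAMELLA_LABEL,
    OBJECT_LABEL,
    TissueField,
    WALL_LABEL,
)

#: Published test-system sizes: atrial EM, LV EM, aortic light microscopy.
POINTS_ATRIUM = 82
POINTS_LV = 140
POINTS_AORTA = 200

#: IMA fixation/processing shrinkage correction factor.
SHRINKAGE_FACTOR = 1.28

#: dyne/cm per (mmHg * mm): 1 mmHg = 1333.22 dyne/cm^2, 1 mm = 0.1 cm.
DYNE_PER_CM_PER_MMHG_MM = 1333.22 / 10.0


@dataclass
class PointGrid:
    """Systematic-uniform-random point lattice overlaid on a field."""

    points: np.ndarray      # (n, 2) row/col pixel coordinates
    labels: np.ndarray      # mask label hit by each point
    n_points: int

    def hits(self, label: int) -> int:
        return int(np.sum(self.labels == label))


@dataclass
class GranuleStats:
    """Count, size and volume-density metrics of secretory granules."""

    n_fields: int
    counts_per_field: list[int]
    mean_count_per_field: float
    density_per_mm2: float
    areas_nm2: np.ndarray
    mean_area_nm2: float
    diameters_nm: np.ndarray
    mean_diameter_nm: float
    vv_pct: float


@dataclass
class VesselGeometry:
    """Aortic-ring morphometry with Laplace wall tension."""

    lumen_area_mm2: float
    lumen_diameter_mm: float
    imt_um: float
    ima_raw_mm2: float
    ima_mm2: float           # shrinkage-corrected
    lamellae: int | None
    vv_collagen_pct: float | None
    cwt_mmhg_mm: float | None
    cwt_dyne_per_cm: float | None
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# point counting
# ---------------------------------------------------------------------------

def overlay_grid(field: TissueField | np.ndarray, n_points: int,
                 seed: int = 0) -> PointGrid:
    """Overlay a near-square regular lattice of exactly ``n_points``.

    The lattice has a single uniform random offset (systematic uniform
    random sampling), which keeps the Vv estimator unbiased while
    retaining the efficiency of a regular grid.
    """
    mask = field.mask if isinstance(field, TissueField) else np.asarray(field)
    if n_points < 4:
        raise ValueError("need at least 4 test points")
    if n_points > mask.size:
        raise ValueError("more test points than pixels")
    h, w = mask.shape
    rng = np.random.default_rng(seed)
    ny = max(1, int(round(math.sqrt(n_points * h / w))))
    nx = int(math.ceil(n_points / ny))
    sy, sx = h / ny, w / nx
    oy, ox = rng.uniform(0, sy), rng.uniform(0, sx)
    rows = np.minimum((oy + sy * np.arange(ny)).astype(int), h - 1)
    cols = np.minimum((ox + sx * np.arange(nx)).astype(int), w - 1)
    pts = np.array([(r, c) for r in rows for c in cols])
    if pts.shape[0] > n_points:
        # drop surplus lattice positions at random to avoid spatial bias
        pts = pts[np.sort(rng.choice(pts.shape[0], n_points, replace=False))]
    labels = mask[pts[:, 0], pts[:, 1]]
    return PointGrid(points=pts, labels=labels, n_points=n_points)


def volume_density(grid: PointGrid, label: int) -> float:
    """Vv[structure] = 100 * PP / PT, percent."""
    if grid.n_points <= 0:
        raise ValueError("empty point grid")
    return 100.0 * grid.hits(label) / grid.n_points


def numerical_density(object_count: float, reference: float,
                      unit: str = "mm2") -> dict:
    """Objects per unit reference area (or volume), unit-tagged."""
    if reference <= 0:
        raise ValueError("reference area/volume must be positive")
    return {"density": object_count / reference, "unit": f"per_{unit}",
            "count": object_count, "reference": reference}


def count_objects(field: TissueField, label: int = OBJECT_LABEL,
                  min_px: int = 2) -> tuple[int, np.ndarray]:
    """Count connected components of a label; returns (count, areas in px)."""
    lab = measure.label(field.mask == label, connectivity=1)
    areas = np.bincount(lab.ravel())[1:]
    areas = areas[areas >= min_px]
    return int(areas.size), areas.astype(float)


def granule_stats(fields: list[TissueField], label: int = OBJECT_LABEL,
                  n_points: int = POINTS_ATRIUM, seed: int = 0) -> GranuleStats:
    """Granule metrics over a set of micrograph fields.

    Granule profiles are near-circular, so each profile's size is reported
    as the equivalent-circle diameter 2*sqrt(area/pi).  Vv uses the
    atrial 82-point test system by default.
    """
    if not fields:
        raise ValueError("need at least one field")
    counts: list[int] = []
    areas_um2: list[float] = []
    vv_vals: list[float] = []
    total_area_mm2 = 0.0
    for i, fld in enumerate(fields):
        n, areas_px = count_objects(fld, label)
        counts.append(n)
        areas_um2.extend(areas_px / fld.px_per_um ** 2)
        total_area_mm2 += fld.area_mm2
        grid = overlay_grid(fld, n_points, seed=seed + i)
        vv_vals.append(volume_density(grid, label))
    areas_nm2 = np.asarray(areas_um2) * 1e6
    diameters_nm = 2.0 * np.sqrt(areas_nm2 / np.pi)
    total = int(np.sum(counts))
    return GranuleStats(
        n_fields=len(fields), counts_per_field=counts,
        mean_count_per_field=float(np.mean(counts)),
        density_per_mm2=total / total_area_mm2 if total_area_mm2 else 0.0,
        areas_nm2=areas_nm2,
        mean_area_nm2=float(areas_nm2.mean()) if total else 0.0,
        diameters_nm=diameters_nm,
        mean_diameter_nm=float(diameters_nm.mean()) if total else 0.0,
        vv_pct=float(np.mean(vv_vals)),
    )


# ---------------------------------------------------------------------------
# vessel geometry
# ---------------------------------------------------------------------------

def lumen_diameter(area_mm2: float) -> float:
    """Lumen diameter of an equivalent circle: d = 2 * sqrt(a / pi)."""
    if area_mm2 < 0:
        raise ValueError("lumen area must be non-negative")
    return 2.0 * math.sqrt(area_mm2 / math.pi)


def intima_media(thickness_um: np.ndarray, d_mm: float,
                 shrinkage: float = SHRINKAGE_FACTOR) -> tuple[float, float, float]:
    """Mean intima-media thickness and cross-sectional area of a ring.

    ``thickness_um`` holds the four angular measures (0/90/180/270 deg) in
    micrometres; ``d_mm`` the lumen diameter in millimetres.  Returns
    ``(imt_um, ima_raw_mm2, ima_mm2)`` where
    IMA_raw = pi*(d/2 + IMT)^2 - pi*(d/2)^2 and IMA applies the
    fixation-shrinkage correction factor.
    """
    th = np.asarray(thickness_um, dtype=float)
    if th.size != 4 or np.any(th < 0):
        raise ValueError("need four non-negative thickness measures (um)")
    if d_mm <= 0:
        raise ValueError("lumen diameter must be positive")
    imt_um = float(th.mean())
    imt_mm = imt_um / 1000.0
    if imt_mm > d_mm:
        raise ValueError(
            f"IMT {imt_mm:.3f} mm exceeds lumen diameter {d_mm:.3f} mm — "
            "check units (IMT expected in um, d in mm)")
    r = d_mm / 2.0
    ima_raw = math.pi * ((r + imt_mm) ** 2 - r ** 2)
    return imt_um, ima_raw, shrinkage * ima_raw


def count_lamellae(ring: TissueField, label: int = LAMELLA_LABEL,
                   n_rays: int = 36) -> int:
    """Count elastic lamellae as radial band crossings of a ring mask.

    Casts ``n_rays`` radial profiles from the ring centre, cleans each
    boolean lamella profile with morphological closing+opening (removing
    single-pixel speckle and bridging single-pixel gaps), counts the
    contiguous bands per ray, and reports the median over rays rounded to
    the nearest integer — robust to moderate label noise.
    """
    mask = ring.mask
    wallish = np.isin(mask, (WALL_LABEL, label, COLLAGEN_LABEL))
    if not wallish.any():
        raise ValueError("no vessel wall found in mask")
    cy, cx = ndimage.center_of_mass(wallish)
    r_max = math.hypot(*mask.shape) / 2.0
    radii = np.arange(0.0, r_max, 1.0)
    counts = []
    for theta in np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False):
        rr = np.round(cy + radii * math.sin(theta)).astype(int)
        cc = np.round(cx + radii * math.cos(theta)).astype(int)
        ok = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
        line = mask[rr[ok], cc[ok]]
        # locate the wall along the ray: longest contiguous wall-ish run
        wall_prof = np.isin(line, (WALL_LABEL, label, COLLAGEN_LABEL))
        wall_prof = ndimage.binary_closing(wall_prof, structure=np.ones(5))
        wall_prof = ndimage.binary_opening(wall_prof, structure=np.ones(3))
        runs = _runs(wall_prof)
        if not runs:
            continue
        i0, i1 = max(runs, key=lambda r: r[1] - r[0])
        profile = line[i0:i1 + 1] == label
        # kill single-pixel speckle, bridge single-pixel gaps in a band
        profile = ndimage.binary_closing(profile, structure=np.ones(2))
        profile = ndimage.binary_opening(profile, structure=np.ones(2))
        counts.append(len(_runs(profile)))
    if not counts:
        raise ValueError("no radial wall profile found")
    return int(round(float(np.median(counts))))


def _runs(profile: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) indices of True runs in a boolean profile."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], profile.view(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1] - 1)) for i in range(0, idx.size, 2)]


def wall_tension(msap_mmhg: float, d_mm: float) -> tuple[float, float]:
    """Laplace circumferential wall tension: CWT = MSAP * d / 2.

    Returned as ``(mmHg*mm, dyne/cm)``.  The mmHg*mm scale is the primary
    (table-comparable) value; the dyne/cm conversion uses
    1 mmHg*mm = 133.322 dyne/cm.
    """
    if msap_mmhg < 0 or d_mm < 0:
        raise ValueError("pressure and diameter must be non-negative")
    cwt = msap_mmhg * d_mm / 2.0
    return cwt, cwt * DYNE_PER_CM_PER_MMHG_MM


def vessel_geometry(lumen_area_mm2: float, thickness_um: np.ndarray,
                    msap_mmhg: float | None = None,
                    lamellae: int | None = None,
                    vv_collagen_pct: float | None = None) -> VesselGeometry:
    """Assemble the full ring morphometry record."""
    d = lumen_diameter(lumen_area_mm2)
    imt_um, ima_raw, ima = intima_media(thickness_um, d)
    cwt = cwt_dyne = None
    if msap_mmhg is not None:
        cwt, cwt_dyne = wall_tension(msap_mmhg, d)
    return VesselGeometry(
        lumen_area_mm2=lumen_area_mm2, lumen_diameter_mm=d, imt_um=imt_um,
        ima_raw_mm2=ima_raw, ima_mm2=ima, lamellae=lamellae,
        vv_collagen_pct=vv_collagen_pct, cwt_mmhg_mm=cwt,
        cwt_dyne_per_cm=cwt_dyne,
    )


# ---------------------------------------------------------------------------
# percent change
# ---------------------------------------------------------------------------

def percent_change(reference: float, value: float,
                   denominator: str = "reference") -> float:
    """Signed percent change 100 * (value - reference) / denominator.

    ``denominator`` selects the convention: "reference" divides by the
    reference (baseline) value, "value" by the new value.
    """
    denom = {"reference": reference, "value": value}.get(denominator)
    if denom is None:
        raise ValueError("denominator must be 'reference' or 'value'")
    if denom == 0:
        raise ValueError("zero denominator")
    return 100.0 * (value - reference) / denom
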