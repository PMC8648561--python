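"""3D morphometry and stereology on binary volumes.

Implements the quantitative-biology toolchain: histogram thresholding
(triangle / Yen / Otsu), the integer-weighted (3,4,5,7) chamfer distance
transform, local thickness by the largest-inscribed-sphere (distance
ridge) method, surface-area-to-volume from an isosurface mesh, Euler
connectivity, per-object morphometry (volume, surface area, sphericity),
virtual-biopsy counting with whole-organ extrapolation, and grouped VOI
comparison with one-way ANOVA and Tukey post-hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage, stats
from skimage import filters, measure

from .core_io import CylinderROI, Volume3D

__all__ = [
    "BinaryVolume",
    "ChamferWeights",
    "BiopsyEstimate",
    "MorphometryRecord",
    "threshold",
    "chamfer_distance",
    "local_thickness",
    "thickness_summary",
    "surface_area_to_volume",
    "connectivity",
    "object_morphometry",
    "virtual_biopsy",
    "estimate_total_units",
    "morphometry_report",
]


@dataclass
class BinaryVolume:
    """A binary mask with a phase label and physical voxel size (µm)."""

    mask: np.ndarray
    voxel_size: float
    phase_label: str = "object"  # {"airspace", "tissue", "object"}

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")


@dataclass
class ChamferWeights:
    """Integer chamfer weights for face/edge/vertex/knight moves."""

    w_face: int = 3
    w_edge: int = 4
    w_vertex: int = 5
    w_knight: int = 7

    def __post_init__(self) -> None:
        if not self.w_face <= self.w_edge <= self.w_vertex <= self.w_knight:
            raise ValueError("weights must be ordered face <= edge <= vertex <= knight")


@dataclass
class BiopsyEstimate:
    """Whole-organ unit count extrapolated from a virtual biopsy."""

    count_in_biopsy: int
    parenchyma_vol_biopsy: float  # µm^3
    parenchyma_vol_total: float  # µm^3
    n_total: float
    n_total_se: float  # Poisson standard error scaled by the volume ratio


@dataclass
class MorphometryRecord:
    """Per-VOI morphometric measures used in group comparisons."""

    voi_id: str
    group: str
    surface_area_to_volume: float  # 1/µm
    mean_septal_thickness: float  # µm (tissue phase)
    connectivity: float
    connectivity_density: float  # 1/µm^3
    thickness_histogram: tuple[np.ndarray, np.ndarray] = field(default=None)  # type: ignore


# ---------------------------------------------------------------------------
# thresholding


def threshold(
    volume: np.ndarray,
    method: str = "triangle",
    fixed_value: float | None = None,
    foreground: str = "above",
) -> np.ndarray:
    """Binarise a grey-level volume with a histogram method.

    Methods: ``triangle`` (used for control / structurally preserved
    groups), ``yen`` (consolidated group), ``otsu``, or ``fixed`` with an
    explicit value.  The histogram uses 256 bins over the data range;
    ``foreground="above"`` marks voxels strictly above the threshold.
    """
    v = np.asarray(volume, dtype=np.float64)
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed method needs fixed_value")
        t = fixed_value
    else:
        if v.max() == v.min():
            raise ValueError("constant volume cannot be auto-thresholded")
        if method == "triangle":
            t = filters.threshold_triangle(v, nbins=256)
        elif method == "yen":
            t = filters.threshold_yen(v, nbins=256)
        elif method == "otsu":
            t = filters.threshold_otsu(v, nbins=256)
        else:
            raise ValueError(f"unknown method {method!r}")
    return v > t if foreground == "above" else v <= t


# ---------------------------------------------------------------------------
# chamfer distance (3,4,5,7)

# forward-scan neighbour offsets (dz, dy, dx) with weights; the backward
# pass uses the negated offsets.  Knight moves are the (1,1,2)-type
# displacements of the 5x5x5 neighbourhood.
def _chamfer_offsets(w: ChamferWeights) -> np.ndarray:
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) >= (0, 0, 0):
                    continue  # strictly earlier in raster order
                n = abs(dz) + abs(dy) + abs(dx)
                wt = {1: w.w_face, 2: w.w_edge, 3: w.w_vertex}[n]
                offs.append((dz, dy, dx, wt))
    # (1,1,2)-type knight moves, earlier in raster order only
    for dz in (-2, -1, 0, 1, 2):
        for dy in (-2, -1, 0, 1, 2):
            for dx in (-2, -1, 0, 1, 2):
                if sorted((abs(dz), abs(dy), abs(dx))) != [1, 1, 2]:
                    continue
                if (dz, dy, dx) >= (0, 0, 0):
                    continue
                offs.append((dz, dy, dx, w.w_knight))
    return np.array(offs, dtype=np.int64)


@njit(cache=True)
def _chamfer_sweep(dist, offs, reverse):
    nz, ny, nx = dist.shape
    zr = range(nz - 1, -1, -1) if reverse else range(nz)
    for z in zr:
        yr = range(ny - 1, -1, -1) if reverse else range(ny)
        for y in yr:
            xr = range(nx - 1, -1, -1) if reverse else range(nx)
            for x in xr:
                d = dist[z, y, x]
                for k in range(offs.shape[0]):
                    sign = -1 if reverse else 1
                    zz = z + sign * offs[k, 0]
                    yy = y + sign * offs[k, 1]
                    xx = x + sign * offs[k, 2]
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                        cand = dist[zz, yy, xx] + offs[k, 3]
                        if cand < d:
                            d = cand
                dist[z, y, x] = d


def chamfer_distance(
    binary: BinaryVolume | np.ndarray,
    weights: ChamferWeights | None = None,
    voxel_units: bool = True,
) -> np.ndarray:
    """Two-pass weighted (3,4,5,7) chamfer distance to the background.

    Distances are divided by the face weight so a single face step equals
    one voxel; multiply by the voxel size for µm.  Requires at least one
    background voxel.
    """
    if weights is None:
        weights = ChamferWeights()
    mask = binary.mask if isinstance(binary, BinaryVolume) else np.asarray(binary, bool)
    if mask.all():
        raise ValueError("mask has no background voxel")
    big = np.iinfo(np.int64).max // 4
    dist = np.where(mask, big, 0).astype(np.int64)
    offs = _chamfer_offsets(weights)
    _chamfer_sweep(dist, offs, False)
    _chamfer_sweep(dist, offs, True)
    out = dist.astype(np.float64) / weights.w_face
    if not voxel_units and isinstance(binary, BinaryVolume):
        out *= binary.voxel_size
    return out


# ---------------------------------------------------------------------------
# local thickness (largest inscribed sphere)


@njit(cache=True)
def _paint_spheres(thick, centres, radii):
    # value painted is the sphere diameter measured to the phase surface:
    # the EDT radius reaches the nearest background voxel centre, which
    # lies half a voxel beyond the surface, hence 2r - 1
    nz, ny, nx = thick.shape
    for i in range(centres.shape[0]):
        cz, cy, cx = centres[i, 0], centres[i, 1], centres[i, 2]
        r = radii[i]
        ri = int(np.ceil(r))
        val = max(2.0 * r - 1.0, 1.0)
        for z in range(max(0, cz - ri), min(nz, cz + ri + 1)):
            for y in range(max(0, cy - ri), min(ny, cy + ri + 1)):
                for x in range(max(0, cx - ri), min(nx, cx + ri + 1)):
                    dd = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2
                    if dd <= r * r and thick[z, y, x] < val:
                        thick[z, y, x] = val


def local_thickness(binary: BinaryVolume | np.ndarray, voxel_size: float | None = None) -> np.ndarray:
    """Local thickness: diameter of the largest inscribed sphere per voxel.

    Computed by the distance-ridge method: the Euclidean distance map is
    pruned to non-redundant sphere centres (a centre is redundant when a
    neighbour's inscribed sphere contains its own), and each surviving
    sphere paints its diameter into the voxels it covers, keeping the
    maximum.  Output in µm for :class:`BinaryVolume` input, else voxels.
    """
    if isinstance(binary, BinaryVolume):
        mask = binary.mask
        vs = binary.voxel_size
    else:
        mask = np.asarray(binary, bool)
        vs = voxel_size or 1.0
    if not mask.any():
        raise ValueError("empty phase")
    edt = ndimage.distance_transform_edt(mask)
    # prune redundant centres: c is redundant if a 26-neighbour n satisfies
    # edt[n] >= edt[c] + |n - c| (its sphere contains c's sphere)
    keep = mask.copy()
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                step = np.sqrt(dz * dz + dy * dy + dx * dx)
                shifted = np.full(edt.shape, -np.inf)
                src = tuple(
                    slice(max(0, -d), edt.shape[i] - max(0, d))
                    for i, d in enumerate((dz, dy, dx))
                )
                dst = tuple(
                    slice(max(0, d), edt.shape[i] - max(0, -d))
                    for i, d in enumerate((dz, dy, dx))
                )
                shifted[dst] = edt[src]
                keep &= ~(shifted >= edt + step)
    centres = np.argwhere(keep & mask)
    radii = edt[keep & mask]
    thick = np.zeros(edt.shape)
    _paint_spheres(thick, centres.astype(np.int64), radii.astype(np.float64))
    thick[~mask] = 0.0
    return thick * vs


def thickness_summary(
    thickness_map: np.ndarray, mask: np.ndarray, bin_width: float = 1.0
) -> dict:
    """Mean, modal bin centre, and histogram of a thickness map over a phase."""
    vals = thickness_map[np.asarray(mask, bool)]
    if vals.size == 0:
        raise ValueError("empty phase")
    edges = np.arange(0.0, vals.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return {
        "mean": float(vals.mean()),
        "mode": float(centres[np.argmax(counts)]),
        "bin_centres": centres,
        "counts": counts,
    }


# ---------------------------------------------------------------------------
# surface, connectivity, objects


def _mesh_area(mask: np.ndarray, spacing: float, smooth_sigma: float = 0.6) -> float:
    """Isosurface area of a binary mask via marching cubes.

    The mask is lightly Gaussian-smoothed before meshing: the 0.5
    isosurface of the smoothed field approximates the true object surface,
    whereas meshing the raw binary grid inflates the area of curved
    objects by its staircase facets (~9% for a radius-20 ball).  The
    sigma trades sphere inflation against edge rounding of polyhedra;
    objects thinner than ~5 voxels are meshed unsmoothed (smoothing
    would erode them).
    """
    padded = np.pad(mask.astype(np.float64), 2)
    if smooth_sigma > 0 and min(mask.shape) >= 5:
        sm = ndimage.gaussian_filter(padded, smooth_sigma)
        if (sm > 0.5).any():
            padded = sm
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=(spacing,) * 3)
    return float(measure.mesh_surface_area(verts, faces))


def surface_area_to_volume(binary: BinaryVolume, per_total_volume: bool = False) -> float:
    """Surface area (isosurface mesh) over volume, in 1/µm.

    With ``per_total_volume=False`` the denominator is the phase volume
    (voxel count x voxel volume) — the convention under which a ball of
    radius r gives 3/r.  With ``per_total_volume=True`` the denominator is
    the whole VOI volume (surface density S_V, the lung-morphometry
    convention used for airspace group comparisons, where consolidation
    and septal thickening reduce the ratio).
    """
    mask = binary.mask
    if not mask.any():
        raise ValueError("empty mask")
    area = _mesh_area(mask, binary.voxel_size)
    if per_total_volume:
        volume = float(np.prod(mask.shape)) * binary.voxel_size**3
    else:
        volume = float(mask.sum()) * binary.voxel_size**3
    return area / volume


def connectivity(binary: BinaryVolume) -> tuple[int, int, float]:
    """Euler characteristic, connectivity (1 - chi) and its density.

    chi uses 26-connected foreground (6-connected background); the
    trabecular convention ``connectivity = 1 - chi`` gives 0 for a ball,
    1 for a torus, -1 for two disjoint balls.  Density divides by the
    physical volume of the mask's bounding grid.
    """
    mask = binary.mask
    if not mask.any():
        raise ValueError("empty mask")
    chi = int(measure.euler_number(mask, connectivity=3))
    conn = 1 - chi
    vol = float(np.prod(mask.shape)) * binary.voxel_size**3
    return chi, conn, conn / vol


def object_morphometry(labels: np.ndarray, voxel_size: float) -> pd.DataFrame:
    """Per-object volume (µm^3), mesh surface area (µm^2) and sphericity.

    Sphericity is ``psi = pi^(1/3) * (6V)^(2/3) / A`` (1 for a sphere).
    Objects touching the volume border are flagged (open surface).
    """
    lab = np.asarray(labels)
    ids = [int(i) for i in np.unique(lab) if i != 0]
    if not ids:
        raise ValueError("no labelled objects")
    rows = []
    for oid in ids:
        mask = lab == oid
        sl = ndimage.find_objects(mask.astype(np.uint8))[0]
        crop = mask[sl]
        vol = float(crop.sum()) * voxel_size**3
        area = _mesh_area(crop, voxel_size)
        psi = np.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / area
        touches = any(
            s.start == 0 or s.stop == dim for s, dim in zip(sl, lab.shape)
        )
        rows.append(
            {
                "label": oid,
                "volume_um3": vol,
                "surface_area_um2": area,
                "sphericity": psi,
                "touches_border": touches,
            }
        )
    return pd.DataFrame(rows).set_index("label")


# ---------------------------------------------------------------------------
# virtual biopsy and stereology


def virtual_biopsy(
    centres_um: np.ndarray | list, roi: CylinderROI
) -> tuple[int, float]:
    """Count objects whose centroid lies inside the cylinder (inclusive).

    Returns ``(count, cylinder_volume)`` with the volume ``pi r^2 L`` in
    µm^3.  ``centres_um`` is an (N, 3) array of object centroids in (z, y, x)
    physical coordinates.
    """
    centres = np.asarray(centres_um, dtype=np.float64)
    if centres.size == 0:
        return 0, roi.volume
    count = int(roi.contains(centres).sum())
    return count, roi.volume


def label_centroids(label_volume: Volume3D) -> np.ndarray:
    """Physical (z, y, x) centroids of connected components of a label mask."""
    lab, n = ndimage.label(np.asarray(label_volume.data) > 0)
    if n == 0:
        return np.empty((0, 3))
    cent = np.array(ndimage.center_of_mass(lab > 0, lab, range(1, n + 1)))
    return np.asarray(label_volume.origin) + cent * label_volume.voxel_size


def estimate_total_units(
    count: int, parenchyma_vol_biopsy: float, parenchyma_vol_total: float
) -> BiopsyEstimate:
    """Extrapolate a biopsy count to the whole organ by the volume ratio.

    ``n_total = count * V_total / V_biopsy``; the uncertainty is the
    Poisson standard error of the count scaled by the same ratio.
    """
    if parenchyma_vol_biopsy <= 0 or parenchyma_vol_total <= 0:
        raise ValueError("volumes must be positive")
    if parenchyma_vol_biopsy > parenchyma_vol_total:
        raise ValueError("biopsy volume exceeds total volume")
    if count < 0:
        raise ValueError("count must be non-negative")
    ratio = parenchyma_vol_total / parenchyma_vol_biopsy
    return BiopsyEstimate(
        count_in_biopsy=count,
        parenchyma_vol_biopsy=parenchyma_vol_biopsy,
        parenchyma_vol_total=parenchyma_vol_total,
        n_total=count * ratio,
        n_total_se=np.sqrt(max(count, 1)) * ratio,
    )


# ---------------------------------------------------------------------------
# grouped reporting


def _measure_voi(voi: BinaryVolume, voi_id: str, group: str) -> MorphometryRecord:
    tissue = BinaryVolume(~voi.mask, voi.voxel_size, "tissue")
    sv = surface_area_to_volume(voi, per_total_volume=True)
    th_map = local_thickness(tissue)
    th = thickness_summary(th_map, tissue.mask, bin_width=voi.voxel_size)
    _, conn, conn_dens = connectivity(voi)
    air_map = local_thickness(voi)
    air_hist = thickness_summary(air_map, voi.mask, bin_width=voi.voxel_size)
    return MorphometryRecord(
        voi_id=voi_id,
        group=group,
        surface_area_to_volume=sv,
        mean_septal_thickness=th["mean"],
        connectivity=conn,
        connectivity_density=conn_dens,
        thickness_histogram=(air_hist["bin_centres"], air_hist["counts"]),
    )


def morphometry_report(
    vois: list[BinaryVolume], groups: list[str], voi_ids: list[str] | None = None
) -> dict:
    """Per-VOI morphometry table with ANOVA + Tukey group comparisons.

    ``vois`` are airspace masks; tissue measures use the complement.
    Requires at least 2 groups with at least 2 VOIs each.  Returns a dict
    with the records DataFrame, per-measure ANOVA/Tukey results and pooled
    airspace-diameter histograms per group.
    """
    if voi_ids is None:
        voi_ids = [f"voi{i}" for i in range(len(vois))]
    unique_groups = sorted(set(groups))
    if len(unique_groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in unique_groups:
        if groups.count(g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 VOIs")
    records = [_measure_voi(v, i, g) for v, i, g in zip(vois, voi_ids, groups)]
    df = pd.DataFrame(
        {
            "voi_id": [r.voi_id for r in records],
            "group": [r.group for r in records],
            "surface_area_to_volume": [r.surface_area_to_volume for r in records],
            "mean_septal_thickness": [r.mean_septal_thickness for r in records],
            "connectivity": [r.connectivity for r in records],
            "connectivity_density": [r.connectivity_density for r in records],
        }
    )
    comparisons: dict[str, dict] = {}
    for measure_name in (
        "surface_area_to_volume",
        "mean_septal_thickness",
        "connectivity",
        "connectivity_density",
    ):
        samples = [df.loc[df.group == g, measure_name].to_numpy() for g in unique_groups]
        if all(np.allclose(s, samples[0][0]) for s in samples):
            comparisons[measure_name] = {"anova_F": 0.0, "anova_p": 1.0, "tukey": None}
            continue
        f_stat, p_val = stats.f_oneway(*samples)
        tukey = stats.tukey_hsd(*samples)
        pairs = {}
        for i in range(len(unique_groups)):
            for j in range(i + 1, len(unique_groups)):
                pairs[f"{unique_groups[i]} vs {unique_groups[j]}"] = float(
                    tukey.pvalue[i, j]
                )
        comparisons[measure_name] = {
            "anova_F": float(f_stat),
            "anova_p": float(p_val),
            "tukey": pairs,
        }
    pooled = {}
    for g in unique_groups:
        hists = [r.thickness_histogram for r in records if r.group == g]
        max_len = max(len(h[0]) for h in hists)
        counts = np.zeros(max_len)
        centres = max((h[0] for h in hists), key=len)
        for c, n in hists:
            counts[: len(n)] += n
        pooled[g] = {"bin_centres": centres, "counts": counts}
    return {"records": df, "comparisons": comparisons, "airspace_histograms": pooled}
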