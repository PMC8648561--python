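"""Seeded synthetic phantoms of organs mounted in agar-ethanol jars.

Three generators cover the study geometries at desk scale:

* a cylindrical *jar* phantom — PET wall, agar-ethanol interior, optional
  soft-tissue cylinder — whose tissue-free twin is the flat-field
  *reference jar*;
* a *kidney-like* phantom — a parenchyma shell studded with non-overlapping
  dense spheres standing in for glomeruli, with exact ground truth for
  stereology;
* an *alveolar* foam phantom — Voronoi cells with tissue walls of
  controlled thickness and an optional "consolidated" fraction of cells,
  for airspace morphometry.

All generators are pure functions of their parameters and the seed.
Material properties are scenario defaults chosen to give the weak
absorption / strong phase contrast regime typical of ethanol-fixed soft
tissue at an effective energy of ~85 keV; they are placeholders, not
measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial import cKDTree

from .core_io import Volume3D, rng_for

__all__ = [
    "Material",
    "Phantom",
    "default_materials",
    "wavelength_m",
    "build_jar_phantom",
    "build_kidney_phantom",
    "build_alveolar_phantom",
]

# label conventions shared by all generators
LABEL_AIR = 0
LABEL_JAR = 1
LABEL_AGAR = 2
LABEL_TISSUE = 3
LABEL_SPHERE = 4
LABEL_CONSOLIDATION = 5


def wavelength_m(energy_kev: float) -> float:
    """X-ray wavelength in metres, lambda[A] = 12.398 / E[keV]."""
    return 12.398e-10 / energy_kev


@dataclass
class Material:
    """Complex refractive index n = 1 - delta + i*beta plus attenuation.

    ``mu`` is the linear attenuation coefficient in 1/mm at the effective
    energy; ``beta`` must satisfy mu = 4*pi*beta/lambda.
    """

    name: str
    mu: float
    delta: float
    beta: float

    def __post_init__(self) -> None:
        if self.mu < 0 or self.delta < 0:
            raise ValueError("mu and delta must be non-negative")

    @classmethod
    def from_mu(cls, name: str, mu: float, delta: float, energy_kev: float) -> "Material":
        """Build a material with beta derived from mu (1/mm) at the given energy."""
        lam = wavelength_m(energy_kev)
        beta = mu * 1e3 * lam / (4.0 * np.pi)  # mu in 1/mm -> 1/m
        return cls(name, mu, delta, beta)

    def check_consistency(self, energy_kev: float, rtol: float = 1e-9) -> bool:
        lam = wavelength_m(energy_kev)
        mu_from_beta = 4.0 * np.pi * self.beta / lam / 1e3
        return bool(abs(mu_from_beta - self.mu) <= rtol * max(self.mu, 1e-30))


def default_materials(energy_kev: float = 85.0) -> dict[int, Material]:
    """Scenario-default material table at the effective beam energy.

    Attenuation values are weak (agar-ethanol 0.018/mm, soft tissue
    0.022/mm) and delta/beta ratios are of order 10^3 so that phase
    contrast dominates absorption, as it does for ethanol-stabilised
    organs.  These are placeholders standing in for unpublished measured
    coefficients.
    """
    lam = wavelength_m(energy_kev)

    def mk(name: str, mu: float, delta_beta: float) -> Material:
        beta = mu * 1e3 * lam / (4.0 * np.pi)
        return Material(name, mu, delta_beta * beta, beta)

    return {
        LABEL_AIR: Material("air", 0.0, 0.0, 0.0),
        LABEL_JAR: mk("jar_pet", 0.030, 800.0),
        LABEL_AGAR: mk("agar_ethanol", 0.018, 1000.0),
        LABEL_TISSUE: mk("soft_tissue", 0.022, 1000.0),
        LABEL_SPHERE: mk("glomerulus", 0.026, 1000.0),
        LABEL_CONSOLIDATION: mk("consolidation", 0.024, 1000.0),
    }


@dataclass
class Phantom:
    """Labelled voxel grid plus material table and generator ground truth.

    Generators with analytic geometry may attach partial-volume
    (antialiased) ``mu_data`` / ``delta_data`` maps in which boundary
    voxels carry fractional material coverage; these are the physically
    faithful forward-model inputs, while ``labels`` stays discrete.
    """

    labels: Volume3D
    materials: dict[int, Material]
    truth: dict[str, Any] = field(default_factory=dict)
    mu_data: np.ndarray | None = None
    delta_data: np.ndarray | None = None

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels.data).tolist())
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"labels without material entry: {sorted(missing)}")

    def mu_volume(self) -> Volume3D:
        """Linear attenuation (1/mm) volume (partial-volume map if available)."""
        if self.mu_data is not None:
            return Volume3D(self.mu_data, self.labels.voxel_size, self.labels.origin)
        return self._map("mu")

    def delta_volume(self) -> Volume3D:
        """Refractive-index decrement volume (partial-volume map if available)."""
        if self.delta_data is not None:
            return Volume3D(self.delta_data, self.labels.voxel_size, self.labels.origin)
        return self._map("delta")

    def _map(self, attr: str) -> Volume3D:
        lut = np.zeros(max(self.materials) + 1, dtype=np.float32)
        for lbl, mat in self.materials.items():
            lut[lbl] = getattr(mat, attr)
        return Volume3D(
            lut[self.labels.data], self.labels.voxel_size, self.labels.origin
        )


def _radial_grid(
    shape: tuple[int, int, int],
    voxel_size: float,
    centre_offset: tuple[float, float] = (0.0, 0.0),
):
    """Radial distance (µm) of each in-slice voxel centre from the cylinder axis.

    ``centre_offset`` displaces the cylinder axis (y, x, µm) from the grid
    centre — used to emulate the eccentric jar of off-axis zoom scans,
    where the sample is translated so the VOI sits on the rotation axis.
    """
    _, ny, nx = shape
    cy = (ny - 1) / 2.0 + centre_offset[0] / voxel_size
    cx = (nx - 1) / 2.0 + centre_offset[1] / voxel_size
    y = (np.arange(ny) - cy) * voxel_size
    x = (np.arange(nx) - cx) * voxel_size
    return np.hypot(y[:, None], x[None, :])


def build_jar_phantom(
    shape: tuple[int, int, int],
    voxel_size: float,
    jar_radius: float,
    jar_wall: float,
    materials: dict[int, Material] | None = None,
    tissue_radius: float = 0.0,
    seed: int = 0,
    centre_offset: tuple[float, float] = (0.0, 0.0),
    feature_spheres: list[tuple[float, float, float, float]] | None = None,
    allow_truncated: bool = False,
) -> Phantom:
    """Concentric jar phantom: air exterior, PET wall, agar interior.

    ``jar_radius`` is the outer radius and ``jar_wall`` the wall thickness,
    both in µm.  With ``tissue_radius > 0`` a coaxial soft-tissue cylinder
    is embedded in the agar; with zero tissue the phantom is the reference
    jar used for flat-field normalisation.  ``centre_offset`` (y, x, µm)
    displaces the whole jar from the grid centre (rotation axis), as in
    off-axis zoom scans.  ``feature_spheres`` adds dense spheres
    (z, y, x, radius, µm; coordinates relative to the grid centre) as
    SNR/phase-contrast features.
    """
    if materials is None:
        materials = default_materials()
    nz, ny, nx = shape
    half_extent = min(ny, nx) / 2.0 * voxel_size
    # an eccentric jar (or one explicitly marked as truncated) may extend
    # past the sampled grid — the local-tomography case; otherwise an
    # oversized jar is a configuration error
    if (
        centre_offset == (0.0, 0.0)
        and not allow_truncated
        and jar_radius > half_extent
    ):
        raise ValueError(f"jar radius {jar_radius} exceeds half grid extent {half_extent}")
    r = _radial_grid(shape, voxel_size, centre_offset)
    sl = np.full((ny, nx), LABEL_AIR, dtype=np.uint8)
    sl[r <= jar_radius] = LABEL_JAR
    sl[r <= jar_radius - jar_wall] = LABEL_AGAR
    if tissue_radius > 0:
        sl[r <= tissue_radius] = LABEL_TISSUE
    labels = np.broadcast_to(sl, (nz, ny, nx)).copy()
    vol = Volume3D(labels, voxel_size)

    # partial-volume mu/delta maps: each radial interface gets a 1-voxel
    # linear coverage transition, the physically faithful voxelization of
    # the analytic cylinders
    def inside(radius_um: float) -> np.ndarray:
        return np.clip((radius_um - r) / voxel_size + 0.5, 0.0, 1.0)

    seq = [(LABEL_AIR, None), (LABEL_JAR, jar_radius), (LABEL_AGAR, jar_radius - jar_wall)]
    if tissue_radius > 0:
        seq.append((LABEL_TISSUE, tissue_radius))
    mu2d = np.full((ny, nx), materials[LABEL_AIR].mu, dtype=np.float64)
    de2d = np.full((ny, nx), materials[LABEL_AIR].delta, dtype=np.float64)
    prev = LABEL_AIR
    for lbl, rad in seq[1:]:
        cov = inside(rad)
        mu2d += (materials[lbl].mu - materials[prev].mu) * cov
        de2d += (materials[lbl].delta - materials[prev].delta) * cov
        prev = lbl
    mu3d = np.broadcast_to(mu2d, (nz, ny, nx)).astype(np.float32).copy()
    de3d = np.broadcast_to(de2d, (nz, ny, nx)).astype(np.float32).copy()

    if feature_spheres:
        lab3d = vol.data
        czg, cyg, cxg = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
        mat = materials[LABEL_SPHERE]
        for fz, fy, fx, fr in feature_spheres:
            vz, vy, vx = fz / voxel_size + czg, fy / voxel_size + cyg, fx / voxel_size + cxg
            rv = fr / voxel_size
            iz = slice(max(0, int(vz - rv) - 1), min(nz, int(vz + rv) + 2))
            iy = slice(max(0, int(vy - rv) - 1), min(ny, int(vy + rv) + 2))
            ix = slice(max(0, int(vx - rv) - 1), min(nx, int(vx + rv) + 2))
            zz = np.arange(iz.start, iz.stop)[:, None, None]
            yy = np.arange(iy.start, iy.stop)[None, :, None]
            xx = np.arange(ix.start, ix.stop)[None, None, :]
            dist = np.sqrt((zz - vz) ** 2 + (yy - vy) ** 2 + (xx - vx) ** 2)
            cov = np.clip(rv - dist + 0.5, 0.0, 1.0)
            mu3d[iz, iy, ix] += (mat.mu - mu3d[iz, iy, ix]) * cov
            de3d[iz, iy, ix] += (mat.delta - de3d[iz, iy, ix]) * cov
            sub = lab3d[iz, iy, ix]
            sub[cov >= 0.5] = LABEL_SPHERE
            lab3d[iz, iy, ix] = sub

    truth = {
        "kind": "jar",
        "jar_radius_um": jar_radius,
        "jar_wall_um": jar_wall,
        "tissue_radius_um": tissue_radius,
        "centre_offset_um": list(centre_offset),
        "feature_spheres_um": [list(f) for f in (feature_spheres or [])],
        "seed": seed,
    }
    return Phantom(vol, materials, truth, mu_data=mu3d, delta_data=de3d)


def reference_twin(phantom: Phantom) -> Phantom:
    """The jar-only twin of a jar-based phantom (interior all agar).

    The twin keeps the jar geometry — including any eccentric mounting
    offset — so its projections cancel the jar/agar background of the
    sample scan.
    """
    t = phantom.truth
    return build_jar_phantom(
        phantom.labels.shape,
        phantom.labels.voxel_size,
        t["jar_radius_um"],
        t["jar_wall_um"],
        materials=phantom.materials,
        tissue_radius=0.0,
        seed=int(t.get("seed", 0)),
        centre_offset=tuple(t.get("centre_offset_um", (0.0, 0.0))),
        allow_truncated=True,
    )


def build_kidney_phantom(
    shape: tuple[int, int, int],
    voxel_size: float,
    jar_radius: float,
    jar_wall: float,
    shell_inner: float,
    shell_outer: float,
    n_units: int,
    unit_radius: tuple[float, float],
    min_separation: float,
    materials: dict[int, Material] | None = None,
    seed: int = 0,
    max_retries: int = 100_000,
) -> Phantom:
    """Kidney-like phantom: parenchyma shell studded with dense spheres.

    The parenchyma is a coaxial cylindrical annulus (``shell_inner`` to
    ``shell_outer`` µm) inside the agar.  ``n_units`` spheres with radii
    drawn uniformly from ``unit_radius = (r_lo, r_hi)`` are packed by
    rejection sampling with centres uniform in the shell and pairwise
    centre separation ``>= min_separation``.  Ground truth records every
    centre and radius, so stereological estimates can be checked exactly.
    """
    if materials is None:
        materials = default_materials()
    base = build_jar_phantom(shape, voxel_size, jar_radius, jar_wall, materials, seed=seed)
    labels = base.labels.data.copy()
    nz, ny, nx = shape
    r = _radial_grid(shape, voxel_size)
    shell2d = (r >= shell_inner) & (r <= shell_outer)
    labels[:, shell2d] = LABEL_TISSUE

    rng = rng_for(seed, "kidney-pack")
    cy, cx = (ny - 1) / 2.0 * voxel_size, (nx - 1) / 2.0 * voxel_size
    zmax = (nz - 1) * voxel_size
    centres: list[np.ndarray] = []
    radii: list[float] = []
    tries = 0
    while len(centres) < n_units:
        if tries >= max_retries:
            raise RuntimeError(
                f"infeasible packing: placed {len(centres)} of {n_units} spheres "
                f"after {max_retries} retries"
            )
        tries += 1
        unit_r = float(rng.uniform(*unit_radius))
        # area-uniform radial sampling (pdf proportional to r) so the
        # number density is uniform over the shell volume; the axial range
        # keeps the sphere inside the sampled grid
        rad = np.sqrt(rng.uniform(shell_inner**2, shell_outer**2))
        th = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(unit_r, max(zmax - unit_r, unit_r))
        c = np.array([z, cy + rad * np.sin(th), cx + rad * np.cos(th)])
        if centres and np.min(np.linalg.norm(np.array(centres) - c, axis=1)) < min_separation:
            continue
        centres.append(c)
        radii.append(unit_r)

    # voxelise spheres
    if centres:
        zz = np.arange(nz)[:, None, None] * voxel_size
        yy = np.arange(ny)[None, :, None] * voxel_size
        xx = np.arange(nx)[None, None, :] * voxel_size
        for c, rad in zip(centres, radii):
            iz = slice(
                max(0, int((c[0] - rad) / voxel_size) - 1),
                min(nz, int((c[0] + rad) / voxel_size) + 2),
            )
            iy = slice(
                max(0, int((c[1] - rad) / voxel_size) - 1),
                min(ny, int((c[1] + rad) / voxel_size) + 2),
            )
            ix = slice(
                max(0, int((c[2] - rad) / voxel_size) - 1),
                min(nx, int((c[2] + rad) / voxel_size) + 2),
            )
            d2 = (
                (zz[iz] - c[0]) ** 2
                + (yy[:, iy] - c[1]) ** 2
                + (xx[:, :, ix] - c[2]) ** 2
            )
            sub = labels[iz, iy, ix]
            sub[d2 <= rad**2] = LABEL_SPHERE
            labels[iz, iy, ix] = sub

    vol = Volume3D(labels, voxel_size)
    truth = dict(base.truth)
    truth.update(
        kind="kidney",
        shell_inner_um=shell_inner,
        shell_outer_um=shell_outer,
        centres_um=[c.tolist() for c in centres],
        radii_um=radii,
        n_units=n_units,
        min_separation_um=min_separation,
    )
    return Phantom(vol, materials, truth)


def build_alveolar_phantom(
    shape: tuple[int, int, int],
    voxel_size: float,
    mean_cell_diameter: float,
    wall_thickness: float,
    consolidation_fraction: float = 0.0,
    materials: dict[int, Material] | None = None,
    seed: int = 0,
    consolidation_film_um: float = 0.0,
) -> Phantom:
    """Thin-walled Voronoi foam emulating alveolar airspace and septa.

    Poisson-disk-like seed points (minimum spacing ~0.7 of the mean cell
    diameter) define Voronoi cells.  Voxels within ``wall_thickness`` of a
    cell boundary (measured as the difference of the two nearest-seed
    distances) become tissue; cell interiors are airspace.  A uniformly
    random fraction ``consolidation_fraction`` of cells is filled with
    consolidation material, emulating parenchymal consolidation.

    With ``consolidation_film_um > 0`` each consolidated cell keeps a thin
    residual air film of that thickness along its septa — the small
    unconnected ventilated pockets seen in consolidated parenchyma, which
    make the pooled airspace-diameter distribution bimodal.
    """
    if materials is None:
        materials = default_materials()
    if wall_thickness < voxel_size:
        raise ValueError("wall thickness must be at least one voxel")
    if not 0.0 <= consolidation_fraction <= 1.0:
        raise ValueError("consolidation fraction must be in [0, 1]")

    nz, ny, nx = shape
    extent = np.array([nz, ny, nx]) * voxel_size
    rng = rng_for(seed, "alveolar-seeds")
    target_n = max(4, int(np.ceil(np.prod(extent) / (mean_cell_diameter**3))))
    min_sep = 0.7 * mean_cell_diameter
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < target_n and tries < 50 * target_n:
        tries += 1
        c = rng.uniform(0, 1, 3) * extent
        if pts and np.min(np.linalg.norm(np.array(pts) - c, axis=1)) < min_sep:
            continue
        pts.append(c)
    seeds = np.array(pts)

    tree = cKDTree(seeds)
    zz = np.arange(nz) * voxel_size
    yy = np.arange(ny) * voxel_size
    xx = np.arange(nx) * voxel_size
    grid = np.stack(np.meshgrid(zz, yy, xx, indexing="ij"), axis=-1).reshape(-1, 3)
    dist, idx = tree.query(grid, k=2, workers=-1)
    d1, d2 = dist[:, 0], dist[:, 1]
    cell = idx[:, 0].reshape(shape)
    # moving distance s off the bisector changes d2-d1 by 2s: |d2-d1| < t_w
    # carves a wall of total thickness t_w
    wall = (d2 - d1 < wall_thickness).reshape(shape)

    n_cells = len(seeds)
    consolidated = np.zeros(n_cells, dtype=bool)
    n_cons = int(round(consolidation_fraction * n_cells))
    if n_cons:
        consolidated[rng_for(seed, "alveolar-consolidation").choice(n_cells, n_cons, replace=False)] = True

    labels = np.where(wall, LABEL_TISSUE, LABEL_AIR).astype(np.uint8)
    fill = ~wall & consolidated[cell]
    if consolidation_film_um > 0:
        # the layer within `film` of the wall face stays air: d2 - d1
        # increases by 2 per unit distance from the cell boundary
        gap = (d2 - d1).reshape(shape)
        film = (gap >= wall_thickness) & (
            gap < wall_thickness + 2.0 * consolidation_film_um
        )
        fill &= ~film
    labels[fill] = LABEL_CONSOLIDATION

    vol = Volume3D(labels, voxel_size)
    air_frac = float(np.mean(labels == LABEL_AIR))
    truth = {
        "kind": "alveolar",
        "wall_thickness_um": wall_thickness,
        "consolidation_fraction": consolidation_fraction,
        "mean_cell_diameter_um": mean_cell_diameter,
        "n_cells": n_cells,
        "cell_consolidated": consolidated.tolist(),
        "airspace_fraction": air_frac,
        "seed": seed,
    }
    return Phantom(vol, materials, truth)
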