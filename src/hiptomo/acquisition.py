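"""Parallel-beam, effective-monochromatic forward simulator of HiP-CT scans.

The simulator produces line integrals of attenuation and phase through a
phantom, free-space Fresnel propagation to the detector, multiplicative
beam profiles, Poisson + read noise, sub-frame accumulation, off-centre
(half/annular) rotation geometries, vertical series planning, and the
reference-jar scans used for local-tomography flat fielding.

A monochromatic effective energy stands in for the polychromatic beam;
beam hardening is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .core_io import rng_for
from .phantom import Phantom, reference_twin, wavelength_m

__all__ = [
    "BeamModel",
    "ScanGeometry",
    "ProjectionSet",
    "forward_project",
    "fresnel_propagate",
    "apply_beam_and_noise",
    "simulate_scan",
    "plan_vertical_series",
]

MAX_PROPAGATION_M = 3.5  # physical hutch limit


def scan_preset(name: str) -> tuple["BeamModel", "ScanGeometry"]:
    """Named scan presets: per-organ acquisition settings at desk scale.

    Each preset keeps the published protocol structure — effective beam
    energy, acquisition mode, accumulation count, vertical step — with
    detector grids scaled down ~15x so a scan simulates in seconds.
    """
    presets = {
        # whole-organ overview scans: attenuation protocol, half mode,
        # 10 accumulation sub-frames
        "donor1_kidney_25um": dict(
            energy_kev=85.0, mode="half", cor_offset=60, n_subframes=10,
            n_projections=720, angular_range=360.0, pixel_size_um=25.08,
            vertical_step_mm=2.2, beam_height_mm=2.6, distance_m=3.5,
        ),
        "donor1_lung_25um": dict(
            energy_kev=85.0, mode="half", cor_offset=60, n_subframes=10,
            n_projections=720, angular_range=360.0, pixel_size_um=25.08,
            vertical_step_mm=2.2, beam_height_mm=2.6, distance_m=3.5,
        ),
        # zoom column: phase-dominated, 5 sub-frames
        "donor1_kidney_6um": dict(
            energy_kev=85.0, mode="centered", cor_offset=0, n_subframes=5,
            n_projections=720, angular_range=180.0, pixel_size_um=6.05,
            vertical_step_mm=2.2, beam_height_mm=2.6, distance_m=3.5,
        ),
        # highest-resolution VOI: no accumulation, near-field distance
        "donor1_kidney_1p3um": dict(
            energy_kev=69.0, mode="centered", cor_offset=0, n_subframes=1,
            n_projections=720, angular_range=180.0, pixel_size_um=1.29,
            vertical_step_mm=1.0, beam_height_mm=1.2, distance_m=1.3,
        ),
        "donor1_lung_2p5um": dict(
            energy_kev=70.0, mode="centered", cor_offset=0, n_subframes=1,
            n_projections=720, angular_range=180.0, pixel_size_um=2.45,
            vertical_step_mm=1.0, beam_height_mm=1.2, distance_m=1.3,
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    p = presets[name]
    beam = BeamModel(energy_kev=p["energy_kev"], propagation_distance_m=p["distance_m"])
    geom = ScanGeometry(
        mode=p["mode"], detector_width=256, detector_height=4,
        cor_offset=p["cor_offset"], n_projections=p["n_projections"],
        angular_range=p["angular_range"], n_subframes=p["n_subframes"],
        vertical_step_mm=p["vertical_step_mm"], beam_height_mm=p["beam_height_mm"],
        pixel_size_um=p["pixel_size_um"],
    )
    return beam, geom


@dataclass
class BeamModel:
    """Beam energy, propagation distance, profiles, flux and noise.

    ``horizontal_profile`` is ``(amplitude, centre_px, sigma_px)`` of a
    multiplicative Gaussian across detector columns (the natural horizontal
    profile the off-axis protocol exploits); ``vertical_profile`` is an
    optional per-row multiplicative vector.
    """

    energy_kev: float = 85.0
    propagation_distance_m: float = 0.0
    horizontal_profile: tuple[float, float, float] | None = None
    vertical_profile: np.ndarray | None = None
    flux: float = 40_000.0
    read_noise_sigma: float = 1.0
    column_gain_error: float = 0.0  # stdev of fixed per-column gain field

    def __post_init__(self) -> None:
        if not 0.0 <= self.propagation_distance_m <= MAX_PROPAGATION_M:
            raise ValueError(
                f"propagation distance must lie in [0, {MAX_PROPAGATION_M}] m"
            )
        if self.energy_kev <= 0:
            raise ValueError("energy must be positive")

    @property
    def wavelength_m(self) -> float:
        return wavelength_m(self.energy_kev)

    def profile(self, n_rows: int, n_cols: int) -> tuple[np.ndarray, np.ndarray]:
        """Multiplicative row/column beam profiles h(x), v(y), strictly positive."""
        if self.horizontal_profile is None:
            h = np.ones(n_cols)
        else:
            amp, centre, sigma = self.horizontal_profile
            x = np.arange(n_cols)
            h = 1.0 + amp * np.exp(-0.5 * ((x - centre) / sigma) ** 2)
        if self.vertical_profile is None:
            v = np.ones(n_rows)
        else:
            v = np.asarray(self.vertical_profile, dtype=np.float64)
            if v.shape != (n_rows,):
                raise ValueError("vertical profile length must equal detector rows")
        if (h <= 0).any() or (v <= 0).any():
            raise ValueError("beam profiles must be strictly positive")
        return h, v


@dataclass
class ScanGeometry:
    """Rotation geometry and detector layout of one scan.

    ``cor_offset`` is the signed shift (px) of the rotation centre from the
    detector mid-column; half-acquisition requires ``0 < cor_offset < W/2``
    and a 360 degree angular range.
    """

    mode: str = "centered"  # {"centered", "half", "quarter_annular"}
    detector_width: int = 256
    detector_height: int = 8
    cor_offset: int = 0
    n_projections: int = 720
    angular_range: float = 180.0
    n_subframes: int = 1
    vertical_step_mm: float = 2.2
    beam_height_mm: float = 2.6
    pixel_size_um: float = 25.0

    def __post_init__(self) -> None:
        if self.mode not in {"centered", "half", "quarter_annular"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "half":
            if not 0 < self.cor_offset < self.detector_width / 2:
                raise ValueError("half mode requires 0 < cor_offset < W/2")
            if self.angular_range != 360.0:
                raise ValueError("half mode requires a 360 degree angular range")
        if self.mode == "quarter_annular":
            if self.cor_offset < self.detector_width / 2:
                raise ValueError("annular mode requires cor_offset >= W/2")
            if self.angular_range != 360.0:
                raise ValueError("annular mode requires a 360 degree angular range")
        if self.n_subframes < 1:
            raise ValueError("n_subframes must be >= 1")
        if self.beam_height_mm < self.vertical_step_mm:
            raise ValueError("beam height must cover the vertical step")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.linspace(0.0, self.angular_range, self.n_projections, endpoint=False)

    @property
    def cor_col(self) -> float:
        """Rotation-centre column index on the detector."""
        return (self.detector_width - 1) / 2.0 + self.cor_offset


@dataclass
class ProjectionSet:
    """Simulated detector frames plus flats, darks and reference-jar frames.

    ``frames`` has shape (n_z, n_angles, n_subframes, rows, cols); the
    reference frames share the angular grid and geometry of the sample scan.
    """

    frames: np.ndarray
    angles_deg: np.ndarray
    flats: np.ndarray
    darks: np.ndarray
    reference_frames: np.ndarray
    geometry: ScanGeometry
    beam: BeamModel
    truncated: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def accumulated(self) -> np.ndarray:
        """Arithmetic mean over sub-frames, shape (n_z, n_angles, rows, cols)."""
        return self.frames.mean(axis=2)


# ---------------------------------------------------------------------------
# physics


def forward_project(
    phantom: Phantom,
    angle_deg: float,
    geometry: ScanGeometry,
    z_slices: slice | None = None,
    wavelength: float | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Line integrals (A, Phi) through the phantom at one rotation angle.

    Returns ``A = integral of mu ds`` (dimensionless) and
    ``Phi = -(2*pi/lambda) * integral of delta ds`` per detector pixel, plus a
    flag marking lateral truncation (rays leaving the sampled grid inside
    the jar — expected for local tomography, not an error).

    The rotation axis is the z axis through the grid centre; detector
    column ``c`` samples the lateral position ``(c - cor_col) * pixel``.
    """
    mu = phantom.mu_volume().data
    delta = phantom.delta_volume().data
    if z_slices is not None:
        mu = mu[z_slices]
        delta = delta[z_slices]
    vs_um = phantom.labels.voxel_size

    # rotate slices about the grid centre, then integrate along rows (y)
    both = np.stack([mu, delta]).astype(np.float32)
    if angle_deg % 360.0 != 0.0:
        both = ndimage.rotate(
            both, angle_deg, axes=(2, 3), reshape=False, order=1, mode="constant", cval=0.0
        )
    sums = both.sum(axis=2)  # (2, nz, nx_grid)
    a_full = sums[0] * (vs_um * 1e-3)  # mu in 1/mm, ds in mm
    phi_full = sums[1] * (vs_um * 1e-6)  # delta integral with ds in m

    # map grid columns to detector columns
    nz, nx_grid = a_full.shape
    wd = geometry.detector_width
    grid_centre = (nx_grid - 1) / 2.0
    det_cols = np.arange(wd)
    src = grid_centre + (det_cols - geometry.cor_col)
    inside = (src >= 0) & (src <= nx_grid - 1)
    src_c = np.clip(src, 0, nx_grid - 1)
    lo = np.floor(src_c).astype(int)
    hi = np.minimum(lo + 1, nx_grid - 1)
    w = src_c - lo
    A = (1 - w) * a_full[:, lo] + w * a_full[:, hi]
    Phi = (1 - w) * phi_full[:, lo] + w * phi_full[:, hi]
    A[:, ~inside] = 0.0
    Phi[:, ~inside] = 0.0
    # truncation: non-zero projection values at detector edges, or the grid
    # itself extends beyond the detector
    lam = wavelength if wavelength is not None else wavelength_m(85.0)
    truncated = bool(
        (not inside.all())
        or (A[:, 0].max(initial=0.0) > 1e-6)
        or (A[:, -1].max(initial=0.0) > 1e-6)
        or nx_grid - 1 > src.max()
    )
    k = 2.0 * np.pi / lam
    return A, -k * Phi, truncated


def fresnel_propagate(
    A: np.ndarray,
    Phi: np.ndarray,
    wavelength_m_: float,
    distance_m: float,
    pixel_size_um: float,
    pad_frac: float = 0.25,
) -> np.ndarray:
    """Near-field free-space propagation of the exit wave to the detector.

    ``I = |IFFT[ FFT[exp(-A/2 + i*Phi)] * H_D ]|^2`` with the Fresnel transfer
    function ``H_D = exp(-i*pi*lambda*D*(u^2 + v^2))`` (u, v in cycles/length).
    ``D = 0`` returns the contact-plane intensity ``exp(-A)`` exactly.
    Arrays are symmetrically edge-padded by ``pad_frac`` of each dimension
    to suppress FFT wrap-around.
    """
    if distance_m < 0:
        raise ValueError("propagation distance must be non-negative")
    if distance_m == 0.0:
        return np.exp(-A)
    field2 = np.exp(-A / 2.0 + 1j * Phi)
    py = max(8, int(A.shape[0] * pad_frac))
    px = max(8, int(A.shape[1] * pad_frac))
    fp = np.pad(field2, ((py, py), (px, px)), mode="edge")
    px_m = pixel_size_um * 1e-6
    u = np.fft.fftfreq(fp.shape[0], d=px_m)
    v = np.fft.fftfreq(fp.shape[1], d=px_m)
    chirp = np.exp(
        -1j * np.pi * wavelength_m_ * distance_m * (u[:, None] ** 2 + v[None, :] ** 2)
    )
    out = np.fft.ifft2(np.fft.fft2(fp) * chirp)
    inten = np.abs(out) ** 2
    return inten[py : py + A.shape[0], px : px + A.shape[1]]


def apply_beam_and_noise(
    I: np.ndarray,
    beam: BeamModel,
    seed: int | None = None,
    noise: bool = True,
    gain_field: np.ndarray | None = None,
) -> np.ndarray:
    """Scale intensity by flux and beam profiles and draw detector counts.

    Counts are Poisson(flux * I * h(x) * v(y) * gain) plus Gaussian read
    noise; with ``noise=False`` the noiseless expectation is returned.
    ``gain_field`` is an optional fixed per-column gain error used to drive
    ring artefacts.
    """
    if beam.flux <= 0:
        raise ValueError("flux must be positive")
    h, v = beam.profile(*I.shape)
    expect = beam.flux * I * v[:, None] * h[None, :]
    if gain_field is not None:
        expect = expect * gain_field[None, :]
    if not noise:
        return expect
    rng = rng_for(0 if seed is None else seed, "counts")
    counts = rng.poisson(expect).astype(np.float64)
    if beam.read_noise_sigma > 0:
        counts += rng.normal(0.0, beam.read_noise_sigma, size=counts.shape)
    return counts


def simulate_scan(
    phantom: Phantom,
    beam: BeamModel,
    geometry: ScanGeometry,
    seed: int = 0,
    noise: bool = True,
    reference_phantom: Phantom | None = None,
    n_flats: int = 4,
    n_darks: int = 4,
) -> ProjectionSet:
    """Simulate a full scan: sample frames, flats, darks and reference frames.

    The reference phantom defaults to the jar-only twin of the sample
    (same jar geometry, agar-filled interior), scanned on the same angular
    grid and lateral offset with an independent noise stream.  Because the
    reference jar is axisymmetric about the rotation axis its clean
    projection is computed once and reused for every angle.
    """
    if reference_phantom is None:
        reference_phantom = reference_twin(phantom)
    angles = geometry.angles_deg
    nz = phantom.labels.shape[0]
    rows, cols = nz, geometry.detector_width
    lam = beam.wavelength_m
    h, v = beam.profile(rows, cols)

    gain_field = None
    if beam.column_gain_error > 0:
        gain_field = 1.0 + rng_for(seed, "gain").normal(
            0.0, beam.column_gain_error, size=cols
        )

    frames = np.empty((1, len(angles), geometry.n_subframes, rows, cols), dtype=np.float64)
    truncated = False
    for ia, ang in enumerate(angles):
        A, Phi, trunc = _project_with_beam(phantom, ang, geometry, lam)
        truncated |= trunc
        I = fresnel_propagate(A, Phi, lam, beam.propagation_distance_m, geometry.pixel_size_um)
        for s in range(geometry.n_subframes):
            frames[0, ia, s] = apply_beam_and_noise(
                I, beam, seed=_sub_seed(seed, "sample", ia, s), noise=noise,
                gain_field=gain_field,
            )

    # reference jar: when mounted on the rotation axis it is axisymmetric
    # and one clean projection serves every angle; an eccentric jar (off-
    # axis zoom scans) is projected per angle like the sample
    ref_axisym = tuple(
        reference_phantom.truth.get("centre_offset_um", (0.0, 0.0))
    ) == (0.0, 0.0)
    reference = np.empty((len(angles), rows, cols), dtype=np.float64)
    I0 = None
    for ia, ang in enumerate(angles):
        if I0 is None or not ref_axisym:
            A0, P0, _ = _project_with_beam(
                reference_phantom, 0.0 if ref_axisym else ang, geometry, lam
            )
            I0 = fresnel_propagate(
                A0, P0, lam, beam.propagation_distance_m, geometry.pixel_size_um
            )
        sub = np.stack(
            [
                apply_beam_and_noise(
                    I0, beam, seed=_sub_seed(seed, "reference", ia, s), noise=noise,
                    gain_field=gain_field,
                )
                for s in range(geometry.n_subframes)
            ]
        )
        reference[ia] = sub.mean(axis=0)

    flat_expect = np.ones((rows, cols))
    flats = np.stack(
        [
            apply_beam_and_noise(
                flat_expect, beam, seed=_sub_seed(seed, "flat", i, 0), noise=noise,
                gain_field=gain_field,
            )
            for i in range(n_flats)
        ]
    )
    darks = np.zeros((n_darks, rows, cols))
    if noise and beam.read_noise_sigma > 0:
        rng = rng_for(seed, "darks")
        darks = rng.normal(0.0, beam.read_noise_sigma, size=darks.shape)

    return ProjectionSet(
        frames=frames,
        angles_deg=angles,
        flats=flats,
        darks=darks,
        reference_frames=reference,
        geometry=geometry,
        beam=beam,
        truncated=truncated,
        meta={"seed": seed, "noise": noise},
    )


def _project_with_beam(phantom, angle, geometry, lam):
    return forward_project(phantom, angle, geometry, wavelength=lam)


def _sub_seed(seed: int, stream: str, i: int, j: int) -> int:
    import zlib

    tag = zlib.crc32(f"{stream}:{i}:{j}".encode())
    return (seed * 1_000_003 + tag) & 0x7FFFFFFF


def plan_vertical_series(
    organ_height_mm: float, beam_height_mm: float, step_mm: float
) -> tuple[np.ndarray, int]:
    """z positions of a vertical series and the nominal overlap percentage.

    Overlap is ``100 * (beam_height - step) / step`` rounded to the nearest
    integer; positions start at 0 and advance by ``step`` until the organ
    height is covered by the beam.
    """
    if not 0 < step_mm <= beam_height_mm:
        raise ValueError("require 0 < step <= beam height (a larger step leaves gaps)")
    if beam_height_mm > organ_height_mm:
        return np.array([0.0]), int(round(100.0 * (beam_height_mm - step_mm) / step_mm))
    n = int(np.ceil((organ_height_mm - beam_height_mm) / step_mm)) + 1
    z = np.arange(n) * step_mm
    overlap = int(round(100.0 * (beam_height_mm - step_mm) / step_mm))
    return z, overlap
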