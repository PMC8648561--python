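"""End-to-end simulation scenarios combining phantom, scan and reconstruction.

These are the study protocols exercised by the test suite and the
acceptance script: the centred round trip, the half-acquisition /
wide-detector comparison, the paired reference-vs-classical flat-field
local-tomography run, and the lateral SNR transect that probes image
quality as a function of distance from the rotation centre.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from . import phantom as ph
from .acquisition import BeamModel, ScanGeometry, simulate_scan
from .quality import snr
from .reconstruction import reconstruct_projection_set

__all__ = [
    "centered_roundtrip",
    "local_tomography_pair",
    "cupping_amplitude",
    "lateral_transect_snr",
]


def centered_roundtrip(
    n: int = 256,
    n_projections: int = 720,
    voxel_size: float = 25.0,
    noise: bool = False,
    n_subframes: int = 1,
    flux: float = 40_000.0,
    window: str = "ramp",
    use_reference: bool = False,
    seed: int = 0,
):
    """Simulate and reconstruct a centred jar scan; return (recon, mu_truth).

    The jar diameter fills ~88% of the field of view with a 2 mm PET wall
    and a coaxial soft-tissue cylinder.  Truth is the partial-volume mu
    map masked to the reconstructed field-of-view disc.
    """
    jar_r = 0.44 * n * voxel_size
    phan = ph.build_jar_phantom(
        (1, n, n), voxel_size, jar_r, 2000.0, tissue_radius=jar_r / 2.0, seed=seed
    )
    geom = ScanGeometry(
        mode="centered",
        detector_width=n,
        detector_height=1,
        n_projections=n_projections,
        angular_range=180.0,
        pixel_size_um=voxel_size,
        n_subframes=n_subframes,
    )
    beam = BeamModel(flux=flux)
    pset = simulate_scan(phan, beam, geom, seed=seed, noise=noise)
    vol = reconstruct_projection_set(
        pset, use_reference=use_reference, window=window
    )
    mu = phan.mu_volume().data[0]
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    fov = (y - c) ** 2 + (x - c) ** 2 <= (n / 2.0) ** 2
    return vol.data[0], np.where(fov, mu, 0.0).astype(np.float32), phan


def local_tomography_pair(
    n_grid: int = 320,
    detector_width: int = 128,
    jar_offset_um: float = 1200.0,
    n_projections: int = 360,
    voxel_size: float = 25.0,
    noise: bool = False,
    seed: int = 0,
):
    """Truncated off-axis scan reconstructed with reference vs classical flats.

    The jar is mounted eccentrically (VOI on the rotation axis) and is much
    wider than the detector, so every projection is laterally truncated.
    The tissue cylinder covers the whole VOI, so the true attenuation is
    constant across the field of view and any reconstructed low-frequency
    variation is artefact.  Returns ``(recon_reference, recon_classical)``
    restricted to the VOI disc.
    """
    jar_r = 0.45 * n_grid * voxel_size
    phan = ph.build_jar_phantom(
        (1, n_grid, n_grid),
        voxel_size,
        jar_r,
        2000.0,
        tissue_radius=jar_r - 2600.0,
        centre_offset=(0.0, jar_offset_um),
        seed=seed,
    )
    geom = ScanGeometry(
        mode="centered",
        detector_width=detector_width,
        detector_height=1,
        n_projections=n_projections,
        angular_range=180.0,
        pixel_size_um=voxel_size,
    )
    beam = BeamModel()
    pset = simulate_scan(phan, beam, geom, seed=seed, noise=noise)
    rec_ref = reconstruct_projection_set(
        pset, use_reference=True, window="hann", local=True
    ).data[0]
    rec_cls = reconstruct_projection_set(
        pset, use_reference=False, window="hann", local=True
    ).data[0]
    return rec_ref, rec_cls


def cupping_amplitude(slice_img: np.ndarray, interior_frac: float = 0.7,
                      smooth_sigma: float = 8.0) -> float:
    """Peak-to-peak amplitude of the low-frequency background of a slice.

    The slice is smoothed (sigma in px) and the amplitude taken over the
    central disc covering ``interior_frac`` of the half-width — the
    signature of local-tomography cupping.
    """
    sm = ndimage.gaussian_filter(slice_img, smooth_sigma)
    n = slice_img.shape[0]
    c = (n - 1) / 2.0
    y, x = np.mgrid[0 : slice_img.shape[0], 0 : slice_img.shape[1]]
    disc = (y - c) ** 2 + (x - c) ** 2 <= (interior_frac * n / 2.0) ** 2
    return float(sm[disc].max() - sm[disc].min())


def lateral_transect_snr(
    offsets_um: tuple[float, ...] = (0.0, 600.0, 1200.0, 1800.0, 2400.0),
    n_grid: int = 320,
    detector_width: int = 128,
    n_projections: int = 360,
    voxel_size: float = 25.0,
    feature_radius_um: float = 150.0,
    seed: int = 0,
    n_replicates: int = 1,
):
    """SNR of point-like features vs lateral distance from the jar axis.

    One zoom scan per offset: the jar is translated so the VOI sits on the
    rotation axis (jar increasingly eccentric), giving increasingly
    asymmetric truncation.  Each VOI contains three dense spheres in agar;
    SNR is (feature mean - background mean) / background std in the
    reconstruction.  Returns ``(snr_values, pearson_r, p_value)`` where
    the correlation is computed over all scans (``n_replicates``
    independent noise realisations per offset; with few offsets the
    sample correlation of a flat relationship is noisy, so replicates
    tighten its null distribution).

    The jar interior is wide enough that every VOI sits in agar; the jar
    may extend beyond the sampled grid — that clipping is shared by the
    sample and reference scans and cancels in the flat-field ratio.
    """
    beam = BeamModel()
    geom = ScanGeometry(
        mode="centered",
        detector_width=detector_width,
        detector_height=1,
        n_projections=n_projections,
        angular_range=180.0,
        pixel_size_um=voxel_size,
    )
    jar_r = max(offsets_um) + 1600.0 + 2000.0  # VOI margin + wall
    feats = [(0.0, 0.0, 0.0), (0.0, 500.0, 500.0), (0.0, -500.0, 400.0)]
    snrs = []
    off_list = [off for off in offsets_um for _ in range(n_replicates)]
    for k, off in enumerate(off_list):
        phan = ph.build_jar_phantom(
            (1, n_grid, n_grid),
            voxel_size,
            jar_r,
            2000.0,
            tissue_radius=0.0,
            centre_offset=(0.0, -off),
            feature_spheres=[(z, y, x, feature_radius_um) for z, y, x in feats],
            seed=seed + k,
            allow_truncated=True,
        )
        pset = simulate_scan(phan, beam, geom, seed=seed + 17 * k + 1, noise=True)
        rec = reconstruct_projection_set(
            pset, use_reference=True, window="hann", local=True
        ).data[0]
        nr = rec.shape[0]  # VOI recon is detector-width sized, axis-centred
        c = (nr - 1) / 2.0
        y, x = np.mgrid[0:nr, 0:nr]
        ft = np.zeros_like(rec, dtype=bool)
        bg = np.zeros_like(rec, dtype=bool)
        rad_v = feature_radius_um / voxel_size
        for fz, fy, fx in feats:
            vy, vx = c + fy / voxel_size, c + fx / voxel_size
            d = np.hypot(y - vy, x - vx)
            ft |= d <= 0.6 * rad_v
            bg |= (d > 2.0 * rad_v) & (d <= 3.0 * rad_v)
        # keep background inside the VOI disc and away from all features
        for fz, fy, fx in feats:
            vy, vx = c + fy / voxel_size, c + fx / voxel_size
            bg &= np.hypot(y - vy, x - vx) > 1.5 * rad_v
        bg &= np.hypot(y - c, x - c) <= 0.45 * detector_width
        snrs.append(snr(rec, ft, bg))
    r, p = stats.pearsonr(np.asarray(off_list), np.asarray(snrs))
    return np.asarray(snrs), float(r), float(p)
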