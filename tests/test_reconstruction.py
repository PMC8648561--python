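"""Reconstruction chain: preprocessing, retrieval, assembly, FBP, artefacts."""

import numpy as np
import pytest
from scipy import ndimage

from hiptomo import phantom as ph
from hiptomo.acquisition import BeamModel, ScanGeometry, simulate_scan
from hiptomo.core_io import Volume3D
from hiptomo.reconstruction import (
    RetrievalParams,
    Sinogram,
    accumulate,
    build_annular_sinogram,
    build_half_sinogram,
    classical_flatfield,
    concat_vertical,
    fbp,
    paganin_retrieve,
    reconstruct_local,
    reference_flatfield,
    remove_rings,
    remove_stripes,
    stitch_quarter,
    subtract_vertical_residual,
    to_uint16,
    unsharp_mask,
)


# ---------------------------------------------------------------------- accumulate


def test_accumulate_identical_frames_identity():
    f = np.random.default_rng(0).normal(size=(4, 6))
    out, flagged = accumulate([f, f, f])
    np.testing.assert_allclose(out, f)
    assert not flagged.any()


def test_accumulate_variance_scaling():
    rng = np.random.default_rng(1)
    n = 10
    means = np.stack(
        [accumulate(rng.normal(0, 1, size=(n, 32, 32)))[0] for _ in range(300)]
    )
    var = means.var()
    assert abs(var - 1.0 / n) < 0.1 / n


def test_accumulate_saturation_flagging():
    sub = np.stack([np.full((2, 2), 10.0), np.full((2, 2), 20.0), np.full((2, 2), 7e4)])
    frame, flagged = accumulate(sub, full_well=60000)
    assert flagged.all()
    np.testing.assert_allclose(frame, 15.0)  # mean of unsaturated sub-frames


def test_accumulate_empty_rejected():
    with pytest.raises(ValueError):
        accumulate(np.empty((0, 4, 4)))


# ------------------------------------------------------------------- flat fielding


def test_reference_flatfield_self_is_unity(small_jar):
    ref = ph.reference_twin(small_jar)
    g = ScanGeometry(detector_width=128, detector_height=2, n_projections=20,
                     angular_range=180.0, pixel_size_um=25.0)
    pset = simulate_scan(ref, BeamModel(), g, seed=0, noise=False)
    out = reference_flatfield(pset.accumulated()[0], pset.reference_frames)
    # limited by the interpolation error of the rotated forward projection
    np.testing.assert_allclose(out, 1.0, atol=5e-3)


def test_reference_flatfield_equals_classical_for_constant_beam():
    rng = np.random.default_rng(2)
    proj = rng.uniform(0.5, 1.0, size=(30, 4, 16))
    flat = np.full((4, 16), 2.0)
    refs = np.broadcast_to(flat, (30, 4, 16)).copy()
    a = reference_flatfield(proj, refs, window=10)
    b = classical_flatfield(proj, flat)
    np.testing.assert_allclose(a, b)


def test_reference_flatfield_tracks_drift():
    # linear beam drift: windowed reference removes >90% of it
    n = 100
    drift = 1.0 + 0.2 * np.linspace(0, 1, n)
    proj = drift[:, None, None] * np.ones((n, 2, 8))
    refs = proj.copy()
    out = reference_flatfield(proj, refs, window=5)
    residual = out.max() - out.min()
    assert residual < 0.1 * 0.2


def test_reference_flatfield_nonpositive_rejected():
    with pytest.raises(ValueError):
        reference_flatfield(np.ones((4, 2, 2)), np.zeros((4, 2, 2)))


# --------------------------------------------------------------- vertical residual


def test_vertical_residual_injection_removed():
    rng = np.random.default_rng(3)
    proj = rng.normal(0, 0.01, size=(60, 12, 32)) + 1.0
    offsets = rng.normal(0, 0.05, size=12)
    out = subtract_vertical_residual(proj + offsets[None, :, None])
    per_row = np.array([(out[:, k] - proj[:, k]).mean() for k in range(12)])
    amp_in = np.abs(offsets - offsets.mean()).max()
    assert np.abs(per_row - per_row.mean()).max() < 0.05 * amp_in


def test_vertical_residual_zero_input_unchanged_and_mean_preserved():
    proj = np.random.default_rng(4).normal(1.0, 0.2, size=(40, 6, 16))
    out = subtract_vertical_residual(proj)
    assert abs(out.mean() - proj.mean()) < 1e-9
    flat = np.ones((10, 4, 8))
    np.testing.assert_allclose(subtract_vertical_residual(flat), flat, atol=1e-6)


# ---------------------------------------------------------------- phase retrieval


def test_paganin_uniform_input_exact():
    p = RetrievalParams(delta_beta=800.0, distance_m=1.2, pixel_size_um=6.0)
    I = np.full((16, 16), np.exp(-0.7))
    np.testing.assert_allclose(paganin_retrieve(I, p), 0.7, atol=1e-12)


def test_paganin_zero_distance_is_minus_log():
    I = np.random.default_rng(5).uniform(0.4, 1.0, (8, 8))
    p = RetrievalParams(distance_m=0.0)
    np.testing.assert_allclose(paganin_retrieve(I, p), -np.log(I), rtol=1e-14)


def test_paganin_matches_direct_dft_oracle():
    # brute-force DFT implementation of the same filter on 64x64
    p = RetrievalParams(delta_beta=500.0, distance_m=1.0,
                       wavelength_m=1.55e-11, pixel_size_um=5.0)
    yy, xx = np.mgrid[0:64, 0:64]
    I = 1.0 + 0.3 * np.exp(-((yy - 32) ** 2 + (xx - 30) ** 2) / 40.0)

    pad = (max(8, 16), max(8, 16))
    Ip = np.pad(I, ((pad[0], pad[0]), (pad[1], pad[1])), mode="edge")
    M, N = Ip.shape
    px = p.pixel_size_um * 1e-6
    u = np.fft.fftfreq(M, d=px)
    v = np.fft.fftfreq(N, d=px)
    Wm = np.exp(-2j * np.pi * np.outer(np.arange(M), np.arange(M)) / M)
    Wn = np.exp(-2j * np.pi * np.outer(np.arange(N), np.arange(N)) / N)
    F = Wm @ Ip @ Wn
    filt = 1 + np.pi * p.wavelength_m * p.distance_m * p.delta_beta * (
        u[:, None] ** 2 + v[None, :] ** 2
    )
    g = (Wm.conj() @ (F / filt) @ Wn.conj()) / (M * N)
    oracle = -np.log(np.clip(np.real(g)[pad[0]:pad[0] + 64, pad[1]:pad[1] + 64], 1e-12, None))

    np.testing.assert_allclose(paganin_retrieve(I, p), oracle, atol=1e-6)


def test_paganin_rejects_nonpositive():
    p = RetrievalParams()
    with pytest.raises(ValueError):
        paganin_retrieve(np.zeros((4, 4)), p)


# -------------------------------------------------------------------- unsharp mask


def test_unsharp_identity_and_constant():
    img = np.random.default_rng(6).normal(size=(16, 16))
    np.testing.assert_allclose(unsharp_mask(img, 2.0, 0.0), img)
    const = np.full((8, 8), 3.3)
    np.testing.assert_allclose(unsharp_mask(const, 2.0, 1.5), const, atol=1e-12)


def test_unsharp_step_matches_convolution_oracle():
    img = np.zeros((1, 64))
    img[:, 32:] = 1.0
    out = unsharp_mask(img, 2.0, 1.0)
    blurred = ndimage.gaussian_filter(img, 2.0, mode="nearest")
    np.testing.assert_allclose(out, img + 1.0 * (img - blurred), atol=1e-9)
    assert out.max() > 1.0  # overshoot at the edge


# ------------------------------------------------------------------------ assembly


def _sino_from(pset, rec_mod, row=0):
    frames = pset.accumulated()[0]
    norm = classical_flatfield(frames, pset.flats)
    return -np.log(np.clip(norm, 1e-9, None))[:, row, :]


def test_half_stitch_blend_weights_and_degenerate():
    rng = np.random.default_rng(7)
    d = rng.normal(1.0, 0.1, size=(40, 32))
    s = Sinogram(d, np.linspace(0, 360, 40, endpoint=False), cor_col=15.5)
    out0 = build_half_sinogram(s, 0)
    # o=0: output is the mean of theta and mirrored theta+180 rows
    expect = 0.5 * (d[:20] + d[20:, ::-1])
    np.testing.assert_allclose(out0.data, expect, atol=1e-12)
    with pytest.raises(ValueError):
        build_half_sinogram(s, 16)


def test_half_stitch_matches_wide_detector_oracle(small_jar):
    g_half = ScanGeometry(mode="half", detector_width=96, detector_height=2,
                          cor_offset=24, n_projections=180, angular_range=360.0,
                          pixel_size_um=25.0)
    pset = simulate_scan(small_jar, BeamModel(), g_half, seed=1, noise=False)
    t = _sino_from(pset, None)
    stitched = build_half_sinogram(
        Sinogram(t, pset.angles_deg, cor_col=g_half.cor_col), 24
    )
    g_wide = ScanGeometry(mode="centered", detector_width=96 + 48, detector_height=2,
                          n_projections=90, angular_range=180.0, pixel_size_um=25.0)
    pw = simulate_scan(small_jar, BeamModel(), g_wide, seed=1, noise=False)
    tw = _sino_from(pw, None)
    assert stitched.data.shape == tw.shape
    rmse = np.sqrt(np.mean((stitched.data - tw) ** 2))
    assert rmse < 0.01 * (tw.max() - tw.min())


def test_quarter_stitch_gain_recovery(small_jar):
    g_half = ScanGeometry(mode="half", detector_width=96, detector_height=2,
                          cor_offset=24, n_projections=120, angular_range=360.0,
                          pixel_size_um=25.0)
    g_ann = ScanGeometry(mode="quarter_annular", detector_width=96, detector_height=2,
                         cor_offset=60, n_projections=120, angular_range=360.0,
                         pixel_size_um=25.0)
    ph_big = ph.build_jar_phantom((2, 256, 256), 25.0, 2900.0, 500.0,
                                  tissue_radius=1500.0, seed=2)
    ps_h = simulate_scan(ph_big, BeamModel(), g_half, seed=3, noise=False)
    ps_a = simulate_scan(ph_big, BeamModel(), g_ann, seed=4, noise=False)
    th = _sino_from(ps_h, None)
    ta = _sino_from(ps_a, None)
    half = build_half_sinogram(Sinogram(th, ps_h.angles_deg, cor_col=g_half.cor_col), 24)
    ann = build_annular_sinogram(Sinogram(ta * 1.25, ps_a.angles_deg,
                                          cor_col=g_ann.cor_col), 60)
    out = stitch_quarter(half, ann)
    gain = float(out.provenance[-1].split("gain=")[1].rstrip(")"))
    assert abs(gain - 1.0 / 1.25) < 1e-3
    # identical data -> gain 1, seamless
    ann1 = build_annular_sinogram(Sinogram(ta, ps_a.angles_deg, cor_col=g_ann.cor_col), 60)
    out1 = stitch_quarter(half, ann1)
    gain1 = float(out1.provenance[-1].split("gain=")[1].rstrip(")"))
    assert abs(gain1 - 1.0) < 0.02


# ----------------------------------------------------------------------------- FBP


def test_fbp_zero_sinogram_and_angle_span_guard():
    s = Sinogram(np.zeros((90, 32)), np.linspace(0, 180, 90, endpoint=False), 15.5)
    assert np.allclose(fbp(s), 0.0)
    bad = Sinogram(np.zeros((10, 32)), np.linspace(0, 90, 10, endpoint=False), 15.5)
    with pytest.raises(ValueError, match="span"):
        fbp(bad)


def test_fbp_uniform_disc_interior_recovery():
    # analytic chord sinogram of a uniform disc; interior within 1% RMSE
    n = 128
    mu0 = 0.02  # per mm
    R = 40.0  # px
    s_ax = np.arange(n) - (n - 1) / 2.0
    chord = 2.0 * np.sqrt(np.clip(R**2 - s_ax**2, 0, None))  # px
    sino = np.tile(chord * mu0 * 25e-3, (720, 1))  # A = mu * length(mm)
    s = Sinogram(sino, np.linspace(0, 180, 720, endpoint=False), (n - 1) / 2.0)
    rec = fbp(s, window="ramp", pixel_size_um=25.0)
    y, x = np.mgrid[0:n, 0:n]
    interior = (y - (n - 1) / 2.0) ** 2 + (x - (n - 1) / 2.0) ** 2 <= (0.8 * R) ** 2
    rmse = np.sqrt(np.mean((rec[interior] - mu0) ** 2))
    assert rmse < 0.01 * mu0


def test_fbp_matches_skimage_iradon_oracle():
    # independent-implementation check: both reconstruct the same analytic
    # disc-chord sinogram (radially symmetric, so detector/angle sign
    # conventions cannot mask errors in scaling or filtering)
    from skimage.transform import iradon

    n = 96
    s_ax = np.arange(n) - (n - 1) / 2.0
    chord = 2.0 * np.sqrt(np.clip(30.0**2 - s_ax**2, 0, None))
    theta = np.linspace(0.0, 180.0, 360, endpoint=False)
    sino = np.tile(chord, (len(theta), 1))
    mine = fbp(Sinogram(sino, theta, (n - 1) / 2.0), window="ramp")
    theirs = iradon(sino.T, theta=theta, filter_name="ramp", circle=True)
    y, x = np.mgrid[0:n, 0:n]
    mask = (y - (n - 1) / 2.0) ** 2 + (x - (n - 1) / 2.0) ** 2 <= 24**2
    assert np.sqrt(np.mean((mine[mask] - theirs[mask]) ** 2)) < 0.01


def test_fbp_projection_count_consistency():
    n = 96
    s_ax = np.arange(n) - (n - 1) / 2.0
    chord = 2.0 * np.sqrt(np.clip(30.0**2 - s_ax**2, 0, None)) * 0.02 * 25e-3
    means = []
    for n_ang in (360, 720):
        sino = np.tile(chord, (n_ang, 1))
        s = Sinogram(sino, np.linspace(0, 180, n_ang, endpoint=False), (n - 1) / 2.0)
        rec = fbp(s, window="ramp", pixel_size_um=25.0)
        y, x = np.mgrid[0:n, 0:n]
        means.append(rec[(y - 47.5) ** 2 + (x - 47.5) ** 2 <= 20**2].mean())
    assert abs(means[0] - means[1]) / means[1] < 1e-3


def test_reconstruct_local_degenerate_equals_fbp():
    rng = np.random.default_rng(9)
    d = ndimage.gaussian_filter(rng.normal(size=(180, 64)), 2.0)
    s = Sinogram(d, np.linspace(0, 180, 180, endpoint=False), 31.5)
    a = reconstruct_local(s, pad_cols=0)
    b = fbp(s)
    y, x = np.mgrid[0:64, 0:64]
    fov = (y - 31.5) ** 2 + (x - 31.5) ** 2 <= 31.9**2
    np.testing.assert_allclose(a[fov], b[fov], atol=1e-6)


# ------------------------------------------------------------------ volume assembly


def test_concat_vertical_recovers_injected_shift():
    rng = np.random.default_rng(10)
    base = rng.normal(size=(40, 24, 24)).astype(np.float32)
    top = Volume3D(base[:24], 1.0)
    bottom = Volume3D(base[24 - 9:], 1.0)  # true overlap 9, nominal 7
    out = concat_vertical([top, bottom], [7])
    assert out.data.shape[0] == 40
    np.testing.assert_allclose(out.data, base, atol=1e-5)


def test_concat_vertical_zero_overlap_stacks():
    a = Volume3D(np.zeros((5, 4, 4), dtype=np.float32), 1.0)
    b = Volume3D(np.ones((3, 4, 4), dtype=np.float32), 1.0)
    out = concat_vertical([a, b], [0])
    assert out.data.shape[0] == 8


def test_concat_vertical_blend_weights_sum_to_one():
    a = Volume3D(np.full((10, 4, 4), 2.0, dtype=np.float32), 1.0)
    b = Volume3D(np.full((10, 4, 4), 2.0, dtype=np.float32), 1.0)
    out = concat_vertical([a, b], [4], search_window=0)
    np.testing.assert_allclose(out.data, 2.0, atol=1e-6)


# -------------------------------------------------------------------------- uint16


def test_to_uint16_round_trip_and_degenerate():
    rng = np.random.default_rng(11)
    vol = Volume3D(rng.uniform(0.0, 1.0, size=(4, 8, 8)).astype(np.float32), 1.0)
    out = to_uint16(vol, (0.0, 100.0))
    off, slope = out.scale
    back = off + slope * out.data.astype(np.float64)
    step = slope
    assert np.abs(back - vol.data).max() <= step
    assert out.data.min() == 0 and out.data.max() == 65535
    const = to_uint16(Volume3D(np.full((2, 2, 2), 5.0, dtype=np.float32), 1.0))
    assert (const.data == 32768).all()
    with pytest.raises(ValueError):
        to_uint16(Volume3D(np.full((2, 2, 2), np.nan, dtype=np.float32), 1.0))


# ---------------------------------------------------------------------- ring/stripe


def _smooth_slice(n=256):
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    r = np.hypot(y - c, x - c)
    return r, 0.02 * np.exp(-(r**2) / (2 * 80**2)) + 0.01


def test_remove_rings_suppresses_injected_ring():
    r, smooth = _smooth_slice()
    a = 0.005
    ring = a * np.exp(-0.5 * ((r - 60) / 1.5) ** 2)
    out = remove_rings(smooth + ring)
    assert np.abs(out - smooth).max() < 0.15 * a
    assert abs(out.mean() - (smooth + ring).mean()) < 1e-3 * abs(smooth.mean())


def test_remove_rings_near_identity_on_clean_slice():
    _, smooth = _smooth_slice()
    out = remove_rings(smooth)
    assert np.abs(out - smooth).max() < 0.01 * (smooth.max() - smooth.min())


def test_remove_stripes_injection_and_idempotency():
    rng = np.random.default_rng(12)
    vol = 0.01 * rng.normal(size=(32, 48, 48))
    offsets = np.zeros(32)
    offsets[[8, 20]] = [0.05, -0.04]
    v = Volume3D((vol + offsets[:, None, None]).astype(np.float32), 1.0)
    out = remove_stripes(v)
    resid = out.data - vol
    assert abs(resid[8].mean()) < 0.1 * 0.05
    out2 = remove_stripes(out)
    rng_out = out.data.max() - out.data.min()
    assert np.abs(out2.data - out.data).max() < 0.01 * rng_out
    clean = Volume3D(vol.astype(np.float32), 1.0)
    cleaned = remove_stripes(clean)
    assert np.abs(cleaned.data - vol).max() < 0.01 * (vol.max() - vol.min())
    with pytest.raises(ValueError):
        remove_stripes(Volume3D(np.zeros((4, 8, 8), dtype=np.float32), 1.0))
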