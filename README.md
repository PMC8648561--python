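# hiptomo

Desk-scale simulation and analysis toolkit for **hierarchical
phase-contrast tomography (HiP-CT)** of intact organs: synchrotron
propagation-based scans taken at a whole-organ overview resolution
(~25 µm/voxel) followed by zoomed local-tomography scans of interior
volumes of interest, reconstructed with a reference-jar flat-field /
single-distance phase-retrieval / extended field-of-view chain, and
analysed with 3D morphometry and stereology.

The package is aimed at people developing or validating HiP-CT-style
processing: every stage of the pipeline can be exercised on seeded
synthetic organ phantoms with exact ground truth, so reconstruction and
measurement errors are attributable.

## What it contains

| module | contents |
| --- | --- |
| `hiptomo.core_io` | `Volume3D` voxel container, TIFF/HDF5 I/O, cylindrical ROIs, seeded RNG streams |
| `hiptomo.phantom` | seeded phantoms: mounting jar (agar–ethanol + PET wall), sphere-studded kidney parenchyma, thin-walled alveolar foam with consolidation |
| `hiptomo.acquisition` | parallel-beam forward projector, Fresnel propagation, beam profiles, Poisson + read noise, sub-frame accumulation, half/annular geometries, vertical-series planning, reference-jar scans |
| `hiptomo.reconstruction` | windowed reference flat-fielding, vertical-profile subtraction, Paganin-type single-distance phase retrieval + unsharp mask, half/quarter sinogram stitching, filtered back-projection, local (truncated) reconstruction, ponderate vertical concatenation, 16-bit conversion, ring/stripe correction |
| `hiptomo.quality` | Fourier shell correlation with the ½-bit criterion and subvolume protocol, SNR, SSIM group comparison, histogram statistics |
| `hiptomo.morphometry` | triangle/Yen/Otsu thresholds, (3,4,5,7) chamfer distance, local thickness, surface-area-to-volume, Euler connectivity, object morphometry (volume/surface/sphericity), virtual-biopsy stereology, grouped ANOVA + Tukey reports |
| `hiptomo.scenarios` | end-to-end study protocols (round trip, local-tomography pair, lateral SNR transect) |

## The core methods

**Phase retrieval.** A propagation image at distance `D` is converted to a
projected-thickness map with the homogeneous-object (single-distance)
filter

    t = −ln F⁻¹[ F[I] / (1 + π λ D (δ/β)(u² + v²)) ],

where `δ/β` (default 1000) sets the filter strength, followed by an
optional 2D unsharp mask. `D = 0` reduces to Beer–Lambert `−ln I`.

**Reference-jar flat fielding.** Local (zoom) tomography of an interior
VOI sees laterally truncated projections, which classically produce a
low-frequency cupping background. Dividing each projection by an
angularly windowed mean of projections of an identical jar filled only
with mounting medium cancels the jar/agar contribution, so the
reconstruction recovers `µ − µ_reference` without the truncation
background.

**Extended field of view.** A 360° scan with the rotation centre offset
by `o` pixels is mirror-stitched into 180° projections of width
`W + 2o`; a further annular scan (offset ≥ W/2) is concatenated after
grey-level normalisation in the overlap (quarter acquisition).

**FSC resolution.** Two independently acquired and reconstructed volumes
are compared shell-by-shell in Fourier space; the resolution is
`voxel_size / f`, with `f` the first crossing of the ½-bit information
threshold `T(n) = (0.2071 + 1.9102/√n) / (1.2071 + 0.9102/√n)`,
aggregated over randomly placed subvolumes (mean ± sd).

**Morphometry.** Airspace/tissue masks are measured with the
⟨3,4,5,7⟩ integer chamfer distance, largest-inscribed-sphere local
thickness, mesh surface areas, and Euler connectivity `1 − χ`;
sphericity is `ψ = π^{1/3}(6V)^{2/3}/A`. Virtual-biopsy counts are
scaled by parenchyma-volume ratios to whole-organ totals with Poisson
standard errors.

## Worked example

```python
import numpy as np
from hiptomo import phantom, acquisition as acq, reconstruction as rec

# jar phantom: 2 mm PET wall, agar-ethanol interior, tissue cylinder
phan = phantom.build_jar_phantom((1, 256, 256), voxel_size=25.0,
                                 jar_radius=2816.0, jar_wall=2000.0,
                                 tissue_radius=1408.0, seed=11)
geom = acq.ScanGeometry(mode="centered", detector_width=256,
                        detector_height=1, n_projections=720,
                        angular_range=180.0, pixel_size_um=25.0)
pset = acq.simulate_scan(phan, acq.BeamModel(), geom, seed=11, noise=False)
vol = rec.reconstruct_projection_set(pset, use_reference=False, window="ramp")

mu = phan.mu_volume().data[0]
err = np.sqrt(np.mean((vol.data[0] - np.where(
    (np.hypot(*np.mgrid[0:256, 0:256] - 127.5)) <= 128, mu, 0)) ** 2))
print(f"recovered tissue mu: {vol.data[0][128, 128]:.4f} / mm "
      f"(truth {mu[128, 128]:.4f})")
print(f"round-trip RMSE: {100 * err / (mu.max() - mu.min()):.2f}% of range")
```

prints

```
recovered tissue mu: 0.0220 / mm (truth 0.0220)
round-trip RMSE: 1.80% of range
```

i.e. the simulated scan of the jar phantom is reconstructed back to its
attenuation map with sub-2% error, and the tissue attenuation
(0.022/mm at the effective 85 keV) is recovered at the voxel level.

A command-line interface wraps the common flows:

```bash
hiptomo phantom --scenario kidney --seed 3 --out out/
hiptomo reconstruct --config scan.yaml --seed 3 --out out/
hiptomo qc --metric fsc --vol-a a.h5 --vol-b b.h5 --out out/
hiptomo morph --out out/
```

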