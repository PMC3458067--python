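# longiseg4d

Longitudinally guided, multi-modality coupled level-set segmentation of
serial brain MR images into white matter (WM), gray matter (GM),
cerebrospinal fluid (CSF) and background.

## The problem

During the first year of life the WM/GM intensity contrast inverts: on T1,
white matter starts darker than gray matter, passes through an *isointense*
stage around 6–8 months where the two tissues are nearly indistinguishable,
and ends brighter (adult-like); T2 shows the opposite trend.  Segmenting
the isointense scans of a longitudinal series is therefore hard exactly
where consistency across the series matters most.  This package addresses
it with three ingredients:

1. **Multi-modality local Gaussian fitting** — T1, T2 and FA channels are
   modelled jointly with per-voxel local mean vectors and covariance
   matrices; the FA channel stays WM-bright at all ages and carries the
   WM/GM boundary through the isointense window.
2. **A cortical thickness band** — the WM/GM and GM/CSF surfaces are kept
   between 1 and 6.5 mm apart.
3. **A longitudinal consistency band** — each scan's interfaces must fall
   within ±ε (default 1.5 mm) of the interfaces warped in from the
   subject's other scans, weighted toward the late, high-contrast scans.

## The model

Three signed-distance fields φ1, φ2, φ3 (zero sets: WM/GM, GM/CSF,
CSF/background) evolve by gradient descent on

    E = w_d E_data + w_l E_length + w_t E_thickness + w_g E_longitudinal

with telescoping region memberships u_wm = H(φ1),
u_gm = (1−H(φ1))H(φ2), u_csf = (1−H(φ1))(1−H(φ2))H(φ3),
u_bg = (1−H(φ1))(1−H(φ2))(1−H(φ3)).  E_data is the kernel-integrated
negative log-likelihood under local multivariate Gaussians (optionally
multiplied by an atlas prior), E_length the interface length, and the two
band terms are one-sided quadratic penalties that vanish inside their
bands.  The serial pipeline alternates registration with symmetric
refinement sweeps over the time points; with a single scan or zero
longitudinal weight it reduces exactly to the coupled single-scan model.
See `docs/methods.md` for the full formulation and numerical scheme.

## Worked example

```python
from longiseg4d import (
    CoupledLevelSetModel, EvolutionConfig, PhantomSpec,
    generate_phantom, high_contrast_means,
)

spec = PhantomSpec(shape=(128, 128), ages=(12.0,), channels=("t1",),
                   seed=3, deformation_mm=0.0,
                   tissue_means=high_contrast_means())
sample = generate_phantom(spec)[0]

model = CoupledLevelSetModel(sample.image, config=EvolutionConfig())
result = model.fit()
print(result.summary(truth=sample.labels))
```

prints

```
Coupled level-set segmentation results
==============================================
age (months): 12   grid: (128, 128)
iterations:   40
final energy: total=-848.6419 (data=-1810.4213, length=565.6879, thickness=0.0000, longitudinal=0.0000)
volumes:      WM=2152  GM=505  CSF=792
Dice ratio:   WM=1.000  GM=0.997  CSF=0.997
```

The volumes are areas in mm² (2D grid, 1 mm spacing); the final energy
breakdown shows the data term dominating, a small length penalty from the
gyrified boundary, and an inactive thickness band (the phantom's 3 mm
cortex lies inside [1, 6.5] mm).  Each tissue is recovered with Dice
≥ 0.997 against the generating truth.

For a serial study, build one `MultiModalImage` per scan and use
`LongitudinalLevelSetModel(images, atlases, config, deformations).fit()`;
its results object reports per-age Dice and temporal consistency.

From the shell:

```bash
longiseg4d phantom --spec spec.yaml --out phantom/
longiseg4d run --t1 phantom/t1_t00.nii.gz --age 12 --out out/
longiseg4d eval --pred out/labels_t00.nii.gz --truth phantom/truth_t00.nii.gz
```

## Layout

| module | contents |
| --- | --- |
| `geometry` | signed-distance fields, Heaviside/delta families, region memberships, length term, re-distancing, labels |
| `fitting` | multi-modal images, atlas priors, local Gaussian statistics, data energy/forces |
| `constraints` | thickness and longitudinal band penalties, temporal weights, warping |
| `evolution` | descent controller, initialization, registration backends, single-scan and 4D pipelines |
| `model` | `CoupledLevelSetModel` / `LongitudinalLevelSetModel` with results objects |
| `phantom` | longitudinal contrast-inversion phantom generator, Dice and band metrics |
| `experiments` | the benchmark experiments behind the tests and the reproduction script |
| `io`, `cli` | NIfTI/YAML/JSON readers and writers, run manifests, `longiseg4d` command |
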