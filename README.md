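# glymphdti

Diffusion-MRI indices of glymphatic function, and the Bayesian group
comparison that goes with them.

The glymphatic system is the brain's proposed perivascular waste-clearance
pathway: CSF enters along periarterial spaces, exchanges with interstitial
fluid through astrocytic AQP-4 channels, and drains along perivenous spaces.
Two diffusion-MRI proxies are in common use for it, and this package computes
both from a single-shell DWI acquisition (one b=0 volume plus a b = 1000
s/mm² shell):

- **Free-water (FW) fraction** — the per-voxel fractional volume *f* of an
  isotropic compartment with fixed diffusivity *d*<sub>w</sub> = 3.0×10⁻³
  mm²/s in the bi-tensor model

  S<sub>q</sub>/S₀ = (1−f)·exp(−b<sub>q</sub> g<sub>q</sub>ᵀ D g<sub>q</sub>) + f·exp(−b<sub>q</sub> d<sub>w</sub>),

  summarised as the mean of *f* over a white-matter skeleton with lesions
  excluded. A proxy for interstitial extracellular fluid.
- **DTI-ALPS index** — diffusivity *along* the perivascular space of the
  deep medullary veins (the image x axis at the level of the
  lateral-ventricle body) relative to the diffusivity perpendicular to the
  local fibre tracts:

  ALPS = mean(D<sub>xx,proj</sub>, D<sub>xx,assoc</sub>) / mean(D<sub>yy,proj</sub>, D<sub>zz,assoc</sub>),

  from 5 mm spherical ROIs in the projection fibres (superior corona
  radiata, principal axis z) and association fibres (superior longitudinal
  fasciculus, principal axis y), lesion-excluded, averaged over hemispheres.

Group differences (e.g. multiple sclerosis vs. neuromyelitis optica spectrum
disorder) are then assessed with a **Bayesian model-averaged ANCOVA**: all
2³ additive models over {age, EDSS, group} are scored with JZS
(Zellner–Siow) mixture-of-g Bayes factors, combined into posterior model
probabilities, BF<sub>M</sub> change-of-odds factors, and per-predictor
inclusion Bayes factors — so evidence *for the null* (no group difference)
is quantifiable, not just non-significance.

Because no patient data ship with the package, a first-class synthetic
module generates two-compartment DWI phantoms (oriented fibre slabs, CSF
rim, spherical lesions, Rician noise, known ground truth) and cohort tables
with the covariate structure of a 42 + 21 two-group study, so every stage is
testable end to end.

Intended users: neuroimaging methods researchers who want a transparent,
fully-tested reference implementation of these indices rather than a chain
of opaque vendor scripts.

## Worked example

```python
import numpy as np
from glymphdti import *
from glymphdti.synth import PhantomSpec, build_phantom, phantom_roi_spec

# phantom whose slab diffusivities imply an analytic ALPS index of 2.0,
# acquired at SNR 30 with Rician noise
spec = PhantomSpec(proj_evals=(1.2e-3, 0.6e-3, 1.7e-3),
                   assoc_evals=(1.2e-3, 1.7e-3, 0.6e-3),
                   snr=30.0, seed=42)
dwi, truth = build_phantom(spec)

report = tsnr(dwi)                       # quality screening
tm = fit_tensor(dwi)                     # single-tensor fit (WLS)
alps = compute_alps(tm, phantom_roi_spec(spec), truth.lesion_mask.data)
fw = fit_fw(dwi)                         # bi-tensor free-water fit
skel = wm_skeleton(tm.fa)
fw_idx, n_used, _ = mean_fw_on_skeleton(fw.f, skel, truth.lesion_mask.data)

tab = simulate_cohort(CohortSpec(seed=1))        # 42 MS / 21 NMOSD table
result = run_bayes_ancova(tab, dv="FW")
```

This prints (via the obvious `print` calls):

```
tSNR = 8.92 (cutoff 6.47) -> pass=True
ALPS: left=1.744 right=1.764 mean=1.754 (analytic 2.0)
skeleton-mean FW = 0.149 over 3200 voxels (0 lesion-excluded)
group inclusion BF = 0.407
```

Reading the numbers: the series passes the tSNR screen; the measured mean
ALPS (1.75) sits below the analytic 2.0 because noise and the free-water
compartment bias the single-tensor axis diffusivities (a noise-free,
tissue-only phantom recovers 2.0 to 1e-6 — see the tests); the skeleton-mean
FW of 0.149 reflects the simulated 0.15 fraction; and a group inclusion
Bayes factor of 0.41 means these (null-simulated) data are ~2.5× more likely
under models without the group predictor.

The same stages are scriptable from the shell:

```bash
glymphdti simulate --config config.yaml --out-dir data/ --seed 5
glymphdti qc       --dwi data/dwi.nii.gz --bval data/dwi.bval --bvec data/dwi.bvec
glymphdti fit-dti  --dwi data/dwi.nii.gz --bval data/dwi.bval --bvec data/dwi.bvec --out-dir data/dti
glymphdti alps     --tensor-dir data/dti --rois rois.yaml --out alps.csv
glymphdti bayes-ancova --table data/cohort.csv --dv FW --out bayes.json
glymphdti run      --seed 11 --out-dir results/
```

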