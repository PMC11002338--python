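"""Synthetic DWI phantoms and cohorts with known ground truth.

Two generators live here:

* :func:`build_phantom` — a voxelwise two-compartment (tissue tensor +
  isotropic free water) DWI phantom with oriented white-matter fibre slabs,
  an optional CSF border, spherical lesions and Rician noise.  The default
  geometry mimics a single-shell acquisition: one b=0 volume plus a b=1000
  s/mm^2 shell of 32 directions on a 2 mm grid.
* :func:`simulate_cohort` — a two-group patient table (multiple sclerosis
  vs. neuromyelitis optica spectrum disorder) with age and EDSS covariate
  structure and linear generative models for the two imaging outcomes
  (white-matter free-water fraction and the DTI-ALPS index).

Every generator is deterministic under a fixed seed; ground truth is returned
alongside the data so estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alps import AlpsRoiSpec, SphereROI, alps_from_means
from .dwi_core import DWIVolume, GradientTable, VolumeMask

__all__ = [
    "FREE_WATER_DIFFUSIVITY",
    "LesionSpec",
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "make_gradient_table",
    "simulate_signal",
    "add_noise",
    "build_phantom",
    "simulate_cohort",
]

#: Free-water diffusivity at body temperature, mm^2/s.
FREE_WATER_DIFFUSIVITY = 3.0e-3

# Default slab tensors (mm^2/s): projection fibres run along image z
# (superior corona radiata), association fibres along image y (superior
# longitudinal fasciculus).  The x axis is the perivascular axis.
DEFAULT_PROJ_EVALS = (1.2e-3, 0.6e-3, 1.7e-3)  # (Dxx, Dyy, Dzz)
DEFAULT_ASSOC_EVALS = (1.2e-3, 1.7e-3, 0.6e-3)
DEFAULT_BACKGROUND_EVALS = (0.8e-3, 0.8e-3, 0.8e-3)


def make_gradient_table(
    n_dirs: int = 32, bval: float = 1000.0, n_b0: int = 1, seed: int = 42
) -> GradientTable:
    """A b=0 + single-shell scheme with electrostatically spread directions.

    Directions are spread on the half-sphere by iterative pairwise repulsion
    (antipodally symmetrised), which is the standard way clinical DTI
    direction tables are designed.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_dirs, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    for _ in range(2000):
        diff = v[:, None, :] - v[None, :, :]
        diff_anti = v[:, None, :] + v[None, :, :]
        d = np.linalg.norm(diff, axis=-1) + np.eye(n_dirs)
        da = np.linalg.norm(diff_anti, axis=-1) + 2 * np.eye(n_dirs)
        force = (diff / d[..., None] ** 3).sum(axis=1) + (
            diff_anti / da[..., None] ** 3
        ).sum(axis=1)
        # project force onto the tangent plane and take a small step
        force -= (force * v).sum(axis=1, keepdims=True) * v
        v += 0.002 * force
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), v])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def simulate_signal(
    tensor: np.ndarray,
    f: float,
    gtab: GradientTable,
    s0: float = 1.0,
    d_w: float = FREE_WATER_DIFFUSIVITY,
) -> np.ndarray:
    """Noise-free two-compartment DWI signal for one voxel.

    S_q = s0 * [ (1-f) * exp(-b_q g_q^T D g_q) + f * exp(-b_q d_w) ]

    where ``D`` is the tissue tensor (mm^2/s), ``f`` the free-water volume
    fraction and ``d_w`` the free-water diffusivity.  At b=0 the signal
    equals ``s0`` exactly.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3):
        raise ValueError("tensor must be 3x3")
    if not np.allclose(tensor, tensor.T, atol=1e-12):
        raise ValueError("tensor must be symmetric")
    evals = np.linalg.eigvalsh(tensor)
    if evals.min() < -1e-12:
        raise ValueError(f"tensor is not positive semi-definite (min eig {evals.min():.3e})")
    if not 0.0 <= f <= 1.0:
        raise ValueError("free-water fraction must lie in [0, 1]")
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    adc = np.einsum("qi,ij,qj->q", gtab.bvecs, tensor, gtab.bvecs)
    tissue = np.exp(-gtab.bvals * adc)
    water = np.exp(-gtab.bvals * d_w)
    return s0 * ((1.0 - f) * tissue + f * water)


def add_noise(
    signal: np.ndarray,
    snr: float,
    model: str = "rician",
    seed: int | np.random.Generator = 0,
    s0: float = 1.0,
) -> np.ndarray:
    """Add measurement noise at a given s0-relative SNR.

    ``rician`` forms the magnitude of a complex signal with i.i.d. Gaussian
    noise of standard deviation ``s0/snr`` on each channel (magnitude MRI);
    ``gaussian`` adds real noise; ``none`` is the identity.
    """
    signal = np.asarray(signal, dtype=float)
    if model == "none":
        return signal.copy()
    if model not in ("rician", "gaussian"):
        raise ValueError(f"unknown noise model {model!r}")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = s0 / snr
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, signal.shape)
    e1 = rng.normal(0.0, sigma, signal.shape)
    e2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


@dataclass
class LesionSpec:
    """A spherical white-matter lesion overriding the host region."""

    center_mm: tuple[float, float, float]
    radius_mm: float = 4.0
    diffusivity: float = 1.2e-3  # isotropic lesion tissue, mm^2/s
    f: float = 0.6

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")


@dataclass
class PhantomSpec:
    """Layout and acquisition parameters for a two-compartment DWI phantom.

    The grid is centred on the world origin (RAS+).  Two fibre slabs span
    the full x/z extent at fixed y-index bands: a projection-fibre slab
    (principal axis z) and an association-fibre slab (principal axis y),
    embedded in isotropic background tissue with an optional CSF border at
    the grid faces.
    """

    shape: tuple[int, int, int] = (40, 40, 20)
    voxel_size: float = 2.0  # mm, isotropic
    proj_evals: tuple[float, float, float] = DEFAULT_PROJ_EVALS
    assoc_evals: tuple[float, float, float] = DEFAULT_ASSOC_EVALS
    background_evals: tuple[float, float, float] = DEFAULT_BACKGROUND_EVALS
    proj_f: float = 0.15
    assoc_f: float = 0.15
    background_f: float = 0.10
    csf_border: int = 0  # thickness in voxels of a free-water rim; 0 disables
    lesions: tuple[LesionSpec, ...] = ()
    s0: float = 1000.0
    snr: float = 30.0
    noise_model: str = "rician"  # rician | gaussian | none
    d_w: float = FREE_WATER_DIFFUSIVITY
    n_dirs: int = 32
    bval: float = 1000.0
    direction_seed: int = 42
    seed: int = 0

    def __post_init__(self) -> None:
        # tolerate list-valued fields (e.g. from YAML configs)
        self.shape = tuple(int(s) for s in self.shape)
        self.proj_evals = tuple(float(x) for x in self.proj_evals)
        self.assoc_evals = tuple(float(x) for x in self.assoc_evals)
        self.background_evals = tuple(float(x) for x in self.background_evals)
        for ev in (self.proj_evals, self.assoc_evals, self.background_evals):
            arr = np.asarray(ev)
            if np.any(arr <= 0) or np.any(arr > 4e-3):
                raise ValueError("tissue eigenvalues must lie in (0, 4e-3] mm^2/s")
        for f in (self.proj_f, self.assoc_f, self.background_f):
            if not 0.0 <= f <= 1.0:
                raise ValueError("free-water fractions must lie in [0, 1]")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * self.voxel_size
        return aff

    def slab_bands(self) -> tuple[slice, slice]:
        """y-index bands of the projection and association slabs."""
        ny = self.shape[1]
        w = max(ny // 5, 1)
        proj = slice(ny // 5, ny // 5 + w)
        assoc = slice(3 * ny // 5, 3 * ny // 5 + w)
        return proj, assoc


def phantom_roi_spec(
    spec: PhantomSpec, x_offset_mm: float = 10.0, diameter_mm: float = 5.0
) -> AlpsRoiSpec:
    """ALPS ROI spheres centred inside the phantom's fibre slabs.

    Spheres sit at +-``x_offset_mm`` (right/left), mid-slice in z, at the
    world-y centre of each slab band.
    """
    aff = spec.affine
    proj_band, assoc_band = spec.slab_bands()

    def band_center_y(band: slice) -> float:
        mid = (band.start + band.stop - 1) / 2.0
        return float(aff[1, 1] * mid + aff[1, 3])

    zc = float(aff[2, 2] * (spec.shape[2] - 1) / 2.0 + aff[2, 3])
    yp, ya = band_center_y(proj_band), band_center_y(assoc_band)
    return AlpsRoiSpec(
        proj_left=SphereROI((-x_offset_mm, yp, zc), diameter_mm),
        proj_right=SphereROI((x_offset_mm, yp, zc), diameter_mm),
        assoc_left=SphereROI((-x_offset_mm, ya, zc), diameter_mm),
        assoc_right=SphereROI((x_offset_mm, ya, zc), diameter_mm),
    )


# Region labels in GroundTruth.labels
LABEL_BACKGROUND, LABEL_PROJ, LABEL_ASSOC, LABEL_CSF = 0, 1, 2, 3


@dataclass
class GroundTruth:
    """Voxelwise truth accompanying a phantom."""

    tensor: np.ndarray  # (x, y, z, 3, 3) mm^2/s
    f: np.ndarray  # (x, y, z) free-water fraction
    lesion_mask: VolumeMask
    labels: np.ndarray  # region label map
    analytic_alps: float  # ALPS index implied by the slab diffusivities
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def build_phantom(spec: PhantomSpec) -> tuple[DWIVolume, GroundTruth]:
    """Assemble a phantom voxelwise from its spec.

    Noise-free signals are exactly :func:`simulate_signal` of each voxel's
    ground truth; lesions override region tensors and fractions inside their
    spheres; noise is applied last and reproducibly under ``spec.seed``.
    """
    gtab = make_gradient_table(spec.n_dirs, spec.bval, seed=spec.direction_seed)
    shape = spec.shape
    affine = spec.affine

    labels = np.full(shape, LABEL_BACKGROUND, dtype=np.int8)
    proj_band, assoc_band = spec.slab_bands()
    labels[:, proj_band, :] = LABEL_PROJ
    labels[:, assoc_band, :] = LABEL_ASSOC
    if spec.csf_border > 0:
        b = spec.csf_border
        rim = np.ones(shape, dtype=bool)
        rim[b:-b, b:-b, b:-b] = False
        labels[rim] = LABEL_CSF

    region_tensors = {
        LABEL_BACKGROUND: np.diag(spec.background_evals),
        LABEL_PROJ: np.diag(spec.proj_evals),
        LABEL_ASSOC: np.diag(spec.assoc_evals),
        LABEL_CSF: np.diag([spec.d_w] * 3),
    }
    region_f = {
        LABEL_BACKGROUND: spec.background_f,
        LABEL_PROJ: spec.proj_f,
        LABEL_ASSOC: spec.assoc_f,
        LABEL_CSF: 1.0,
    }

    tensor_field = np.zeros(shape + (3, 3))
    f_field = np.zeros(shape)
    signal = np.zeros(shape + (len(gtab),))
    for lab, D in region_tensors.items():
        sel = labels == lab
        if not np.any(sel):
            continue
        tensor_field[sel] = D
        f_field[sel] = region_f[lab]
        signal[sel] = simulate_signal(D, region_f[lab], gtab, spec.s0, spec.d_w)

    # world coordinates of voxel centres, for lesion carving
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    world = vox @ affine.T
    lesion_mask = np.zeros(shape, dtype=bool)
    for les in spec.lesions:
        dist = np.linalg.norm(world[..., :3] - np.asarray(les.center_mm), axis=-1)
        inside = dist <= les.radius_mm
        if not np.any(inside):
            warnings.warn(f"lesion at {les.center_mm} lies outside the grid; skipped")
            continue
        D = np.diag([les.diffusivity] * 3)
        tensor_field[inside] = D
        f_field[inside] = les.f
        signal[inside] = simulate_signal(D, les.f, gtab, spec.s0, spec.d_w)
        lesion_mask |= inside

    signal = add_noise(
        signal, spec.snr, spec.noise_model, seed=np.random.default_rng(spec.seed), s0=spec.s0
    )
    signal = np.maximum(signal, 0.0)

    analytic = alps_from_means(
        spec.proj_evals[0], spec.assoc_evals[0], spec.proj_evals[1], spec.assoc_evals[2]
    )
    truth = GroundTruth(
        tensor=tensor_field,
        f=f_field,
        lesion_mask=VolumeMask(lesion_mask.astype(np.int8), affine),
        labels=labels,
        analytic_alps=analytic,
        affine=affine,
    )
    return DWIVolume(signal=signal, affine=affine, gtab=gtab), truth


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class OutcomeModel:
    """Linear generative model: outcome = intercept + delta*group + slopes + noise.

    ``group`` is coded MS = 0, NMOSD = 1.
    """

    intercept: float
    delta: float = 0.0
    beta_age: float = 0.0
    beta_edss: float = 0.0
    sd: float = 0.01

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("residual sd must be positive")


@dataclass
class CohortSpec:
    """Two-group cohort with the study's covariate structure.

    Defaults follow the clinical table of the modelled study population:
    42 MS / 21 NMOSD patients; age 33.97 +/- 7.52 vs 47.23 +/- 11.18 years;
    EDSS 1.48 +/- 1.65 vs 2.95 +/- 2.79.  Covariates are drawn as Gaussians
    with exactly these moments (no truncation, so sample moments converge to
    the stated values).  Outcome models default to a null group effect
    (delta = 0) with plausible white-matter values: skeleton free-water
    fraction around 0.2 and an ALPS index around 1.5.
    """

    n_ms: int = 42
    n_nmosd: int = 21
    age_ms: tuple[float, float] = (33.97, 7.52)
    age_nmosd: tuple[float, float] = (47.23, 11.18)
    edss_ms: tuple[float, float] = (1.48, 1.65)
    edss_nmosd: tuple[float, float] = (2.95, 2.79)
    fw_model: OutcomeModel = field(
        default_factory=lambda: OutcomeModel(
            intercept=0.15, delta=0.0, beta_age=0.001, beta_edss=0.005, sd=0.02
        )
    )
    alps_model: OutcomeModel = field(
        default_factory=lambda: OutcomeModel(
            intercept=1.75, delta=0.0, beta_age=-0.005, beta_edss=-0.02, sd=0.12
        )
    )
    #: PhantomSpec keyword overrides applied to every subject (e.g. a smaller
    #: grid for quick runs) and per-subject-index overrides (e.g. a degraded
    #: SNR for one subject); only used with ``with_phantom_specs``.
    phantom_overrides: dict = field(default_factory=dict)
    subject_phantom_overrides: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ms < 2 or self.n_nmosd < 2:
            raise ValueError("group sizes must be at least 2")


def simulate_cohort(
    cspec: CohortSpec, with_phantom_specs: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, list[PhantomSpec]]:
    """Draw a cohort covariate/outcome table, optionally with phantom specs.

    When ``with_phantom_specs`` is true, each subject also gets a
    :class:`PhantomSpec` whose slab free-water fractions and perpendicular
    diffusivities are back-solved so that the image pipeline measures
    (approximately) the tabled FW and ALPS values.
    """
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_ms + cspec.n_nmosd
    group = np.array([0] * cspec.n_ms + [1] * cspec.n_nmosd)
    age = np.where(
        group == 0,
        rng.normal(*cspec.age_ms, n),
        rng.normal(*cspec.age_nmosd, n),
    )
    edss = np.where(
        group == 0,
        rng.normal(*cspec.edss_ms, n),
        rng.normal(*cspec.edss_nmosd, n),
    )

    def draw(m: OutcomeModel) -> np.ndarray:
        mu = m.intercept + m.delta * group + m.beta_age * age + m.beta_edss * edss
        return mu + rng.normal(0.0, m.sd, n)

    fw = draw(cspec.fw_model)
    alps = draw(cspec.alps_model)
    table = pd.DataFrame(
        {
            "subject": [f"sub-{i:03d}" for i in range(n)],
            "group": np.where(group == 0, "MS", "NMOSD"),
            "age": age,
            "EDSS": edss,
            "FW": fw,
            "ALPS": alps,
        }
    )
    if not with_phantom_specs:
        return table

    specs = []
    for i in range(n):
        target_alps = float(np.clip(alps[i], 1.05, 2.8))
        target_fw = float(np.clip(fw[i], 0.02, 0.9))
        dxx = 1.2e-3
        dperp = dxx / target_alps  # back-solve: ALPS = Dxx / Dperp in this layout
        kwargs = dict(
            proj_evals=(dxx, dperp, 1.7e-3),
            assoc_evals=(dxx, 1.7e-3, dperp),
            proj_f=target_fw,
            assoc_f=target_fw,
            background_f=target_fw,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        kwargs.update(cspec.phantom_overrides)
        kwargs.update(cspec.subject_phantom_overrides.get(i, {}))
        specs.append(PhantomSpec(**kwargs))
    return table, specs
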