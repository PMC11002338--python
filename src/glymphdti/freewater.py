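"""Bi-tensor free-water estimation and white-matter skeleton summaries.

The two-compartment model per voxel is

    S_q / s0 = (1 - f) exp(-b_q g_q^T D g_q) + f exp(-b_q d_w)

with a tissue tensor ``D`` and an isotropic free-water compartment of fixed
diffusivity ``d_w`` (3.0e-3 mm^2/s at body temperature).  From single-shell
data the problem is ill-posed: for a range of f values a tissue tensor can
be found that fits one shell almost as well.  The estimator therefore uses
alternating minimisation with spatial regularisation:

1. f step — per-voxel 1-D bounded minimisation of the profile objective
   J(f) = sum_q (A_q - (1-f) e^{-b g^T D(f) g} - f e^{-b d_w})^2, where
   D(f) is the tensor step nested inside the search (variable projection:
   a plain coordinate alternation creeps along the ridge, while profiling
   out the tensor lands on the joint minimum directly);
2. tensor step — weighted log-linear fit of the water-corrected signal
   ``(S - f s0 e^{-b d_w}) / (1 - f)`` with eigenvalues clamped to tissue
   bounds;
3. spatial step — Gaussian smoothing of the f map (the regulariser).

Iterations stop when the largest f change falls below a tolerance.  Voxels
whose objective is flat in f (tissue diffusivity indistinguishable from
``d_w`` along every gradient) keep their value but carry a ridge flag.

The skeleton operator is a deliberately simplified stand-in for a full
tract-based spatial statistics (TBSS) pipeline: FA thresholding followed by
a distance-transform medial-surface (ridge) extraction, which reduces a
plate-like white-matter mask to its 1-voxel medial surface — the same kind
of object as a TBSS skeleton, without group-wise registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dwi_core import DWIVolume, VolumeMask
from .synth import FREE_WATER_DIFFUSIVITY
from .tensor import TensorMaps, _averaged_series, _floor_signal, _tensor_derived_maps

__all__ = ["FWConfig", "FWResult", "init_fw", "fit_fw", "wm_skeleton", "mean_fw_on_skeleton"]


@dataclass
class FWConfig:
    """Knobs of the free-water fit.

    d_w : free-water diffusivity, mm^2/s.
    eval_bounds : tissue-tensor eigenvalue clamp, mm^2/s — separates the
        tissue compartment from free water.
    smoothing_sigma : Gaussian sigma (voxels) applied to f between
        iterations; 0 disables the spatial regulariser.
    max_iter / tol : alternating-minimisation stopping rule (tol is on
        max |delta f|).
    md_tissue_ref : reference tissue mean diffusivity used by the
        initialiser's linear MD -> f ramp.
    init_clip : clip range of the initial f map.
    """

    d_w: float = FREE_WATER_DIFFUSIVITY
    eval_bounds: tuple[float, float] = (0.1e-3, 2.5e-3)
    smoothing_sigma: float = 1.0
    max_iter: int = 50
    tol: float = 1e-4
    md_tissue_ref: float = 0.6e-3
    init_clip: tuple[float, float] = (0.05, 0.95)
    f_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        for lo, hi in (self.eval_bounds, self.init_clip, self.f_bounds):
            if lo >= hi:
                raise ValueError("bounds must be ordered (low < high)")


@dataclass
class FWResult:
    """Free-water fit output: f map, corrected tissue tensor, diagnostics."""

    f: np.ndarray  # (x, y, z) in [0, 1]
    tissue: TensorMaps  # water-corrected tissue tensor maps
    converged: np.ndarray  # per-voxel convergence flag
    ridge: np.ndarray  # per-voxel flat-objective flag
    n_iter: int
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def init_fw(md: np.ndarray, cfg: FWConfig | None = None) -> np.ndarray:
    """Initial f from single-tensor MD: a linear ramp between a tissue
    reference MD and the free-water diffusivity, clipped away from the
    boundary so both compartments stay active.

    f_init = clip((MD - md_ref) / (d_w - md_ref), 0.05, 0.95)
    """
    cfg = cfg or FWConfig()
    raw = (np.asarray(md, float) - cfg.md_tissue_ref) / (cfg.d_w - cfg.md_tissue_ref)
    return np.clip(raw, *cfg.init_clip)


def _clamp_tensor(coef: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    """Clamp eigenvalues of packed (n, 6) tensors into the tissue bounds."""
    full = np.zeros(coef.shape[:-1] + (3, 3))
    full[..., 0, 0] = coef[..., 0]
    full[..., 1, 1] = coef[..., 1]
    full[..., 2, 2] = coef[..., 2]
    full[..., 0, 1] = full[..., 1, 0] = coef[..., 3]
    full[..., 0, 2] = full[..., 2, 0] = coef[..., 4]
    full[..., 1, 2] = full[..., 2, 1] = coef[..., 5]
    w, v = np.linalg.eigh(full)
    w = np.clip(w, bounds[0], bounds[1])
    full = np.einsum("...ij,...j,...kj->...ik", v, w, v)
    out = np.empty_like(coef)
    out[..., 0] = full[..., 0, 0]
    out[..., 1] = full[..., 1, 1]
    out[..., 2] = full[..., 2, 2]
    out[..., 3] = full[..., 0, 1]
    out[..., 4] = full[..., 0, 2]
    out[..., 5] = full[..., 1, 2]
    return out


def fit_fw(
    dwi: DWIVolume, mask: VolumeMask | None = None, cfg: FWConfig | None = None
) -> FWResult:
    """Alternating-minimisation bi-tensor fit; see the module docstring.

    s0 is the mean of the b=0 volumes per voxel; all attenuations are
    relative to it, which makes the estimate invariant to global signal
    scaling.
    """
    cfg = cfg or FWConfig()
    m = np.ones(dwi.shape, dtype=bool) if mask is None else mask.data.copy()
    if not m.any():
        raise ValueError("mask is empty")

    sig, bvals, bvecs = _averaged_series(dwi)
    sig = _floor_signal(sig[m])  # (n, q), q[0] is the averaged b0
    s0 = sig[:, :1]
    atten = sig / s0  # A_q = S_q / s0
    shell = bvals > 0
    b = bvals[shell]
    g = bvecs[shell]
    A = atten[:, shell]
    e_w = np.exp(-b * cfg.d_w)  # free-water attenuation on the shell

    # shell-only log-linear design for the tissue tensor (no intercept:
    # the corrected attenuation is normalised to 1 at b=0 by construction)
    gx, gy, gz = g.T
    G = np.column_stack(
        [b * gx**2, b * gy**2, b * gz**2, 2 * b * gx * gy, 2 * b * gx * gz, 2 * b * gy * gz]
    )

    Gq = np.column_stack(
        [gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )  # ADC design (no b), for evaluating fitted tensors

    def tensor_step(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """WLS tissue tensor for given f; returns (packed coefs, e_t)."""
        At = (A - f[:, None] * e_w) / np.maximum(1.0 - f[:, None], 1e-8)
        At = np.maximum(At, 1e-8)
        y = -np.log(At)  # = b g^T D g for exact data
        w = At**2  # WLS weights for the log transform
        gtg = np.einsum("nq,qi,qj->nij", w, G, G)
        gty = np.einsum("nq,qi,nq->ni", w, G, y)
        coef = np.linalg.solve(gtg, gty[..., None])[..., 0]
        coef = _clamp_tensor(coef, cfg.eval_bounds)
        e_t = np.exp(-b * (coef @ Gq.T))
        return coef, e_t

    def profile_sse(f: np.ndarray) -> np.ndarray:
        _, e_t = tensor_step(f)
        resid = A - (1.0 - f[:, None]) * e_t - f[:, None] * e_w
        return (resid**2).sum(axis=1)

    n_vox = int(m.sum())
    f_lo = max(cfg.f_bounds[0], 0.0)
    f_hi = min(cfg.f_bounds[1], 0.99)

    # initial f from the single-tensor MD (reported initialiser; the profile
    # search below is global over [f_lo, f_hi] so it also seeds the bracket)
    md_st = _single_tensor_md(atten, b, G)
    f = np.clip((md_st - cfg.md_tissue_ref) / (cfg.d_w - cfg.md_tissue_ref), *cfg.init_clip)

    coef = np.zeros((n_vox, 6))
    converged = np.zeros(n_vox, dtype=bool)
    n_iter = 0

    # (i) first f step: global 1-D bounded minimisation of the profile
    # objective — coarse grid to bracket the minimum, golden-section refine.
    grid = np.linspace(f_lo, f_hi, 17)
    sse = np.stack([profile_sse(np.full(n_vox, fv)) for fv in grid])
    sse_min = sse.min(axis=0)
    # parsimony tie-break on the single-shell ridge: when several f fit the
    # data equally well (isotropic tissue), prefer the smallest f; such
    # voxels are flagged rather than masked out
    tie_tol = sse_min + 1e-9 * (A**2).sum(axis=1)
    is_tie = sse <= tie_tol[None, :]
    first_tie = is_tie.argmax(axis=0)
    last_tie = is_tie.shape[0] - 1 - is_tie[::-1].argmax(axis=0)
    ridge = grid[last_tie] - grid[first_tie] > 0.3
    best = np.where(ridge, first_tie, sse.argmin(axis=0))
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid.size - 1)]
    f_data = np.where(ridge, grid[best], _golden_section(profile_sse, lo, hi, n_steps=25))

    # (ii)/(iii) damped fixed-point iteration between the data-driven f and
    # its Gaussian-smoothed neighbourhood consensus: solves the spatially
    # regularised problem  f = S(0.5 f + 0.5 f_data)  with smoother S;
    # contraction factor 0.5 gives geometric convergence of max |delta f|
    f = f_data
    for n_iter in range(1, cfg.max_iter + 1):
        if cfg.smoothing_sigma <= 0:
            converged = np.ones(n_vox, dtype=bool)
            break
        blend_map = np.zeros(dwi.shape)
        blend_map[m] = 0.5 * f + 0.5 * f_data
        sm = ndimage.gaussian_filter(blend_map * m, cfg.smoothing_sigma)
        norm = ndimage.gaussian_filter(m.astype(float), cfg.smoothing_sigma)
        f_new = np.clip((sm / np.maximum(norm, 1e-12))[m], *cfg.f_bounds)
        delta = np.abs(f_new - f)
        f = f_new
        converged = delta < cfg.tol
        if delta.max() < cfg.tol:
            break

    # final tensor step at the regularised f
    coef, e_t = tensor_step(f)
    ridge |= ((e_w - e_t) ** 2).sum(axis=1) < 1e-12

    f_map = np.zeros(dwi.shape)
    f_map[m] = f
    tensor = np.zeros(dwi.shape + (6,))
    tensor[m] = coef
    derived = _tensor_derived_maps(tensor, m)
    s0_map = np.zeros(dwi.shape)
    s0_map[m] = s0[:, 0]
    tissue = TensorMaps(
        tensor=tensor,
        evals=derived["evals"],
        fa=derived["fa"],
        md=derived["md"],
        dxx=tensor[..., 0],
        dyy=tensor[..., 1],
        dzz=tensor[..., 2],
        s0=s0_map,
        degenerate=derived["degenerate"],
        mask=m,
        affine=dwi.affine,
    )
    conv_map = np.zeros(dwi.shape, dtype=bool)
    conv_map[m] = converged
    ridge_map = np.zeros(dwi.shape, dtype=bool)
    ridge_map[m] = ridge
    return FWResult(
        f=f_map,
        tissue=tissue,
        converged=conv_map,
        ridge=ridge_map,
        n_iter=n_iter,
        mask=m,
        affine=dwi.affine,
    )


def _golden_section(fun, lo: np.ndarray, hi: np.ndarray, n_steps: int = 25) -> np.ndarray:
    """Vectorised golden-section minimisation on per-voxel brackets."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, bnd = lo.copy(), hi.copy()
    for _ in range(n_steps):
        c = bnd - invphi * (bnd - a)
        d = a + invphi * (bnd - a)
        left = fun(c) < fun(d)
        bnd = np.where(left, d, bnd)
        a = np.where(left, a, c)
    return (a + bnd) / 2.0


def _single_tensor_md(atten: np.ndarray, b: np.ndarray, G: np.ndarray) -> np.ndarray:
    """MD of a plain log-linear tensor fit (initialiser input)."""
    y = -np.log(np.maximum(atten[:, -G.shape[0]:], 1e-8))
    coef = y @ np.linalg.pinv(G).T
    return (coef[:, 0] + coef[:, 1] + coef[:, 2]) / 3.0


# ---------------------------------------------------------------------------
# Skeleton


def wm_skeleton(
    fa: np.ndarray, mask: np.ndarray | None = None, fa_threshold: float = 0.2
) -> np.ndarray:
    """Medial-surface skeleton of the suprathreshold white matter.

    Voxels with FA > threshold (within ``mask``) form the WM mask; the
    skeleton is the ridge of its Euclidean distance transform: voxels whose
    distance value is >= that of every 6-neighbour and > at least one.
    For a plate of odd thickness this is exactly the 1-voxel medial plane.
    Out-of-grid space counts as foreground, so a slab spanning the whole
    grid keeps its medial plane rather than eroding from the grid faces.
    Deterministic, and idempotent on its own output.
    """
    fa = np.asarray(fa, float)
    wm = fa > fa_threshold
    if mask is not None:
        wm &= np.asarray(mask, bool)
    if not wm.any():
        raise ValueError(f"no voxels exceed the FA threshold {fa_threshold}")
    if wm.all():
        # degenerate: no background anywhere — treat grid faces as background
        dt = ndimage.distance_transform_edt(np.pad(wm, 1))[1:-1, 1:-1, 1:-1]
    else:
        dt = ndimage.distance_transform_edt(wm)

    ridge = wm.copy()
    strict = np.zeros_like(wm)
    for axis in range(3):
        for shift in (1, -1):
            # out-of-grid neighbours are ignored: they can neither disqualify
            # a ridge voxel (fill -inf for >=) nor make one (fill +inf for >)
            ridge &= dt >= _shifted(dt, axis, shift, fill=-np.inf) - 1e-9
            strict |= dt > _shifted(dt, axis, shift, fill=np.inf) + 1e-9
    return ridge & strict


def _shifted(a: np.ndarray, axis: int, shift: int, fill: float) -> np.ndarray:
    out = np.full_like(a, fill, dtype=float)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift > 0:
        src[axis] = slice(None, -shift)
        dst[axis] = slice(shift, None)
    else:
        src[axis] = slice(-shift, None)
        dst[axis] = slice(None, shift)
    out[tuple(dst)] = a[tuple(src)]
    return out


def mean_fw_on_skeleton(
    f: np.ndarray,
    skeleton: np.ndarray,
    lesion_mask: np.ndarray | None = None,
) -> tuple[float, int, int]:
    """Arithmetic mean of f over skeleton voxels outside the lesion mask.

    Returns (FW index, n_used, n_excluded).
    """
    skeleton = np.asarray(skeleton, bool)
    if lesion_mask is None:
        keep = skeleton
        n_excl = 0
    else:
        keep = skeleton & ~np.asarray(lesion_mask, bool)
        n_excl = int(skeleton.sum() - keep.sum())
    n_used = int(keep.sum())
    if n_used == 0:
        raise ValueError("no usable skeleton voxels after lesion exclusion")
    return float(np.asarray(f)[keep].mean()), n_used, n_excl
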