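"""Single-tensor diffusion model fitting (log-linear OLS/WLS).

The model per voxel is ``ln S_q = ln s0 - b_q g_q^T D g_q``, solved by
ordinary or weighted least squares over the 6 unique tensor elements plus
``ln s0``.  The WLS weights are the squared predicted signals from a first
OLS pass, the standard correction for the heteroscedasticity that the log
transform induces on Rician-noised magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dwi_core import DWIVolume, VolumeMask

__all__ = ["TensorMaps", "fit_tensor", "fa_from_eigenvalues", "axis_diffusivities"]

# Order of the 6 unique tensor elements throughout this module.
TENSOR_ELEMENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class TensorMaps:
    """Voxelwise tensor fit results.

    ``tensor`` holds the 6 unique elements (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in
    image axes; eigenvalues are sorted descending with negatives clamped to
    zero (and flagged), so FA is guaranteed to lie in [0, 1].
    """

    tensor: np.ndarray  # (x, y, z, 6) mm^2/s
    evals: np.ndarray  # (x, y, z, 3), lambda1 >= lambda2 >= lambda3 >= 0
    fa: np.ndarray
    md: np.ndarray
    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    s0: np.ndarray
    degenerate: np.ndarray  # True where eigenvalues were clamped
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def tensor_3x3(self) -> np.ndarray:
        """Full symmetric (x, y, z, 3, 3) tensor field."""
        t = self.tensor
        out = np.zeros(t.shape[:-1] + (3, 3))
        out[..., 0, 0] = t[..., 0]
        out[..., 1, 1] = t[..., 1]
        out[..., 2, 2] = t[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = t[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = t[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = t[..., 5]
        return out


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """(q, 7) log-linear design: columns [1, -b gx^2, -b gy^2, -b gz^2,
    -2b gx gy, -2b gx gz, -2b gy gz]."""
    gx, gy, gz = bvecs.T
    b = bvals
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def _averaged_series(dwi: DWIVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average multiple b=0 volumes into one; return (signal, bvals, bvecs)."""
    gtab = dwi.gtab
    b0 = gtab.b0_mask
    sig_b0 = dwi.signal[..., b0].mean(axis=-1, keepdims=True)
    sig = np.concatenate([sig_b0, dwi.signal[..., ~b0]], axis=-1)
    bvals = np.concatenate([[0.0], gtab.bvals[~b0]])
    bvecs = np.vstack([[0.0, 0.0, 0.0], gtab.bvecs[~b0]])
    return sig, bvals, bvecs


def _floor_signal(sig: np.ndarray) -> np.ndarray:
    """Replace non-positive samples by (smallest positive observed) * 1e-3."""
    pos = sig[sig > 0]
    if pos.size == 0:
        raise ValueError("signal contains no positive samples")
    return np.where(sig > 0, sig, pos.min() * 1e-3)


def fit_tensor(
    dwi: DWIVolume, mask: VolumeMask | None = None, method: str = "wls"
) -> TensorMaps:
    """Fit the single diffusion tensor per voxel inside a mask.

    Parameters
    ----------
    dwi : DWIVolume
        Series with at least 6 non-collinear directions plus b=0.
    mask : VolumeMask, optional
        Voxels to fit; default = whole grid.
    method : {'wls', 'ols'}
        'wls' (default) reweights a first OLS pass by its squared predicted
        signal.

    Raises
    ------
    ValueError
        If the gradient design is rank deficient (the message names the
        condition number).
    """
    if method not in ("ols", "wls"):
        raise ValueError(f"unknown fit method {method!r}")
    sig, bvals, bvecs = _averaged_series(dwi)
    if len(bvals) < 7:
        raise ValueError("tensor fit needs at least 6 directions plus b=0")
    X = design_matrix(bvals, bvecs)
    cond = np.linalg.cond(X)
    if cond > 1e6:
        raise ValueError(
            f"rank-deficient gradient design (condition number {cond:.3g}); "
            "directions are collinear"
        )

    m = np.ones(dwi.shape, dtype=bool) if mask is None else mask.data
    y = np.log(_floor_signal(sig[m]))  # (n, q)

    coef = y @ np.linalg.pinv(X).T  # OLS, (n, 7)
    if method == "wls":
        w = np.exp(2.0 * (coef @ X.T))  # squared predicted signal
        # per-voxel normal equations  (X^T W X) beta = X^T W y
        xtwx = np.einsum("nq,qi,qj->nij", w, X, X)
        xtwy = np.einsum("nq,qi,nq->ni", w, X, y)
        coef = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]

    shape = dwi.shape
    tensor = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    tensor[m] = coef[:, 1:]
    s0[m] = np.exp(coef[:, 0])

    maps = _tensor_derived_maps(tensor, m)
    return TensorMaps(
        tensor=tensor,
        evals=maps["evals"],
        fa=maps["fa"],
        md=maps["md"],
        dxx=tensor[..., 0],
        dyy=tensor[..., 1],
        dzz=tensor[..., 2],
        s0=s0,
        degenerate=maps["degenerate"],
        mask=m,
        affine=dwi.affine,
    )


def _tensor_derived_maps(tensor: np.ndarray, m: np.ndarray) -> dict:
    shape = tensor.shape[:-1]
    full = np.zeros(shape + (3, 3))
    full[..., 0, 0] = tensor[..., 0]
    full[..., 1, 1] = tensor[..., 1]
    full[..., 2, 2] = tensor[..., 2]
    full[..., 0, 1] = full[..., 1, 0] = tensor[..., 3]
    full[..., 0, 2] = full[..., 2, 0] = tensor[..., 4]
    full[..., 1, 2] = full[..., 2, 1] = tensor[..., 5]
    ev = np.linalg.eigvalsh(full[m])[:, ::-1]  # descending
    degenerate = ev[:, -1] < 0
    ev = np.clip(ev, 0.0, None)

    evals = np.zeros(shape + (3,))
    evals[m] = ev
    fa = np.zeros(shape)
    fa[m] = fa_from_eigenvalues(ev[:, 0], ev[:, 1], ev[:, 2])
    md = np.zeros(shape)
    md[m] = ev.mean(axis=1)
    deg = np.zeros(shape, dtype=bool)
    deg[m] = degenerate
    return {"evals": evals, "fa": fa, "md": md, "degenerate": deg}


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy from sorted non-negative eigenvalues.

    FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l1-l3)^2) / sqrt(l1^2+l2^2+l3^2);
    all-zero voxels are defined as FA = 0.
    """
    l1, l2, l3 = np.broadcast_arrays(
        np.asarray(l1, float), np.asarray(l2, float), np.asarray(l3, float)
    )
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(num / den)
    fa = np.where(den > 0, fa, 0.0)
    return fa if fa.ndim else float(fa)


def axis_diffusivities(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonal tensor elements (Dxx, Dyy, Dzz) in image axes (unrotated).

    Accepts either the packed (..., 6) element layout used by
    :class:`TensorMaps` or a full (..., 3, 3) tensor field.
    """
    tensor = np.asarray(tensor)
    if tensor.shape[-1] == 6:
        return tensor[..., 0], tensor[..., 1], tensor[..., 2]
    if tensor.shape[-2:] == (3, 3):
        return tensor[..., 0, 0], tensor[..., 1, 1], tensor[..., 2, 2]
    raise ValueError("tensor field must end in 6 packed elements or a 3x3 matrix")
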