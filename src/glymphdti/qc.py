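"""Temporal signal-to-noise (tSNR) screening of DWI series.

tSNR per voxel is the mean over the selected volumes divided by the sample
standard deviation (n-1) over those volumes; the subject-level summary is
the mean of the per-voxel values inside a brain mask.  A series passes when
the summary exceeds a cutoff (6.47 by default, a published screening
threshold for poor diffusion data).

Which volumes are "temporal" is ambiguous for a b0 + single-shell protocol;
the default uses the diffusion-weighted shell only, since the single b0
volume offers no variance of its own.  The selector used is recorded in the
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dwi_core import B0_THRESHOLD, DWIVolume, VolumeMask

__all__ = ["QCReport", "tsnr", "DEFAULT_TSNR_CUTOFF"]

DEFAULT_TSNR_CUTOFF = 6.47


@dataclass
class QCReport:
    tsnr_map: np.ndarray
    summary: float
    cutoff: float
    passed: bool
    n_voxels: int
    n_constant: int  # sd = 0 voxels, excluded from the summary
    volumes: str  # selector used: all | b0 | shell
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def to_dict(self) -> dict:
        return {
            "tsnr": self.summary,
            "cutoff": self.cutoff,
            "passed": bool(self.passed),
            "n_voxels": self.n_voxels,
            "n_constant": self.n_constant,
            "volumes": self.volumes,
        }


def tsnr(
    dwi: DWIVolume,
    mask: VolumeMask | None = None,
    volumes: str = "shell",
    cutoff: float = DEFAULT_TSNR_CUTOFF,
) -> QCReport:
    """Temporal SNR report for a DWI series.

    Parameters
    ----------
    volumes : {'shell', 'b0', 'all'}
        Which volumes form the "time" axis; default the b>0 shell.
    cutoff : float
        Pass/fail threshold on the mask-mean tSNR.

    Voxels with zero temporal variance are excluded from the summary (and
    counted) rather than producing infinities; a series where every voxel is
    constant is rejected as degenerate.
    """
    if volumes == "all":
        sel = np.ones(len(dwi.gtab), dtype=bool)
    elif volumes == "b0":
        sel = dwi.gtab.bvals < B0_THRESHOLD
    elif volumes == "shell":
        sel = dwi.gtab.bvals >= B0_THRESHOLD
    else:
        raise ValueError(f"unknown volume selector {volumes!r}")
    if sel.sum() < 3:
        raise ValueError(f"tSNR needs at least 3 volumes; selector {volumes!r} gives {sel.sum()}")

    m = np.ones(dwi.shape, dtype=bool) if mask is None else mask.data
    series = dwi.signal[..., sel]
    mean = series.mean(axis=-1)
    sd = series.std(axis=-1, ddof=1)

    tsnr_map = np.zeros(dwi.shape)
    valid = m & (sd > 0)
    tsnr_map[valid] = mean[valid] / sd[valid]
    n_constant = int((m & ~valid).sum())
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("degenerate series: zero temporal variance in every mask voxel")
    summary = float(tsnr_map[valid].mean())
    return QCReport(
        tsnr_map=tsnr_map,
        summary=summary,
        cutoff=cutoff,
        passed=summary > cutoff,
        n_voxels=n_valid,
        n_constant=n_constant,
        volumes=volumes,
        affine=dwi.affine,
    )
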