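"""DTI-ALPS: diffusivity along the perivascular space.

At the level of the lateral-ventricle body, the deep medullary veins run
left-right (the image x axis), perpendicular both to the projection fibres of
the superior corona radiata (z axis) and to the association fibres of the
superior longitudinal fasciculus (y axis).  The ALPS index is the ratio of
the mean x-axis diffusivity in the projection- and association-fibre ROIs to
the mean of the y-axis (projection) and z-axis (association) diffusivities:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

computed per hemisphere from 5 mm spherical ROIs, with manually drawn lesions
excluded from every ROI mean; the reported index is the mean of the left and
right indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SphereROI",
    "AlpsRoiSpec",
    "AlpsResult",
    "sphere_mask",
    "roi_mean",
    "alps_from_means",
    "compute_alps",
]


@dataclass(frozen=True)
class SphereROI:
    """A spherical ROI in world-space millimetres."""

    center_mm: tuple[float, float, float]
    diameter_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("sphere diameter must be positive")


@dataclass(frozen=True)
class AlpsRoiSpec:
    """The four ALPS spheres: projection and association fibres, both sides.

    Sides follow the RAS+ convention (left hemisphere at negative world x).
    """

    proj_left: SphereROI
    proj_right: SphereROI
    assoc_left: SphereROI
    assoc_right: SphereROI

    def __post_init__(self) -> None:
        centers = [
            self.proj_left.center_mm,
            self.proj_right.center_mm,
            self.assoc_left.center_mm,
            self.assoc_right.center_mm,
        ]
        if len({tuple(np.round(c, 6)) for c in centers}) < 4:
            raise ValueError("ALPS ROI centres must be distinct")

    @classmethod
    def from_dict(cls, d: dict) -> "AlpsRoiSpec":
        rois = {}
        for name in ("proj_left", "proj_right", "assoc_left", "assoc_right"):
            entry = d[name]
            rois[name] = SphereROI(
                tuple(float(x) for x in entry["center_mm"]),
                float(entry.get("diameter_mm", 5.0)),
            )
        return cls(**rois)


#: Placeholder ROI centres (world mm) in FA-template space at the level of
#: the lateral-ventricle body, near the superior corona radiata (projection)
#: and superior longitudinal fasciculus (association).  These are documented
#: approximations for atlas-registered data, not study-exact coordinates;
#: supply label-derived centres for real analyses.
DEFAULT_ATLAS_ROIS = AlpsRoiSpec(
    proj_left=SphereROI((-26.0, -18.0, 26.0)),
    proj_right=SphereROI((26.0, -18.0, 26.0)),
    assoc_left=SphereROI((-38.0, -22.0, 26.0)),
    assoc_right=SphereROI((38.0, -22.0, 26.0)),
)


@dataclass
class AlpsResult:
    """Per-hemisphere and mean ALPS indices with their ingredient means."""

    left: float
    right: float
    mean: float
    diffusivities: dict  # {(side, name): mean diffusivity mm^2/s}
    counts: dict  # {(side, name): (n_used, n_excluded)}

    def to_row(self) -> dict:
        row = {"alps_left": self.left, "alps_right": self.right, "alps_mean": self.mean}
        for (side, name), v in self.diffusivities.items():
            row[f"{name}_{side}"] = v
        return row


def sphere_mask(
    center_mm,
    diameter_mm: float,
    shape: tuple[int, int, int],
    affine: np.ndarray,
) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within diameter/2 of a point.

    The voxel-centre rule (no partial-volume weighting) is deterministic and
    matches common ROI practice.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    affine = np.asarray(affine, float)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    world = vox @ affine.T
    dist = np.linalg.norm(world[..., :3] - np.asarray(center_mm, float), axis=-1)
    out = dist <= diameter_mm / 2.0
    if not out.any():
        raise ValueError(f"sphere at {tuple(center_mm)} does not intersect the grid")
    return out


def roi_mean(
    values: np.ndarray,
    roi: np.ndarray,
    lesion_mask: np.ndarray | None = None,
    label: str = "ROI",
) -> tuple[float, int, int]:
    """Mean of ``values`` over ROI voxels outside the lesion mask.

    Returns (mean, n_used, n_excluded); raises if every ROI voxel is
    lesion-excluded, naming the ROI.
    """
    roi = np.asarray(roi, bool)
    if lesion_mask is None:
        keep = roi
        n_excl = 0
    else:
        keep = roi & ~np.asarray(lesion_mask, bool)
        n_excl = int(roi.sum() - keep.sum())
    n_used = int(keep.sum())
    if n_used == 0:
        raise ValueError(f"all voxels of {label} are lesion-excluded or empty")
    return float(np.asarray(values)[keep].mean()), n_used, n_excl


def alps_from_means(dxx_proj, dxx_assoc, dyy_proj, dzz_assoc) -> float:
    """ALPS ratio from the four ingredient mean diffusivities."""
    vals = np.asarray([dxx_proj, dxx_assoc, dyy_proj, dzz_assoc], dtype=float)
    if np.any(vals <= 0):
        raise ValueError("ALPS ingredient diffusivities must all be positive")
    return float((vals[0] + vals[1]) / (vals[2] + vals[3]))


def compute_alps(
    tensor_maps,
    rois: AlpsRoiSpec,
    lesion_mask: np.ndarray | None = None,
) -> AlpsResult:
    """Per-hemisphere ALPS indices from fitted axis-diffusivity maps.

    ``tensor_maps`` must expose ``dxx``, ``dyy``, ``dzz`` and ``affine``
    (maps are assumed already registered to the ROI space); lesion voxels
    are excluded from every ingredient mean.
    """
    shape = tensor_maps.dxx.shape
    affine = tensor_maps.affine
    lm = None if lesion_mask is None else np.asarray(lesion_mask, bool)

    diffusivities: dict = {}
    counts: dict = {}
    side_index: dict[str, float] = {}
    for side in ("left", "right"):
        proj_roi = getattr(rois, f"proj_{side}")
        assoc_roi = getattr(rois, f"assoc_{side}")
        proj = sphere_mask(proj_roi.center_mm, proj_roi.diameter_mm, shape, affine)
        assoc = sphere_mask(assoc_roi.center_mm, assoc_roi.diameter_mm, shape, affine)
        ingredients = {
            "dxx_proj": (tensor_maps.dxx, proj),
            "dxx_assoc": (tensor_maps.dxx, assoc),
            "dyy_proj": (tensor_maps.dyy, proj),
            "dzz_assoc": (tensor_maps.dzz, assoc),
        }
        means = {}
        for name, (vals, roi) in ingredients.items():
            mu, n_used, n_excl = roi_mean(vals, roi, lm, label=f"{name}_{side}")
            means[name] = mu
            diffusivities[(side, name)] = mu
            counts[(side, name)] = (n_used, n_excl)
        side_index[side] = alps_from_means(
            means["dxx_proj"], means["dxx_assoc"], means["dyy_proj"], means["dzz_assoc"]
        )

    return AlpsResult(
        left=side_index["left"],
        right=side_index["right"],
        mean=(side_index["left"] + side_index["right"]) / 2.0,
        diffusivities=diffusivities,
        counts=counts,
    )
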