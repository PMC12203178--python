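"""Substantia-nigra ROI construction and quantification.

The nigral territories are built from a whole-SN mask per hemisphere and a
red-nucleus mask: the dorsal SN is the part lying on axial slices where the
red nucleus is visible, the ventral SN lies on the slices inferior to the red
nucleus, and each of the two is split halfway along the anterior-posterior
extent of the hemisphere's SN into anterior and posterior territories.  The
posteroventral territory is the one earliest affected by iron accumulation in
Parkinson's disease.

Axis convention (validated, never guessed): axis 0 is left-right, axis 1 is
anterior-posterior with *posterior at larger index*, axis 2 is
inferior-superior with *inferior at smaller index* (an RAS-like contract).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LABEL_CODES",
    "COMPOSITE_ROIS",
    "ROILabelMap",
    "derive_sn_subdivisions",
    "extract_roi_stats",
    "pct_rate_change",
    "apply_inverse_warp",
]

#: Canonical integer codes for the finest-grained labels.  Composite ROIs
#: (whole SN, dorsal, ventral) are unions of these, see :data:`COMPOSITE_ROIS`.
LABEL_CODES: dict[str, int] = {
    "anterodorsal_L": 1,
    "posterodorsal_L": 2,
    "anteroventral_L": 3,
    "posteroventral_L": 4,
    "anterodorsal_R": 5,
    "posterodorsal_R": 6,
    "anteroventral_R": 7,
    "posteroventral_R": 8,
    "STN_L": 9,
    "STN_R": 10,
    "red_nucleus_L": 11,
    "red_nucleus_R": 12,
}

#: Composite ROIs as unions of base label names, per hemisphere.
COMPOSITE_ROIS: dict[str, tuple[str, ...]] = {
    "whole_SN_L": ("anterodorsal_L", "posterodorsal_L", "anteroventral_L", "posteroventral_L"),
    "whole_SN_R": ("anterodorsal_R", "posterodorsal_R", "anteroventral_R", "posteroventral_R"),
    "dorsal_L": ("anterodorsal_L", "posterodorsal_L"),
    "dorsal_R": ("anterodorsal_R", "posterodorsal_R"),
    "ventral_L": ("anteroventral_L", "posteroventral_L"),
    "ventral_R": ("anteroventral_R", "posteroventral_R"),
}

#: ROI base names (without hemisphere suffix) reported in the standard outputs.
REPORTED_ROIS = (
    "whole_SN",
    "ventral",
    "posteroventral",
    "anteroventral",
    "dorsal",
    "posterodorsal",
    "anterodorsal",
    "STN",
)


@dataclass
class ROILabelMap:
    """Integer label volume plus the dictionary naming each code.

    ``data`` stores the finest partition (one code per voxel); composite ROIs
    are resolved through :data:`COMPOSITE_ROIS` at extraction time.
    """

    data: np.ndarray
    labels: dict[str, int] = field(default_factory=lambda: dict(LABEL_CODES))
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def mask_for(self, name: str) -> np.ndarray:
        """Boolean mask of a base or composite ROI name."""
        if name in self.labels:
            return self.data == self.labels[name]
        if name in COMPOSITE_ROIS:
            codes = [self.labels[m] for m in COMPOSITE_ROIS[name]]
            return np.isin(self.data, codes)
        raise KeyError(f"unknown ROI name: {name!r}")

    def has(self, name: str) -> bool:
        try:
            return bool(self.mask_for(name).any())
        except KeyError:
            return False


def derive_sn_subdivisions(
    sn_mask_left: np.ndarray,
    sn_mask_right: np.ndarray,
    red_nucleus_mask: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ROILabelMap:
    """Partition each hemisphere's SN into the four nigral territories.

    Dorsal SN: voxels on axial slices (axis 2) at or above the lowest slice
    where the red nucleus is present.  Ventral SN: voxels on slices inferior
    to the red nucleus.  Within each, the anterior/posterior split is at the
    midpoint of the hemisphere SN's own anterior-posterior voxel extent
    (axis 1, posterior = larger index); midpoint ties go to posterior.

    Raises ``ValueError`` when masks overlap/disagree in shape, the red
    nucleus is empty, or any of the eight subdivisions comes out empty.
    """
    shape = sn_mask_left.shape
    for m, nm in ((sn_mask_right, "right SN"), (red_nucleus_mask, "red nucleus")):
        if m.shape != shape:
            raise ValueError(f"{nm} mask shape {m.shape} != left SN shape {shape}")
    if np.logical_and(sn_mask_left, sn_mask_right).any():
        raise ValueError("left and right SN masks overlap")
    if not red_nucleus_mask.any():
        raise ValueError("red nucleus mask is empty")

    rn_slices = np.flatnonzero(red_nucleus_mask.any(axis=(0, 1)))
    rn_lowest = int(rn_slices.min())
    rn_highest = int(rn_slices.max())

    out = np.zeros(shape, dtype=np.int16)
    for side, sn in (("L", sn_mask_left), ("R", sn_mask_right)):
        if not sn.any():
            raise ValueError(f"hemisphere {side} SN mask is empty")
        zz = np.flatnonzero(sn.any(axis=(0, 1)))
        if zz.max() > rn_highest:
            warnings.warn(
                f"SN slices superior to all red-nucleus slices in hemisphere {side}; "
                "labelled dorsal",
                stacklevel=2,
            )
        yy = np.flatnonzero(sn.any(axis=(0, 2)))
        ap_mid = 0.5 * (yy.min() + yy.max())

        iy, iz = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
        dorsal_plane = iz >= rn_lowest  # slices where RN visible (and above)
        posterior_plane = iy >= ap_mid  # ties -> posterior

        planes = {
            "anterodorsal": dorsal_plane & ~posterior_plane,
            "posterodorsal": dorsal_plane & posterior_plane,
            "anteroventral": ~dorsal_plane & ~posterior_plane,
            "posteroventral": ~dorsal_plane & posterior_plane,
        }
        for base, plane in planes.items():
            sel = sn & plane[None, :, :]
            if not sel.any():
                raise ValueError(f"empty subdivision: {base}_{side}")
            out[sel] = LABEL_CODES[f"{base}_{side}"]

    labels = ROILabelMap(out, dict(LABEL_CODES), tuple(voxel_size))
    _check_partition(labels, sn_mask_left, sn_mask_right)
    return labels


def _check_partition(labels: ROILabelMap, sn_left: np.ndarray, sn_right: np.ndarray) -> None:
    """The four subdivisions must partition each hemisphere's SN exactly."""
    for side, sn in (("L", sn_left), ("R", sn_right)):
        union = labels.mask_for(f"whole_SN_{side}")
        if not np.array_equal(union, sn):
            raise ValueError(f"subdivisions do not partition the {side} SN")


def extract_roi_stats(
    values: np.ndarray,
    labels: ROILabelMap,
    modality: str = "qsm_ppm",
    rois: tuple[str, ...] = REPORTED_ROIS,
    valid_mask: np.ndarray | None = None,
):
    """Per-ROI mean/SD/voxel count plus the left-right averaged value.

    The left-right averaged entry (``side == "mean"``) is the arithmetic mean
    of the two hemisphere *means* (equal hemisphere weight, not voxel
    pooling).  Absent labels are reported as missing rows (NaN mean, zero
    count), never as zeros.
    """
    import pandas as pd

    if values.shape != labels.data.shape:
        raise ValueError(f"map grid {values.shape} != label grid {labels.data.shape}")
    if valid_mask is not None and valid_mask.shape != values.shape:
        raise ValueError("valid_mask grid mismatch")

    rows = []
    for roi in rois:
        side_means: dict[str, float] = {}
        for side in ("L", "R"):
            name = f"{roi}_{side}"
            try:
                m = labels.mask_for(name)
            except KeyError:
                m = np.zeros_like(values, dtype=bool)
            if valid_mask is not None:
                m = m & valid_mask
            n = int(m.sum())
            if n == 0:
                mean = sd = float("nan")
            else:
                v = values[m]
                mean = float(v.mean())
                sd = float(v.std(ddof=1)) if n > 1 else 0.0
            side_means["left" if side == "L" else "right"] = mean
            rows.append(
                {"roi": roi, "side": "left" if side == "L" else "right",
                 "modality": modality, "mean": mean, "sd": sd, "n_voxels": n}
            )
        lr = 0.5 * (side_means["left"] + side_means["right"])
        rows.append(
            {"roi": roi, "side": "mean", "modality": modality,
             "mean": float(lr), "sd": float("nan"), "n_voxels": 0}
        )
    return pd.DataFrame(rows)


def pct_rate_change(x_initial: float, x_final: float) -> float:
    """Percentage rate of change, ``(x_final - x_initial) / x_initial * 100``."""
    if x_initial == 0:
        raise ValueError("x_initial must be nonzero")
    return (x_final - x_initial) / x_initial * 100.0


def apply_inverse_warp(
    labels: ROILabelMap,
    displacement: np.ndarray,
    target_shape: tuple[int, int, int] | None = None,
) -> ROILabelMap:
    """Denormalize a template-space label map through a displacement field.

    ``displacement`` has shape ``target_shape + (3,)`` and maps each target
    voxel ``x`` to source coordinate ``x + displacement[x]`` (voxel units).
    Labels are resampled nearest-neighbour so they stay categorical; voxels
    sent outside the label grid become background (0).
    """
    if target_shape is None:
        target_shape = displacement.shape[:-1]
    if displacement.shape != tuple(target_shape) + (3,):
        raise ValueError("displacement shape must be target_shape + (3,)")
    grid = np.meshgrid(*[np.arange(n) for n in target_shape], indexing="ij")
    coords = [grid[a] + displacement[..., a] for a in range(3)]
    warped = ndimage.map_coordinates(
        labels.data, coords, order=0, mode="constant", cval=0
    ).astype(labels.data.dtype)
    return ROILabelMap(warped, dict(labels.labels), labels.voxel_size)
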