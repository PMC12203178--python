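"""NIfTI-1 volume and sidecar I/O with a strict axis-aligned contract.

Volumes are stored single-file NIfTI (optionally gzipped); complex echo
series are stored as paired real/imaginary 4-D volumes with a JSON sidecar
recording echo times (seconds), field strength and B0 direction.  Affines
must be axis-aligned (rotation part a signed permutation-scaling); anything
else is an error, never a silent reorientation.  Voxel indexing is 0-based.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import EchoSeries

__all__ = [
    "read_volume",
    "write_volume",
    "write_echo_series",
    "read_echo_series",
    "file_sha256",
]


def _check_axis_aligned(affine: np.ndarray) -> np.ndarray:
    """Validate that the 3x3 part is a signed permutation-scaling; return voxel sizes."""
    r = np.asarray(affine)[:3, :3]
    vox = np.zeros(3)
    for j in range(3):
        col = r[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-6 * max(np.abs(col).max(), 1e-30))
        if nz.size != 1:
            raise ValueError(
                "affine is not axis-aligned (oblique orientation); this pipeline "
                "does not silently reorient volumes"
            )
        vox[j] = abs(col[nz[0]])
    return vox


def read_volume(path):
    """Load a NIfTI volume; returns (data, affine, voxel_size)."""
    img = nib.load(str(path))
    vox = _check_axis_aligned(img.affine)
    data = np.asarray(img.dataobj)
    return data, np.asarray(img.affine), tuple(float(v) for v in vox)


def write_volume(data, path, voxel_size=(1.0, 1.0, 1.0), affine=None):
    """Write a NIfTI volume (float64 preserved; boolean stored as uint8)."""
    if affine is None:
        affine = np.diag(list(voxel_size) + [1.0])
    _check_axis_aligned(affine)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return Path(path)


def write_echo_series(echoes: EchoSeries, out_dir, stem: str = "echoes"):
    """Store a complex echo series as real/imag NIfTI pair + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vox = echoes.voxel_size
    real_p = out / f"{stem}_real.nii.gz"
    imag_p = out / f"{stem}_imag.nii.gz"
    write_volume(np.real(echoes.signal), real_p, vox)
    write_volume(np.imag(echoes.signal), imag_p, vox)
    sidecar = {
        "echo_times_s": [float(t) for t in echoes.echo_times],
        "b0_tesla": float(echoes.b0_tesla),
        "b0_dir": [float(v) for v in echoes.b0_dir],
        "complex_storage": "real_imag",
        "voxel_size_mm": [float(v) for v in vox],
    }
    side_p = out / f"{stem}.json"
    side_p.write_text(json.dumps(sidecar, indent=2))
    return real_p, imag_p, side_p


def read_echo_series(real_path, imag_path, sidecar_path) -> EchoSeries:
    """Load a real/imag NIfTI pair + sidecar back into an EchoSeries."""
    meta = json.loads(Path(sidecar_path).read_text())
    re, _, vox = read_volume(real_path)
    im, _, _ = read_volume(imag_path)
    if re.shape != im.shape:
        raise ValueError("real/imag volume shapes differ")
    te = np.asarray(meta["echo_times_s"], float)
    if re.shape[-1] != te.size:
        raise ValueError(
            f"sidecar lists {te.size} echo times but volumes carry {re.shape[-1]} echoes"
        )
    return EchoSeries(
        re + 1j * im,
        te,
        tuple(meta.get("voxel_size_mm", vox)),
        float(meta.get("b0_tesla", 3.0)),
        np.asarray(meta.get("b0_dir", [0.0, 0.0, 1.0]), float),
    )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
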