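"""NIfTI-1 read/write helpers with JSON sidecars for echo metadata.

Volumes are stored with the package's (slice, row, col) axis order mapped
directly onto NIfTI array axes; voxel spacing goes into the affine diagonal.
Complex dual-echo data is stored as real/imaginary channel pairs, declared
in the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Tuple

import nibabel as nib
import numpy as np

from .phantom import DualEchoComplex, MultiEchoStack, ScalarVolume


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_scalar(path, data: np.ndarray, spacing: Sequence[float]) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(spacing)), str(path))


def load_scalar(path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in np.diag(img.affine)[:3])
    return np.asarray(img.dataobj, dtype=float), spacing


def save_multiecho(path, stack: MultiEchoStack) -> None:
    """4D NIfTI (echo last) plus a sidecar JSON with echo times in ms."""
    path = Path(path)
    data = np.moveaxis(np.asarray(stack.volumes, dtype=np.float64), 0, -1)
    nib.save(nib.Nifti1Image(data, _affine(stack.spacing)), str(path))
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"EchoTimesMs": list(stack.echo_times)}, fh)


def load_multiecho(path) -> MultiEchoStack:
    path = Path(path)
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    spacing = tuple(float(z) for z in np.diag(img.affine)[:3])
    sidecar = path.with_suffix(".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    return MultiEchoStack(data, tuple(meta["EchoTimesMs"]), spacing)


def save_dixon(prefix, data: DualEchoComplex) -> None:
    """Write <prefix>_real.nii / <prefix>_imag.nii (4D, echo last) + sidecar."""
    prefix = Path(prefix)
    real = np.stack([data.echo1.real, data.echo2.real], axis=-1)
    imag = np.stack([data.echo1.imag, data.echo2.imag], axis=-1)
    nib.save(nib.Nifti1Image(real, _affine(data.spacing)), str(prefix) + "_real.nii")
    nib.save(nib.Nifti1Image(imag, _affine(data.spacing)), str(prefix) + "_imag.nii")
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(
            {
                "EchoTimesMs": list(data.echo_times),
                "FatShiftHz": data.fat_shift_hz,
                "ComplexConvention": "real_imag",
            },
            fh,
        )


def load_dixon(prefix) -> DualEchoComplex:
    prefix = str(prefix)
    real = np.asarray(nib.load(prefix + "_real.nii").dataobj, dtype=float)
    img = nib.load(prefix + "_imag.nii")
    imag = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in np.diag(img.affine)[:3])
    with open(prefix + ".json") as fh:
        meta = json.load(fh)
    echo1 = real[..., 0] + 1j * imag[..., 0]
    echo2 = real[..., 1] + 1j * imag[..., 1]
    return DualEchoComplex(
        echo1, echo2, tuple(meta["EchoTimesMs"]), float(meta["FatShiftHz"]), spacing
    )
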