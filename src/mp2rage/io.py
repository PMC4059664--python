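"""NIfTI volume I/O and run-report sidecars."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from .combination import ComplexVolumePair

__all__ = [
    "read_volume",
    "write_volume",
    "read_complex_volume",
    "load_pair",
    "write_sidecar",
]


def read_volume(path) -> Tuple[np.ndarray, np.ndarray, "nib.Nifti1Header"]:
    """Load a NIfTI volume; returns (data, affine, header)."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine, img.header


def write_volume(data: np.ndarray, affine: Optional[np.ndarray], path, dtype=None) -> None:
    """Write a NIfTI-1 volume (float32 by default, affine identity if None)."""
    if affine is None:
        affine = np.eye(4)
    data = np.asarray(data)
    if dtype is None:
        dtype = np.int16 if np.issubdtype(data.dtype, np.integer) else np.float32
    img = nib.Nifti1Image(data.astype(dtype), affine)
    nib.save(img, str(path))


def _check_match(name_a, a, aff_a, name_b, b, aff_b) -> None:
    if a.shape != b.shape:
        raise ValueError(
            f"shape mismatch between {name_a} {a.shape} and {name_b} {b.shape}"
        )
    if aff_a is not None and aff_b is not None and not np.allclose(aff_a, aff_b, atol=1e-4):
        raise ValueError(f"affine mismatch between {name_a} and {name_b}")


def read_complex_volume(mag_path, phase_path=None) -> Tuple[np.ndarray, np.ndarray]:
    """Complex volume from a native-complex file or a magnitude+phase pair.

    Phase images are expected in radians (commonly exported in [-pi, pi]).
    Returns (complex data, affine).
    """
    data, affine, _ = read_volume(mag_path)
    if np.iscomplexobj(data):
        return np.asarray(data, dtype=complex), affine
    if phase_path is None:
        return np.asarray(data, dtype=complex), affine
    phase, aff_p, _ = read_volume(phase_path)
    _check_match(str(mag_path), data, affine, str(phase_path), phase, aff_p)
    return data * np.exp(1j * phase), affine


def load_pair(inv1_path, inv2_path, phase1_path=None, phase2_path=None) -> ComplexVolumePair:
    """Load the GRE_TI1/GRE_TI2 pair, validating shapes and affines."""
    s1, aff1 = read_complex_volume(inv1_path, phase1_path)
    s2, aff2 = read_complex_volume(inv2_path, phase2_path)
    _check_match(str(inv1_path), s1, aff1, str(inv2_path), s2, aff2)
    return ComplexVolumePair(s1=s1, s2=s2, affine=aff1)


def write_sidecar(path, payload: dict) -> None:
    """JSON sidecar capturing the resolved parameters of one run."""
    from . import __version__

    payload = dict(payload)
    payload.setdefault("software", {"name": "mp2rage", "version": __version__})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
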