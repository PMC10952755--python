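"""NIfTI volume I/O helpers (nibabel).

Volumes are stored with a diagonal affine built from the in-plane pixel
size and slice pitch (mm); provenance (stage, method, config hash) goes
into the NIfTI description field.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

__all__ = ["save_volume", "load_volume"]


def save_volume(path, data: np.ndarray, pixel_size_cm: float = 0.7,
                slice_pitch_cm: float = 1.0, description: str = "") -> None:
    affine = np.diag([pixel_size_cm * 10.0, pixel_size_cm * 10.0,
                      slice_pitch_cm * 10.0, 1.0])
    img = nib.Nifti1Image(np.asarray(data, np.float32), affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), float)
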