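"""Slice-frame geometry: map scanner-frame gradient vectors onto the
readout (RO), phase-encode (PE) and slice (SL) axes for any principal
orientation, tilt and PE polarity convention.

Scanner frame is RAS: +X right, +Y anterior, +Z superior (head).
Canonical frames:

* transverse: PE anterior->posterior (-Y), SL +Z, RO +X
* sagittal:   PE anterior->posterior (-Y), SL +X, RO +Z
* coronal:    PE feet->head (+Z),          SL +Y, RO +X

Tilt convention: for transverse and coronal slices the tilt is a slice
angulation, i.e. a rotation of (e_PE, e_SL) about e_RO; for sagittal slices
it is an in-plane rotation of (e_RO, e_PE) about e_SL. The sign is fixed so
that for transverse slices a positive angle tips the anterior slice edge
towards the feet; the sagittal sense is chosen so that transverse and
sagittal acquisitions at equal tilt share the same PE axis, and the coronal
sense uses the same rotation table. Both choices are conventions encoded in
``_TILT_AXIS`` and verified by unit tests against the canonical frames.

Gradients are projected voxel-wise into the tilted frame; the volume is
never resampled onto tilted slices (slice-coverage changes from tilting are
not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .protocol import Orientation

__all__ = ["SliceFrame", "canonical_frame", "tilt_frame",
           "project_gradient", "project_gradient_volumes"]


_CANONICAL = {
    Orientation.TRANSVERSE: dict(e_ro=(1.0, 0.0, 0.0),
                                 e_pe=(0.0, -1.0, 0.0),
                                 e_sl=(0.0, 0.0, 1.0)),
    Orientation.SAGITTAL: dict(e_ro=(0.0, 0.0, 1.0),
                               e_pe=(0.0, -1.0, 0.0),
                               e_sl=(1.0, 0.0, 0.0)),
    Orientation.CORONAL: dict(e_ro=(1.0, 0.0, 0.0),
                              e_pe=(0.0, 0.0, 1.0),
                              e_sl=(0.0, 1.0, 0.0)),
}

# (name of the rotation axis, sense multiplier applied to the angle)
_TILT_AXIS = {
    Orientation.TRANSVERSE: ("e_ro", -1.0),
    Orientation.CORONAL: ("e_ro", -1.0),
    Orientation.SAGITTAL: ("e_sl", -1.0),
}


@dataclass(frozen=True)
class SliceFrame:
    """Orthonormal acquisition frame (RO, PE, SL) in scanner coordinates."""

    orientation: Orientation
    tilt_deg: float
    e_ro: np.ndarray
    e_pe: np.ndarray
    e_sl: np.ndarray

    def basis(self) -> np.ndarray:
        """Rows are e_RO, e_PE, e_SL."""
        return np.stack([self.e_ro, self.e_pe, self.e_sl])


def canonical_frame(orientation) -> SliceFrame:
    """The untilted frame for a principal orientation."""
    orientation = Orientation(orientation)
    vecs = _CANONICAL[orientation]
    return SliceFrame(orientation=orientation, tilt_deg=0.0,
                      **{k: np.asarray(v) for k, v in vecs.items()})


def tilt_frame(frame: SliceFrame, tilt_deg: float) -> SliceFrame:
    """Rotate a frame by ``tilt_deg`` about its orientation's tilt axis."""
    axis_name, sense = _TILT_AXIS[frame.orientation]
    axis = getattr(frame, axis_name)
    rot = Rotation.from_rotvec(np.deg2rad(sense * tilt_deg) * axis)
    new = {name: rot.apply(getattr(frame, name))
           for name in ("e_ro", "e_pe", "e_sl")}
    # the rotation axis itself stays put exactly
    new[axis_name] = getattr(frame, axis_name)
    return SliceFrame(orientation=frame.orientation,
                      tilt_deg=frame.tilt_deg + tilt_deg, **new)


def project_gradient(grad, frame: SliceFrame):
    """Project a scanner-frame 3-vector (uT/m) onto (RO, PE, SL).

    PE polarity does not alter the projection; it only selects the sign in
    the echo-shift factor downstream.
    """
    grad = np.asarray(grad, dtype=float)
    return (float(grad @ frame.e_ro),
            float(grad @ frame.e_pe),
            float(grad @ frame.e_sl))


def project_gradient_volumes(gx, gy, gz, frame: SliceFrame):
    """Vectorized projection of per-voxel gradient component volumes.

    Returns (G_RO, G_PE, G_SL) volumes sharing the input shape.
    """
    out = []
    for e in (frame.e_ro, frame.e_pe, frame.e_sl):
        out.append(gx * e[0] + gy * e[1] + gz * e[2])
    return tuple(out)
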