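"""Volume I/O, field-map estimation and susceptibility-gradient derivation.

A :class:`FieldMap` is a 3D lattice of off-resonance values in Hz together
with its geometry (voxel size, orientation codes, optional mask, NIfTI
affine). A :class:`GradientField` holds the three susceptibility-gradient
component volumes in uT/m, expressed in the scanner RAS frame (+X right,
+Y anterior, +Z superior) regardless of the lattice storage order.

All multi-subject inputs are assumed co-registered; registration and
spatial normalization are outside the scope of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from skimage.restoration import unwrap_phase

from . import constants

__all__ = [
    "FieldMap", "GradientField", "read_volume", "write_volume",
    "fieldmap_from_double_echo", "gradient_field", "average_maps",
]

_AXCODE_TO_RAS = {
    "R": (0, +1), "L": (0, -1),
    "A": (1, +1), "P": (1, -1),
    "S": (2, +1), "I": (2, -1),
}


@dataclass
class FieldMap:
    """Scalar off-resonance volume in Hz with lattice geometry.

    ``axes`` gives the anatomical direction of increasing index along each
    lattice axis using nibabel orientation codes (default ``("R","A","S")``:
    lattice axes aligned with scanner +X, +Y, +Z).
    """

    values: np.ndarray
    voxel_size: np.ndarray
    axes: tuple[str, str, str] = ("R", "A", "S")
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.values.ndim}D")
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64)
        if self.voxel_size.shape != (3,) or not np.all(self.voxel_size > 0):
            raise ValueError("voxel_size must be a positive 3-vector (mm)")
        self.axes = tuple(str(a).upper() for a in self.axes)
        if sorted(_AXCODE_TO_RAS[a][0] for a in self.axes) != [0, 1, 2]:
            raise ValueError(f"axes {self.axes} are not a signed permutation")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")
            if not np.all(np.isfinite(self.values[self.mask])):
                raise ValueError("non-finite field values inside mask")

    @property
    def shape(self):
        return self.values.shape

    def same_geometry(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel_size, other.voxel_size)
                and self.axes == other.axes)

    def default_affine(self) -> np.ndarray:
        """Affine implied by axes + voxel size, centred on the volume."""
        if self.affine is not None:
            return self.affine
        aff = np.zeros((4, 4))
        aff[3, 3] = 1.0
        for lat, code in enumerate(self.axes):
            ras, sgn = _AXCODE_TO_RAS[code]
            aff[ras, lat] = sgn * self.voxel_size[lat]
        centre = (np.asarray(self.shape) - 1) / 2.0
        aff[:3, 3] = -aff[:3, :3] @ centre
        return aff


@dataclass
class GradientField:
    """Susceptibility-gradient component volumes, uT/m, scanner RAS frame."""

    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    voxel_size: np.ndarray
    axes: tuple[str, str, str] = ("R", "A", "S")
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.gx = np.asarray(self.gx, dtype=np.float64)
        self.gy = np.asarray(self.gy, dtype=np.float64)
        self.gz = np.asarray(self.gz, dtype=np.float64)
        if not (self.gx.shape == self.gy.shape == self.gz.shape):
            raise ValueError("component shapes differ")
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64)
        self.axes = tuple(str(a).upper() for a in self.axes)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self):
        return self.gx.shape

    def same_geometry(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel_size, other.voxel_size)
                and self.axes == other.axes)

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.gx**2 + self.gy**2 + self.gz**2)


def read_volume(path, axes_override=None) -> FieldMap:
    """Read a 3D NIfTI volume as a :class:`FieldMap`.

    Axis/direction semantics are derived from the affine via nibabel's
    orientation codes; ``axes_override`` (e.g. ``("R","A","S")``) takes
    precedence for files with ambiguous or wrong headers.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D single-frame volume, got shape "
            f"{data.shape}")
    zooms = img.header.get_zooms()[:3]
    if axes_override is not None:
        axes = tuple(axes_override)
    else:
        axes = tuple(nib.aff2axcodes(img.affine))
    return FieldMap(values=np.asarray(data, dtype=np.float64),
                    voxel_size=np.asarray(zooms, dtype=np.float64),
                    axes=axes, affine=np.asarray(img.affine))


def write_volume(fmap, path) -> None:
    """Write a FieldMap (or a single component array with geometry) to NIfTI.

    Values are stored as float64 so that a write/read round trip preserves
    them bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(fmap.values, dtype=np.float64),
                          fmap.default_affine())
    img.header.set_zooms(tuple(fmap.voxel_size))
    nib.save(img, str(path))


def _wrap(phase):
    """Wrap to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phase, dtype=np.float64)))


def fieldmap_from_double_echo(phase_short: FieldMap, phase_long: FieldMap,
                              te_short: float, te_long: float,
                              unwrap: bool = True) -> FieldMap:
    """Estimate an off-resonance map (Hz) from a double-echo phase pair.

    The wrapped phase difference is divided by ``2*pi*(te_long - te_short)``;
    the difference is spatially unwrapped first (quality-guided unwrapping,
    restricted to the mask when present) so that fields beyond the
    ``+-1/(2*dTE)`` ambiguity range are recovered up to a global offset. The
    global 2*pi multiple is fixed by agreement with the wrapped difference.
    """
    if te_long <= te_short:
        raise ValueError("te_long must exceed te_short")
    if not phase_short.same_geometry(phase_long):
        raise ValueError("phase volumes have mismatched geometry")
    dte = te_long - te_short
    dphi = _wrap(phase_long.values - phase_short.values)
    mask = phase_short.mask
    if mask is None and phase_long.mask is not None:
        mask = phase_long.mask
    if unwrap:
        if mask is not None:
            arr = np.ma.array(dphi, mask=~mask)
            unwrapped = np.ma.filled(unwrap_phase(arr), 0.0)
        else:
            unwrapped = unwrap_phase(dphi)
        # pin the global 2*pi multiple to the wrapped difference
        sel = mask if mask is not None else np.ones_like(dphi, bool)
        offset = np.median(unwrapped[sel] - dphi[sel])
        unwrapped = unwrapped - 2.0 * np.pi * np.round(offset / (2.0 * np.pi))
        dphi = unwrapped
    values = dphi / (2.0 * np.pi * dte)
    return replace(phase_short, values=values, mask=mask)


def gradient_field(fmap: FieldMap, erode_mask: bool = False) -> GradientField:
    """Numerically differentiate a field map into a gradient field (uT/m).

    Central differences on interior voxels and one-sided differences at the
    edges, aware of the (possibly anisotropic) voxel spacing. The Hz/m
    derivative is converted to uT/m via division by gamma/2*pi. Components
    are returned in the scanner RAS frame using the map's axis codes.

    With ``erode_mask=True`` the output mask is eroded by one voxel so that
    one-sided boundary estimates are excluded from downstream statistics.
    """
    if min(fmap.shape) < 2:
        raise ValueError("cannot differentiate along a singleton dimension")
    spacing_m = fmap.voxel_size * 1e-3
    derivs = np.gradient(fmap.values, *spacing_m)  # Hz/m along lattice axes
    comps = [None, None, None]
    for lat, code in enumerate(fmap.axes):
        ras, sgn = _AXCODE_TO_RAS[code]
        comps[ras] = sgn * constants.hz_per_m_to_ut_per_m(derivs[lat])
    mask = fmap.mask
    if mask is not None and erode_mask:
        from scipy.ndimage import binary_erosion
        mask = binary_erosion(mask)
    return GradientField(gx=comps[0], gy=comps[1], gz=comps[2],
                         voxel_size=fmap.voxel_size.copy(), axes=fmap.axes,
                         mask=None if mask is None else mask.copy(),
                         affine=None if fmap.affine is None
                         else fmap.affine.copy())


def average_maps(maps: Sequence):
    """Voxel-wise arithmetic mean of co-registered maps (same type).

    The output mask is the intersection of input masks; voxels where any
    input is non-finite are excluded (set to NaN outside the mask).
    """
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one map")
    first = maps[0]
    for m in maps[1:]:
        if not first.same_geometry(m):
            raise ValueError("geometry mismatch between maps")

    def _mean(arrays):
        stack = np.stack(arrays)
        finite = np.all(np.isfinite(stack), axis=0)
        out = np.full(stack.shape[1:], np.nan)
        out[finite] = stack[:, finite].mean(axis=0)
        return out, finite

    masks = [m.mask for m in maps if m.mask is not None]
    inter = None
    if masks:
        inter = np.logical_and.reduce(masks)

    if isinstance(first, GradientField):
        gx, fx = _mean([m.gx for m in maps])
        gy, fy = _mean([m.gy for m in maps])
        gz, fz = _mean([m.gz for m in maps])
        finite = fx & fy & fz
        mask = finite if inter is None else (inter & finite)
        return replace(first, gx=gx, gy=gy, gz=gz, mask=mask)
    values, finite = _mean([m.values for m in maps])
    mask = finite if inter is None else (inter & finite)
    return replace(first, values=values, mask=mask)
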