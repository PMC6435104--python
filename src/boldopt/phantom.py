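"""Synthetic field-map phantoms and forward-simulated EPI data.

The phantom emulates the inhomogeneity structure of a head in a uniform
main field: spherical air cavities superpose external dipole fields

    f(r) = gamma_bar * B0 * (dchi / 3) * (a / r)^3 * (3 cos^2 theta - 1)

(theta measured from the main-field +Z axis), producing susceptibility
gradients on the +-100 uT/m scale above/behind the cavities. The analytic
form makes the numerical gradient operator testable against symbolic
derivatives, which is why sphere superposition is used instead of an FFT
dipole convolution.

A simple per-column EPI forward simulator is included so the experimental
BS estimator can be validated in a closed loop without scanner data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants
from .field_io import FieldMap, GradientField, gradient_field
from .optimizer import ROISet
from .protocol import EPIProtocol, Polarity, effective_readout

__all__ = [
    "Cavity", "PhantomSpec", "dipole_field", "analytic_dipole_gradient",
    "brain_mask", "roi_labels", "make_cohort", "default_head_phantom",
    "simulate_epi",
]


@dataclass(frozen=True)
class Cavity:
    """Spherical air cavity: centre (mm, volume-centred coords), radius (mm),
    susceptibility difference dchi (ppm)."""

    centre: tuple[float, float, float]
    radius: float
    dchi: float = 9.4

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("cavity radius must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic head field map (bit-reproducible given seed)."""

    shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)  # mm
    b0: float = 3.0  # T
    cavities: tuple[Cavity, ...] = ()
    brain_semiaxes: tuple[float, float, float] = (80.0, 95.0, 65.0)  # mm
    brain_centre: tuple[float, float, float] = (0.0, 0.0, 10.0)  # mm
    rois: tuple[tuple[int, str, tuple, float], ...] = ()
    # each roi: (label, name, centre mm, radius mm) — spherical ROIs
    #: tissue does not extend right up to an air cavity; the brain mask
    #: excludes a shell of this thickness (mm) around each cavity, which
    #: caps the in-mask gradient magnitude at a realistic scale
    cavity_standoff: float = 18.0
    noise_sd: float = 0.0  # Hz
    seed: int = 0

    def __post_init__(self):
        half = [(n - 1) / 2.0 * d
                for n, d in zip(self.shape, self.voxel_size)]
        for cav in self.cavities:
            if any(abs(c) + cav.radius > h
                   for c, h in zip(cav.centre, half)):
                raise ValueError(f"cavity {cav} extends outside the volume")


def _coords(spec: PhantomSpec):
    """Volume-centred physical coordinates (mm) of every voxel."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * d
            for n, d in zip(spec.shape, spec.voxel_size)]
    return np.meshgrid(*axes, indexing="ij")


def _single_dipole(x, y, z, cav: Cavity, b0: float):
    """External dipole field of one cavity, Hz; uniform (0) inside."""
    dx, dy, dz = x - cav.centre[0], y - cav.centre[1], z - cav.centre[2]
    r2 = dx * dx + dy * dy + dz * dz
    a2 = cav.radius ** 2
    inside = r2 < a2
    r2s = np.where(inside, a2, r2)
    cos2 = dz * dz / r2s
    amp = constants.GAMMA_BAR * b0 * (cav.dchi * 1e-6) / 3.0
    f = amp * (a2 / r2s) ** 1.5 * (3.0 * cos2 - 1.0)
    return np.where(inside, 0.0, f)


def dipole_field(spec: PhantomSpec) -> FieldMap:
    """Off-resonance map (Hz) from superposed cavity dipole fields.

    Overlapping cavities raise a warning; their fields simply superpose.
    Optional Gaussian noise (``noise_sd`` Hz) is seeded from ``spec.seed``.
    """
    for i, a in enumerate(spec.cavities):
        for b in spec.cavities[i + 1:]:
            d = np.linalg.norm(np.subtract(a.centre, b.centre))
            if d < a.radius + b.radius:
                warnings.warn("overlapping cavities: fields superpose",
                              stacklevel=2)
    x, y, z = _coords(spec)
    f = np.zeros(spec.shape)
    for cav in spec.cavities:
        f += _single_dipole(x, y, z, cav, spec.b0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return FieldMap(values=f, voxel_size=np.asarray(spec.voxel_size),
                    mask=brain_mask(spec))


def analytic_dipole_gradient(spec: PhantomSpec, point_mm) -> np.ndarray:
    """Exact spatial gradient (uT/m) of the noise-free dipole field at a
    physical point (mm), summed over cavities. Independent of the numerical
    differentiation path."""
    px, py, pz = (float(v) for v in point_mm)
    grad_hz_per_mm = np.zeros(3)
    for cav in spec.cavities:
        dx, dy, dz = px - cav.centre[0], py - cav.centre[1], pz - cav.centre[2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < cav.radius ** 2:
            continue
        amp = constants.GAMMA_BAR * spec.b0 * (cav.dchi * 1e-6) / 3.0 \
            * cav.radius ** 3
        # f = amp * a^3 * (3 dz^2 - r^2) / r^5 with lengths in mm; gradient
        # components follow from the quotient rule
        r = np.sqrt(r2)
        common = amp / r ** 7
        gx = common * dx * (3.0 * r2 - 15.0 * dz * dz)
        gy = common * dy * (3.0 * r2 - 15.0 * dz * dz)
        gz = common * dz * (9.0 * r2 - 15.0 * dz * dz)
        grad_hz_per_mm += np.array([gx, gy, gz])
    return constants.hz_per_m_to_ut_per_m(grad_hz_per_mm * 1e3)  # /mm -> /m


def brain_mask(spec: PhantomSpec) -> np.ndarray:
    """Ellipsoidal brain mask minus cavity interiors."""
    x, y, z = _coords(spec)
    cx, cy, cz = spec.brain_centre
    ax, ay, az = spec.brain_semiaxes
    mask = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 \
        + ((z - cz) / az) ** 2 <= 1.0
    for cav in spec.cavities:
        dx, dy, dz = x - cav.centre[0], y - cav.centre[1], z - cav.centre[2]
        excl = cav.radius + spec.cavity_standoff
        mask &= dx * dx + dy * dy + dz * dz > excl ** 2
    return mask


def roi_labels(spec: PhantomSpec) -> ROISet:
    """Label volume from the spec's spherical ROI definitions."""
    x, y, z = _coords(spec)
    labels = np.zeros(spec.shape, dtype=np.int32)
    names = {}
    mask = brain_mask(spec)
    for label, name, centre, radius in spec.rois:
        dx, dy, dz = x - centre[0], y - centre[1], z - centre[2]
        sel = (dx * dx + dy * dy + dz * dz <= radius ** 2) & mask
        if labels[sel].any():
            raise ValueError(f"ROI {name} overlaps an earlier ROI")
        labels[sel] = label
        names[label] = name
    return ROISet(labels=labels, names=names)


def make_cohort(spec: PhantomSpec, n_subjects: int,
                jitter: float = 0.05) -> list[FieldMap]:
    """Generate co-registered subject field maps by jittering cavities.

    Cavity centres are perturbed by ``jitter * radius`` (sd, mm) and radii
    by a factor ``1 + jitter * N(0,1)``; perturbations are drawn from
    independent per-subject streams spawned from ``spec.seed``, so a fixed
    seed yields a bit-identical cohort.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    out = []
    seeds = np.random.SeedSequence(spec.seed).spawn(n_subjects)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        cavs = []
        for cav in spec.cavities:
            centre = tuple(c + jitter * cav.radius * rng.standard_normal()
                           for c in cav.centre)
            radius = cav.radius * float(
                np.clip(1.0 + jitter * rng.standard_normal(), 0.5, 1.5))
            cavs.append(Cavity(centre=centre, radius=radius, dchi=cav.dchi))
        sub = replace(spec, cavities=tuple(cavs),
                      seed=int(rng.integers(2 ** 31)))
        fmap = dipole_field(sub)
        # cohort maps share the parent geometry/mask (co-registered)
        fmap.mask = brain_mask(spec) if spec.cavities else fmap.mask
        out.append(fmap)
    return out


def default_head_phantom() -> PhantomSpec:
    """64 x 64 x 48 lattice at 3 mm with four air cavities (two
    inferior-anterior, two inferior-lateral, mirror-symmetric in X) and five
    labelled ROIs near them. Peak in-mask gradient magnitude lands on the
    ~100 uT/m scale."""
    cavities = (
        # frontal-sinus-like, anterior-inferior
        Cavity(centre=(-12.0, 72.0, -48.0), radius=11.0),
        Cavity(centre=(12.0, 72.0, -48.0), radius=11.0),
        # ear-canal-like, lateral-inferior
        Cavity(centre=(-66.0, -9.0, -42.0), radius=13.0),
        Cavity(centre=(66.0, -9.0, -42.0), radius=13.0),
    )
    rois = (
        (1, "orbitofrontal", (0.0, 60.0, -24.0), 18.0),
        (2, "temporal-left", (-54.0, -9.0, -18.0), 15.0),
        (3, "temporal-right", (54.0, -9.0, -18.0), 15.0),
        (4, "medial-temporal", (0.0, -21.0, -12.0), 15.0),
        (5, "parietal-control", (0.0, -30.0, 42.0), 18.0),
    )
    return PhantomSpec(cavities=cavities, rois=rois)


def simulate_epi(fmap: FieldMap, protocol: EPIProtocol,
                 polarity: Polarity = Polarity.POSITIVE,
                 pe_axis: int = 1, pe_direction: int = 1,
                 obj: np.ndarray | None = None,
                 attenuation: np.ndarray | None = None):
    """Forward-simulate single-shot EPI magnitude/phase from a field map.

    Each 1D column along ``pe_axis`` is acquired independently: k-space
    line ``k`` is sampled at ``t_k = TE0 + (k - N//2) * dt_eff`` with
    per-voxel off-resonance phase ``2*pi*f*t_k`` and T2* decay, then
    reconstructed by inverse DFT. Echo shifts, geometric distortion and the
    1/q intensity modulation emerge from the acquisition physics rather
    than from the analytic BS model, so this is an independent oracle for
    the experimental-BS estimator.

    The column length must equal the protocol's acquired line count and the
    voxel size along PE must match ``res_pe``. ``obj`` is the proton
    density (defaults to the mask); ``attenuation`` optionally multiplies
    it (e.g. to emulate through-plane dephasing). ``pe_direction`` orients
    the acquisition-frame PE axis relative to increasing lattice index
    (same convention as :func:`boldopt.bs_core.experimental_bs`).

    Returns ``(magnitude, phase)`` float volumes.
    """
    if pe_direction not in (1, -1):
        raise ValueError("pe_direction must be +1 or -1")
    ro = effective_readout(protocol)
    n = fmap.shape[pe_axis]
    if n != ro.acquired_lines:
        raise ValueError(
            f"PE-axis length {n} != acquired line count {ro.acquired_lines}")
    if abs(fmap.voxel_size[pe_axis] * 1e-3 - protocol.res_pe) > 1e-9:
        raise ValueError("PE voxel size does not match protocol res_pe")

    if obj is None:
        obj = (fmap.mask.astype(float) if fmap.mask is not None
               else np.ones(fmap.shape))
    obj = np.asarray(obj, dtype=np.float64)
    if attenuation is not None:
        obj = obj * np.asarray(attenuation, dtype=np.float64)

    f = np.moveaxis(fmap.values, pe_axis, -1).reshape(-1, n)
    m = np.moveaxis(obj, pe_axis, -1).reshape(-1, n)

    k_index = np.arange(n) - n // 2
    t = protocol.te0 + k_index * ro.echo_spacing  # (n,)
    fov = n * protocol.res_pe
    ky = Polarity(polarity).sign * pe_direction * k_index / fov  # cycles/m
    ypos = np.arange(n) * protocol.res_pe

    # encode: S[c, k] = sum_y m exp(2i pi f t_k) exp(-t_k/T2*) exp(-2i pi ky y)
    enc = np.exp(-2j * np.pi * np.outer(ky, ypos))  # (k, y)
    decay = np.exp(-t / protocol.t2star)  # (k,)
    sig = np.empty((f.shape[0], n), dtype=complex)
    chunk = max(1, int(2**22 // (n * n)))  # bound the (chunk, k, y) temporary
    for lo in range(0, f.shape[0], chunk):
        sl = slice(lo, lo + chunk)
        phase_evol = np.exp(2j * np.pi * f[sl, None, :] * t[None, :, None])
        sig[sl] = np.einsum("cy,ky,cky,k->ck", m[sl], enc, phase_evol, decay,
                            optimize=True)
    # reconstruct: I[c, y] = (1/N) sum_k S exp(+2i pi ky y)
    img = sig @ np.conj(enc) / n

    img = np.moveaxis(img.reshape(np.moveaxis(fmap.values, pe_axis, -1).shape),
                      -1, pe_axis)
    return np.abs(img), np.angle(img)
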