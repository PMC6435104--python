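"""The BOLD-sensitivity (BS) physics model.

Given the susceptibility-gradient components of a voxel in the acquisition
frame (RO, PE, SL), the protocol and the adjustable parameters, the model
combines

* an in-plane PE gradient shifting the echo: ``q = 1 -/+ gamma_bar * dt_eff
  * FoV_P * G_PE`` (minus for positive PE polarity), local TE = TE0/q and
  initial intensity scaled by 1/q,
* through-plane dephasing across a Gaussian slice profile:
  ``psi = gamma * dz / C * (G_SL * TE_local + M_shim)`` with attenuation
  ``exp(-psi^2)`` (C defaults to 4*ln 2),
* complete dropout when the shifted echo leaves the acquisition window
  (local TE outside ``TE0 +- TA/2`` or ``q <= 0``) or when the RO k-space
  shift ``|gamma * TE * G_RO|`` exceeds ``pi / dx``.

The relative sensitivity of the unperturbed reference voxel is normalized
to 1, so ``bs_rel = (1/q^2) * exp(-(TE_local - TE0)/T2*) * exp(-psi^2)``
inside the acquisition window and exactly 0 outside.

All functions broadcast over numpy arrays; gradients are in uT/m and the
shim moment in mT/m*ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from . import constants
from .protocol import (AdjustableParams, EPIProtocol, Polarity,
                       effective_readout, REFERENCE_PARAMS)

__all__ = [
    "BSModelConfig", "VoxelBS", "q_factor", "local_echo_time",
    "through_plane_attenuation", "dropout", "voxel_bs", "wellshimmed_loss",
    "max_feasible_zshim", "bs_gain", "ExperimentalBS", "experimental_bs",
    "bs_difference_stats", "DEFAULT_CONFIG",
]

#: Dephasing-term denominator for a Gaussian slice profile, as conventionally
#: printed. The analytic constant for a Gaussian FWHM profile would be
#: 4*sqrt(ln 2); both are supported via ``profile_constant``.
PROFILE_CONSTANT_DEFAULT = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class BSModelConfig:
    """Tunable constants of the physics model."""

    gamma: float = constants.GAMMA
    profile_constant: float = PROFILE_CONSTANT_DEFAULT
    #: TE used in the readout-direction dropout condition: "local" evaluates
    #: it at the PE-shifted echo time, "nominal" at TE0.
    dropout_te_mode: str = "local"

    def __post_init__(self):
        if self.gamma <= 0 or self.profile_constant <= 0:
            raise ValueError("gamma and profile_constant must be positive")
        if self.dropout_te_mode not in ("local", "nominal"):
            raise ValueError("dropout_te_mode must be 'local' or 'nominal'")

    @property
    def gamma_bar(self) -> float:
        return self.gamma / (2.0 * math.pi)


DEFAULT_CONFIG = BSModelConfig()


@dataclass
class VoxelBS:
    """Per-voxel model outputs (arrays broadcast over the inputs)."""

    bs_rel: np.ndarray
    local_te: np.ndarray
    q: np.ndarray
    attenuation_sl: np.ndarray
    dropped: np.ndarray


def q_factor(g_pe, protocol: EPIProtocol, polarity: Polarity,
             config: BSModelConfig = DEFAULT_CONFIG):
    """Echo-shift factor q from a PE susceptibility gradient (uT/m).

    ``q < 1`` (positive polarity, positive gradient) prolongs the local TE;
    ``q <= 0`` signals total echo loss and is handled by the dropout check,
    not raised here.
    """
    ro = effective_readout(protocol)
    g_pe = np.asarray(g_pe, dtype=np.float64)
    shift = config.gamma_bar * ro.echo_spacing * ro.fov_pe * \
        (g_pe * constants.UT_PER_M)
    sign = -1.0 if Polarity(polarity) is Polarity.POSITIVE else 1.0
    return 1.0 + sign * shift


def local_echo_time(q, protocol: EPIProtocol):
    """Local TE = TE0 / q; +inf where the echo is lost (q <= 0)."""
    q = np.asarray(q, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(q > 0, protocol.te0 / np.where(q > 0, q, 1.0), np.inf)
    return te


def through_plane_attenuation(g_sl, zshim_moment, protocol: EPIProtocol,
                              local_te=None,
                              config: BSModelConfig = DEFAULT_CONFIG):
    """Slice-profile dephasing attenuation exp(-psi^2) in [0, 1].

    ``g_sl`` in uT/m, ``zshim_moment`` in mT/m*ms. The gradient-echo-time
    product uses the local (echo-shifted) TE when given, else TE0.
    """
    te = protocol.te0 if local_te is None else np.asarray(local_te)
    g_sl = np.asarray(g_sl, dtype=np.float64)
    net_moment = g_sl * constants.UT_PER_M * te \
        + zshim_moment * constants.MT_PER_M_MS
    psi = config.gamma * protocol.slice_thickness / config.profile_constant \
        * net_moment
    return np.exp(-psi * psi)


def dropout(g_pe, g_ro, protocol: EPIProtocol, polarity: Polarity,
            local_te=None, config: BSModelConfig = DEFAULT_CONFIG):
    """True where the voxel suffers complete signal loss.

    Covers the PE condition (shifted echo outside ``TE0 +- TA/2``,
    including total echo loss ``q <= 0``) and the RO condition
    (``|gamma * TE * G_RO| > pi / dx``).
    """
    ro = effective_readout(protocol)
    q = q_factor(g_pe, protocol, polarity, config)
    if local_te is None:
        local_te = local_echo_time(q, protocol)
    local_te = np.asarray(local_te, dtype=np.float64)
    lo = protocol.te0 - ro.duration / 2.0
    hi = protocol.te0 + ro.duration / 2.0
    pe_drop = (q <= 0) | (local_te < lo) | (local_te > hi)
    if config.dropout_te_mode == "local":
        # voxels with a lost echo (infinite local TE) are dropped by the PE
        # condition already; evaluate the RO condition at TE0 there
        te_ro = np.where(np.isfinite(local_te), local_te, protocol.te0)
    else:
        te_ro = protocol.te0
    kshift = np.abs(config.gamma * te_ro *
                    np.asarray(g_ro, dtype=np.float64) * constants.UT_PER_M)
    ro_drop = kshift > (math.pi / protocol.res_ro)
    return pe_drop | ro_drop


def voxel_bs(g_ro, g_pe, g_sl, protocol: EPIProtocol,
             params: AdjustableParams = REFERENCE_PARAMS,
             config: BSModelConfig = DEFAULT_CONFIG) -> VoxelBS:
    """Relative BOLD sensitivity of voxels with slice-frame gradients (uT/m).

    The reference (zero gradients, zero shim) has ``bs_rel = 1``; dropped
    voxels have ``bs_rel = 0`` exactly.
    """
    q = q_factor(g_pe, protocol, params.pe_polarity, config)
    te_local = local_echo_time(q, protocol)
    dropped = dropout(g_pe, g_ro, protocol, params.pe_polarity,
                      local_te=te_local, config=config)
    att = through_plane_attenuation(g_sl, params.zshim_moment, protocol,
                                    local_te=np.where(np.isfinite(te_local),
                                                      te_local, protocol.te0),
                                    config=config)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        qsafe = np.where(q > 0, q, 1.0)
        decay = np.exp(-(np.where(np.isfinite(te_local), te_local,
                                  protocol.te0) - protocol.te0)
                       / protocol.t2star)
        bs = (1.0 / (qsafe * qsafe)) * decay * att
    bs = np.where(dropped, 0.0, bs)
    return VoxelBS(bs_rel=bs, local_te=te_local, q=q, attenuation_sl=att,
                   dropped=dropped)


def wellshimmed_loss(params: AdjustableParams, protocol: EPIProtocol,
                     config: BSModelConfig = DEFAULT_CONFIG) -> float:
    """Fractional BS loss in gradient-free (well-shimmed) tissue.

    Only the z-shim moment contributes; tilt and polarity leave a
    zero-gradient voxel untouched.
    """
    ref = voxel_bs(0.0, 0.0, 0.0, protocol, params, config)
    return float(1.0 - ref.bs_rel)


def max_feasible_zshim(protocol: EPIProtocol,
                       config: BSModelConfig = DEFAULT_CONFIG,
                       max_loss: float = 0.15) -> float:
    """Largest |z-shim moment| (mT/m*ms) with well-shimmed loss <= max_loss."""
    psi_max = math.sqrt(-math.log(1.0 - max_loss))
    c = config.gamma * protocol.slice_thickness / config.profile_constant
    return psi_max / c / constants.MT_PER_M_MS


def bs_gain(bs, bs_ref):
    """Symmetric percent gain ``200 * (bs - bs_ref) / (bs + bs_ref)``.

    Bounded in [-200, 200] for non-negative inputs; NaN where both are 0.
    """
    bs = np.asarray(bs, dtype=np.float64)
    bs_ref = np.asarray(bs_ref, dtype=np.float64)
    denom = bs + bs_ref
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = 200.0 * (bs - bs_ref) / denom
    # rounding can overshoot the analytic bound by one ulp
    gain = np.clip(gain, -200.0, 200.0)
    gain = np.where(denom > 0, gain, np.nan)
    if gain.ndim == 0:
        return float(gain)
    return gain


@dataclass
class ExperimentalBS:
    """BS map measured from complex EPI data."""

    bs: np.ndarray
    local_te: np.ndarray
    echo_shift_lines: np.ndarray


def experimental_bs(magnitude, phase, protocol: EPIProtocol,
                    polarity: Polarity = Polarity.POSITIVE,
                    pe_axis: int = 1, pe_direction: int = 1) -> ExperimentalBS:
    """Measure BS = local TE * I from magnitude/phase EPI volumes.

    The local TE is recovered from the wrapped phase difference between
    adjacent voxels along the PE axis: an echo shifted by ``n`` lines in a
    readout of ``N_acq`` acquired lines produces an image phase ramp of
    ``2*pi*n/N_acq`` per PE voxel, so ``n = dphi * N_acq / (2*pi)`` (sign
    flipped for negative polarity) and
    ``TE_local = TE0 + n * dt_eff``. Voxels with a non-positive recovered
    TE are reported as NaN.

    ``pe_direction`` is the orientation of the acquisition-frame PE axis
    relative to increasing lattice index along ``pe_axis`` (+1 or -1; for a
    transverse acquisition stored RAS it is -1, since PE runs
    anterior -> posterior).
    """
    if pe_direction not in (1, -1):
        raise ValueError("pe_direction must be +1 or -1")
    magnitude = np.asarray(magnitude, dtype=np.float64)
    phase = np.asarray(phase, dtype=np.float64)
    if magnitude.shape != phase.shape:
        raise ValueError("magnitude/phase shape mismatch")
    if not (-magnitude.ndim <= pe_axis < magnitude.ndim):
        raise ValueError(f"pe_axis {pe_axis} outside array dimensions")
    cplx = magnitude * np.exp(1j * phase)
    fwd = np.roll(cplx, -1, axis=pe_axis)
    dphi = np.angle(fwd * np.conj(cplx))
    # the wrap-around difference at the last voxel is meaningless; reuse the
    # previous interior difference (one-sided estimate at the edge)
    last = [slice(None)] * dphi.ndim
    prev = [slice(None)] * dphi.ndim
    last[pe_axis] = -1
    prev[pe_axis] = -2
    dphi[tuple(last)] = dphi[tuple(prev)]
    ro = effective_readout(protocol)
    sign = Polarity(polarity).sign * pe_direction
    n = sign * dphi * ro.acquired_lines / (2.0 * np.pi)
    local_te = protocol.te0 + n * ro.echo_spacing
    local_te = np.where(local_te > 0, local_te, np.nan)
    return ExperimentalBS(bs=local_te * magnitude, local_te=local_te,
                          echo_shift_lines=n)


def bs_difference_stats(sim_gain, exp_gain, mask):
    """Mean and standard deviation of sim - exp gain within a mask.

    Returns ``(mean, sd, differences)`` where the last element is the 1D
    vector of voxel-wise differences (for histogram export). Non-finite
    voxels are excluded.
    """
    sim_gain = np.asarray(sim_gain, dtype=np.float64)
    exp_gain = np.asarray(exp_gain, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if sim_gain.shape != exp_gain.shape or sim_gain.shape != mask.shape:
        raise ValueError("map/mask shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    diff = sim_gain[mask] - exp_gain[mask]
    diff = diff[np.isfinite(diff)]
    if diff.size == 0:
        raise ValueError("no finite differences inside mask")
    return float(diff.mean()), float(diff.std(ddof=0)), diff
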