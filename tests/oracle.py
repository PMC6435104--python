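"""Independent brute-force re-implementation of the BS grid search.

Used as the equivalence oracle for the vectorized optimizer: plain Python
triple loops, ``math``-module scalar arithmetic, and explicitly written-out
rotation formulas (no shared code path with the package internals beyond
the protocol container and the documented conventions).
"""

import math

from boldopt import constants
from boldopt.protocol import effective_readout


def project_oracle(gx, gy, gz, orientation, tilt_deg):
    """Slice-frame components from the documented frame conventions.

    transverse: e_RO=+X, untilted e_PE=-Y, e_SL=+Z; tilt rotates (PE, SL)
    about +X by -tilt. sagittal: e_RO=+Z, e_PE=-Y, e_SL=+X; tilt rotates
    (RO, PE) about +X by -tilt. coronal: e_RO=+X, e_PE=+Z, e_SL=+Y; tilt
    rotates (PE, SL) about +X by -tilt.
    """
    a = math.radians(tilt_deg)
    c, s = math.cos(a), math.sin(a)
    if orientation == "transverse":
        # e_PE = (0, -c, s), e_SL = (0, s, c), e_RO = (1, 0, 0)
        return gx, -gy * c + gz * s, gy * s + gz * c
    if orientation == "sagittal":
        # rotation about e_SL=+X by -a: e_RO = (0, s, c), e_PE = (0, -c, s)
        return gy * s + gz * c, -gy * c + gz * s, gx
    if orientation == "coronal":
        # rotation about e_RO=+X by -a: e_PE = R @ (0,0,1) = (0, s, c),
        # e_SL = R @ (0,1,0) = (0, c, -s)
        return gx, gy * s + gz * c, gy * c - gz * s
    raise ValueError(orientation)


def bs_oracle(g_ro, g_pe, g_sl, protocol, zshim, positive, config):
    """Scalar BS evaluation mirroring the published model term by term."""
    ro = effective_readout(protocol)
    shift = (config.gamma / (2 * math.pi)) * ro.echo_spacing * ro.fov_pe \
        * g_pe * 1e-6
    q = 1.0 - shift if positive else 1.0 + shift
    if q <= 0:
        return 0.0
    te = protocol.te0 / q
    if te < protocol.te0 - ro.duration / 2 or \
            te > protocol.te0 + ro.duration / 2:
        return 0.0
    te_ro = te if config.dropout_te_mode == "local" else protocol.te0
    if abs(config.gamma * te_ro * g_ro * 1e-6) > math.pi / protocol.res_ro:
        return 0.0
    psi = config.gamma * protocol.slice_thickness / config.profile_constant \
        * (g_sl * 1e-6 * te + zshim * 1e-6)
    return (1.0 / (q * q)) * math.exp(-(te - protocol.te0)
                                      / protocol.t2star) \
        * math.exp(-psi * psi)


def wellshimmed_loss_oracle(zshim, protocol, config):
    return 1.0 - bs_oracle(0.0, 0.0, 0.0, protocol, zshim, True, config)


def ordered_feasible(grid, protocol, config, max_loss=0.15):
    sets = [(z, t, pol)
            for pol in ("positive", "negative")
            for t in grid.tilt_values
            for z in grid.zshim_values
            if wellshimmed_loss_oracle(z, protocol, config) <= max_loss]
    sets.sort(key=lambda s: (abs(s[0]), s[0] < 0, abs(s[1]), s[1] < 0,
                             s[2] != "positive"))
    return sets


def optimize_voxel_oracle(gx, gy, gz, protocol, grid, config):
    """Exhaustive argmax for a single voxel; returns (z, tilt, pol, bs)."""
    orientation = protocol.orientation.value
    best = (None, -math.inf)
    for z, t, pol in ordered_feasible(grid, protocol, config):
        g_ro, g_pe, g_sl = project_oracle(gx, gy, gz, orientation, t)
        bs = bs_oracle(g_ro, g_pe, g_sl, protocol, z, pol == "positive",
                       config)
        if bs > best[1]:
            best = ((z, t, pol), bs)
    return best


def optimize_roi_oracle(voxels, protocol, grid, config):
    """Exhaustive argmax of the mean BS over a list of (gx, gy, gz)."""
    orientation = protocol.orientation.value
    best = (None, -math.inf)
    for z, t, pol in ordered_feasible(grid, protocol, config):
        total = 0.0
        for gx, gy, gz in voxels:
            g_ro, g_pe, g_sl = project_oracle(gx, gy, gz, orientation, t)
            total += bs_oracle(g_ro, g_pe, g_sl, protocol, z,
                               pol == "positive", config)
        mean = total / len(voxels)
        if mean > best[1]:
            best = ((z, t, pol), mean)
    return best
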