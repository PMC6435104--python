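"""EPI acquisition protocols, adjustable parameters and the search grid.

The protocol holds the fixed acquisition settings (echo time, echo spacing,
matrix, resolution, slice thickness, parallel-imaging factor, assumed T2*);
the adjustable parameters are the three quantities the optimizer searches
over: z-shim gradient moment, slice tilt / in-plane rotation, and the
polarity of the phase-encode gradient.

All stored quantities are SI (seconds, metres); config files use the
conventional units ms / mm / mT/m*ms / degrees and are converted on parse.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Orientation",
    "Polarity",
    "EPIProtocol",
    "AdjustableParams",
    "ParameterGrid",
    "EffectiveReadout",
    "effective_readout",
    "build_grid",
    "default_grid",
    "get_preset",
    "protocol_from_config",
    "grid_from_config",
    "PRESETS",
    "REFERENCE_PARAMS",
]


class Orientation(str, enum.Enum):
    TRANSVERSE = "transverse"
    SAGITTAL = "sagittal"
    CORONAL = "coronal"


class Polarity(str, enum.Enum):
    """Sign of the phase-encode prewinder moment."""

    POSITIVE = "positive"
    NEGATIVE = "negative"

    @property
    def sign(self) -> int:
        return 1 if self is Polarity.POSITIVE else -1


def _as_orientation(value) -> Orientation:
    if isinstance(value, Orientation):
        return value
    return Orientation(str(value).lower())


def _as_polarity(value) -> Polarity:
    if isinstance(value, Polarity):
        return value
    s = str(value).lower()
    if s in ("positive", "pos", "+", "1", "+1"):
        return Polarity.POSITIVE
    if s in ("negative", "neg", "-", "-1"):
        return Polarity.NEGATIVE
    raise ValueError(f"unknown PE polarity: {value!r}")


@dataclass(frozen=True)
class EPIProtocol:
    """Fixed 2D gradient-echo EPI acquisition parameters (SI units).

    Parameters
    ----------
    te0 : float
        Nominal echo time, s.
    echo_spacing : float
        Inter-echo spacing of the EPI readout train, s.
    matrix_pe, matrix_ro : int
        Base matrix size along phase-encode / readout.
    res_pe, res_ro : float
        In-plane resolution along PE / RO, m.
    slice_thickness : float
        Nominal slice thickness, m.
    orientation : Orientation
        Principal slice orientation.
    grappa_factor : int
        Parallel-imaging acceleration factor (>= 1).
    pe_oversampling : float
        Phase oversampling fraction (0.15625 means 15.625 % extra lines).
    t2star : float
        Assumed effective transverse relaxation time, s.
    fov_pe : float or None
        Acquired field of view along PE, m. Derived from matrix, resolution
        and oversampling when omitted.
    """

    te0: float
    echo_spacing: float
    matrix_pe: int
    matrix_ro: int
    res_pe: float
    res_ro: float
    slice_thickness: float
    orientation: Orientation = Orientation.TRANSVERSE
    grappa_factor: int = 1
    pe_oversampling: float = 0.0
    t2star: float = 0.050
    fov_pe: float | None = None
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "orientation", _as_orientation(self.orientation))
        for attr in ("te0", "echo_spacing", "res_pe", "res_ro",
                     "slice_thickness", "t2star"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{attr} must be strictly positive")
        if self.matrix_pe < 1 or self.matrix_ro < 1:
            raise ValueError("matrix sizes must be positive integers")
        if int(self.grappa_factor) != self.grappa_factor or self.grappa_factor < 1:
            raise ValueError("grappa_factor must be an integer >= 1")
        if self.pe_oversampling < 0:
            raise ValueError("pe_oversampling must be >= 0")
        acquired = round(self.matrix_pe * (1.0 + self.pe_oversampling))
        if self.fov_pe is not None:
            # fov must match the acquired line count within line rounding
            if abs(self.fov_pe / self.res_pe - acquired) > 1.0 + 1e-9:
                raise ValueError(
                    "fov_pe inconsistent with matrix_pe, res_pe and "
                    "pe_oversampling")


@dataclass(frozen=True)
class EffectiveReadout:
    """Readout quantities derived from an :class:`EPIProtocol`."""

    acquired_lines: int
    echo_spacing: float  # effective, s (base spacing / GRAPPA factor)
    duration: float      # acquisition duration TA, s
    fov_pe: float        # acquired field of view along PE, m


def effective_readout(protocol: EPIProtocol) -> EffectiveReadout:
    """Derive acquired line count, effective echo spacing, TA and FoV_P.

    GRAPPA acceleration R is modelled as an effective echo spacing of
    ``echo_spacing / R`` (the acquisition window shrinks by R); phase
    oversampling increases both the acquired line count and the acquired
    field of view.
    """
    acquired = int(round(protocol.matrix_pe * (1.0 + protocol.pe_oversampling)))
    dt_eff = protocol.echo_spacing / protocol.grappa_factor
    ta = acquired * dt_eff
    fov = protocol.fov_pe if protocol.fov_pe is not None \
        else acquired * protocol.res_pe
    if acquired <= 0 or dt_eff <= 0 or ta <= 0 or fov <= 0:
        raise ValueError("malformed protocol: non-positive derived quantity")
    return EffectiveReadout(acquired_lines=acquired, echo_spacing=dt_eff,
                            duration=ta, fov_pe=fov)


@dataclass(frozen=True, order=True)
class AdjustableParams:
    """The optimization variables: z-shim moment, tilt and PE polarity.

    ``zshim_moment`` is the slice-direction compensation gradient moment in
    mT/m*ms; ``tilt_deg`` is the slice angulation (transverse/coronal) or
    in-plane rotation (sagittal) in degrees.
    """

    zshim_moment: float = 0.0
    tilt_deg: float = 0.0
    pe_polarity: Polarity = Polarity.POSITIVE

    def __post_init__(self):
        object.__setattr__(self, "pe_polarity", _as_polarity(self.pe_polarity))


#: The reference parameter set: no shim, no tilt, positive PE gradient.
REFERENCE_PARAMS = AdjustableParams(0.0, 0.0, Polarity.POSITIVE)


def _inclusive_range(lo: float, hi: float, step: float) -> tuple[float, ...]:
    if step <= 0:
        raise ValueError("step must be positive")
    if hi < lo:
        raise ValueError("max must be >= min")
    if step > hi - lo and hi != lo:
        raise ValueError("step larger than range")
    n = int(round((hi - lo) / step)) + 1
    vals = tuple(round(lo + i * step, 12) for i in range(n))
    return vals


@dataclass(frozen=True)
class ParameterGrid:
    """Ordered axes of the exhaustive search over adjustable parameters."""

    zshim_values: tuple[float, ...]
    tilt_values: tuple[float, ...]
    polarities: tuple[Polarity, ...] = (Polarity.POSITIVE, Polarity.NEGATIVE)

    def __post_init__(self):
        z = tuple(float(v) for v in self.zshim_values)
        t = tuple(float(v) for v in self.tilt_values)
        p = tuple(_as_polarity(v) for v in self.polarities)
        if not z or not t or not p:
            raise ValueError("grid axes must be non-empty")
        if any(b <= a for a, b in zip(z, z[1:])) or \
           any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("numeric grid axes must be strictly increasing")
        if 0.0 not in z or 0.0 not in t or Polarity.POSITIVE not in p:
            raise ValueError(
                "grid must contain the reference point (0 shim, 0 tilt, "
                "positive polarity)")
        object.__setattr__(self, "zshim_values", z)
        object.__setattr__(self, "tilt_values", t)
        object.__setattr__(self, "polarities", p)

    def __len__(self) -> int:
        return len(self.zshim_values) * len(self.tilt_values) * len(self.polarities)

    def __iter__(self):
        for pol in self.polarities:
            for tilt in self.tilt_values:
                for z in self.zshim_values:
                    yield AdjustableParams(z, tilt, pol)


def build_grid(zshim=(-5.0, 5.0, 0.5), tilt=(-45.0, 45.0, 5.0),
               polarities=("positive", "negative")) -> ParameterGrid:
    """Build an inclusive-endpoint grid from (min, max, step) axis specs.

    Defaults reproduce the reference search space: z-shim -5..5 mT/m*ms in
    steps of 0.5, tilt -45..45 degrees in steps of 5, both PE polarities.
    """
    zlo, zhi, zstep = zshim
    tlo, thi, tstep = tilt
    if not (zlo <= 0.0 <= zhi) or not (tlo <= 0.0 <= thi):
        raise ValueError("grid axes must bracket 0 (the reference point)")
    return ParameterGrid(
        zshim_values=_inclusive_range(zlo, zhi, zstep),
        tilt_values=_inclusive_range(tlo, thi, tstep),
        polarities=tuple(_as_polarity(p) for p in polarities),
    )


def default_grid() -> ParameterGrid:
    return build_grid()


# Reference protocols. "standard": 3 mm isotropic, 64 matrix; "highres":
# 2 mm isotropic, 96 matrix; "grappa2": highres with GRAPPA factor 2.
# "invivo" is the validation variant of "standard" with 74 acquired lines
# (nominally 13 % phase oversampling; 74/64 - 1 = 0.15625 reproduces the
# stated acquired-line count).
PRESETS: Mapping[str, EPIProtocol] = {
    "standard": EPIProtocol(
        name="standard", te0=0.030, echo_spacing=0.5e-3,
        matrix_pe=64, matrix_ro=64, res_pe=3e-3, res_ro=3e-3,
        slice_thickness=3e-3),
    "highres": EPIProtocol(
        name="highres", te0=0.030, echo_spacing=0.78e-3,
        matrix_pe=96, matrix_ro=96, res_pe=2e-3, res_ro=2e-3,
        slice_thickness=2e-3),
    "grappa2": EPIProtocol(
        name="grappa2", te0=0.030, echo_spacing=0.78e-3,
        matrix_pe=96, matrix_ro=96, res_pe=2e-3, res_ro=2e-3,
        slice_thickness=2e-3, grappa_factor=2),
    "invivo": EPIProtocol(
        name="invivo", te0=0.030, echo_spacing=0.5e-3,
        matrix_pe=64, matrix_ro=64, res_pe=3e-3, res_ro=3e-3,
        slice_thickness=3e-3, pe_oversampling=10.0 / 64.0),
    "comparison": EPIProtocol(
        name="comparison", te0=0.030, echo_spacing=0.33e-3,
        matrix_pe=64, matrix_ro=64, res_pe=3e-3, res_ro=3e-3,
        slice_thickness=2e-3),
}


def get_preset(name: str, orientation=None) -> EPIProtocol:
    try:
        proto = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol preset {name!r}; available: "
            f"{sorted(PRESETS)}") from None
    if orientation is not None:
        proto = replace(proto, orientation=_as_orientation(orientation))
    return proto


_MS = 1e-3
_MM = 1e-3


def protocol_from_config(source) -> EPIProtocol:
    """Read a protocol from a YAML/plain ``key: value`` config.

    Expected keys (units): ``te0_ms``, ``echo_spacing_ms``, ``matrix_pe``,
    ``matrix_ro``, ``res_pe_mm``, ``res_ro_mm``, ``slice_thickness_mm``,
    optional ``orientation``, ``grappa_factor``, ``pe_oversampling``,
    ``t2star_ms``, ``fov_pe_mm``, ``preset``. Protocols declaring partial
    Fourier are rejected: the dropout model assumes symmetric k-space
    sampling.
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, Mapping):
            raise ValueError(f"protocol config {source} is not a mapping")
        cfg = dict(cfg)

    pf = cfg.pop("partial_fourier", None)
    if pf not in (None, 1, 1.0, "off", "none", False):
        raise ValueError(
            "partial Fourier is not supported: the signal-dropout condition "
            "assumes symmetric k-space sampling")

    if "preset" in cfg:
        proto = get_preset(cfg.pop("preset"), cfg.pop("orientation", None))
        if cfg:
            raise ValueError(f"unexpected keys with preset: {sorted(cfg)}")
        return proto

    kwargs = dict(
        te0=float(cfg.pop("te0_ms")) * _MS,
        echo_spacing=float(cfg.pop("echo_spacing_ms")) * _MS,
        matrix_pe=int(cfg.pop("matrix_pe")),
        matrix_ro=int(cfg.pop("matrix_ro")),
        res_pe=float(cfg.pop("res_pe_mm")) * _MM,
        res_ro=float(cfg.pop("res_ro_mm")) * _MM,
        slice_thickness=float(cfg.pop("slice_thickness_mm")) * _MM,
    )
    if "orientation" in cfg:
        kwargs["orientation"] = cfg.pop("orientation")
    if "grappa_factor" in cfg:
        kwargs["grappa_factor"] = int(cfg.pop("grappa_factor"))
    if "pe_oversampling" in cfg:
        kwargs["pe_oversampling"] = float(cfg.pop("pe_oversampling"))
    if "t2star_ms" in cfg:
        kwargs["t2star"] = float(cfg.pop("t2star_ms")) * _MS
    if "fov_pe_mm" in cfg:
        kwargs["fov_pe"] = float(cfg.pop("fov_pe_mm")) * _MM
    if "name" in cfg:
        kwargs["name"] = str(cfg.pop("name"))
    if cfg:
        raise ValueError(f"unknown protocol config keys: {sorted(cfg)}")
    return EPIProtocol(**kwargs)


def grid_from_config(source) -> ParameterGrid:
    """Read a grid from a mapping / YAML file with keys
    ``zshim: [min, max, step]`` (mT/m*ms), ``tilt: [min, max, step]``
    (degrees) and optional ``polarities``."""
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        with open(source) as fh:
            cfg = dict(yaml.safe_load(fh))
    kwargs = {}
    if "zshim" in cfg:
        kwargs["zshim"] = tuple(float(v) for v in cfg.pop("zshim"))
    if "tilt" in cfg:
        kwargs["tilt"] = tuple(float(v) for v in cfg.pop("tilt"))
    if "polarities" in cfg:
        kwargs["polarities"] = tuple(cfg.pop("polarities"))
    if cfg:
        raise ValueError(f"unknown grid config keys: {sorted(cfg)}")
    return build_grid(**kwargs)
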