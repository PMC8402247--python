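"""Static mechanics of a brachial artery segment under a pressure cuff.

The artery under the cuff is described by a transmural-pressure-dependent
cross-sectional area

    A(Ptm) = d * ln(a*Ptm + 3.3) / (1 + exp(-c*Ptm))      [cm^2]

where ``Ptm = Part - Pcuff`` is the pressure across the wall, ``a`` sets the
collapse point (the log argument reaches zero at Ptm = -3.3/a), ``c`` the
sigmoid steepness of the open-to-collapsed transition and ``d`` the absolute
area scale.  From the area follow radius, Poiseuille flow resistance over the
occluded segment, segment volume/compliance and the Bramwell-Hill pulse wave
velocity.

Internal units are mmHg, s, cm and mL (1 cm^3 == 1 mL); PWV is returned in
m/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CollapseParams",
    "transmural",
    "artery_area",
    "artery_radius",
    "brachial_resistance",
    "artery_volume",
    "artery_compliance",
    "pwv",
    "OCCLUDED_RESISTANCE",
]

#: conversion factor: 1 mmHg = 1333.22 dyn/cm^2 = 1333.22 g cm^-1 s^-2
MMHG_TO_CGS = 1333.22

#: sentinel flow resistance for a fully collapsed segment (mmHg*s/mL).
#: Numerically indistinguishable from full occlusion at physiologic
#: pressure gradients (flow < 1e-4 mL/s) while keeping the ODE integrable.
OCCLUDED_RESISTANCE = 1.0e6


@dataclass(frozen=True)
class CollapseParams:
    """Collapse-law parameters plus geometric and fluid constants.

    Parameters
    ----------
    a : float
        Collapse shape factor inside the logarithm (1/mmHg).  The area
        reaches zero at ``Ptm = (1 - offset_const)/a``.
    c : float
        Sigmoid steepness of the collapse transition (1/mmHg).
    d : float
        Area scale (cm^2).  Chosen by default so the fully open radius at
        Ptm = 100 mmHg is ~0.22 cm, mid-range of ultrasound measurements
        of the brachial artery.
    cuff_length : float
        Length of the occluded segment L (cm).
    viscosity : float
        Blood viscosity eta (mmHg*s); default 3.2e-5 mmHg*s (~4.3 mPa*s).
    blood_density : float
        rho (g/cm^3), default 1.06.
    """

    a: float = 0.03
    c: float = 0.1
    d: float = field(default=0.0826)
    offset_const: float = field(default=3.3, init=True)
    cuff_length: float = 10.0
    viscosity: float = 3.2e-5
    blood_density: float = 1.06

    def __post_init__(self) -> None:
        for name in ("a", "c", "d", "cuff_length", "viscosity", "blood_density"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"CollapseParams.{name} must be finite and > 0, got {v!r}")

    @property
    def ptm_collapse(self) -> float:
        """Transmural pressure below which the area is zero (log arg <= 1)."""
        return (1.0 - self.offset_const) / self.a

    @property
    def ptm_domain_edge(self) -> float:
        """Transmural pressure at which the log argument reaches zero."""
        return -self.offset_const / self.a

    @classmethod
    def with_open_radius(cls, r_open: float = 0.22, ptm_open: float = 100.0,
                         **kwargs) -> "CollapseParams":
        """Build params with ``d`` scaled so the radius at ``ptm_open`` is ``r_open`` cm."""
        base = cls(d=1.0, **kwargs)
        a_unit = artery_area(ptm_open, base)
        return cls(d=math.pi * r_open ** 2 / a_unit, **kwargs)


def transmural(part: float, pcuff: float):
    """Transmural pressure Ptm = Part - Pcuff (mmHg); elementwise for arrays."""
    part = np.asarray(part, dtype=float)
    pcuff = np.asarray(pcuff, dtype=float)
    if not (np.all(np.isfinite(part)) and np.all(np.isfinite(pcuff))):
        raise ValueError("transmural: inputs must be finite")
    out = part - pcuff
    return out if out.ndim else float(out)


def artery_area(ptm, p: CollapseParams, *, clamp_collapsed: bool = False):
    """Cross-sectional area A(Ptm) in cm^2.

    ``clamp_collapsed=True`` maps the sub-collapse regime (log argument <= 1,
    where the formula would give a non-physical negative area, and <= 0 where
    it is undefined) to area 0 instead of raising.
    """
    ptm_arr = np.asarray(ptm, dtype=float)
    arg = p.a * ptm_arr + p.offset_const
    if clamp_collapsed:
        with np.errstate(invalid="ignore", divide="ignore"):
            area = p.d * np.log(np.maximum(arg, 1.0)) / (1.0 + np.exp(-p.c * ptm_arr))
        area = np.where(arg <= 1.0, 0.0, area)
    else:
        if np.any(arg <= 0.0):
            raise ValueError(
                f"artery_area: log argument non-positive at Ptm <= {p.ptm_domain_edge:.2f} mmHg"
            )
        area = p.d * np.log(arg) / (1.0 + np.exp(-p.c * ptm_arr))
    return area if area.ndim else float(area)


def artery_radius(ptm, p: CollapseParams, *, clamp_collapsed: bool = False):
    """Radius r = sqrt(A/pi) in cm (lumen treated as circular)."""
    area = artery_area(ptm, p, clamp_collapsed=clamp_collapsed)
    r = np.sqrt(np.maximum(np.asarray(area, dtype=float), 0.0) / math.pi)
    return r if r.ndim else float(r)


def brachial_resistance(ptm, p: CollapseParams, *, cap: float = OCCLUDED_RESISTANCE):
    """Poiseuille resistance of the segment, Ra = 8*eta*L / (pi r^4), mmHg*s/mL.

    Fully collapsed (r -> 0) returns the ``cap`` sentinel rather than raising,
    and any value above the cap is clipped to it.
    """
    r = np.asarray(artery_radius(ptm, p, clamp_collapsed=True), dtype=float)
    with np.errstate(divide="ignore"):
        ra = 8.0 * p.viscosity * p.cuff_length / (math.pi * r ** 4)
    ra = np.where(np.isfinite(ra), np.minimum(ra, cap), cap)
    return ra if ra.ndim else float(ra)


def artery_volume(ptm, p: CollapseParams, *, clamp_collapsed: bool = False):
    """Segment volume V = A(Ptm) * L in mL."""
    area = np.asarray(artery_area(ptm, p, clamp_collapsed=clamp_collapsed), dtype=float)
    v = area * p.cuff_length
    return v if v.ndim else float(v)


def artery_compliance(ptm, p: CollapseParams):
    """Analytic segment compliance C = dV/dPtm in mL/mmHg.

    dA/dPtm = d * [ a / (arg * s)  +  ln(arg) * c * e^{-c Ptm} / s^2 ],
    with arg = a*Ptm + 3.3 and s = 1 + e^{-c Ptm}.
    """
    ptm_arr = np.asarray(ptm, dtype=float)
    arg = p.a * ptm_arr + p.offset_const
    if np.any(arg <= 0.0):
        raise ValueError("artery_compliance: outside the admissible Ptm domain")
    e = np.exp(-p.c * ptm_arr)
    s = 1.0 + e
    dA = p.d * (p.a / (arg * s) + np.log(arg) * p.c * e / (s * s))
    out = dA * p.cuff_length
    return out if out.ndim else float(out)


def pwv(ptm, p: CollapseParams):
    """Bramwell-Hill pulse wave velocity, PWV = sqrt(V / (rho * C)), in m/s.

    V/(rho*C) carries units mmHg*cm^3/g; one mmHg is 1333.22 g/(cm s^2), so
    the root is in cm/s and is divided by 100.  The area scale ``d`` cancels
    in V/C, so PWV depends only on (a, c) and the fluid density.
    """
    v = np.asarray(artery_volume(ptm, p), dtype=float)
    cart = np.asarray(artery_compliance(ptm, p), dtype=float)
    if np.any(cart <= 0.0):
        raise ValueError("pwv: non-positive compliance")
    out = 0.01 * np.sqrt(MMHG_TO_CGS * v / (p.blood_density * cart))
    return out if out.ndim else float(out)
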