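"""Closed-form NMR mass-conservation model of compound uptake and partitioning.

Amide-proton NMR signal of an isotope-labelled compound is proportional to
its free concentration, so comparing the medium signal with and without
cells gives the fractional uptake U; simple bookkeeping of the added amount
then yields the extracellular and intracellular concentrations.  For in
vitro condensates, the measured signal factor SF (dilute phase over
resuspended condensate) together with the condensate pellet volume —
a spherical cap sitting in the hemispherical tube bottom — yields the
condensate/dilute partition coefficient and the absolute phase
concentrations by mass conservation.

All functions take SI-coherent scalars (m, m^3, mol/L for concentrations,
L for liquid volumes); the CLI converts from field units (uM, ul, nm^2, mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AVOGADRO",
    "UptakeMeasurement",
    "MembraneBoundParams",
    "PartitionMeasurement",
    "fractional_uptake",
    "concentrations_from_uptake",
    "lipid_ratio",
    "sphere_geometry",
    "cap_volume",
    "partition_coefficient",
    "phase_concentrations",
    "condensate_signal_fraction",
]

AVOGADRO = 6.02214076e23  # mol^-1

M3_TO_L = 1e3  # 1 m^3 = 1000 L


@dataclass(frozen=True)
class UptakeMeasurement:
    """Signal pair and geometry for a cellular-uptake experiment.

    s_plus_cells, s_minus_cells : medium signal with / without cells (a.u.)
    c_add : concentration of compound added (mol/L)
    v_add : volume of medium added (L)
    v_out : extracellular volume (L); the cell volume is negligible next to
        the medium volume, so this defaults to v_add
    n_cell : number of cells
    v_1 : single-cell volume (m^3)
    """

    s_plus_cells: float
    s_minus_cells: float
    c_add: float
    v_add: float
    n_cell: float
    v_1: float
    v_out: float | None = None

    def __post_init__(self) -> None:
        if self.s_minus_cells <= 0:
            raise ValueError("s_minus_cells must be positive")
        if self.s_plus_cells < 0:
            raise ValueError("s_plus_cells must be non-negative")
        for name in ("c_add", "v_add", "n_cell", "v_1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.v_out is None:
            object.__setattr__(self, "v_out", self.v_add)


@dataclass(frozen=True)
class MembraneBoundParams:
    """Constants of the membrane-bound upper-bound estimate.

    a_l : footprint of one phospholipid molecule (m^2); 0.5 nm^2 default
    a_1 : surface area of a single cell (m^2)
    """

    a_l: float = 0.5e-18
    a_1: float = 1.3e-9

    def __post_init__(self) -> None:
        if self.a_l <= 0 or self.a_1 <= 0:
            raise ValueError("areas must be positive")


@dataclass(frozen=True)
class PartitionMeasurement:
    """Inputs of the condensate-partitioning calculation.

    sf : NMR signal ratio, dilute phase / resuspended condensate (>0)
    a : condensate pellet radius (m)
    r : inner radius of the hemispherical tube bottom (m)
    v_added : resuspension volume (L)
    l_tot : total compound concentration in the sample (mol/L)
    v_tot : total sample volume (L)
    """

    sf: float
    a: float
    r: float
    v_added: float
    l_tot: float
    v_tot: float

    def __post_init__(self) -> None:
        if self.sf <= 0:
            raise ValueError("sf must be positive")
        if not 0 <= self.a <= self.r:
            raise ValueError("pellet radius must satisfy 0 <= a <= r")
        if self.v_added <= 0 or self.v_tot <= 0 or self.l_tot <= 0:
            raise ValueError("volumes and concentration must be positive")


def fractional_uptake(m: UptakeMeasurement, tolerance: float = 0.02) -> float:
    """U = 1 - S(+cells)/S(-cells), the fraction of compound taken up.

    A signal marginally above the no-cell reference (within ``tolerance``
    relative) is clipped to U = 0; beyond that the measurement is
    inconsistent and an error is raised.
    """
    ratio = m.s_plus_cells / m.s_minus_cells
    if ratio > 1.0 + tolerance:
        raise ValueError(
            f"s_plus_cells exceeds s_minus_cells by {ratio - 1:.1%} "
            f"(> {tolerance:.0%} tolerance): inconsistent measurement"
        )
    return max(0.0, 1.0 - ratio)


def concentrations_from_uptake(m: UptakeMeasurement, u: float) -> tuple[float, float]:
    """(C_out, C_cell) in mol/L given fractional uptake ``u``.

    C_out = (1 - U) c_add V_add / V_out ; C_cell = U c_add V_add / (V_1 N_cell),
    with the single-cell volume converted from m^3 to L.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    c_out = (1.0 - u) * m.c_add * m.v_add / m.v_out
    c_cell = u * m.c_add * m.v_add / (m.v_1 * M3_TO_L * m.n_cell)
    return c_out, c_cell


def lipid_ratio(
    u: float, c_add: float, v_add: float, params: MembraneBoundParams, n_cell: float
) -> float:
    """Compound molecules per plasma-membrane lipid if all uptake were membrane-bound.

    R = A_L N_A U c_add V_add / (A_1 N_cell); dimensionless.  Values well
    above ~1 rule out the membrane as the sink of the lost signal.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    return params.a_l * AVOGADRO * u * c_add * v_add / (params.a_1 * n_cell)


def sphere_geometry(radius: float) -> tuple[float, float]:
    """Volume (m^3) and surface area (m^2) of a sphere of ``radius`` (m)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return (4.0 / 3.0) * math.pi * radius**3, 4.0 * math.pi * radius**2


def cap_volume(a: float, r: float) -> float:
    """Volume (m^3) of a pellet of contact radius ``a`` in a hemispherical tube bottom.

    The pellet is the spherical cap subtending theta = asin(a/r):
    V = (pi/3) r^3 (2 + cos theta)(1 - cos theta)^2.  At a = r this is the
    full hemisphere (2/3) pi r^3; at a = 0 it vanishes.
    """
    if r <= 0:
        raise ValueError("tube radius must be positive")
    if not 0 <= a <= r:
        raise ValueError("pellet radius must satisfy 0 <= a <= r")
    theta = math.asin(a / r)
    c = math.cos(theta)
    return (math.pi / 3.0) * r**3 * (2.0 + c) * (1.0 - c) ** 2


def partition_coefficient(pm: PartitionMeasurement, v_cond: float) -> float:
    """Condensate/dilute partition coefficient PC = (V_cond + V_added) / (SF V_cond).

    ``v_cond`` is the condensate volume in L (convert the cap volume from
    m^3 with 1 m^3 = 1000 L before calling, or use :meth:`derive`).
    """
    if v_cond <= 0:
        raise ValueError("no condensate: PC undefined for v_cond <= 0")
    return (v_cond + pm.v_added) / (pm.sf * v_cond)


def phase_concentrations(
    l_tot: float, v_tot: float, v_cond: float, pc: float
) -> tuple[float, float]:
    """([L]_cond, [L]_dil) in mol/L from total amount, volumes and PC.

    [L]_cond = L_tot V_tot / (V_cond + (V_tot - V_cond)/PC) and
    [L]_dil = [L]_cond / PC; mass is conserved exactly:
    [L]_cond V_cond + [L]_dil (V_tot - V_cond) = L_tot V_tot.
    """
    if not 0 < v_cond < v_tot:
        raise ValueError("need 0 < v_cond < v_tot")
    if pc <= 0:
        raise ValueError("pc must be positive")
    l_cond = l_tot * v_tot / (v_cond + (v_tot - v_cond) / pc)
    return l_cond, l_cond / pc


def condensate_signal_fraction(sf: float) -> float:
    """Percent of total compound signal residing in the condensate: 100/(1+SF)."""
    if sf < 0:
        raise ValueError("sf must be non-negative")
    return 100.0 / (1.0 + sf)
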