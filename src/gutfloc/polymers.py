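"""Solution properties of a free, non-adsorbing polymer.

A flexible polymer in a good solvent is characterised here by its molecular
weight ``MW`` (Da) and its dilute radius of gyration ``Rg(0)`` (nm).  From
these two numbers the module derives the quantities that drive depletion
attraction between large colloids:

* the overlap concentration ``cp*`` marking the dilute/semi-dilute crossover,
  taken as one chain's mass per its pervaded spherical volume,
* the osmotic pressure ``Π_P(cp)`` from the good-solvent crossover expression
  ``Π_P = (N_A k T / MW) · cp · (1 + (cp/cp*)^1.3)``, which reduces to the
  van't Hoff law at dilution and to the des Cloizeaux scaling ``Π ~ cp^2.3``
  deep in the semi-dilute regime,
* the concentration-dependent characteristic polymer size
  ``R_P(cp) = Rg(0) · [(MW / N_A k T) · dΠ_P/dcp]^(-1/2)``, equal to ``Rg(0)``
  at dilution and shrinking towards the blob (correlation) length as coils
  interpenetrate.

Units at the interface are nm, mg/mL and Da; conversions to SI happen
internally.  Note that mg/mL and kg/m^3 are numerically identical, which the
implementation relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants

__all__ = [
    "KIRKWOOD_RISEMAN_RATIO",
    "PolymerSpec",
    "SolutionCondition",
    "rg_from_rh",
    "overlap_concentration",
    "osmotic_pressure",
    "osmotic_pressure_slope",
    "polymer_size",
]

#: Rh/Rg ratio for a flexible coil in good solvent (Kirkwood–Riseman value).
KIRKWOOD_RISEMAN_RATIO = 0.665

#: Exponent of the semi-dilute correction in the osmotic crossover equation.
_CROSSOVER_EXPONENT = 1.3


@dataclass(frozen=True)
class PolymerSpec:
    """A free polymer in solution.

    Parameters
    ----------
    name:
        Label used in tables and reports.
    molecular_weight:
        Molar mass in Da (g/mol).
    rg_dilute:
        Dilute-limit radius of gyration ``Rg(0)`` in nm.
    intrinsic_viscosity:
        Optional ``[η]`` in mL/g, used by the transport module.
    huggins_coefficient:
        Optional dimensionless Huggins coefficient ``k_H``.
    """

    name: str
    molecular_weight: float
    rg_dilute: float
    intrinsic_viscosity: float | None = None
    huggins_coefficient: float | None = None

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"molecular_weight must be > 0, got {self.molecular_weight}")
        if self.rg_dilute <= 0:
            raise ValueError(f"rg_dilute must be > 0, got {self.rg_dilute}")
        if self.intrinsic_viscosity is not None and self.intrinsic_viscosity <= 0:
            raise ValueError("intrinsic_viscosity must be > 0 when given")


@dataclass(frozen=True)
class SolutionCondition:
    """Solvent-side state of an aggregation assay.

    concentration is the free-polymer mass concentration ``cp`` in mg/mL;
    temperature in K; ionic_strength in mM (1:1 electrolyte); solvent
    viscosity in mPa·s.  Defaults describe the buffered aqueous assays:
    room temperature and an isotonic saline of ~170 mM ionic strength.
    """

    concentration: float
    temperature: float = 298.15
    ionic_strength: float = 170.0
    solvent_viscosity: float = 0.89

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if self.ionic_strength < 0:
            raise ValueError(f"ionic_strength must be >= 0, got {self.ionic_strength}")


def rg_from_rh(rh: float, ratio: float = KIRKWOOD_RISEMAN_RATIO) -> float:
    """Radius of gyration from a hydrodynamic radius, ``Rg = Rh / ratio``.

    ``ratio`` is the coil's Rh/Rg value; the default is the Kirkwood–Riseman
    good-solvent value 0.665.  Both radii in nm.
    """
    if rh <= 0:
        raise ValueError(f"rh must be > 0, got {rh}")
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    return rh / ratio


def overlap_concentration(spec: PolymerSpec) -> float:
    """Overlap concentration ``cp* = 3 MW / (4 π N_A Rg(0)^3)`` in mg/mL.

    One chain's mass divided by the volume of the sphere it pervades; above
    this concentration coils interpenetrate and the solution is semi-dilute.
    """
    rg_cm = spec.rg_dilute * 1e-7
    cstar_g_per_cm3 = 3.0 * spec.molecular_weight / (
        4.0 * math.pi * constants.Avogadro * rg_cm**3
    )
    return cstar_g_per_cm3 * 1e3  # g/cm^3 -> mg/mL


def _vant_hoff_slope(spec: PolymerSpec, temperature: float) -> float:
    # dΠ/dcp in the dilute limit, Pa per (kg/m^3); MW Da -> kg/mol.
    return constants.R * temperature / (spec.molecular_weight * 1e-3)


def osmotic_pressure(spec: PolymerSpec, cond: SolutionCondition) -> float:
    """Osmotic pressure ``Π_P`` (Pa) from the good-solvent crossover equation.

    ``Π_P = (N_A k T / MW) cp (1 + (cp/cp*)^1.3)`` with cp in kg/m^3
    (numerically mg/mL).  Returns 0 at cp = 0.
    """
    cp = cond.concentration
    if cp == 0:
        return 0.0
    x = cp / overlap_concentration(spec)
    return _vant_hoff_slope(spec, cond.temperature) * cp * (1.0 + x**_CROSSOVER_EXPONENT)


def osmotic_pressure_slope(spec: PolymerSpec, cond: SolutionCondition) -> float:
    """Analytic ``dΠ_P/dcp`` in Pa/(kg/m^3).

    ``dΠ/dcp = (N_A k T / MW) (1 + 2.3 (cp/cp*)^1.3)``.  Computed in closed
    form rather than by finite differences to stay exact near cp = 0.
    """
    x = cond.concentration / overlap_concentration(spec)
    bracket = 1.0 + (_CROSSOVER_EXPONENT + 1.0) * x**_CROSSOVER_EXPONENT
    return _vant_hoff_slope(spec, cond.temperature) * bracket


def polymer_size(spec: PolymerSpec, cond: SolutionCondition) -> float:
    """Concentration-dependent characteristic polymer size ``R_P(cp)`` in nm.

    ``R_P = Rg(0) [(MW / N_A k T) dΠ/dcp]^(-1/2)``, which with the crossover
    pressure reduces to ``Rg(0) / sqrt(1 + 2.3 (cp/cp*)^1.3)``: the dilute
    radius of gyration at low cp, crossing over to the correlation length in
    the semi-dilute regime.  Strictly decreasing in cp.
    """
    x = cond.concentration / overlap_concentration(spec)
    return spec.rg_dilute / math.sqrt(1.0 + (_CROSSOVER_EXPONENT + 1.0) * x**_CROSSOVER_EXPONENT)
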