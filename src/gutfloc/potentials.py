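"""Combined depletion + steric inter-particle potential.

Two sterically stabilised colloids of core radius ``a`` in a solution of free,
non-adsorbing polymer interact through

* an Asakura–Oosawa depletion attraction (valid for ``a >> R_P``)::

      U_dep(r) = +inf                       for r <= 0
               = -2π Π_P a (R_P - r/2)^2    for 0 < r < 2 R_P
               = 0                          for r >= 2 R_P

  where ``r`` is the gap between bare particle surfaces (r = 0 at hard
  contact), ``Π_P`` the polymer osmotic pressure and ``R_P`` the
  concentration-dependent polymer size, and

* a steric repulsion of the two grafted brushes.  For gaps between one and
  two brush lengths the repulsion is the Flory–Huggins free energy of mixing
  of the overlapping step-profile brushes::

      U_s,mix(r) = (4π a kT / υ1) φ̄² (1/2 - χ) (L - r/2)^2   for L < r < 2 L

  and for r <= L elastic deformation of the layers dominates, modelled here
  as a hard wall (+inf).

The total is ``U = U_s,mix + U_dep`` for ``L < r < 2L`` and ``U_dep`` alone
beyond.  When the depletant is small (``R_P < L``) the attractive range lies
entirely inside the hard wall — the well is "buried" and the dispersion stays
stable at every concentration; long polymers open a well whose depth first
grows with concentration and then shrinks again as ``R_P`` collapses in the
semi-dilute regime (depletion restabilisation).

All energies are reported in units of kT; all lengths at the interface in nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants
from scipy.optimize import minimize_scalar

from .errors import ConfigurationError
from .polymers import PolymerSpec, SolutionCondition, osmotic_pressure, polymer_size

__all__ = [
    "ColloidBrushSpec",
    "PotentialProfile",
    "depletion_potential",
    "steric_mixing_potential",
    "total_potential",
    "potential_minimum_curve",
    "locate_minimum",
]

#: Default volume of a water molecule, m^3 (18 cm^3/mol / N_A).
WATER_MOLECULE_VOLUME = 2.99e-29


@dataclass(frozen=True)
class ColloidBrushSpec:
    """A brush-grafted colloid: core radius a (nm), brush length L (nm),
    step-profile brush volume fraction φ̄, Flory–Huggins χ of the grafted
    polymer with the solvent, and the solvent molecular volume υ1 (m^3)."""

    core_radius: float
    brush_length: float
    brush_volume_fraction: float
    chi: float = 0.45
    water_molecule_volume: float = WATER_MOLECULE_VOLUME

    def __post_init__(self) -> None:
        if self.core_radius <= 0 or self.brush_length <= 0:
            raise ValueError("core_radius and brush_length must be > 0")
        if not 0 < self.brush_volume_fraction < 1:
            raise ValueError(
                f"brush_volume_fraction must lie in (0, 1), got {self.brush_volume_fraction}"
            )
        if self.water_molecule_volume <= 0:
            raise ValueError("water_molecule_volume must be > 0")
        if self.core_radius / self.brush_length < 10:
            warnings.warn(
                "core_radius/brush_length < 10: the Derjaguin/AO forms assume "
                "a thin brush on a large particle",
                stacklevel=2,
            )


@dataclass
class PotentialProfile:
    """U(r)/kT sampled on a separation grid, with its located minimum.

    ``energy`` is +inf for r <= L (hard wall) and tends to 0 at large r.
    ``u_min`` is min(0, min of the profile); ``r_min`` is NaN when no well
    exists (u_min == 0).
    """

    separations: np.ndarray
    energy: np.ndarray
    u_min: float
    r_min: float
    polymer_size_nm: float = field(default=float("nan"))
    osmotic_pressure_pa: float = field(default=float("nan"))


def depletion_potential(r, a: float, pressure: float, rp: float,
                        temperature: float = 298.15):
    """Asakura–Oosawa depletion attraction in kT.

    Piecewise: +inf at r <= 0, ``-2π Π a (R_P - r/2)^2 / kT`` for
    0 < r < 2 R_P, zero beyond.  ``r``, ``a`` and ``rp`` in nm, ``pressure``
    in Pa.  Accepts scalars or arrays for ``r``.
    """
    if a <= 0 or rp <= 0:
        raise ValueError("a and rp must be > 0")
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    r = np.asarray(r, dtype=float)
    kt = constants.k * temperature
    a_m, rp_m, r_m = a * 1e-9, rp * 1e-9, r * 1e-9
    well = -2.0 * math.pi * pressure * a_m * (rp_m - r_m / 2.0) ** 2 / kt
    out = np.where(r < 2.0 * rp, well, 0.0)
    out = np.where(r <= 0, np.inf, out)
    return out if out.ndim else float(out)


def steric_mixing_potential(r, brush: ColloidBrushSpec,
                            temperature: float = 298.15):
    """Brush-mixing repulsion in kT.

    ``(4π a / υ1) φ̄² (1/2 - χ) (L - r/2)^2`` for L < r < 2L (the kT of the
    free-energy prefactor cancels against the kT reporting unit); zero for
    r >= 2L; +inf for r <= L, where elastic compression of the layers is
    treated as a hard wall.
    """
    r = np.asarray(r, dtype=float)
    a_m = brush.core_radius * 1e-9
    l_m = brush.brush_length * 1e-9
    r_m = r * 1e-9
    amp = (4.0 * math.pi * a_m / brush.water_molecule_volume
           * brush.brush_volume_fraction**2 * (0.5 - brush.chi))
    val = amp * (l_m - r_m / 2.0) ** 2
    out = np.where(r < 2.0 * brush.brush_length, val, 0.0)
    out = np.where(r <= brush.brush_length, np.inf, out)
    return out if out.ndim else float(out)


def _energy_outside_wall(r, spec: PolymerSpec, cond: SolutionCondition,
                         brush: ColloidBrushSpec, pressure: float, rp: float):
    """U(r)/kT for r > L (finite branch); array-valued."""
    u = depletion_potential(r, brush.core_radius, pressure, rp, cond.temperature)
    u = u + steric_mixing_potential(r, brush, cond.temperature)
    return u


def total_potential(grid, spec: PolymerSpec, cond: SolutionCondition,
                    brush: ColloidBrushSpec) -> PotentialProfile:
    """Evaluate the combined potential on a separation grid (nm).

    The grid must be strictly increasing and must cover the depletion range,
    i.e. extend past max(2 R_P, 2 L); otherwise a ConfigurationError is
    raised.  Π_P and R_P are evaluated from the polymer-solution model at the
    given condition.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ConfigurationError("grid must be a 1-D array with at least 2 points")
    if not np.all(np.diff(grid) > 0):
        raise ConfigurationError("grid must be strictly increasing")
    pressure = osmotic_pressure(spec, cond)
    rp = polymer_size(spec, cond)
    needed = max(2.0 * rp, 2.0 * brush.brush_length)
    if grid[-1] < needed:
        raise ConfigurationError(
            f"grid ends at {grid[-1]:.3g} nm but must cover the depletion "
            f"range out to {needed:.3g} nm"
        )
    energy = _energy_outside_wall(grid, spec, cond, brush, pressure, rp)
    energy = np.where(grid <= brush.brush_length, np.inf, energy)

    finite = np.isfinite(energy)
    if finite.any():
        i = int(np.nanargmin(np.where(finite, energy, np.inf)))
        u_min = min(0.0, float(energy[i]))
        r_min = float(grid[i]) if u_min < 0 else float("nan")
    else:  # grid entirely inside the wall
        u_min, r_min = 0.0, float("nan")
    return PotentialProfile(grid, energy, u_min, r_min, rp, pressure)


def locate_minimum(spec: PolymerSpec, cond: SolutionCondition,
                   brush: ColloidBrushSpec, n_grid: int = 10_000,
                   r_max: float | None = None) -> tuple[float, float]:
    """Global minimum of the combined potential over r in (L, r_max].

    Dense log-spaced scan (``n_grid`` points) followed by bounded scalar
    refinement around the best grid point (tolerance 1e-4 kT in practice).
    Returns ``(u_min, r_min)`` with ``u_min <= 0`` by definition: 0 (and NaN
    location) when no well exists.
    """
    pressure = osmotic_pressure(spec, cond)
    rp = polymer_size(spec, cond)
    L = brush.brush_length
    if r_max is None:
        r_max = max(4.0 * rp, 4.0 * L)
    grid = np.geomspace(L * (1.0 + 1e-6), r_max, n_grid)
    energy = _energy_outside_wall(grid, spec, cond, brush, pressure, rp)
    i = int(np.argmin(energy))
    if energy[i] >= 0:
        return 0.0, float("nan")

    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda r: float(_energy_outside_wall(np.array([r]), spec, cond, brush,
                                             pressure, rp)[0]),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-9 * max(1.0, hi)},
    )
    u_min = float(min(res.fun, energy[i]))
    r_min = float(res.x) if res.fun <= energy[i] else float(grid[i])
    if u_min >= 0:
        return 0.0, float("nan")
    return u_min, r_min


def potential_minimum_curve(spec: PolymerSpec, concentrations,
                            brush: ColloidBrushSpec,
                            cond_template: SolutionCondition | None = None,
                            n_grid: int = 10_000):
    """Depth and location of the potential well as a function of concentration.

    Returns a list of ``(cp, u_min, r_min)`` tuples, one per concentration in
    mg/mL.  ``cond_template`` supplies temperature / ionic strength; its
    concentration field is ignored.
    """
    if cond_template is None:
        cond_template = SolutionCondition(concentration=0.0)
    out = []
    for cp in concentrations:
        if cp < 0:
            raise ValueError(f"concentrations must be >= 0, got {cp}")
        if cp == 0:
            out.append((0.0, 0.0, float("nan")))
            continue
        cond = SolutionCondition(
            concentration=float(cp),
            temperature=cond_template.temperature,
            ionic_strength=cond_template.ionic_strength,
            solvent_viscosity=cond_template.solvent_viscosity,
        )
        u_min, r_min = locate_minimum(spec, cond, brush, n_grid=n_grid)
        out.append((float(cp), u_min, r_min))
    return out
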