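"""Grafted-layer (polymer brush) parameters from measurable quantities.

The PEG chains grafted onto the particles are dense enough to stretch into a
brush.  This module turns bench-top numbers — the PEG loading measured by NMR
(nmol per mg of particles), the particle geometry, and literature values for
the Kuhn length and Flory exponent — into the Alexander–de Gennes step-profile
brush parameters used by the interaction-potential module:

* grafting density  Γ = chains per nm^2 of particle surface,
* overlap grafting density  Γ* = 1/(π Rg^2), above which grafted coils
  overlap and the layer is a brush,
* Kuhn segments per chain  N = (Rg/b)^(1/ν),
* brush length  L = N Γ^((1-ν)/(2ν)) b^(1/ν),
* step-profile volume fraction  φ = (Γ b^2)^((3ν-1)/(2ν)).

Also provides the Debye screening length, which sets the (short) range of
residual electrostatic repulsion in the high-ionic-strength luminal buffers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import constants

from .potentials import ColloidBrushSpec

__all__ = [
    "BrushDerivation",
    "BrushGeometry",
    "grafting_density_from_loading",
    "brush_geometry",
    "debye_length",
    "colloid_spec_from_derivation",
]


@dataclass(frozen=True)
class BrushDerivation:
    """Inputs for deriving brush parameters.

    loading: nmol grafted polymer per mg of particles (from NMR);
    particle_diameter in µm; particle_density in g/cm^3 (polystyrene default);
    kuhn_length b in nm; graft_rg: dilute Rg of the grafted chain in nm;
    flory_exponent ν (good-solvent value 0.588 by default).
    """

    loading: float
    particle_diameter: float = 1.0
    particle_density: float = 1.05
    kuhn_length: float = 0.76
    graft_rg: float = 3.45
    flory_exponent: float = 0.588

    def __post_init__(self) -> None:
        for field in ("loading", "particle_diameter", "particle_density",
                      "kuhn_length", "graft_rg"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be > 0, got {getattr(self, field)}")
        if not 0.5 < self.flory_exponent <= 0.6:
            raise ValueError(
                f"flory_exponent must lie in (0.5, 0.6], got {self.flory_exponent}"
            )


@dataclass(frozen=True)
class BrushGeometry:
    """Derived Alexander–de Gennes brush parameters (step profile)."""

    n_segments: float          # Kuhn segments per chain (real-valued; round for display)
    brush_length: float        # L in nm
    volume_fraction: float     # φ, dimensionless
    overlap_density: float     # Γ* in chains/nm^2
    grafting_density: float    # Γ in chains/nm^2 actually used


def grafting_density_from_loading(d: BrushDerivation) -> float:
    """Grafting density Γ in chains/nm^2 from an NMR loading.

    Converts nmol of chains per mg of particles into chains per unit surface
    area, assuming monodisperse spheres of the given diameter and density.
    """
    diameter_cm = d.particle_diameter * 1e-4
    sphere_volume_cm3 = math.pi / 6.0 * diameter_cm**3
    sphere_mass_g = d.particle_density * sphere_volume_cm3
    spheres_per_mg = 1e-3 / sphere_mass_g

    diameter_nm = d.particle_diameter * 1e3
    area_per_sphere_nm2 = math.pi * diameter_nm**2

    chains_per_mg = d.loading * 1e-9 * constants.Avogadro
    return chains_per_mg / (spheres_per_mg * area_per_sphere_nm2)


def brush_geometry(d: BrushDerivation, grafting_density: float | None = None) -> BrushGeometry:
    """Brush length, volume fraction and overlap density for a grafted layer.

    If ``grafting_density`` is omitted it is derived from the NMR loading.
    ``n_segments`` is kept real-valued; the conventional "number of Kuhn
    segments" is its nearest integer.
    """
    gamma = grafting_density if grafting_density is not None else grafting_density_from_loading(d)
    if gamma <= 0:
        raise ValueError(f"grafting density must be > 0, got {gamma}")
    nu = d.flory_exponent
    b = d.kuhn_length
    n_seg = (d.graft_rg / b) ** (1.0 / nu)
    brush_len = n_seg * gamma ** ((1.0 - nu) / (2.0 * nu)) * b ** (1.0 / nu)
    phi = (gamma * b**2) ** ((3.0 * nu - 1.0) / (2.0 * nu))
    overlap = 1.0 / (math.pi * d.graft_rg**2)
    return BrushGeometry(
        n_segments=n_seg,
        brush_length=brush_len,
        volume_fraction=phi,
        overlap_density=overlap,
        grafting_density=gamma,
    )


def debye_length(ionic_strength: float, temperature: float = 298.15,
                 rel_permittivity: float = 78.5) -> float:
    """Debye screening length κ⁻¹ in nm for a 1:1 electrolyte.

    ``κ⁻¹ = sqrt(ε0 εr k T / (2 N_A e² I))`` with the ionic strength I given
    in mM (numerically mol/m^3).
    """
    if ionic_strength <= 0:
        raise ValueError(f"ionic_strength must be > 0, got {ionic_strength}")
    if temperature <= 0 or rel_permittivity <= 0:
        raise ValueError("temperature and rel_permittivity must be > 0")
    num = constants.epsilon_0 * rel_permittivity * constants.k * temperature
    den = 2.0 * constants.Avogadro * constants.e**2 * ionic_strength
    return math.sqrt(num / den) * 1e9


def colloid_spec_from_derivation(d: BrushDerivation, chi: float = 0.45,
                                 grafting_density: float | None = None) -> ColloidBrushSpec:
    """Convenience: build the ColloidBrushSpec used by the potential module."""
    geom = brush_geometry(d, grafting_density=grafting_density)
    return ColloidBrushSpec(
        core_radius=d.particle_diameter * 1e3 / 2.0,
        brush_length=geom.brush_length,
        brush_volume_fraction=geom.volume_fraction,
        chi=chi,
    )
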