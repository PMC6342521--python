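"""Transport-side estimates: viscosity-limited diffusivity and elasticity.

Aggregation at short times is collision-limited, so the particle diffusivity
matters.  The solution viscosity is estimated from the Huggins equation

    η/η_s = 1 + [η] c + k_H ([η] c)^2,

and the particle diffusivity from the Stokes–Einstein–Sutherland relation at
fixed particle radius and temperature, so that D_P/D_W = η_water/η_solution.
The Weissenberg number Wi = γ̇ λ weighs elastic against viscous stresses for
flow in the intestine; λ grows with polymer molecular weight as MW^(2/3).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError
from .polymers import PolymerSpec

__all__ = [
    "FlowContext",
    "relative_viscosity",
    "particle_diffusivity_ratio",
    "weissenberg_number",
    "scaled_relaxation_time",
]


@dataclass(frozen=True)
class FlowContext:
    """Shear rate γ̇ (1/s) and fluid relaxation time λ (s)."""

    shear_rate: float
    relaxation_time: float

    def __post_init__(self) -> None:
        if self.shear_rate < 0 or self.relaxation_time < 0:
            raise ValueError("shear_rate and relaxation_time must be >= 0")


def relative_viscosity(spec: PolymerSpec, cp: float) -> float:
    """η/η_solvent from the Huggins equation.

    ``cp`` in mg/mL is converted to g/mL to match ``[η]`` in mL/g.  Requires
    the polymer's viscometric constants.
    """
    if spec.intrinsic_viscosity is None or spec.huggins_coefficient is None:
        raise ConfigurationError(
            f"polymer {spec.name!r} has no intrinsic_viscosity/huggins_coefficient"
        )
    if cp < 0:
        raise ValueError(f"cp must be >= 0, got {cp}")
    x = spec.intrinsic_viscosity * (cp * 1e-3)
    return 1.0 + x + spec.huggins_coefficient * x**2


def particle_diffusivity_ratio(spec: PolymerSpec, cp: float) -> float:
    """D_P/D_W: particle diffusivity in the polymer solution over that in water.

    Stokes–Einstein–Sutherland at fixed radius and temperature makes this the
    reciprocal of the relative viscosity.
    """
    return 1.0 / relative_viscosity(spec, cp)


def weissenberg_number(ctx: FlowContext) -> float:
    """Wi = γ̇ λ."""
    return ctx.shear_rate * ctx.relaxation_time


def scaled_relaxation_time(mw: float, mw_ref: float, relaxation_ref: float) -> float:
    """Relaxation time at another molecular weight via λ ∝ MW^(2/3)."""
    if mw <= 0 or mw_ref <= 0 or relaxation_ref < 0:
        raise ValueError("molecular weights must be > 0 and relaxation_ref >= 0")
    return relaxation_ref * (mw / mw_ref) ** (2.0 / 3.0)
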