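"""Energy-balance identity and DXA body-composition unit conversion.

The package works on three daily quantities, all in kcal/day: energy
expenditure (EE), energy intake (EI) and change in energy stores (dES),
linked by the first-law identity ``dES = EI - EE``.  DXA reports changes
in fat mass and fat-free mass (kg); those are converted to kcal/day with
fixed energy densities.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EnergyConstants",
    "BodyCompositionChange",
    "DEFAULT_CONSTANTS",
    "delta_es_from_dxa",
    "energy_intake",
]


@dataclass(frozen=True)
class EnergyConstants:
    """Energy densities of the two body-composition compartments.

    Parameters
    ----------
    c_fm : float
        Energy density of fat mass, kcal/kg.
    c_ffm : float
        Energy density of fat-free mass, kcal/kg.

    The defaults are the conventional two-compartment values; they are
    injectable because a single constant does not capture biological
    variation between subjects.
    """

    c_fm: float = 9500.0
    c_ffm: float = 1100.0

    def __post_init__(self) -> None:
        if not (self.c_fm > 0 and self.c_ffm > 0):
            raise ValueError("energy densities must be strictly positive")
        if not self.c_fm > self.c_ffm:
            raise ValueError("fat mass must be more energy dense than fat-free mass")


DEFAULT_CONSTANTS = EnergyConstants()


@dataclass(frozen=True)
class BodyCompositionChange:
    """Change in body composition over an elapsed period.

    Attributes
    ----------
    delta_fm : float
        Change in fat mass, kg.
    delta_ffm : float
        Change in fat-free mass, kg.
    delta_t : float
        Elapsed time, days; must be strictly positive.
    """

    delta_fm: float
    delta_ffm: float
    delta_t: float

    def __post_init__(self) -> None:
        if not self.delta_t > 0:
            raise ValueError(f"delta_t must be positive, got {self.delta_t}")


def delta_es_from_dxa(
    change: BodyCompositionChange,
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> float:
    """Convert a DXA-measured body-composition change to kcal/day.

    Returns ``(c_fm * delta_fm + c_ffm * delta_ffm) / delta_t``.  The sign
    is preserved: positive values mean net energy storage.
    """
    return (
        constants.c_fm * change.delta_fm + constants.c_ffm * change.delta_ffm
    ) / change.delta_t


def energy_intake(ee, delta_es):
    """Back-calculate energy intake from the balance identity EI = EE + dES.

    Accepts scalars or numpy arrays; the identity is exact by construction.
    """
    return ee + delta_es
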