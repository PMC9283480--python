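"""Unit conversions and dose-to-species bookkeeping for aqueous radiolysis.

Canonical unit system used throughout the package: absorbed dose in gray
(Gy = J/kg), concentrations in µM, times in hours, radiochemical yields in
µmol/J.  The legacy dosimetry representation of a radiochemical yield — the
G-value, molecules affected per 100 eV of absorbed energy — is carried
alongside and interconverted exactly.

The conversion factor between the two representations follows from the
CODATA (exact, 2019 SI) elementary charge and Avogadro constant:

    1 molecule / 100 eV  =  10^6 / (100 · e · N_A)  µmol/J  ≈ 0.103642 µmol/J

so a yield of G = 81 per 100 eV corresponds to 8.40 µmol/J.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .errors import DomainError, NumericalError

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .radiolysis import RadiationSource, SolutionConditions

#: Elementary charge in coulomb (exact since the 2019 SI redefinition).
ELEMENTARY_CHARGE_C = 1.602176634e-19
#: Avogadro constant in mol^-1 (exact since the 2019 SI redefinition).
AVOGADRO_PER_MOL = 6.02214076e23

#: µmol/J per (molecule / 100 eV).
UMOL_PER_J_PER_G100EV = 1e6 / (100.0 * ELEMENTARY_CHARGE_C * AVOGADRO_PER_MOL)


def _require_non_negative_finite(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise DomainError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise DomainError(f"{name} must be non-negative, got {value!r}")
    return value


@dataclass(frozen=True)
class RadiochemicalYield:
    """A radiochemical yield for one species, stored in µmol/J.

    Parameters
    ----------
    value_umol_per_J:
        Yield in µmol of species per joule of absorbed energy.
    species:
        Label of the species produced or consumed, e.g. ``"HO•"`` or
        ``"trans-isomer"``.
    """

    value_umol_per_J: float
    species: str = "HO•"

    def __post_init__(self) -> None:
        _require_non_negative_finite(self.value_umol_per_J, "yield")

    @property
    def value_per_100eV(self) -> float:
        """The same yield expressed as molecules per 100 eV (classic G)."""
        return umol_per_j_to_g_per_100ev(self.value_umol_per_J)

    @classmethod
    def from_per_100ev(cls, g: float, species: str = "HO•") -> "RadiochemicalYield":
        return cls(g_per_100ev_to_umol_per_j(g), species)

    def scaled(self, factor: float) -> "RadiochemicalYield":
        return RadiochemicalYield(self.value_umol_per_J * float(factor), self.species)


def g_per_100ev_to_umol_per_j(g: float) -> float:
    """Convert a G-value (molecules / 100 eV) to µmol/J.

    >>> round(g_per_100ev_to_umol_per_j(81), 2)
    8.4
    """
    g = _require_non_negative_finite(g, "G-value (per 100 eV)")
    return g * UMOL_PER_J_PER_G100EV


def umol_per_j_to_g_per_100ev(y: float) -> float:
    """Convert a yield in µmol/J to a G-value in molecules per 100 eV."""
    y = _require_non_negative_finite(y, "yield (µmol/J)")
    return y / UMOL_PER_J_PER_G100EV


def species_concentration_from_dose(
    dose_gy: float,
    yield_umol_per_j: float,
    density_kg_per_l: float = 1.0,
) -> float:
    """Concentration (µM) of a species produced by a given absorbed dose.

    Dose is energy per mass (Gy = J/kg); multiplying by the yield (µmol/J)
    and the solution density (kg/L, default 1.0 for dilute aqueous media)
    gives µmol/L = µM.  Exactly linear in both dose and yield.
    """
    dose_gy = _require_non_negative_finite(dose_gy, "dose (Gy)")
    yield_umol_per_j = _require_non_negative_finite(yield_umol_per_j, "yield (µmol/J)")
    density_kg_per_l = float(density_kg_per_l)
    if not density_kg_per_l > 0:
        raise DomainError(f"density must be positive, got {density_kg_per_l!r}")
    return yield_umol_per_j * dose_gy * density_kg_per_l


def equivalent_dose(
    dose_gy: float,
    conditions_from: "SolutionConditions",
    conditions_to: "SolutionConditions",
    source: "RadiationSource",
) -> float:
    """Dose under ``conditions_to`` producing the same HO• amount.

    A dose D delivered under one set of solution conditions generates
    ``D × G_eff(from)`` of hydroxyl radical; the equivalent dose under a
    second set of conditions is the one matching that amount:

        D_eq = D × G_eff(from) / G_eff(to)

    e.g. 5 Gy in N₂O-saturated water (G doubled) is equivalent to 10 Gy in
    plain water.
    """
    from .radiolysis import effective_g_ho  # local import: avoids a cycle

    dose_gy = _require_non_negative_finite(dose_gy, "dose (Gy)")
    g_from = effective_g_ho(source, conditions_from).value_umol_per_J
    g_to = effective_g_ho(source, conditions_to).value_umol_per_J
    if g_to <= 0:
        raise NumericalError(
            "target conditions have zero effective G(HO•); the equivalent "
            "dose is undefined (division by zero)"
        )
    if g_from <= 0:
        raise NumericalError("source conditions have zero effective G(HO•)")
    return dose_gy * g_from / g_to
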