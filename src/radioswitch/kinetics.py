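"""Forward model of the azobenzene radioswitch.

The switch starts at the UV photostationary state PSS1 (~90% cis).  Two
first-order processes move the composition toward all-trans:

* **thermal back relaxation** in the dark, with half-life t½ = 2.3 h at
  37 °C in PBS:

      trans(t) = 1 − (1 − trans₀) · exp(−ln2 · t / t½)

* **radiation activation**, a monoexponential approach to the all-trans
  endpoint in cumulative dose D:

      trans(D) = 1 − (1 − trans₀) · exp(−k_eff · D)

The central modelling assumption, supported by the N₂O dose-equivalence
experiments, is that activation is driven by the homogeneous HO• amount
only, so the effective rate constant scales linearly with the effective
hydroxyl-radical yield:

      k_eff = k_act × G_eff(HO•) / G_ref

with k_act = 0.21 Gy⁻¹ measured under γ irradiation in water
(G_ref = 0.280 µmol/J).

A separate, empirically fitted dose-efficiency model predicts the
radiochemical yield of trans formation from the initial cis concentration
and dose over the 2–20 Gy range:

      G(trans) = [cis]₀ · (a · ln D + b),  a = −0.036, b = 0.1304 (G/µM)

The two models are deliberately not forced to agree (see docs/methods.md).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from .errors import DomainError
from .radiolysis import RadiationSource, SolutionConditions, effective_g_ho

LN2 = math.log(2.0)

#: Dose range over which the logarithmic efficiency model was fitted.
EFFICIENCY_DOSE_RANGE_GY = (2.0, 20.0)


@dataclass(frozen=True)
class SwitchParameters:
    """Kinetic constants of the radioswitch.

    Defaults are the γ-irradiation values in water at 37 °C:
    k_act = 0.21 Gy⁻¹ referenced to G(HO•) = 0.280 µmol/J, PSS1 = 90% cis,
    t½ = 2.3 h, efficiency-model coefficients (−0.036, 0.1304) G-value/µM.
    """

    k_act_per_Gy: float = 0.21
    pss1_cis_fraction: float = 0.90
    thermal_half_life_h: float = 2.3
    reference_g_ho_umol_per_j: float = 0.280
    efficiency_a: float = -0.036
    efficiency_b: float = 0.1304

    def __post_init__(self) -> None:
        if not self.k_act_per_Gy > 0:
            raise DomainError("k_act_per_Gy must be positive")
        if not 0.0 <= self.pss1_cis_fraction <= 1.0:
            raise DomainError("pss1_cis_fraction must lie in [0, 1]")
        if not self.thermal_half_life_h > 0:
            raise DomainError("thermal_half_life_h must be positive")
        if not self.reference_g_ho_umol_per_j > 0:
            raise DomainError("reference_g_ho_umol_per_j must be positive")

    @property
    def pss1_trans_fraction(self) -> float:
        return 1.0 - self.pss1_cis_fraction

    @property
    def thermal_rate_per_h(self) -> float:
        return LN2 / self.thermal_half_life_h


@dataclass(frozen=True)
class IsomerState:
    """Isomer composition of a switch solution at a moment in time.

    cis and trans are the only species (no side product is formed on
    irradiation), so cis_fraction = 1 − trans_fraction by construction.
    """

    trans_fraction: float
    total_concentration_uM: float = 50.0
    time_h: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.trans_fraction <= 1.0:
            raise DomainError(
                f"trans_fraction must lie in [0, 1], got {self.trans_fraction}"
            )
        if not self.total_concentration_uM > 0:
            raise DomainError("total_concentration_uM must be positive")
        if self.time_h < 0:
            raise DomainError("time_h must be >= 0")

    @property
    def cis_fraction(self) -> float:
        return 1.0 - self.trans_fraction

    @property
    def trans_concentration_uM(self) -> float:
        return self.trans_fraction * self.total_concentration_uM

    @property
    def cis_concentration_uM(self) -> float:
        return self.cis_fraction * self.total_concentration_uM


def pss1_state(
    params: SwitchParameters, total_concentration_uM: float = 50.0
) -> IsomerState:
    """The photostationary starting state (default 90% cis)."""
    return IsomerState(params.pss1_trans_fraction, total_concentration_uM, 0.0)


def effective_rate_constant(
    params: SwitchParameters,
    source: RadiationSource | None = None,
    conditions: SolutionConditions | None = None,
) -> float:
    """k_eff (Gy⁻¹): the activation constant rescaled by G_eff/G_ref.

    With no source/conditions the reference constant is returned unchanged
    (γ source in plain water).
    """
    if source is None and conditions is None:
        return params.k_act_per_Gy
    if source is None or conditions is None:
        raise DomainError("provide both source and conditions, or neither")
    g_eff = effective_g_ho(source, conditions).value_umol_per_J
    return params.k_act_per_Gy * g_eff / params.reference_g_ho_umol_per_j


def thermal_relax(
    state: IsomerState, elapsed_h: float, params: SwitchParameters
) -> IsomerState:
    """Advance the state through dark first-order cis→trans relaxation."""
    elapsed_h = float(elapsed_h)
    if elapsed_h < 0:
        raise DomainError(f"elapsed time must be >= 0, got {elapsed_h}")
    decay = math.exp(-params.thermal_rate_per_h * elapsed_h)
    return replace(
        state,
        trans_fraction=1.0 - state.cis_fraction * decay,
        time_h=state.time_h + elapsed_h,
    )


def radiation_activate(
    state: IsomerState,
    dose_gy: float,
    params: SwitchParameters,
    source: RadiationSource | None = None,
    conditions: SolutionConditions | None = None,
) -> IsomerState:
    """Apply a dose of ionising radiation (treated as instantaneous).

    Monoexponential approach to all-trans, with rate constant rescaled by
    the effective HO• yield of the source/conditions pair.
    """
    dose_gy = float(dose_gy)
    if dose_gy < 0:
        raise DomainError(f"dose must be >= 0, got {dose_gy}")
    k_eff = effective_rate_constant(params, source, conditions)
    return replace(
        state,
        trans_fraction=1.0 - state.cis_fraction * math.exp(-k_eff * dose_gy),
    )


def predict_g_trans(
    cis_concentration_uM: float, dose_gy: float, params: SwitchParameters
) -> float:
    """Predicted G(trans) in molecules / 100 eV from the efficiency model.

        G = [cis]₀ · (a · ln D + b)

    Linear in concentration (no catalytic pathway) and decreasing in dose
    for a < 0 (energy is lost to non-specific reactions at high dose).
    Warns outside the fitted 2–20 Gy range; clips at zero (with a warning)
    where the linear-in-ln(D) form would go negative (~37 Gy at defaults).
    """
    if not cis_concentration_uM > 0:
        raise DomainError("cis concentration must be positive")
    dose_gy = float(dose_gy)
    if dose_gy <= 0:
        raise DomainError("dose must be positive (ln(dose) undefined at 0)")
    lo, hi = EFFICIENCY_DOSE_RANGE_GY
    if not lo <= dose_gy <= hi:
        warnings.warn(
            f"dose {dose_gy} Gy is outside the fitted {lo}-{hi} Gy range of "
            "the efficiency model; extrapolating",
            stacklevel=2,
        )
    per_uM = params.efficiency_a * math.log(dose_gy) + params.efficiency_b
    if per_uM < 0:
        warnings.warn(
            "efficiency model predicts a negative yield at this dose; "
            "clipping to 0",
            stacklevel=2,
        )
        per_uM = 0.0
    return cis_concentration_uM * per_uM


def fenton_equivalent_dose(
    trans_before: float,
    trans_after: float,
    params: SwitchParameters,
    source: RadiationSource | None = None,
    conditions: SolutionConditions | None = None,
) -> float:
    """Radiation dose (Gy) equivalent to a chemically induced trans jump.

    Inverts the monoexponential:  D = −ln[(1−after)/(1−before)] / k_eff.
    Round-trips exactly with :func:`radiation_activate`.
    """
    if not 0.0 <= trans_before <= 1.0 or not 0.0 <= trans_after <= 1.0:
        raise DomainError("trans fractions must lie in [0, 1]")
    # tolerate one-ulp rounding of a no-op jump; reject genuine reversals
    if trans_after < trans_before - 1e-12:
        raise DomainError(
            f"trans_after ({trans_after}) < trans_before ({trans_before}): "
            "a chemical oxidation cannot reduce the trans fraction"
        )
    if trans_after >= 1.0:
        raise DomainError(
            "trans_after = 1 corresponds to an infinite equivalent dose"
        )
    k_eff = effective_rate_constant(params, source, conditions)
    dose = math.log((1.0 - trans_before) / (1.0 - trans_after)) / k_eff
    return max(dose, 0.0)
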