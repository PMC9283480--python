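"""Estimators for the radioswitch assays.

Each estimator is the statistical inverse of a forward model in
:mod:`radioswitch.kinetics` / :mod:`radioswitch.radiolysis`:

* ``fit_activation_constant`` — activation constant k from the log-linear
  transform ln[(A0−Ainf)/(At−Ainf)] vs dose (ordinary least squares,
  through-origin by default);
* ``fit_g_value`` — radiochemical yield of trans formation at a given dose,
  corrected for thermal back relaxation with the paired dark-control plate;
* ``fit_g_ho`` — G(HO•) from the coumarin fluorescent-probe assay
  (standard-curve conversion, dose-slope regression, division by the 3.1%
  coumarin→7-hydroxycoumarin conversion yield);
* ``enhancement_profile`` — fractional G(HO•) enhancement vs [Gd³⁺];
* ``fit_thermal_half_life`` — dark-relaxation half-life from ln(1−trans);
* ``fit_efficiency_model`` — coefficients of G/[cis] = a·ln(dose) + b.

All regressions go through statsmodels OLS so standard errors and r² come
from standard regression theory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    ConfigurationError,
    DataError,
    DataOrderingError,
    DomainError,
    InsufficientDataError,
    PairingError,
)
from .kinetics import SwitchParameters, thermal_relax, IsomerState
from .units import RadiochemicalYield

Readout = Literal["trans_fraction", "absorbance_367nm"]


# --------------------------------------------------------------------------
# Data containers
# --------------------------------------------------------------------------

@dataclass
class DoseResponseSeries:
    """Paired irradiated/dark-control measurements vs cumulative dose.

    ``irradiated_values`` (plate 2) and ``control_values`` (plate 1, never
    irradiated, same wall-clock timestamps) share the readout: either the
    trans-isomer fraction directly (HPLC) or the absorbance at 367 nm.
    ``a0`` and ``a_inf`` are the readout at the start (PSS1) and at full
    trans conversion; ``trans0`` is the trans fraction the a0 endpoint
    corresponds to (default 0.10, i.e. 90% cis at PSS1).
    """

    doses_Gy: np.ndarray
    irradiated_values: np.ndarray
    timestamps_h: np.ndarray
    readout: Readout = "trans_fraction"
    control_values: np.ndarray | None = None
    a0: float | None = None
    a_inf: float | None = None
    trans0: float = 0.10
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses_Gy = np.asarray(self.doses_Gy, dtype=float)
        self.irradiated_values = np.asarray(self.irradiated_values, dtype=float)
        self.timestamps_h = np.asarray(self.timestamps_h, dtype=float)
        n = self.doses_Gy.size
        if self.irradiated_values.size != n or self.timestamps_h.size != n:
            raise DataError("doses, values and timestamps must have equal length")
        if self.control_values is not None:
            self.control_values = np.asarray(self.control_values, dtype=float)
            if self.control_values.size != n:
                raise DataError("control column length mismatch")
        if np.any(np.diff(self.doses_Gy) < 0):
            raise DataError("doses must be non-decreasing")
        if np.any(np.diff(self.timestamps_h) < 0):
            raise DataError("timestamps must be non-decreasing")
        if self.readout == "trans_fraction":
            if self.a0 is None:
                self.a0 = float(self.irradiated_values[0])
            if self.a_inf is None:
                self.a_inf = 1.0
        elif self.readout == "absorbance_367nm":
            if self.a0 is None or self.a_inf is None:
                raise DataError(
                    "absorbance series need calibrated a0 and a_inf endpoints"
                )
        else:
            raise DataError(f"unknown readout {self.readout!r}")

    def trans_fractions(self, which: str = "irradiated") -> np.ndarray:
        """Readout converted to trans fraction.

        Absorbance converts by linear two-component mixing at 367 nm
        (Beer–Lambert additivity of the two isomers):

            trans(A) = 1 − (1 − trans0) · (A − A_inf) / (A0 − A_inf)
        """
        values = (
            self.irradiated_values if which == "irradiated" else self.control_values
        )
        if values is None:
            raise PairingError("series has no control column")
        if self.readout == "trans_fraction":
            return values.copy()
        span = self.a0 - self.a_inf
        if span == 0:
            raise DataError("degenerate calibration: a0 == a_inf")
        return 1.0 - (1.0 - self.trans0) * (values - self.a_inf) / span


@dataclass(frozen=True)
class ActivationFit:
    """Result of the activation-constant regression."""

    k_per_Gy: float
    k_stderr: float
    r_squared: float
    n_points: int
    dose_range_Gy: tuple[float, float]
    intercept: float | None = None
    thermal_corrected: bool = False


@dataclass(frozen=True)
class GValueResult:
    """Radiochemical yield of trans formation at a single dose."""

    g: RadiochemicalYield
    corrected_for_thermal: bool
    dose_Gy: float
    initial_cis_uM: float
    stderr: float = 0.0
    correction_method: str = "paired-control"


@dataclass(frozen=True)
class HalfLifeFit:
    """Result of the thermal-relaxation regression."""

    half_life_h: float
    stderr_h: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class EfficiencyFit:
    """Coefficients of the logarithmic dose-efficiency model."""

    a: float
    b: float
    r_squared: float
    a_stderr: float
    b_stderr: float


@dataclass
class CoumarinAssayData:
    """Coumarin HO•-probe assay: fluorescence vs dose plus standard curve.

    The standard curve maps 7-hydroxycoumarin concentration (µM) to
    fluorescence (au): F = slope·c + intercept.  ``conversion_yield`` is
    the fraction of coumarin+HO• encounters that yield the fluorescent
    7-OH product (3.1%).
    """

    doses_Gy: np.ndarray
    fluorescence_au: np.ndarray
    standard_curve: tuple[float, float]
    conversion_yield: float = 0.031
    gd_concentration_uM: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses_Gy = np.asarray(self.doses_Gy, dtype=float)
        self.fluorescence_au = np.asarray(self.fluorescence_au, dtype=float)
        if self.doses_Gy.size != self.fluorescence_au.size:
            raise DataError("doses and fluorescence must have equal length")
        slope, _ = self.standard_curve
        if not slope > 0:
            raise ConfigurationError("standard-curve slope must be positive")
        if not 0.0 < self.conversion_yield <= 1.0:
            raise ConfigurationError("conversion_yield must lie in (0, 1]")


# --------------------------------------------------------------------------
# Estimators
# --------------------------------------------------------------------------

def _log_survival(trans: np.ndarray, trans0: float) -> np.ndarray:
    """y = ln[(1 − trans0) / (1 − trans)] — the monoexponential transform.

    In this variable radiation activation contributes k·D and thermal
    relaxation contributes λ·t additively, which is what makes the paired
    correction below exact for first-order processes.
    """
    return np.log((1.0 - trans0) / (1.0 - trans))


def fit_activation_constant(
    series: DoseResponseSeries,
    include_intercept: bool = False,
    thermal_correction: bool | None = None,
) -> ActivationFit:
    """Activation constant k (Gy⁻¹) from a dose-response series.

    Ordinary least squares of ln[(A0−Ainf)/(At−Ainf)] against dose,
    through-origin by default (the transform forces y = 0 at D = 0; an
    intercept can be requested for diagnostics).  When a paired dark
    control is present (``thermal_correction=None`` resolves to True in
    that case) the control's own log-survival drift is subtracted at
    matched timestamps, which removes the thermal contribution exactly.
    """
    if thermal_correction is None:
        thermal_correction = series.control_values is not None
    if thermal_correction and series.control_values is None:
        raise PairingError("thermal correction requested but no control column")

    trans_irr = series.trans_fractions("irradiated")
    positive = series.doses_Gy > 0
    if np.count_nonzero(positive) < 3:
        raise InsufficientDataError(
            f"need >= 3 dose points above 0 Gy, have {np.count_nonzero(positive)}"
        )

    trans0_irr = float(trans_irr[0])
    bad = positive & ~((trans_irr > trans0_irr) & (trans_irr < 1.0))
    if np.any(bad):
        dose = series.doses_Gy[bad][0]
        raise DataOrderingError(
            f"readout at dose {dose} Gy lies outside the open (A_inf, A0) "
            "interval; the monoexponential transform is undefined there"
        )

    y = _log_survival(trans_irr[positive], trans0_irr)
    if thermal_correction:
        trans_ctrl = series.trans_fractions("control")
        y_ctrl = _log_survival(trans_ctrl, float(trans_ctrl[0]))
        y = y - y_ctrl[positive]

    doses = series.doses_Gy[positive]
    X = sm.add_constant(doses) if include_intercept else doses[:, None]
    fit = sm.OLS(y, X).fit()
    slope_idx = 1 if include_intercept else 0
    return ActivationFit(
        k_per_Gy=float(fit.params[slope_idx]),
        k_stderr=float(fit.bse[slope_idx]),
        r_squared=float(min(max(fit.rsquared, 0.0), 1.0)),
        n_points=int(doses.size),
        dose_range_Gy=(float(doses.min()), float(doses.max())),
        intercept=float(fit.params[0]) if include_intercept else None,
        thermal_corrected=bool(thermal_correction),
    )


def fit_g_value(
    series: DoseResponseSeries,
    initial_cis_uM: float,
    dose_Gy: float,
    correct_thermal: bool = True,
    params: SwitchParameters | None = None,
    density_kg_per_l: float = 1.0,
) -> GValueResult:
    """Radiochemical yield of trans formation at one dose.

    The trans increment of the irradiated plate between the start and the
    row at ``dose_Gy`` is corrected by subtracting the dark control's
    increment at the matched timestamps, converted to µM via the switch
    pool (``initial_cis_uM`` of cis at PSS1, pool = initial_cis/(1−trans0)),
    divided by dose to give µmol/J, and re-expressed per 100 eV.

    Without a control column a model-based fallback subtracts the thermal
    drift predicted by ``params`` (flagged in ``correction_method``).
    """
    if not dose_Gy > 0:
        raise DomainError("dose must be positive")
    if not initial_cis_uM > 0:
        raise DomainError("initial cis concentration must be positive")

    idx = int(np.argmin(np.abs(series.doses_Gy - dose_Gy)))
    if not np.isclose(series.doses_Gy[idx], dose_Gy):
        raise DataError(f"series has no row at dose {dose_Gy} Gy")

    trans_irr = series.trans_fractions("irradiated")
    delta_irr = float(trans_irr[idx] - trans_irr[0])

    method = "none"
    delta_ctrl = 0.0
    if correct_thermal:
        if series.control_values is not None:
            trans_ctrl = series.trans_fractions("control")
            delta_ctrl = float(trans_ctrl[idx] - trans_ctrl[0])
            method = "paired-control"
        elif params is not None:
            elapsed = float(series.timestamps_h[idx] - series.timestamps_h[0])
            start = IsomerState(series.trans0, max(initial_cis_uM, 1e-12))
            delta_ctrl = (
                thermal_relax(start, elapsed, params).trans_fraction
                - start.trans_fraction
            )
            method = "model-based"
        else:
            raise PairingError(
                "thermal correction requested but the series has no control "
                "column and no SwitchParameters fallback was provided"
            )

    delta_corr = delta_irr - delta_ctrl
    pool_uM = initial_cis_uM / (1.0 - series.trans0)
    delta_uM = delta_corr * pool_uM
    g_umol_per_j = delta_uM / (dose_Gy * density_kg_per_l)
    if g_umol_per_j < 0:
        # a yield cannot be negative; warn with the signed value and clip
        warnings.warn(
            f"corrected trans increment is negative ({delta_uM:.3g} µM, "
            f"{g_umol_per_j:.3g} µmol/J); reporting G = 0",
            stacklevel=2,
        )
        method += " (negative increment)"
        g_umol_per_j = 0.0
    return GValueResult(
        g=RadiochemicalYield(g_umol_per_j, species="trans-isomer"),
        corrected_for_thermal=not method.startswith("none"),
        dose_Gy=float(dose_Gy),
        initial_cis_uM=float(initial_cis_uM),
        stderr=0.0,
        correction_method=method,
    )


def bootstrap_g_value(
    series_list: Sequence[DoseResponseSeries],
    initial_cis_uM: float,
    dose_Gy: float,
    n_boot: int = 1000,
    seed: int = 0,
    **kwargs,
) -> tuple[float, float]:
    """Seeded bootstrap over replicate series: mean and SD of G (per 100 eV).

    Requires >= 3 replicate series (the experiments report n = 3 means ± SD).
    """
    if len(series_list) < 3:
        raise InsufficientDataError("bootstrap needs >= 3 replicate series")
    g_values = np.array(
        [
            fit_g_value(s, initial_cis_uM, dose_Gy, **kwargs).g.value_per_100eV
            for s in series_list
        ]
    )
    rng = np.random.default_rng(seed)
    draws = rng.choice(g_values, size=(n_boot, g_values.size), replace=True)
    means = draws.mean(axis=1)
    return float(means.mean()), float(means.std(ddof=1))


def fit_g_ho(assay: CoumarinAssayData) -> RadiochemicalYield:
    """G(HO•) in µmol/J from the coumarin fluorescent-probe assay.

    Fluorescence → [7-OH-Coum] via the standard curve; an OLS slope of
    concentration vs dose gives G(7-OH-Coum) in µM/Gy ≡ µmol/J (density
    1 kg/L); dividing by the coumarin conversion yield gives G(HO•).
    """
    if assay.doses_Gy.size < 3:
        raise InsufficientDataError("need >= 3 dose points")
    slope_sc, intercept_sc = assay.standard_curve
    conc_uM = (assay.fluorescence_au - intercept_sc) / slope_sc
    X = sm.add_constant(assay.doses_Gy)
    fit = sm.OLS(conc_uM, X).fit()
    g_7ohc = float(fit.params[1])
    if g_7ohc <= 0:
        warnings.warn(
            f"fitted 7-OH-coumarin dose slope is non-positive ({g_7ohc:.3g} "
            "µM/Gy); reporting G = 0",
            stacklevel=2,
        )
        return RadiochemicalYield(0.0, species="HO•")
    return RadiochemicalYield(g_7ohc / assay.conversion_yield, species="HO•")


def enhancement_profile(
    g_by_gd: Mapping[float, RadiochemicalYield | float],
) -> tuple[dict[float, float], tuple[float, float]]:
    """Fractional enhancement vs [Gd³⁺] and its maximum.

    enhancement(c) = G(c)/G(0) − 1.  Requires the 0 µM baseline entry.
    Returns (profile, (argmax concentration, max enhancement)).
    """
    def as_value(v) -> float:
        return v.value_umol_per_J if isinstance(v, RadiochemicalYield) else float(v)

    baseline = None
    for c, v in g_by_gd.items():
        if float(c) == 0.0:
            baseline = as_value(v)
    if baseline is None or baseline <= 0:
        raise DataError(
            "enhancement profile requires a positive baseline yield at 0 µM"
        )
    profile = {
        float(c): as_value(v) / baseline - 1.0 for c, v in g_by_gd.items()
    }
    c_max = max(profile, key=profile.get)
    return profile, (c_max, profile[c_max])


def fit_thermal_half_life(
    times_h: np.ndarray | pd.DataFrame,
    trans_fractions: np.ndarray | None = None,
) -> HalfLifeFit:
    """Thermal back-relaxation half-life from a dark time course.

    OLS of ln(1 − trans) vs time (intercept fitted); t½ = ln2/|slope|,
    stderr propagated by the delta method.  Saturated points (trans ≥ 1)
    are filtered with a warning; a non-monotone course raises a warning
    but the points are kept (noise jitter is expected).  A course that
    shows no decay (slope ≥ 0) raises InsufficientDataError.
    """
    if isinstance(times_h, pd.DataFrame):
        df = times_h
        times = df["time_h"].to_numpy(dtype=float)
        trans = df["trans_fraction"].to_numpy(dtype=float)
    else:
        times = np.asarray(times_h, dtype=float)
        trans = np.asarray(trans_fractions, dtype=float)
    if times.size != trans.size:
        raise DataError("times and fractions must have equal length")

    keep = np.isfinite(trans) & (trans < 1.0)
    if np.any(~keep):
        warnings.warn(
            f"filtered {np.count_nonzero(~keep)} saturated/invalid point(s) "
            "(trans >= 1)",
            stacklevel=2,
        )
    times, trans = times[keep], trans[keep]
    if times.size < 4:
        raise InsufficientDataError(
            f"need >= 4 usable points after filtering, have {times.size}"
        )
    if np.any(np.diff(trans) < 0):
        warnings.warn(
            "relaxation course is not monotone; proceeding (noise jitter)",
            stacklevel=2,
        )

    y = np.log(1.0 - trans)
    X = sm.add_constant(times)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    if slope >= 0:
        raise InsufficientDataError(
            "no thermal decay detected (non-negative slope of ln(1-trans))"
        )
    se_slope = float(fit.bse[1])
    half_life = np.log(2.0) / abs(slope)
    return HalfLifeFit(
        half_life_h=float(half_life),
        stderr_h=float(np.log(2.0) * se_slope / slope**2),
        r_squared=float(fit.rsquared),
        n_points=int(times.size),
    )


def fit_efficiency_model(
    g_per_conc_by_dose: Mapping[float, float],
) -> EfficiencyFit:
    """Coefficients (a, b) of Y = a·ln(dose) + b by ordinary least squares.

    Y is the per-concentration G-value slope (G-value per µM of cis) at
    each dose.  Requires >= 3 strictly positive doses.
    """
    doses = np.array([float(d) for d in g_per_conc_by_dose], dtype=float)
    if np.any(doses <= 0):
        raise DomainError("all doses must be strictly positive (ln undefined)")
    if doses.size < 3:
        raise InsufficientDataError(
            f"need >= 3 doses to fit two coefficients, have {doses.size}"
        )
    y = np.array([g_per_conc_by_dose[d] for d in g_per_conc_by_dose], dtype=float)
    X = sm.add_constant(np.log(doses))
    fit = sm.OLS(y, X).fit()
    return EfficiencyFit(
        a=float(fit.params[1]),
        b=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        a_stderr=float(fit.bse[1]),
        b_stderr=float(fit.bse[0]),
    )
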