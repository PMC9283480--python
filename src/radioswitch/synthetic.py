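"""Seeded generators for every assay the estimators consume.

Emulates the experimental designs used to characterise the radioswitch:

* paired-plate dose-response series (plate 1 dark control / plate 2
  irradiated in increments, measured concurrently with a preparation lag),
* dark thermal-relaxation time courses,
* coumarin-probe fluorescence vs dose with a 7-hydroxycoumarin standard
  curve,
* G(HO•) vs [Gd³⁺] tables,
* two-band absorbance spectra (cis 322 nm / trans 367 nm).

Randomness: one root seed; each assay type draws from a deterministic
child stream so outputs are bit-identical for identical seeds and
parameters regardless of generation order.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .inference import CoumarinAssayData, DoseResponseSeries
from .kinetics import (
    IsomerState,
    SwitchParameters,
    pss1_state,
    radiation_activate,
    thermal_relax,
)
from .radiolysis import (
    RadiationSource,
    SolutionConditions,
    WATER,
    effective_g_ho,
)
from .units import RadiochemicalYield, species_concentration_from_dose

#: Stream offsets keeping assay types statistically independent per seed.
_STREAMS = {
    "dose_response": 1,
    "relaxation": 2,
    "coumarin": 3,
    "gd_table": 4,
    "spectrum": 5,
}


@dataclass(frozen=True)
class AssayNoiseModel:
    """Measurement-noise magnitudes for the synthetic assays.

    Additive Gaussian noise on absorbance (OD) and on fractions (clipped to
    [0, 1]); multiplicative Gaussian noise on fluorescence and on yield
    tables.  Defaults approximate the few-percent triplicate scatter of the
    wet assays.
    """

    absorbance_sigma: float = 0.01
    fraction_sigma: float = 0.018
    fluorescence_sigma_rel: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("absorbance_sigma", "fraction_sigma", "fluorescence_sigma_rel"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic child generator for one assay type."""
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


ZERO_NOISE = AssayNoiseModel(0.0, 0.0, 0.0, seed=0)


@dataclass(frozen=True)
class SpectrumModel:
    """Gaussian-band model of the two pure-isomer UV-vis spectra.

    The cis isomer absorbs at 322 nm, the trans isomer at 367 nm with much
    higher intensity; a mixture spectrum is the fraction-weighted sum of
    the pure spectra.  Peak extinctions are absorbance per µM per cm.
    """

    band_centers_nm: Mapping[str, float] = field(
        default_factory=lambda: {"cis": 322.0, "trans": 367.0}
    )
    band_widths_nm: Mapping[str, float] = field(
        default_factory=lambda: {"cis": 28.0, "trans": 30.0}
    )
    peak_extinctions_per_uM: Mapping[str, float] = field(
        default_factory=lambda: {"cis": 0.010, "trans": 0.022}
    )
    wavelength_grid_nm: tuple[float, ...] = tuple(np.arange(250.0, 501.0, 1.0))

    def pure_absorbance(self, isomer: str, wavelength_nm: np.ndarray) -> np.ndarray:
        """Absorbance per µM of a pure isomer at given wavelengths."""
        mu = self.band_centers_nm[isomer]
        sig = self.band_widths_nm[isomer]
        amp = self.peak_extinctions_per_uM[isomer]
        wl = np.asarray(wavelength_nm, dtype=float)
        return amp * np.exp(-0.5 * ((wl - mu) / sig) ** 2)

    def absorbance(self, state: IsomerState, wavelength_nm) -> np.ndarray:
        """Mixture absorbance: fraction-weighted sum of the pure spectra."""
        wl = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
        a = state.total_concentration_uM * (
            state.trans_fraction * self.pure_absorbance("trans", wl)
            + state.cis_fraction * self.pure_absorbance("cis", wl)
        )
        return a


DEFAULT_SPECTRUM = SpectrumModel()


def _measure(
    trans_true: np.ndarray,
    readout: str,
    noise: AssayNoiseModel,
    rng: np.random.Generator,
    replicates: int,
    spectrum: SpectrumModel,
    total_uM: float,
) -> np.ndarray:
    """Replicate-averaged noisy measurement of a vector of trans fractions."""
    n = trans_true.size
    if readout == "trans_fraction":
        draws = trans_true[None, :] + noise.fraction_sigma * rng.standard_normal(
            (replicates, n)
        )
        draws = np.clip(draws, 0.0, 1.0)
    else:  # absorbance at 367 nm
        a_true = np.array(
            [
                float(
                    spectrum.absorbance(
                        IsomerState(t, total_uM), 367.0
                    )[0]
                )
                for t in trans_true
            ]
        )
        draws = a_true[None, :] + noise.absorbance_sigma * rng.standard_normal(
            (replicates, n)
        )
    return draws.mean(axis=0)


def gen_dose_response(
    params: SwitchParameters,
    source: RadiationSource,
    conditions: SolutionConditions = WATER,
    doses_Gy: Sequence[float] = (0.0, 2.0, 3.0, 5.0, 10.0),
    readout: str = "trans_fraction",
    noise: AssayNoiseModel = ZERO_NOISE,
    lag_h: float = 0.5,
    interval_h: float = 0.25,
    replicates: int = 3,
    total_uM: float = 50.0,
    spectrum: SpectrumModel = DEFAULT_SPECTRUM,
) -> DoseResponseSeries:
    """Paired-plate dose-response series.

    Plate 2 is irradiated in increments (instantaneous activation at each
    step) and relaxes thermally between measurements spaced ``interval_h``
    apart; plate 1 (control) was prepared ``lag_h`` earlier, is never
    irradiated, and relaxes only.  Both are measured at the same wall-clock
    timestamps with replicate-averaged noise.
    """
    doses = np.asarray(doses_Gy, dtype=float)
    if doses.size == 0 or doses[0] != 0 or np.any(np.diff(doses) < 0):
        raise DomainError("doses must be non-decreasing and start at 0 Gy")
    rng = noise.rng("dose_response")
    timestamps = np.arange(doses.size) * float(interval_h)

    irr = pss1_state(params, total_uM)
    ctrl = thermal_relax(pss1_state(params, total_uM), lag_h, params)
    trans_irr = [irr.trans_fraction]
    trans_ctrl = [ctrl.trans_fraction]
    for i in range(1, doses.size):
        irr = thermal_relax(irr, interval_h, params)
        irr = radiation_activate(irr, doses[i] - doses[i - 1], params, source, conditions)
        ctrl = thermal_relax(ctrl, interval_h, params)
        trans_irr.append(irr.trans_fraction)
        trans_ctrl.append(ctrl.trans_fraction)
    trans_irr = np.array(trans_irr)
    trans_ctrl = np.array(trans_ctrl)

    meas_irr = _measure(trans_irr, readout, noise, rng, replicates, spectrum, total_uM)
    meas_ctrl = _measure(trans_ctrl, readout, noise, rng, replicates, spectrum, total_uM)

    trans0 = params.pss1_trans_fraction
    if readout == "absorbance_367nm":
        a0 = float(spectrum.absorbance(IsomerState(trans0, total_uM), 367.0)[0])
        a_inf = float(spectrum.absorbance(IsomerState(1.0, total_uM), 367.0)[0])
    else:
        a0, a_inf = trans0, 1.0

    return DoseResponseSeries(
        doses_Gy=doses,
        irradiated_values=meas_irr,
        control_values=meas_ctrl,
        timestamps_h=timestamps,
        readout=readout,
        a0=a0,
        a_inf=a_inf,
        trans0=trans0,
        metadata={
            "generator": "gen_dose_response",
            "seed": noise.seed,
            "source": source.name,
            "gas": conditions.gas,
            "gd_concentration_uM": conditions.gd_concentration_uM,
            "k_act_per_Gy": params.k_act_per_Gy,
            "thermal_half_life_h": params.thermal_half_life_h,
            "pss1_cis_fraction": params.pss1_cis_fraction,
            "lag_h": lag_h,
            "interval_h": interval_h,
            "replicates": replicates,
            "total_uM": total_uM,
            "noise": asdict(noise),
        },
    )


def gen_relaxation_course(
    params: SwitchParameters,
    duration_h: float = 8.0,
    n_points: int = 8,
    noise: AssayNoiseModel = ZERO_NOISE,
    start_trans: float | None = None,
) -> pd.DataFrame:
    """Dark thermal-relaxation time course (columns time_h, trans_fraction)."""
    if n_points < 2:
        raise DomainError("need at least 2 time points")
    if duration_h <= 0:
        raise DomainError("duration must be positive")
    rng = noise.rng("relaxation")
    t0 = params.pss1_trans_fraction if start_trans is None else float(start_trans)
    times = np.linspace(0.0, duration_h, n_points)
    trans = 1.0 - (1.0 - t0) * np.exp(-params.thermal_rate_per_h * times)
    trans = np.clip(
        trans + noise.fraction_sigma * rng.standard_normal(n_points), 0.0, 1.0
    )
    return pd.DataFrame({"time_h": times, "trans_fraction": trans})


def gen_coumarin_assay(
    source: RadiationSource,
    conditions: SolutionConditions = WATER,
    doses_Gy: Sequence[float] = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0),
    standard_curve: tuple[float, float] = (1500.0, 30.0),
    noise: AssayNoiseModel = ZERO_NOISE,
    conversion_yield: float = 0.031,
    coumarin_mM: float = 0.5,
) -> CoumarinAssayData:
    """Coumarin-probe fluorescence assay for G(HO•).

    [7-OH-Coum](D) = conversion_yield × G_eff(HO•) × D; fluorescence is the
    standard curve applied to that concentration with multiplicative noise.
    """
    doses = np.asarray(doses_Gy, dtype=float)
    rng = noise.rng("coumarin")
    g_eff = effective_g_ho(source, conditions).value_umol_per_J
    conc_7ohc = conversion_yield * np.array(
        [species_concentration_from_dose(d, g_eff) for d in doses]
    )
    slope, intercept = standard_curve
    fluo = slope * conc_7ohc + intercept
    fluo = fluo * (
        1.0 + noise.fluorescence_sigma_rel * rng.standard_normal(doses.size)
    )
    return CoumarinAssayData(
        doses_Gy=doses,
        fluorescence_au=fluo,
        standard_curve=standard_curve,
        conversion_yield=conversion_yield,
        gd_concentration_uM=conditions.gd_concentration_uM,
        metadata={
            "generator": "gen_coumarin_assay",
            "seed": noise.seed,
            "source": source.name,
            "gas": conditions.gas,
            "coumarin_mM": coumarin_mM,
            "g_eff_umol_per_J": g_eff,
            "noise": asdict(noise),
        },
    )


def gen_gd_enhancement_table(
    source: RadiationSource,
    concentrations_uM: Sequence[float] = (0.0, 10.0, 25.0, 100.0, 200.0, 500.0, 1000.0, 2000.0),
    noise: AssayNoiseModel = ZERO_NOISE,
    gas: str = "none",
) -> dict[float, RadiochemicalYield]:
    """G(HO•) vs [Gd³⁺] table from the built-in enhancement curve.

    Always includes the 0 µM baseline.  Noise is multiplicative with the
    fluorescence relative SD (the measurement behind the table is the
    coumarin assay).
    """
    conc = [float(c) for c in concentrations_uM]
    if 0.0 not in conc:
        conc = [0.0] + conc
    rng = noise.rng("gd_table")
    table: dict[float, RadiochemicalYield] = {}
    for c in conc:
        g = effective_g_ho(
            source, SolutionConditions(gas=gas, gd_concentration_uM=c)
        ).value_umol_per_J
        g *= 1.0 + noise.fluorescence_sigma_rel * rng.standard_normal()
        table[c] = RadiochemicalYield(max(g, 0.0), species="HO•")
    return table


def gen_absorbance_spectrum(
    state: IsomerState,
    model: SpectrumModel = DEFAULT_SPECTRUM,
    noise: AssayNoiseModel = ZERO_NOISE,
) -> pd.DataFrame:
    """Full mixture spectrum (columns wavelength_nm, absorbance)."""
    rng = noise.rng("spectrum")
    wl = np.asarray(model.wavelength_grid_nm, dtype=float)
    a = model.absorbance(state, wl)
    a = a + noise.absorbance_sigma * rng.standard_normal(wl.size)
    return pd.DataFrame({"wavelength_nm": wl, "absorbance": a})
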