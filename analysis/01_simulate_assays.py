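#!/usr/bin/env python
"""Generate the synthetic assay corpus for the downstream analyses.

Emulates the activation study's four assay designs for all three radiation
sources (γ 662 keV, X-ray 80 keV, electron 4.5 MeV): paired-plate
dose-response series, dark relaxation time courses, coumarin HO•-probe
assays, and G(HO•)-vs-[Gd³⁺] tables.  Everything downstream
(02–05) reads from results/synthetic/.
"""

from pathlib import Path

import radioswitch as rs
from radioswitch.io import (
    write_coumarin_assay,
    write_dose_response,
    write_gd_table,
    write_timecourse,
)
from radioswitch.synthetic import AssayNoiseModel

SEED = 20260922
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = rs.SwitchParameters()
    noise = AssayNoiseModel(seed=SEED)

    for name, source in rs.SOURCE_PRESETS.items():
        outdir = OUT / name
        outdir.mkdir(exist_ok=True)
        # low-dose series for the activation-constant fit (0.5 Gy steps)
        write_dose_response(
            rs.gen_dose_response(
                params, source, doses_Gy=[0.0, 0.5, 1.0, 1.5, 2.0], noise=noise
            ),
            outdir / "dose_response_low.csv",
        )
        # clinical-dose series (2-10 Gy increments) for G-value work
        write_dose_response(
            rs.gen_dose_response(
                params, source, doses_Gy=[0.0, 2.0, 3.0, 5.0, 10.0], noise=noise
            ),
            outdir / "dose_response_clinical.csv",
        )
        write_coumarin_assay(
            rs.gen_coumarin_assay(source, noise=noise), outdir / "coumarin.csv"
        )
        write_gd_table(
            rs.gen_gd_enhancement_table(source, noise=noise),
            outdir / "gd_table.csv",
            meta={"source": name, "seed": SEED},
        )
        print(f"{name}: corpus written to {outdir}")

    write_timecourse(
        rs.gen_relaxation_course(
            params, noise=AssayNoiseModel(fraction_sigma=0.01, seed=SEED)
        ),
        OUT / "relaxation.csv",
        meta={"seed": SEED},
    )
    print(f"relaxation time course written to {OUT/'relaxation.csv'}")
    print(f"root seed {SEED}; regenerate by re-running this script")


if __name__ == "__main__":
    main()
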