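#!/usr/bin/env python
"""Gradient-elution prediction for purified mAb at varying gradient length.

Simulates 100 µL injections of 4 mg/mL mAb at 3 mL/min with linear
20-500 mM salt gradients of 5, 7.5 and 10 column volumes, and summarises
retention, width and height: longer (shallower) gradients broaden and
lower the elution peak.  Writes results/gradient_prediction.csv and the
outlet chromatograms.
"""

from pathlib import Path

import pandas as pd

from fiberchrom import (
    Component,
    FlowProgram,
    GroundTruth,
    SolverSettings,
    assemble_system,
    peak_moments,
    simulate,
)
from fiberchrom.solver import _fwhm

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    truth = GroundTruth()
    mab = Component("mAb", 4.00e-11, binding=truth.binding["mAb"])
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for cv in (5.0, 7.5, 10.0):
        prog = FlowProgram.bind_wash_elute(load={"mAb": 4.0}, gradient_cv=cv)
        system = assemble_system(truth.bed, [mab], {}, prog,
                                 settings=SolverSettings())
        res = simulate(system)
        t, y = res.column_outlet.time_s, res.column_outlet.signal("mAb")
        m = peak_moments(t, y)
        rows.append({"gradient_cv": cv, "retention_s": m.mu,
                     "fwhm_s": _fwhm(t, y), "peak_max_mg_ml": float(y.max()),
                     "eluted_mg": res.mass_balance.set_index("species")
                     .loc["mAb", "eluted_mg"]})
        # downsampled, fixed-precision copy keeps the stored table compact
        frame = res.column_outlet.to_frame().iloc[::3]
        frame.to_csv(RESULTS / f"gradient_{cv:g}cv_chromatogram.csv",
                     index=False, float_format="%.5g")
        print(f"{cv:4.1f} CV gradient: retention {m.mu:6.1f} s, "
              f"FWHM {_fwhm(t, y):5.1f} s, peak {y.max():.3f} mg/mL")
    pd.DataFrame(rows).to_csv(RESULTS / "gradient_prediction.csv", index=False)
    print("longer gradients broaden the peak and lower its maximum")
    print(f"wrote {RESULTS / 'gradient_prediction.csv'}")


if __name__ == "__main__":
    main()
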