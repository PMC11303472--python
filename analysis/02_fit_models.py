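#!/usr/bin/env python
"""Fit the base and FFM covariate models to the reference synthetic study.

Reads results/study.csv (run 01 first), fits both models by SAEM, computes
their importance-sampling OFV/BICc with a shared Monte Carlo seed, and
writes estimate tables plus a base-vs-FFM comparison.  The printed summary
reports each recovered parameter next to the generating value.
"""

from pathlib import Path

import pandas as pd

from rifpk import SAEMSettings, fit_saem, load_preset, read_event_table
from rifpk.saem import ofv

SEED = 20260930
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_event_table(OUT / "study.csv", lloq=0.1)
    rows = []
    fits = {}
    for pid in ("base", "ffm"):
        model = load_preset(pid)
        fit = fit_saem(table, model, SAEMSettings(seed=SEED + hash(pid) % 97),
                       compute_ofv=False)
        val, se = ofv(table, fit.model, fit, mc_size=4000, seed=SEED)
        fits[pid] = (fit, val, se)
        fit.summary().to_csv(OUT / f"estimates_{pid}.csv", index=False)
        truth = load_preset("ffm").theta
        print(f"\n== {pid} model ==  OFV {val:.2f} (MC-SE {se:.2f})")
        for p in ("Tlag", "Tk0", "V", "Vmax", "Km"):
            print(f"  {p:5s} {fit.theta[p]:8.3f}   (generating value "
                  f"{truth[p]:.3f})")
        print(f"  IIV Vmax (CV%) {fit.iiv_cv.get('Vmax', float('nan')):6.1f}"
              f"   prop err (%) {100 * fit.error_b:5.2f}")

    delta = fits["base"][1] - fits["ffm"][1]
    print(f"\nOFV drop from adding FFM on V/F and Vmax/F: {delta:.1f} "
          "(the study this design emulates reported 56.4)")
    pd.DataFrame([
        {"model": pid, "ofv": v, "ofv_mc_se": s}
        for pid, (_f, v, s) in fits.items()
    ]).to_csv(OUT / "model_comparison.csv", index=False)


if __name__ == "__main__":
    main()
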