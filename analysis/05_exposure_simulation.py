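#!/usr/bin/env python
"""Monte Carlo exposure: AUC versus fat-free mass at a 600 mg oral dose.

10,000 virtual subjects per FFM grid value (30-60 kg female, 50-80 kg male)
under the FFM covariate model, and one covariate-free band under the base
model.  Each grid value is annotated with the body weight of a
typical-height individual (1.65 m female, 1.85 m male).  Prints the
median (5th-95th) AUC per grid point and writes results/exposure.csv.
"""

from pathlib import Path

import numpy as np

from rifpk import load_preset
from rifpk.exposure import simulate_exposure

SEED = 20261003
N_VIRTUAL = 10_000
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    model = load_preset("ffm", resolve_fallback_references=True)
    base = load_preset("base")
    summ = simulate_exposure(model, 600.0, n_virtual=N_VIRTUAL,
                             rng=np.random.default_rng(SEED),
                             base_model=base)
    summ.to_csv(OUT / "exposure.csv", index=False)

    print("model  sex     FFM(kg)  BW(kg)   AUC median (5th-95th)  [mg*h/L]")
    for _, r in summ.iterrows():
        ffm = f"{r['FFM']:.0f}" if isinstance(r["FFM"], float) else "-"
        bw = f"{r['BW']:.1f}" if np.isfinite(r["BW"]) else "-"
        print(f"{r['model']:<6} {r['sex']:<7} {ffm:>6}  {bw:>6}   "
              f"{r['auc_median']:7.1f} ({r['auc_p05']:.1f}-{r['auc_p95']:.1f})")

    cov = summ[summ["model"] != "base"]
    base_row = summ[summ["model"] == "base"].iloc[0]
    bw_base = base_row["auc_p95"] - base_row["auc_p05"]
    print(f"\ncovariate-free 90% band width: {bw_base:.1f}; "
          f"FFM-conditional widths {cov['auc_p95'].sub(cov['auc_p05']).min():.1f}"
          f"-{cov['auc_p95'].sub(cov['auc_p05']).max():.1f} "
          "(conditioning on FFM removes a large share of the variability)")


if __name__ == "__main__":
    main()
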