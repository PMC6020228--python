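"""One-site binding fits: exact recovery and noise robustness.

Fits Y = Bmax·X/(Kd+X) to curves generated from the published equilibrium
SPR parameters of wild-type and F57A P2 binding to DOPC:DOPS vesicles
(wt: Bmax 1466 R.U., Kd 3.1 μM; F57A: Bmax 1408 R.U., Kd 6.2 μM) over the
0.1–15 μM concentration ladder.  Noise-free curves are recovered exactly;
a 200-replicate sweep at 2 % noise quantifies estimator spread.
"""

import json
from pathlib import Path

import numpy as np

from portalwatch.binding_fit import fit_one_site
from portalwatch.synthetic_data import (DEFAULT_SPR_CONCENTRATIONS,
                                        simulate_binding)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 2024
TABLE_PARAMS = {"wt": (1466.0, 3.1), "f57a": (1408.0, 6.2)}
report = {"seed": SEED, "concentrations_uM": DEFAULT_SPR_CONCENTRATIONS.tolist()}

for variant, (bmax, kd) in TABLE_PARAMS.items():
    clean = fit_one_site(simulate_binding(DEFAULT_SPR_CONCENTRATIONS, bmax, kd))
    kds, bmaxs = [], []
    for rep in range(200):
        noisy = simulate_binding(DEFAULT_SPR_CONCENTRATIONS, bmax, kd,
                                 noise_sd=0.02 * bmax, seed=SEED + rep)
        fit = fit_one_site(noisy)
        kds.append(fit.kd)
        bmaxs.append(fit.bmax)
    report[variant] = {
        "generating": {"Bmax_RU": bmax, "Kd_uM": kd},
        "noise_free_fit": {"Bmax_RU": round(clean.bmax, 3),
                           "Kd_uM": round(clean.kd, 5),
                           "R2": round(clean.r_squared, 6)},
        "noisy_200_replicates": {
            "Kd_median_uM": round(float(np.median(kds)), 3),
            "Kd_iqr_uM": [round(float(np.percentile(kds, 25)), 3),
                          round(float(np.percentile(kds, 75)), 3)],
            "Bmax_median_RU": round(float(np.median(bmaxs)), 1),
        },
    }
    print(f"{variant}: noise-free fit Bmax {clean.bmax:.1f} R.U., "
          f"Kd {clean.kd:.4f} uM, R2 {clean.r_squared:.6f}")
    print(f"       2% noise, 200 replicates: median Kd {np.median(kds):.3f} uM "
          f"(truth {kd}), median Bmax {np.median(bmaxs):.0f} R.U. (truth {bmax:.0f})")

ratio = report["f57a"]["noise_free_fit"]["Kd_uM"] / report["wt"]["noise_free_fit"]["Kd_uM"]
report["kd_ratio_f57a_over_wt"] = round(ratio, 3)
print(f"Kd ratio F57A/wt = {ratio:.2f}: the mutant binds the membrane "
      f"surface ~2-fold more weakly at similar saturation")

(OUT / "binding_report.json").write_text(json.dumps(report, indent=2) + "\n")
print(f"wrote binding_report.json to {OUT}")
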