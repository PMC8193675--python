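"""Fit the QE-TMDD population model to the synthetic dataset by FOCE-I.

Starts from initial values deliberately displaced from the generating
truth (30-100% on the typical values, doubled variabilities) so the run
demonstrates genuine estimation, with the binding constant KD and the
internalisation rate kint held fixed as in the published analysis.
Writes the estimate table and a text report.
"""

import time
from dataclasses import replace
from pathlib import Path

import pandas as pd

from ropepk.dataset import read_dataset
from ropepk.nlme import cv_percent, fit
from ropepk.trial_data import final_model, final_structural

OUT = Path(__file__).resolve().parent.parent / "results"


def perturbed_initials():
    truth = final_model()
    init = truth.copy()
    init.theta = dict(truth.theta)
    init.theta["cl"] *= 1.4
    init.theta["v"] *= 0.7
    init.theta["ka"] *= 1.3
    init.theta["tlag"] *= 1.5
    init.theta["r0"] *= 2.0
    init.theta["kdeg"] *= 0.5
    init.covariate_links = [replace(truth.covariate_links[0], coef=0.5)]
    init.omega2 = {k: 2 * v for k, v in truth.omega2.items()}
    init.sigma2 = {k: 2 * v for k, v in truth.sigma2.items()}
    return init


def main() -> None:
    ds = read_dataset(OUT / "dataset.csv")
    t0 = time.perf_counter()
    # below-LLOQ samples handled as censored likelihood terms (M3)
    res = fit(ds, perturbed_initials(), final_structural(),
              estimate_se=False, inner_tol=1e-6, outer_maxfev=1300, blq="m3",
              outer_time_limit=600.0)
    print(f"fit finished in {time.perf_counter() - t0:.0f}s: {res.convergence_status}")
    print(f"OFV {res.ofv:.2f}  AIC {res.aic:.2f}  BIC {res.bic:.2f}")

    rep = res.estimates_reported()
    published = {"cl": 0.778, "v": 2.32, "ka": 0.14, "tlag": 0.426,
                 "r0": 0.111, "kdeg": 0.544, "cl~weight": 0.927}
    rows = []
    for name, pub in published.items():
        est = rep[name]
        rows.append({"parameter": name, "estimate": est, "generating": pub,
                     "rel_err_pct": 100 * (est - pub) / pub})
    for name, cv_pub in (("cl", 35.7), ("v", 90.8), ("ka", 63.5)):
        cv = cv_percent(res.model.omega2[name])
        rows.append({"parameter": f"bsv_cv_{name}", "estimate": cv,
                     "generating": cv_pub, "rel_err_pct": 100 * (cv - cv_pub) / cv_pub})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "fit-recovery.csv", index=False)
    print(table.round(3).to_string(index=False))
    print("\neta-shrinkage %:", {k: round(v, 1) for k, v in res.eta_shrinkage_percent.items()})


if __name__ == "__main__":
    main()
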