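"""Model evaluation: goodness-of-fit residuals, pc-VPC and bootstrap.

Evaluates the final QE-TMDD model against the synthetic dataset: CWRES
calibration, prediction-corrected VPC percentile coverage, and a
subject-resampling bootstrap (stratified by study).  The bootstrap size is
configurable; the published analysis used 1,000 replicates, which is also
the default here (expect a multi-hour run; pass a smaller n for a quick
look).
"""

import sys
from pathlib import Path

import pandas as pd

from ropepk.dataset import read_dataset
from ropepk.diagnostics import bootstrap, gof_residuals, pc_vpc
from ropepk.nlme import fit
from ropepk.trial_data import DEFAULT_SEED, final_model, final_structural

OUT = Path(__file__).resolve().parent.parent / "results"


def main(n_bootstrap: int = 1000, n_sim: int = 1000) -> None:
    ds = read_dataset(OUT / "dataset.csv")
    model = final_model()
    structural = final_structural()

    print("evaluating the final model at its published values (EBEs + residuals)...")
    res = fit(ds, model, structural, estimate_se=False, evaluate_only=True)
    gof = gof_residuals(res, ds, structural)
    gof.to_csv(OUT / "gof-residuals.csv", index=False)
    print(f"CWRES: mean {gof['cwres'].mean():+.3f}, variance {gof['cwres'].var():.3f} "
          f"over {len(gof)} observations")

    print(f"\npc-VPC with {n_sim} simulated replicates...")
    vpc = pc_vpc(model, structural, ds, n_sim=n_sim, seed=DEFAULT_SEED)
    rows = []
    for k, (lo, hi) in enumerate(vpc.bin_edges):
        for j, q in enumerate(vpc.percentiles):
            rows.append({"bin_lo": lo, "bin_hi": hi, "n": vpc.n_obs[k], "pct": q,
                         "observed": vpc.observed[k, j], "sim_lower": vpc.sim_lower[k, j],
                         "sim_median": vpc.sim_median[k, j], "sim_upper": vpc.sim_upper[k, j]})
    pd.DataFrame(rows).to_csv(OUT / "vpc.csv", index=False)
    inside = ((vpc.observed >= vpc.sim_lower) & (vpc.observed <= vpc.sim_upper)).mean()
    print(f"observed percentile curves inside the simulated bands in {inside:.0%} of bins")

    from ropepk.plots import plot_gof, plot_pc_vpc

    plot_gof(gof, OUT / "gof.png")
    plot_pc_vpc(vpc, OUT / "vpc.png", log_scale=True)

    print(f"\nbootstrap with {n_bootstrap} replicates (stratified by study)...")
    bs = bootstrap(ds, model, structural, n=n_bootstrap, seed=DEFAULT_SEED,
                   inner_tol=1e-6, outer_ftol=1e-4, outer_maxfev=300)
    bs.summary.to_csv(OUT / "bootstrap-summary.csv")
    print(f"success rate {bs.success_rate:.0%}")
    print(bs.summary.round(4).to_string())


if __name__ == "__main__":
    n = int(sys.argv[1]) if len(sys.argv) > 1 else 1000
    main(n_bootstrap=n)
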