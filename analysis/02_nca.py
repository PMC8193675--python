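"""Non-compartmental analysis of the synthetic trials.

Computes per-subject Cmax, trapezoidal AUC and empirical CL/F, and
summarises the dose dependence of apparent clearance — the saturable
elimination shows up as CL/F falling with dose.
"""

from pathlib import Path

from ropepk.dataset import read_dataset
from ropepk.nca import nca_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = read_dataset(OUT / "dataset.csv")
    table = nca_table(ds)
    table.to_csv(OUT / "nca.csv", index=False)
    by_dose = table.groupby("dose")[["cmax", "auc_0_inf", "cl_f_per_day"]].median()
    print("median NCA metrics by dose cohort:")
    print(by_dose.round(3).to_string())
    trend = by_dose["cl_f_per_day"]
    print("\nCL/F decreases with dose:", bool(trend.is_monotonic_decreasing))


if __name__ == "__main__":
    main()
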