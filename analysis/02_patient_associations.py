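"""Patient-level association screen of mean log10 TTV vs fixed covariates.

Each patient is reduced to the mean of their monthly log10 loads; categorical
covariates (gender, disease, donation type, DSA, dual-vs-triple regimen,
CNI-vs-mTORi class) are tested by one-way ANOVA and continuous ones (ages,
post-transplant time, HLA mismatch count) by simple linear regression.
Writes table2_associations.csv under results/.
"""

from pathlib import Path

from ttvmonitor import read_cohort, run_association_table, write_results

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "cohort"


def main() -> None:
    cohort = read_cohort(COHORT / "patients.csv", COHORT / "visits.csv")
    results = run_association_table(cohort)
    write_results(results, ROOT / "results")
    print("variable                family             p")
    for r in sorted(results, key=lambda r: r.p_value):
        flag = "*" if r.p_value < 0.05 else " "
        print(f"{r.variable:22s} {r.family:18s} {r.p_value:.3f}{flag}")


if __name__ == "__main__":
    main()
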