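"""Repeated-measures correlation of monthly TTV with doses, troughs,
co-virus loads and eGFR.

For every monthly metric variable: per-patient Spearman correlation with the
same-visit log10 TTV load, cohort mean coefficient, and a 10,000-iteration
within-patient permutation test of that mean.  Writes
table3_correlations.csv under results/.
"""

from pathlib import Path

from ttvmonitor import read_cohort, run_correlation_table, write_results

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "cohort"
SEED = 20260928


def main() -> None:
    cohort = read_cohort(COHORT / "patients.csv", COHORT / "visits.csv")
    results = run_correlation_table(cohort, n_permutations=10_000, seed=SEED)
    write_results(results, ROOT / "results")
    print("variable                mean rho      p   patients")
    for r in sorted(results, key=lambda r: r.p_value):
        flag = "*" if r.p_value < 0.05 else " "
        print(f"{r.variable:22s} {r.mean_rho:+.3f}  {r.p_value:.4f}{flag}  {r.n_patients:3d}")


if __name__ == "__main__":
    main()
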