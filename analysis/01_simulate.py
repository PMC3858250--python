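"""Generate the synthetic study cohort.

Draws a cohort emulating the target study design: 225 patients with
1,000-gene log-scale expression, 20 planted prognostic genes reading a
shared latent axis at a per-SD log hazard ratio of 0.5, five adverse
clinical factors, ~40% censoring, and a 15% competing-event fraction for
the liver-recurrence endpoint.  Writes expression TSV, clinical CSV,
outcome CSVs and the ground-truth JSON under results/cohort/.
"""

import sys
from pathlib import Path

from mrsig import io as mio
from mrsig.cohort import SimulationConfig, simulate_cohort
from mrsig.validation import compute_crs

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    config = SimulationConfig(
        n_samples=225, n_genes=1000, n_prognostic=20, effect_size=0.5, seed=SEED
    )
    cohort = simulate_cohort(config)
    OUT.mkdir(parents=True, exist_ok=True)
    mio.write_expression(cohort.expression, OUT / "expression.tsv")
    mio.write_clinical(cohort.clinical, OUT / "clinical.csv")
    mio.write_outcomes(cohort.outcomes_dss, OUT / "outcomes_dss.csv")
    mio.write_outcomes(cohort.outcomes_lrfs, OUT / "outcomes_lrfs.csv")
    mio.write_json({"planted_genes": cohort.truth, "seed": SEED}, OUT / "truth.json")

    n_events = sum(o.event for o in cohort.outcomes_dss)
    n_comp = sum(o.event_type == 2 for o in cohort.outcomes_lrfs)
    n_high_crs = sum(compute_crs(c)[1] == "high" for c in cohort.clinical)
    print(f"cohort: {config.n_samples} samples x {config.n_genes} genes -> {OUT}")
    print(f"  cancer deaths (DSS events): {n_events} "
          f"({100 * n_events / config.n_samples:.0f}%)")
    print(f"  competing events (LRFS):    {n_comp}")
    print(f"  CRS >= 3 (high clinical risk): {n_high_crs} "
          f"({100 * n_high_crs / config.n_samples:.0f}%)")


if __name__ == "__main__":
    main()
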