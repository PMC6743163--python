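"""Simulate the two study cohorts.

Generates (a) a 31-person paired validation cohort in which the
accelerometer TEE is the questionnaire TEE under the calibrated MET set
plus device noise, and (b) a 48,618-person baseline roster with the
published exclusion counts (998 pregnancies, 1,416 missing
anthropometry, 15,267 missing activity responses).  The validation
cohort is written to results/; the large baseline roster goes to
scratch/ (it is regenerated from the seed by downstream scripts).
"""

import argparse
from pathlib import Path

import numpy as np

from metcal import apply_exclusions
from metcal.io import write_baseline_roster, write_validation_cohort
from metcal.simulate import (
    GeneratorConfig,
    generate_baseline_roster,
    generate_validation_cohort,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--scratch", type=Path, default=Path("scratch"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    args.scratch.mkdir(parents=True, exist_ok=True)

    cohort = generate_validation_cohort(
        GeneratorConfig.validation_default(n=31, seed=args.seed)
    )
    path = args.outdir / "validation_cohort.csv"
    write_validation_cohort(cohort, path)
    tees = np.array([r.accelerometer_tee for r in cohort])
    ages = np.array([r.participant.age for r in cohort])
    print(f"validation cohort: n={len(cohort)} -> {path}")
    print(f"  age {ages.mean():.1f} +/- {ages.std(ddof=1):.1f} y; "
          f"accelerometer TEE {tees.mean():.0f} +/- {tees.std(ddof=1):.0f} kcal/day")

    roster = generate_baseline_roster(
        GeneratorConfig.baseline_default(
            n=48618, seed=args.seed, exclusion_counts=(998, 1416, 15267)
        )
    )
    rpath = args.scratch / "baseline_roster.csv"
    write_baseline_roster(roster, rpath)
    _, report = apply_exclusions(roster)
    print(f"baseline roster: n={len(roster)} -> {rpath}")
    print(f"  exclusions {report.excluded} -> retained {report.n_retained}")


if __name__ == "__main__":
    main()
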