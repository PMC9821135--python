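#!/usr/bin/env python
"""Simulate the recruited cohort under the study conditions.

Generates the default synthetic cohort (186 recruited pregnancies with
suspected growth restriction; 114 eligible for analysis, 37 with the
composite adverse outcome) and writes it to results/cohort.csv.
"""

import argparse
from pathlib import Path

from upcr import SimConfig, generate_cohort
from upcr.io import write_cohort_csv


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=None, help="override the default seed")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SimConfig()
    if args.seed is not None:
        cfg.seed = args.seed
    cohort = generate_cohort(cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    path = args.out / "cohort.csv"
    write_cohort_csv(cohort, path)

    print(f"recruited {cohort.n_recruited} pregnancies (seed={cfg.seed})")
    for reason, count in cohort.ledger.items():
        print(f"  excluded {count:3d}  {reason}")
    print(f"  analyzed {cohort.n_analyzed:3d}")
    n_adv = sum(1 for r in cohort.analyzed if r.nicu_admission or r.stillbirth
                or r.emergency_cs_fetal_distress or r.apgar5 < 7 or r.ua_ph < 7.10)
    print(f"  composite adverse outcome in {n_adv} "
          f"({round(100 * n_adv / cohort.n_analyzed)}%) of the analyzed pregnancies")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
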