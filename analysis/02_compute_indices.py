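#!/usr/bin/env python
"""Apply the exclusion filter and compute per-pregnancy Doppler indices.

Reads results/cohort.csv (or regenerates the default cohort), drops the
ineligible records, computes replicate means, CPR, UPCR and their
gestational-age MoMs for every analyzed pregnancy, and writes the
analysis-ready table to results/analysis.csv.
"""

import argparse
from pathlib import Path

from upcr import SimConfig, generate_cohort
from upcr.io import read_cohort_csv
from upcr.pipeline import build_analysis_frame


def load_cohort(results: Path):
    path = results / "cohort.csv"
    if path.exists():
        print(f"reading {path}")
        return read_cohort_csv(path)
    print("cohort.csv not found; generating the default cohort")
    return generate_cohort(SimConfig())


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = load_cohort(args.results)
    frame = build_analysis_frame(cohort)
    args.results.mkdir(parents=True, exist_ok=True)
    out = args.results / "analysis.csv"
    frame.to_csv(out, index=False)

    print(f"{frame.attrs['n_recruited']} recruited -> {len(frame)} analyzed "
          f"(ledger {frame.attrs['ledger']})")
    for col in ("ua_mom", "mca_mom", "uta_mom", "cpr_mom", "upcr_mom"):
        g = frame.groupby("adverse")[col]
        m, s = g.mean(), g.std()
        print(f"  {col:9s} normal {m[0]:.2f} +/- {s[0]:.2f}   adverse {m[1]:.2f} +/- {s[1]:.2f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
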