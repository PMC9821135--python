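#!/usr/bin/env python
"""Multivariable logistic regression with backward-stepwise LR selection.

Fits the full eight-term model (five Doppler MoMs, gestational age at
delivery, birthweight percentile, preeclampsia) for the composite adverse
outcome, then runs backward-stepwise selection on single-term
likelihood-ratio tests, writing results/table3.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from upcr.pipeline import build_table3, _fit_rows


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--alpha-remove", type=float, default=0.10)
    args = ap.parse_args()

    frame = pd.read_csv(args.results / "analysis.csv")
    res = build_table3(frame, alpha_remove=args.alpha_remove)

    rows = _fit_rows(res.initial) + [{"variable": "--- final model ---"}] + _fit_rows(res.final)
    pd.DataFrame(rows).to_csv(args.results / "table3.csv", index=False)

    print(f"full model ({res.initial.n_obs} pregnancies):")
    for r in _fit_rows(res.initial):
        print(f"  {r['variable']:<24s} B={r['B']:+.3f} SE={r['SE']:.3f} "
              f"aOR={r['aOR']:.3f} ({r['ci_low']:.2f}-{r['ci_high']:.2f}) p={r['p']:.3f}")
    print("removal trace (largest non-significant LR p first):")
    for name, p in res.trace:
        print(f"  dropped {name:<20s} p={p:.3f}")
    kept = res.final.term_names()
    print(f"final model retains: {', '.join(kept) if kept else '(intercept only)'}")
    print(f"wrote {args.results / 'table3.csv'}")


if __name__ == "__main__":
    main()
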