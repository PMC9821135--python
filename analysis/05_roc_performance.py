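#!/usr/bin/env python
"""Prognostic performance of the Doppler markers: ROC, Youden, DeLong.

For each MoM marker: empirical AUC with a DeLong 95% CI, the
Youden-optimal cutoff with sensitivity/specificity/PPV/NPV (exact
binomial CIs), and a paired DeLong comparison against the UPCR MoM.
Writes results/table4.csv; --plot additionally renders the ROC curves.
"""

import argparse
from pathlib import Path

import pandas as pd

from upcr.pipeline import MARKERS, build_table4, _roc_row


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--plot", action="store_true", help="write results/roc_curves.png")
    args = ap.parse_args()

    frame = pd.read_csv(args.results / "analysis.csv")
    summaries, comparisons = build_table4(frame)
    rows = [_roc_row(summaries[m], comparisons.get(m)) for m in summaries]
    pd.DataFrame(rows).to_csv(args.results / "table4.csv", index=False)

    for row in rows:
        vs = f"  p_vs_upcr={row['p_vs_upcr']:.3f}" if "p_vs_upcr" in row else " (reference)"
        print(f"  {row['marker']:<9s} AUC {row['auc']:.3f} "
              f"({row['auc_ci_low']:.3f}-{row['auc_ci_high']:.3f})  "
              f"sens {row['sensitivity_pct']:.1f}%  spec {row['specificity_pct']:.1f}%{vs}")

    if args.plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from upcr.roc import roc_curve

        y = frame["adverse"].to_numpy(int)
        fig, ax = plt.subplots(figsize=(5, 5))
        for marker, orientation in MARKERS.items():
            s = frame[marker].to_numpy(float)
            curve = roc_curve(s if orientation == "higher" else -s, y)
            ax.plot(1 - curve.specificity, curve.sensitivity,
                    label=f"{marker} (AUC {summaries[marker].auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(args.results / "roc_curves.png", dpi=150)
        print(f"wrote {args.results / 'roc_curves.png'}")

    print(f"wrote {args.results / 'table4.csv'}")


if __name__ == "__main__":
    main()
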