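"""Compare models and devices over the bootstrap metric distributions.

One-way ANOVA asks whether the mean bootstrapped R2 (and RMSER) differs
between M1/M2/M3 for each device, and whether the M3 R2 differs between
devices; Bonferroni-corrected pairwise t tests locate the differences
(threshold 0.05/3 for three model pairs, 0.05 divided by the number of
device pairs).  KS checks screen each bootstrap distribution for
normality first.

Reads results/bootstrap_samples.csv; writes results/comparisons.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import wearload as wl


def _report_rows(rep, label, metric):
    rows = []
    for _, r in rep.pairwise.iterrows():
        rows.append(
            {
                "comparison": label,
                "metric": metric,
                "pair": r["pair"],
                "t": r["t"],
                "p": r["p"],
                "alpha_adjusted": r["alpha_adjusted"],
                "significant": r["significant"],
                "anova_F": rep.F,
                "anova_p": rep.p,
                "best_group": rep.best_group,
            }
        )
    return rows


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--family-alpha", type=float, default=0.05)
    args = ap.parse_args()

    samples = pd.read_csv(args.results / "bootstrap_samples.csv")
    overall = samples[samples.stratum == "overall"]

    rows = []
    for device, sub in overall.groupby("device"):
        r2_groups = {m: g.r2.to_numpy() for m, g in sub.groupby("model")}
        rmser_groups = {m: g.rmser.to_numpy() for m, g in sub.groupby("model")}
        rep_r2 = wl.compare_groups(r2_groups, args.family_alpha, higher_is_better=True)
        rep_rm = wl.compare_groups(rmser_groups, args.family_alpha, higher_is_better=False)
        rows += _report_rows(rep_r2, f"models ({device})", "r2")
        rows += _report_rows(rep_rm, f"models ({device})", "rmser")
        print(f"{device}: model ANOVA on R2 F={rep_r2.F:.1f} p={rep_r2.p:.2g} "
              f"-> best model: {rep_r2.best_group}")
        for model, (stat, p) in rep_r2.normality.items():
            print(f"  KS normality of {model} R2 samples: p={p:.2f}")

    m3 = overall[overall.model == "M3"]
    if m3.device.nunique() >= 2:
        dev_groups = {d: g.r2.to_numpy() for d, g in m3.groupby("device")}
        rep_dev = wl.compare_groups(dev_groups, args.family_alpha, higher_is_better=True)
        rows += _report_rows(rep_dev, "devices (M3)", "r2")
        print(f"devices: ANOVA on M3 R2 F={rep_dev.F:.1f} p={rep_dev.p:.2g} "
              f"(threshold {rep_dev.alpha_adjusted:.4f})")

    pd.DataFrame(rows).to_csv(args.results / "comparisons.csv", index=False)
    print(f"wrote {args.results / 'comparisons.csv'}")


if __name__ == "__main__":
    main()
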