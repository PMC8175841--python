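"""Bootstrap cross-validated R2 and RMSER, overall and per speed.

For each device and model, B bootstrap resamples are drawn, the model is
refitted on each, and agreement is measured on the out-of-bag rows; the
2.5/97.5 percentiles of the B values give the 95% confidence intervals.
The speed-stratified rows mirror the per-speed validity analysis.

Reads results/observations.csv; writes results/metrics.csv (summary)
and results/bootstrap_samples.csv (raw B values, reused by script 04).
"""

import argparse
from pathlib import Path

import pandas as pd

import wearload as wl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--B", type=int, default=200,
                    help="bootstrap resamples (1000 for a full replication)")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    table = pd.read_csv(args.results / "observations.csv")
    metric_rows, sample_rows = [], []
    for device, sub in table.groupby("device"):
        sub = sub.reset_index(drop=True)
        for spec in wl.MODEL_SPECS:
            results = {"overall": wl.bootstrap_validate(sub, spec, B=args.B, seed=args.seed)}
            results.update(
                wl.bootstrap_validate(sub, spec, B=args.B, seed=args.seed,
                                      stratify_by="speed")
            )
            for stratum, res in results.items():
                metric_rows.append(
                    {
                        "stratum": stratum,
                        "device": device,
                        "model": spec,
                        "r2_mean": res.r2_mean,
                        "r2_lo": res.r2_ci[0],
                        "r2_hi": res.r2_ci[1],
                        "rmser_mean": res.rmser_mean,
                        "rmser_lo": res.rmser_ci[0],
                        "rmser_hi": res.rmser_ci[1],
                    }
                )
                for b, (r2, rmser) in enumerate(zip(res.r2_samples, res.rmser_samples)):
                    sample_rows.append(
                        {"stratum": stratum, "device": device, "model": spec,
                         "b": b, "r2": r2, "rmser": rmser}
                    )
            print(f"{device} {spec}: overall R2 = {results['overall'].r2_mean:.3f} "
                  f"[{results['overall'].r2_ci[0]:.3f}, {results['overall'].r2_ci[1]:.3f}]")

    pd.DataFrame(metric_rows).to_csv(args.results / "metrics.csv", index=False)
    pd.DataFrame(sample_rows).to_csv(args.results / "bootstrap_samples.csv", index=False)
    print(f"wrote {args.results / 'metrics.csv'} and bootstrap_samples.csv (B={args.B})")


if __name__ == "__main__":
    main()
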