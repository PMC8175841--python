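"""Fit the three nested model specifications to the observation table.

M1 regresses the force-plate load rate on the wearable estimate with
fixed effects only; M2 adds a per-participant random intercept; M3 adds
random intercept and slope.  All fits use maximum likelihood so the
nested log-likelihoods are comparable.

Reads results/observations.csv; writes results/model_fits.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import wearload as wl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = pd.read_csv(args.results / "observations.csv")
    rows = []
    for device, sub in table.groupby("device"):
        sub = sub.reset_index(drop=True)
        for spec in wl.MODEL_SPECS:
            m = wl.fit_model(sub, spec)
            pred, _ = wl.predict(m, sub)
            r2, rmser = wl.agreement_metrics(sub.y, pred)
            rows.append(
                {
                    "device": device,
                    "model": spec,
                    "alpha_Ns": m.alpha,
                    "beta": m.beta,
                    "sd_intercept_Ns": m.var_components["var_intercept"] ** 0.5,
                    "sd_slope": m.var_components["var_slope"] ** 0.5,
                    "sd_residual_Ns": m.var_components["var_residual"] ** 0.5,
                    "loglike": m.loglike,
                    "r2_insample": r2,
                    "rmser_insample": rmser,
                }
            )
            print(
                f"{device} {spec}: alpha={m.alpha:8.1f} N/s  beta={m.beta:.3f}  "
                f"in-sample R2={r2:.3f}  RMSER={rmser:.3f}"
            )
    fits = pd.DataFrame(rows)
    fits.to_csv(args.results / "model_fits.csv", index=False)
    print(f"wrote {args.results / 'model_fits.csv'}")


if __name__ == "__main__":
    main()
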