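"""Fit the action-selection model to each simulated cohort by MCMC.

Reads the trial tables written by 01_simulate_cohorts.py, samples the
posterior over (cost scaler, bias scaler, bias rate) per experiment, and
writes posterior draws, HDI summaries and convergence diagnostics.  The
between-experiment bias-scaler contrasts (experiment 2 and 3 each minus
experiment 1) quantify how much the bias contribution shrinks when
temporal constraints are eased or task demands are reduced.
"""

import argparse
import json
from pathlib import Path

from motorhyst.inference import FitConfig, contrast_parameter, sample_posterior
from motorhyst.pipeline_io import read_trials, write_posterior


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohorts", type=str, default="results/cohorts")
    ap.add_argument("--out", type=str, default="results/fits")
    ap.add_argument("--chains", type=int, default=16)
    ap.add_argument("--warmup", type=int, default=600)
    ap.add_argument("--draws", type=int, default=800)
    ap.add_argument("--full-scale", action="store_true",
                    help="use the 8 x 5000+5000 sampling profile")
    args = ap.parse_args()

    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    draws_by_exp = {}
    for exp in (1, 2, 3):
        trials = read_trials(Path(args.cohorts) / f"exp{exp}_trials.csv")
        if args.full_scale:
            cfg = FitConfig.full_scale(seed=args.seed + exp)
        else:
            cfg = FitConfig(n_chains=args.chains, n_warmup=args.warmup,
                            n_draws=args.draws, seed=args.seed + exp)
        draws, summary = sample_posterior(trials, cfg)
        draws_by_exp[exp] = draws
        write_posterior(draws, outdir / f"exp{exp}_posterior.csv")
        payload = {"summary": summary.to_dict(), "rhat": draws.rhat,
                   "ess": draws.ess, "converged": draws.converged}
        (outdir / f"exp{exp}_summary.json").write_text(json.dumps(payload, indent=2))
        print(f"experiment {exp}:")
        for name, (mean, lo, hi) in summary.summary.items():
            print(f"  {name:12s} {mean:7.3f}  95% HDI [{lo:7.3f}, {hi:7.3f}]  "
                  f"R-hat {draws.rhat[name]:.3f}")

    contrasts = {}
    for exp in (2, 3):
        diff, (lo, hi) = contrast_parameter(draws_by_exp[exp], draws_by_exp[1],
                                            "bias_scaler")
        contrasts[f"bias_scaler_exp{exp}_minus_exp1"] = {
            "mean": diff, "hdi_low": lo, "hdi_high": hi}
        print(f"bias scaler, exp{exp} - exp1: {diff:.2f} [{lo:.2f}, {hi:.2f}]")
    (outdir / "bias_scaler_contrasts.json").write_text(json.dumps(contrasts, indent=2))


if __name__ == "__main__":
    main()
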