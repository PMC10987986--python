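"""Simulate the three experiments' cohorts at the fitted mean parameters.

Writes one trial table per experiment under results/cohorts/, with
provenance (seed, generating parameters).  Cohort sizes default to the
study's 152 / 20 / 20; pass --scale to shrink them uniformly for quick
runs.
"""

import argparse
from pathlib import Path

from motorhyst.choice_model import EXPERIMENT_PARAMS
from motorhyst.pipeline_io import substream, write_trials
from motorhyst.synthetic_data import default_error_table, make_cohort

COHORT_SIZES = {1: 152, 2: 20, 3: 20}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--scale", type=float, default=1.0,
                    help="multiply cohort sizes (e.g. 0.25 for a quick run)")
    ap.add_argument("--out", type=str, default="results/cohorts")
    args = ap.parse_args()

    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    for exp, n_full in COHORT_SIZES.items():
        n = max(2, round(n_full * args.scale))
        rng = substream(args.seed, f"cohort-exp{exp}")
        cohort = make_cohort(
            n, EXPERIMENT_PARAMS[exp], rng, experiment=exp,
            error_table=default_error_table(exp), seed=args.seed,
        )
        write_trials(cohort.trials, outdir / f"exp{exp}_trials.csv")
        cohort.write_provenance(outdir / f"exp{exp}_provenance.json")
        n_exp = (cohort.trials["block_type"] == "experimental").sum()
        n_fail = (cohort.trials["side"] == "none").sum()
        print(f"experiment {exp}: {n} participants, {n_exp} experimental trials, "
              f"{n_fail} failed trials -> {outdir}/exp{exp}_trials.csv")


if __name__ == "__main__":
    main()
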