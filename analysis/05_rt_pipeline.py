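"""Reaction-time pipeline: trajectories -> filtering -> onset -> models.

Simulates stylus traces for a subset of experiment-1 trials, runs the
kinematic preprocessing (10 Hz zero-phase Butterworth, 50 mm/s onset
detection), computes RTs, applies the four-rule exclusion cascade, and
fits the inverse-RT mixed models (condition EMMs at the middle trial and
the switch/repeat comparison in the random block).  The synthetic
generator draws RTs from one lognormal regardless of condition, so the
expected condition differences here are null; the script demonstrates
the measurement pipeline, not an RT effect.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from motorhyst.behavior_stats import (
    fit_rt_lmm,
    preprocess_choices,
    rt_switch_analysis,
)
from motorhyst.choice_model import TrialRecord
from motorhyst.kinematics import (
    TrajectoryTrace,
    clean_rt,
    compute_rt,
    lowpass_filter,
    movement_onset,
)
from motorhyst.pipeline_io import read_trials, substream
from motorhyst.synthetic_data import simulate_trajectory


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohorts", type=str, default="results/cohorts")
    ap.add_argument("--out", type=str, default="results/rt")
    ap.add_argument("--n-participants", type=int, default=8)
    args = ap.parse_args()

    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    trials = read_trials(Path(args.cohorts) / "exp1_trials.csv")
    keep = sorted(trials["participant_id"].unique())[: args.n_participants]
    exp = trials[
        (trials["block_type"] == "experimental")
        & (trials["side"] != "none")
        & trials["participant_id"].isin(keep)
    ]

    rng = substream(args.seed, "rt-trajectories")
    rows = []
    for _, t in exp.iterrows():
        rec = TrialRecord(t["participant_id"], 1, t["block_type"], t["condition"],
                          int(t["trial_index"]), float(t["obstacle_x_mm"]),
                          t["side"], t["outcome"])
        traj = simulate_trajectory(rec, rng, noise_sd=0.3)
        trace = TrajectoryTrace(
            traj[["t_ms", "x_mm", "y_mm"]].copy(), stimulus_onset_ms=0.0,
            exit_timestamp_ms=float(traj.attrs["onset_ms"]),
        )
        onset = movement_onset(lowpass_filter(trace))
        rt = compute_rt(1, trace, onset)
        rows.append({
            "participant_id": t["participant_id"], "experiment": 1,
            "block_type": "experimental", "condition": t["condition"],
            "trial_index": int(t["trial_index"]),
            "obstacle_x_mm": float(t["obstacle_x_mm"]), "side": t["side"],
            "outcome": t["outcome"],
            "rt_ms": rt if rt is not None else np.nan,
        })
    rt_df = pd.DataFrame(rows)

    retained, report = clean_rt(rt_df)
    (outdir / "exclusion_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    print("exclusion cascade:", report.counts,
          f"({report.n_retained}/{report.n_input} retained)")
    print(f"mean RT after cleaning: {retained['rt_ms'].mean():.0f} ms")

    clean = preprocess_choices(retained)
    res = fit_rt_lmm(clean)
    emm_rows = [{"condition": k, "emm_ms": v[0], "ci_low_ms": v[1], "ci_high_ms": v[2]}
                for k, v in res.emm_ms.items()]
    sw = rt_switch_analysis(clean)
    emm_rows += [{"condition": f"random/{k}", "emm_ms": v[0],
                  "ci_low_ms": v[1], "ci_high_ms": v[2]}
                 for k, v in sw.emm_ms.items()]
    pd.DataFrame(emm_rows).to_csv(outdir / "rt_emms.csv", index=False)
    print("EMM RT at the middle trial (back-transformed from inverse RT):")
    for row in emm_rows:
        print(f"  {row['condition']:18s} {row['emm_ms']:5.0f} ms "
              f"[{row['ci_low_ms']:.0f}, {row['ci_high_ms']:.0f}]")


if __name__ == "__main__":
    main()
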