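"""Simulate the study cohort: 38 expert and 20 novice responders, each
seeing the 111-trial occlusion design, with known per-cell parameters.

Writes results/trials.csv (the trial table downstream stages consume)
and results/ground_truth.csv (the sampled parameters, for recovery
checks only — real participants have no such file).
"""

import argparse
from pathlib import Path

from bouncebayes import CohortSpec, DesignSpec, simulate_cohort
from bouncebayes.cli import stage_seed
from bouncebayes.io import write_trials


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0, help="master seed")
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    seed = stage_seed(args.seed, "simulate")
    trials, truth = simulate_cohort(DesignSpec(seed=seed), CohortSpec(seed=seed))
    write_trials(trials, args.out_dir / "trials.csv")
    truth.to_csv(args.out_dir / "ground_truth.csv", index=False)

    by_group = trials.groupby("group").participant_id.nunique()
    print(f"simulated {len(trials)} trials: "
          f"{by_group['expert']} experts + {by_group['novice']} novices x 111 trials")
    print("per-participant outcome composition:")
    print(trials.groupby(["kick_type", "outcome_cue"]).size() // trials.participant_id.nunique())


if __name__ == "__main__":
    main()
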