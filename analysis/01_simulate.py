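#!/usr/bin/env python
"""Generate the synthetic study data: two conditions, three replicates each.

Builds the toy receptor, then simulates the loop's two-state dynamics under
an agonist-bound analog (PR state strongly favored) and an agonist-removed
analog (NR state strongly favored, started from the PR/crystal-like
conformation), with 0.3 A coordinate noise and occasional transient
unfolding.  Trajectories, topology, landmark map, ground truth and the run
config land under scratch/synthetic_study/ (regenerated, not versioned).

Run from the repository root:  python analysis/01_simulate.py
"""

from pathlib import Path

import pandas as pd
import yaml

from loopstate.structures import save_landmark_map, write_structure, write_trajectory
from loopstate.synth import TwoStateSimSpec, build_toy_receptor, simulate_two_state

OUT = Path("scratch/synthetic_study")
N_REPLICATES = 3
N_FRAMES = 400
CONDITIONS = {
    "agonist_bound": dict(p_stay_pr=0.995, p_stay_nr=0.80, seed0=100),
    "agonist_free": dict(p_stay_pr=0.80, p_stay_nr=0.995, seed0=200),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    frame, lmap = build_toy_receptor()
    write_structure(frame, OUT / "topology.pdb")
    save_landmark_map(lmap, OUT / "landmarks.yaml")

    config = {"landmarks": str(OUT / "landmarks.yaml"),
              "output_dir": str(OUT / "out"),
              "pairs": [{"atoms": ["icl2_marker_tip", "tm2_ref"], "label": "tip--tm2"}],
              "conditions": []}
    for name, kw in CONDITIONS.items():
        paths = []
        for r in range(N_REPLICATES):
            sim = simulate_two_state(
                frame, lmap,
                TwoStateSimSpec(
                    n_frames=N_FRAMES, p_stay_pr=kw["p_stay_pr"],
                    p_stay_nr=kw["p_stay_nr"], noise_sigma=0.3,
                    unfold_probability=0.01, seed=kw["seed0"] + r,
                    start_state="PR", label=f"{name}/rep{r + 1}",
                ),
            )
            path = OUT / f"{name}_rep{r + 1}.pdb"
            write_trajectory(sim.trajectory, path)
            paths.append(str(path))
            pd.DataFrame(
                {"frame": range(N_FRAMES), "time_ns": sim.trajectory.times,
                 "true_state": sim.true_states, "true_angle": sim.true_angles}
            ).to_csv(OUT / f"ground_truth_{name}_rep{r + 1}.csv",
                     index=False, float_format="%.6f")
            frac_pr = sum(s == "PR" for s in sim.true_states) / N_FRAMES
            print(f"{name} rep{r + 1}: true PR fraction {frac_pr:.3f}")
        config["conditions"].append(
            {"name": name, "topology": str(OUT / "topology.pdb"),
             "trajectories": paths}
        )
    (OUT / "run.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    print(f"wrote {2 * N_REPLICATES} trajectories of {N_FRAMES} frames and "
          f"run config to {OUT}")


if __name__ == "__main__":
    main()
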