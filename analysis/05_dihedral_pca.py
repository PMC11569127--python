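#!/usr/bin/env python
"""Dihedral PCA of loop backbone conformations across conditions.

Fits principal components to the sin/cos-encoded (phi, psi) dihedrals of
the loop residues (resolved through the Ballesteros-Weinstein table in the
landmark map), merging folded frames from all conditions and replicates,
then projects each condition onto the leading components.  Writes
results/pca_variance.csv and results/pca_scores_head.csv.  Requires
analysis/01_simulate.py to have run.
"""

from pathlib import Path

import pandas as pd
import yaml

from loopstate.stats import dihedral_features, pca_fit, pca_project
from loopstate.structures import load_landmark_map, read_structure, read_trajectory

STUDY = Path("scratch/synthetic_study")
RESULTS = Path("results")


def main() -> None:
    config = yaml.safe_load((STUDY / "run.yaml").read_text())
    lmap = load_landmark_map(config["landmarks"])
    reference = read_structure(config["conditions"][0]["topology"])

    trajs, labels = [], []
    for cond in config["conditions"]:
        for path in cond["trajectories"]:
            traj = read_trajectory(cond["topology"], path, source_label=Path(path).stem)
            trajs.append(traj)
            labels.append(cond["name"])

    matrix = dihedral_features(
        trajs, lmap, ("3.55", "4.39"), helical_filter=True, reference=reference
    )
    # replicate labels look like "agonist_bound_rep1": strip the _repN suffix
    matrix.provenance["condition"] = [
        rep.rsplit("_", 1)[0] for rep in matrix.provenance["replicate"]
    ]
    model = pca_fit(matrix)
    total = model.explained_variance.sum()
    var = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(len(model.explained_variance))],
            "explained_variance": model.explained_variance,
            "fraction": model.explained_variance / total,
        }
    )
    RESULTS.mkdir(exist_ok=True)
    var.head(10).to_csv(RESULTS / "pca_variance.csv", index=False, float_format="%.6f")

    scores = pca_project(model, matrix, k=2)
    head = matrix.provenance.copy()
    head["pc1"], head["pc2"] = scores[:, 0], scores[:, 1]
    head.head(50).to_csv(RESULTS / "pca_scores_head.csv", index=False, float_format="%.4f")

    top2 = var["fraction"][:2].sum()
    print(f"frames kept (folded): {matrix.data.shape[0]}")
    print(f"top-2 components carry {100 * top2:.1f}% of dihedral variance")
    print(var.head(4).to_string(index=False))


if __name__ == "__main__":
    main()
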