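# loopstate

Two-state conformational analysis of a GPCR intracellular loop in
molecular-dynamics trajectories.

## The problem

Some allosteric agonists of free fatty acid receptor 1 (FFAR1/GPR40) do not
work the canonical way — by rearranging transmembrane (TM) helices — but by
rotating the short helical second intracellular loop (ICL2) between two
well-defined orientations: a *positively rotated* (PR) state seen in the
agonist-bound crystal structure and a *negatively rotated* (NR) state about
−40° away about the helix axis, which changes how well the loop fits the
G-protein surface.  Testing that mechanism on simulation data requires a
reproducible way to (i) measure the loop's rotation frame by frame,
(ii) decide when the loop is folded at all, (iii) classify frames into
PR/NR/disordered, (iv) quantify the hydrogen-bond network (direct and
water-mediated) that holds the loop in place, and (v) compare conditions
across independent replicate simulations with honest statistics.

`loopstate` implements that analysis as a tested, reusable library for
anyone studying loop-orientation switching in membrane proteins, plus a
synthetic trajectory generator so every stage can be verified against
known ground truth without any external data.

## The metrics and the classifier

With the receptor aligned on the TM1–TM4 CA atoms of a reference frame
(which places the ICL2 helix axis approximately along x), the loop
orientation is read from the marker vector **v** between two sidechain
atoms (L112:CG → Y114:OH in FFAR1) projected into the z,y plane:

    a = atan2(v_z, v_y)            # ICL2 angle, degrees
    d = |Y114:OH − T39:CB|         # tip-to-TM2 distance, Å

A frame is *helical* when the loop keeps ≥ 3 backbone i,i+4 hydrogen bonds
or its backbone RMSD to the helical reference is < 2 Å.  The state is then

    DISORDERED  if not helical
    PR          if helical and 45 < a < 120 and 10 − a/20 < d < 13
    NR          otherwise

Also provided: an axis-fitted rotation angle (validation metric for the
plane projection), the TM5 vertical shift relative to TM4 (projection of
the TM5 residue-190 CA onto the TM4 130→141 CA axis, oriented toward the
extracellular side), Gα helix-5 displacement after receptor-only
alignment, loop end-to-end distances, geometric hydrogen-bond and
single-water-bridge detection with per-replicate frequencies, dihedral PCA
on sin/cos-encoded (φ, ψ), and the exact two-sided Mann–Whitney U test on
per-replicate means (complete enumeration for small samples).

## Worked example

```python
import loopstate as ls
from loopstate.metrics import icl2_frame_metrics
from loopstate.synth import TwoStateSimSpec

frame, lmap = ls.build_toy_receptor()          # crystal-like reference
sim = ls.simulate_two_state(                    # agonist-removed analog
    frame, lmap,
    TwoStateSimSpec(n_frames=400, p_stay_pr=0.8, p_stay_nr=0.995,
                    noise_sigma=0.3, seed=3),
)
m = icl2_frame_metrics(sim.trajectory.frame(399), frame, lmap)
print(f"a_rel = {m.a_rel:.1f} deg, d = {m.d:.1f} A, state = {m.state}")
```

prints

```
a_rel = -40.5 deg, d = 16.3 A, state = NR
```

the loop has rotated −40° from the crystal-like reference and its tip has
swung 16 Å from TM2 — the rotated (NR) state.  The numbered scripts under
`analysis/` run the full synthetic study (simulate → per-frame metrics →
replicate comparison → hydrogen-bond network → dihedral PCA → crystal
shift) and write their tables under `results/`; on the default data the
agonist-bound analog holds PR (fraction 0.95 ± 0.02, mean ± 68% CI over
3 replicates), the agonist-removed analog settles into NR (PR fraction
0.07 ± 0.003), the difference is maximal for 3-vs-3 replicates (exact
two-sided Mann–Whitney p = 0.1) while the helical fraction does not
separate (p = 0.3): the condition controls loop *orientation*, not loop
*folding*.

A CLI covers the same ground on file inputs:

```sh
loopstate synth --out demo/ --replicates 3        # data with ground truth
loopstate analyze --config run.yaml               # full metric pipeline
loopstate compare --summary out/summary.csv --pairs bound:free
loopstate crystal-shift bound.pdb free.pdb --map landmarks.yaml
```

Structures and trajectories are PDB (multi-model PDB for trajectories);
coordinates are Å, times ns (default stride 0.2 ns/frame).  Residue
numbering is never hard-coded: a YAML landmark map binds anchor roles
(`icl2_marker_tip`, `tm2_ref`, `tm5_probe`, …) and ranges (`icl2`,
`align_set`, …) to chain/residue/atom for the receptor at hand.

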