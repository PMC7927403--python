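"""Call MD runs agonist-like or antagonist-like from the descriptor series.

Simulates two 500 ns mean-reverting descriptor trajectories -- one forced
toward the active-state distance (agonist-bound behaviour), one staying at
the inactive distance -- drops the 50 ns annealing segment, smooths with a
20-frame moving average, and compares the production distributions.
"""

import numpy as np

from conformo import trajectory
from conformo.synthetic import agonist_trajectory_spec, antagonist_trajectory_spec, make_trajectory

ACTIVE_REF, INACTIVE_REF = 14.53, 12.96  # A, crystal-form references

ago, _ = make_trajectory(agonist_trajectory_spec(seed=1))
ant, _ = make_trajectory(antagonist_trajectory_spec(seed=2))
ago.label, ant.label = "agonist-bound", "antagonist-bound"

for series in (ago, ant):
    seg = trajectory.production_segment(series)
    smooth = trajectory.moving_average(series, 20)
    verdict = trajectory.classify_state(series, ACTIVE_REF, INACTIVE_REF)
    print(f"{series.label}: {seg.size} production frames, "
          f"median {np.median(seg):.2f} A, smoothed end {smooth[-1]:.2f} A -> {verdict}")

comp = trajectory.compare_distributions(ago, ant)
print(f"\nagonist vs antagonist production distributions: "
      f"medians {comp.median_a:.2f} / {comp.median_b:.2f} A, "
      f"Mann-Whitney p = {comp.mw_p:.3g}, KS p = {comp.ks_p:.3g}")
print("\nA production median near 14.5 A means the receptor drifted to the")
print("active-state geometry: the ligand behaves like an agonist in silico.")
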