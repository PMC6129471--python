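# Desk-scale synthetic docking study.
#
# Unset keys fall back to the full-protocol defaults (1 ps timestep,
# 185/204 Å start/stop spheres, 98/40 Å encounter criteria, 1 Å
# deduplication RMSD, 5000-record archive, 10 clusters, 20000 trajectories,
# 3.2-3.6 Å H-bond window, 0.5 Å excluded volume, 298.15 K, 100 mM,
# dielectrics 78.54/2).  This file scales the stochastic stages down to a
# single-CPU study of the synthetic fixtures.

seed: 1

grid:
  spacing: 2.0        # Å; coarser than the 1 Å default, fine vs. the 9.6 Å Debye length
  padding: 25.0       # Å beyond the nucleosome bounding box

docking:
  n_trajectories: 500
  max_steps: 300000   # 300 ns ceiling per trajectory
  auto_scale: true    # start = bounding radii + 30 Å, stop = start + 19 Å

conformers:           # L-DNA (arm1, arm2) opening angles in degrees
  - [0.0, 0.0]

variants: []          # e.g. [K85V, S67ph]
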