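"""Compare Ne-trajectory shapes between island and continental species.

Simulates per-species effective-population-size histories (island species
fluctuate more and decline toward the present), grids them on a shared
log-time axis, and runs the distance-based phylogenetic GLS with residual
randomization (RRPP).  Also demonstrates PSMC text parsing.
"""

import os
import tempfile

import halcyon as h

# --- parsing PSMC-format text -------------------------------------------
psmc_text = (
    "RD\t25\nTR\t0.004000\t0.000100\n"
    + "".join(f"RS\t{k}\t{0.004 * k:.4f}\t{1 + 0.2 * k:.4f}\t0\t0\n"
              for k in range(8)) + "//\n")
fd, path = tempfile.mkstemp(suffix=".psmc")
with os.fdopen(fd, "w") as fh:
    fh.write(psmc_text)
traj = h.parse_psmc_output(path, mu=1e-8, gen_time=4.8, bin_size=100)
os.unlink(path)
print(f"parsed PSMC block: N0 = {traj.ne_values[0]:.0f} individuals, "
      f"{len(traj.times)} intervals, most recent at {traj.times[0]:.0f} yr")

# --- group shape test on simulated trajectories --------------------------
cfg = h.SimConfig(n_tips=16)
tree, traits, _ = h.simulate_tree_and_traits(cfg, seed=4)
trajs = h.simulate_ne_trajectories(tree, traits, cfg, seed=5)
curves = h.common_grid(trajs, n_points=64)
res = h.dpgls_rrpp(curves, traits.island, tree, n_perm=999, seed=6)

n_isl = sum(traits.island.values())
print(f"\n{tree.n_tips} species ({n_isl} island), 64-point log-time grid "
      f"spanning {curves.grid[0]:.0f}-{curves.grid[-1]:.0f} yr")
print(f"curve-shape divergence island vs continental: "
      f"F = {res.f_ratio:.2f}, P_rand = {res.p_rand:.4f} "
      f"({res.n_perm} permutations)")
print("\nP_rand below 0.05 indicates island and continental species have "
      "systematically\ndifferent demographic-history shapes after "
      "accounting for phylogeny.")
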