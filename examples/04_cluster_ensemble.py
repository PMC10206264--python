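"""Trajectory clustering and medoid receptor extraction.

Builds a trajectory that mixes two receptor conformations 80/20, clusters
frames by average-linkage on the pairwise backbone RMSD matrix, and
extracts the medoid (centroid frame) of each cluster — the receptor
ensemble used downstream for ensemble scoring.
"""

import numpy as np

import bindsight as bs

spec = bs.SyntheticSpec(n_receptor_residues=10, n_ligand_atoms=8, seed=1)
structure = bs.generate_complex(spec)
rec = structure.group_indices("receptor")

rng = np.random.default_rng(1)
base = structure.coords
other = base.copy()
other[rec[len(rec) // 2:]] += np.array([0.0, 3.0, 2.0])
which = np.array([0] * 160 + [1] * 40)
rng.shuffle(which)
frames = np.array([(base if w == 0 else other) + rng.normal(0, 0.1, base.shape)
                   for w in which])
traj = bs.Trajectory(structure=structure, frames=frames,
                     frame_times=np.arange(200.0))

result = bs.cluster_frames(traj, rec, n_clusters=2)
for cid in sorted(result.populations):
    print(f"Cluster{cid}: {result.populations[cid]:5.1f}% "
          f"({result.counts[cid]} frames), medoid = frame "
          f"{result.representative_frames[cid]}")

medoids = bs.representative_structures(traj, result, group="receptor")
print(f"\nextracted {len(medoids)} medoid receptor structures "
      f"({medoids[1].n_atoms} atoms each) for the scoring ensemble.")
print("Populations should recover the planted 80/20 mix exactly at this "
      "separation.")
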