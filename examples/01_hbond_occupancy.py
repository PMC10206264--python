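"""Hydrogen-bond occupancy on a synthetic trajectory with planted truth.

Builds a toy receptor/ligand complex, plants two intermolecular hydrogen
bonds at 80% and 30% occupancy, and checks that the geometric detector
(<3.5 A donor-acceptor, >120 deg at the hydrogen) recovers them.
"""

import bindsight as bs

spec = bs.SyntheticSpec(n_receptor_residues=10, n_ligand_atoms=8,
                        n_frames=1000, seed=42)
structure = bs.generate_complex(spec)
spec.planted_hbonds = bs.default_planted_hbonds(structure, [0.8, 0.3])
traj = bs.generate_trajectory(structure, spec)

records = bs.detect_hbonds(traj)
print("donor            acceptor        occupancy  mean d (A)")
for r in records:
    print(f"{r.donor_label:<16} {r.acceptor_label:<15} "
          f"{r.occupancy:8.2f}%  {r.mean_distance:.2f} +/- {r.sd_distance:.2f}")

counts, mean, sd = bs.hbond_count_series(traj)
print(f"\nintermolecular H-bond count: {mean:.2f} +/- {sd:.2f} per frame")
print("The occupancies should sit within sampling noise of the planted "
      "80% and 30%; the count mean near their sum (1.1).")
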