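# bindsight

Binding-model analysis and combinatorial R-group design for
protein–ligand MD trajectories.

Given a trajectory of an inhibitor bound to a receptor (the motivating
system is an ATP-competitive inhibitor in the ATP pocket of a
CDK-family kinase), `bindsight` answers the questions a structure-based
design campaign asks in sequence:

1. **Is the complex stable, and which contacts hold it together?**
   Kabsch-superposed RMSD/RMSF series, geometric monitors, and
   hydrogen-bond occupancy (a bond counts in a frame when the
   donor–acceptor distance is < 3.5 Å and the acceptor–H–donor angle,
   vertex at the hydrogen, exceeds 120°; occupancy is the percentage of
   frames).
2. **How strong is binding, and which residues pay for it?**
   Single-trajectory MM/GBSA:

   ΔG_bind = ΔE_vdW + ΔE_ele + ΔE_GB + ΔE_surf − TΔS
           = ΔE_gas + ΔE_solv − TΔS = ΔH − TΔS

   with every Δ = complex − receptor − ligand extracted from the same
   complex frame, so bonded terms cancel exactly. Polar solvation is
   generalized Born (Still pairwise form, OBC-II effective radii),
   the nonpolar term is γ·SASA (Shrake–Rupley), and TΔS is a
   quasi-harmonic estimate (or an externally supplied value). The
   per-residue decomposition splits every intermolecular pair term half
   to each partner residue and conserves ΔH exactly, with a
   backbone/side-chain split and a 0.50 kcal/mol key-residue threshold.
3. **Which receptor conformations should new compounds be scored
   against?** Average-linkage hierarchical clustering of frames on the
   pairwise-RMSD matrix; each cluster's medoid frame becomes an ensemble
   receptor.
4. **What should be made next?** Two-stage R-group design on a
   four-region scaffold: one-region modification libraries, selection of
   the top three groups per region by docking-style score, the full
   3⁴ = 81 cross-combination named `C{r1}{r2}{r3}{r4}`, named variants
   (e.g. deleting the benzylic methylene: `C2213 → C2213-A`), ensemble
   scoring with min-aggregation, and a −10.00 kcal/mol shortlist.

A seeded synthetic-data module generates toy complexes and trajectories
with *known* ground truth — planted hydrogen-bond occupancies, planted
contact distances, Boltzmann-exact harmonic fluctuations, analytic
Born-ion cases — so every estimator in the package is testable without
any external data.

## Worked example

```python
import bindsight as bs

spec = bs.SyntheticSpec(n_receptor_residues=10, n_ligand_atoms=8,
                        n_frames=1000, seed=42)
structure = bs.generate_complex(spec)
spec.planted_hbonds = bs.default_planted_hbonds(structure, [0.8, 0.3])
traj = bs.generate_trajectory(structure, spec)

for r in bs.detect_hbonds(traj):
    print(r.donor_label, r.acceptor_label, f"{r.occupancy:.2f}%")
```

prints

```
A:ALA6@N B:LIG1@O2 78.90%
A:ALA7@N B:LIG1@O4 30.70%
```

— the two planted bonds recovered at their target occupancies (80% and
30%) to within binomial sampling noise at 1,000 frames. Continuing with
the energetics on the same system (`examples/02_mmgbsa_binding_energy.py`):

```
dE_gas  =    -1.83  (vdW + ele)
dE_solv =     0.30  (GB + surf)
dH      =    -1.53
T*dS    =    -9.15  (quasi-harmonic)
dG_bind =     7.62  (dH - T*dS)
```

The toy complex binds weakly (small contact surface, near-zero net
charges); what the numbers demonstrate is the exact accounting — each
derived quantity equals its component sum by construction — and the
entropy penalty of a loosely confined ligand. The `examples/` directory
has one short script per capability: occupancy recovery, MM/GBSA,
decomposition, clustering, R-group design, and the end-to-end pipeline.

## Command line

A thin CLI wraps the library for shell use:

```sh
bindsight synth   --residues 12 --frames 500 --seed 1 --out toy
bindsight analyze --traj toy.traj.pdb --top toy.top.txt --cluster 2 --out analysis/
bindsight mmgbsa  --traj toy.traj.pdb --top toy.top.txt --decompose --out energy/
bindsight design  --stage combine --out compounds.smi
bindsight score   --compounds compounds.smi --ensemble c1.pdb,c2.pdb \
                  --top toy.top.txt --scorer table:scores.tsv --out ranked.tsv
bindsight run     --seed 1 --out rundir/
```

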