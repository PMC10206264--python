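# Methods

This note records the models, conventions and numerical choices behind
`bindsight`, and what the synthetic-data tests do and do not demonstrate
about real MD data.

## Units and conventions

Coordinates in Å, energies in kcal/mol, charges in elementary charges,
masses in amu, times in ps, angles in degrees. Frame indices are 0-based
internally and 1-based in written reports. Residue identity is the
triple (chain, residue index, residue name) exactly as read from the
input PDB; no renumbering. The protein backbone atom set is
{N, CA, C, O} plus H and HA when present; everything else is side
chain, and ligand atoms are never backbone. The Coulomb constant is
332.0637 kcal·Å/(mol·e²).

## Hydrogen bonds

A donor–H…acceptor triple is bonded in a frame when the donor–acceptor
distance is strictly below 3.5 Å **and** the acceptor–H–donor angle
(vertex at the hydrogen) strictly exceeds 120°. Donors are N/O/S atoms
with an attached hydrogen (from the bond table, or any hydrogen within
1.2 Å as a fallback); acceptors are N/O atoms. Occupancy is the
percentage of frames bonded; the default reporting floor of 5%
suppresses noise rows. Reported mean distance/angle are taken over all
frames of the window, bonded or not, matching the way trajectory tools
report monitor series. Both inequalities are strict; at the printed
precision of real data this is indistinguishable from non-strict, but
the convention is fixed and tested.

## Superposition, RMSD, RMSF, clustering

Superposition is Kabsch least squares via SVD with a determinant
correction, so the returned rotation is always proper. RMSF first
superposes all frames to their mean structure (iterated mean–fit, two
passes), then reports per-residue means of the per-atom RMS
fluctuations. Note that removing six rigid-body degrees of freedom
slightly deflates fluctuations for small atom subsets (factor
≈ √(1 − 6/3N)); tests that compare against the isotropic closed form
use subsets large enough to make this negligible.

Frame clustering is hierarchical agglomerative with average linkage on
the pairwise best-fit RMSD matrix (the algorithm is not dictated by the
underlying science; average linkage is the common default of trajectory
analysis tools). Clusters are relabelled by descending population so
Cluster1 is always the majority; the representative is the medoid — the
member minimising summed RMSD to its cluster — which is deterministic
given frame order. For long trajectories the pairwise matrix is
computed on a strided frame subset (a configuration knob).

## MM/GBSA

Single-trajectory protocol only: receptor and ligand coordinates are
extracted from the same complex frame, so all bonded and intramolecular
terms cancel in the delta and only intermolecular Lennard-Jones
(Lorentz–Berthelot combination, no cutoff) and Coulomb terms are
evaluated. Pairs closer than 0.5 Å raise an error, since that signals
broken geometry rather than physics.

Polar solvation is generalized Born in the Still pairwise form,
f_GB = √(r² + R_iR_j·exp(−r²/4R_iR_j)), with self terms included, so a
single ion reduces exactly to the Born formula. Effective radii are
OBC-II: HCT pairwise descreening integrals over scaled, offset radii
(element-based scale factors H 0.85, C 0.72, N 0.79, O 0.85, F 0.88,
P 0.86, S 0.96; default 0.80), offset 0.09 Å, tanh rescaling with
α = 1.0, β = 0.8, γ = 4.85. Dielectrics default to 1 (interior) and
78.5 (exterior), zero salt. These are the standard defaults of the
widely used end-state tools; nothing in the method depends on them
being the only possible choice, and all are exposed in `GBParams`.

The nonpolar term is E_surf = γ·SASA + β with γ = 0.0072
kcal/(mol·Å²), β = 0, probe 1.4 Å. SASA is Shrake–Rupley with
deterministic golden-spiral sphere points (default 960; the isolated
sphere is then exact and two-sphere cases converge to ~1%, checked
against a 10,000-point evaluation). Atomic radii are half the
Lennard-Jones minimum distance (2^{1/6}σ/2), falling back to the
intrinsic Born radius for atoms without LJ parameters. In the delta,
the per-context β offsets leave a −β residue; with the default β = 0
the surface delta is exactly γ·ΔSASA.

The entropy term is quasi-harmonic: frames are superposed to their
mean, the mass-weighted coordinate covariance is diagonalised, each
eigenvalue λ is treated as a harmonic mode of angular frequency
ω = √(k_BT/λ), and the quantum harmonic-oscillator entropy is summed
over modes, discarding the six smallest eigenvalues as residual
rigid-body freedom. On Boltzmann-exact harmonic fixtures the estimate
matches the closed form per mode to better than 1% at 10,000 frames. An
externally computed TΔS can be passed through instead, so the ΔG
assembly is testable independently of the estimator. The estimator
warns when frames < 3 × atoms (ill-conditioned covariance); the toy
pipeline accepts this because its entropy term is illustrative.

ΔG = ΔH − TΔS, ΔH = ΔE_gas + ΔE_solv, ΔE_gas = ΔE_vdW + ΔE_ele and
ΔE_solv = ΔE_GB + ΔE_surf are maintained as derived quantities, so the
accounting identities hold to machine precision by construction, and
the polar (E_ele + E_GB) / nonpolar (E_vdW + E_surf) partition is a
property of the same object.

## Per-residue decomposition

Per frame, each intermolecular vdW/Coulomb pair energy is split half to
each partner atom's residue (ligand halves accumulate under the
ligand's own residue). The GB delta is attributed per atom as the
difference of its symmetric pair-matrix row sums between the complex
and the isolated context, which covers both the cross terms and the
descreening-induced change in self terms; the surface delta is γ times
the per-atom SASA difference. Backbone/side-chain subtotals follow the
per-atom backbone flag. Because every attribution is a partition of the
corresponding total, the sum of residue subtotals equals the delta
enthalpy to floating-point precision, frame by frame — this
conservation is asserted in the tests. Residues whose mean |subtotal| ≥
0.50 kcal/mol are flagged as key residues.

## Interaction classification

A residue hosting a hydrogen bond at ≥ 50% occupancy is classed
`hydrogen-bond`; occupancy in [10%, 50%) is `unstable-hydrogen-bond`;
otherwise a favorable residue (subtotal ≤ −0.50 kcal/mol) with a mean
ring–carbon heavy-atom distance ≤ 4.5 Å is `pi-alkyl` (a geometric +
energetic criterion, not an orbital analysis); an opposing residue
(subtotal ≥ +0.50) is `unfavorable`. Only the 0.50 kcal/mol threshold
is inherent to the decomposition convention; the occupancy bands and
distance cutoff are package defaults, all configurable and recorded in
the report. Region assignment of ligand atoms (R1–R4) is user-supplied
and validated for disjointness; no automatic ring perception is
attempted.

## R-group design

The scaffold is a SMILES string with four numbered attachment points
mapped to regions R1–R4; group fragments carry exactly one attachment
point, with `[*][H]` denoting hydrogen. Assembly substitutes fragments
at the attachment points (single bonds) and canonicalizes with RDKit,
which makes de-duplication and the uniqueness invariants exact. No 3-D
conformers are generated at design time.

Stage one substitutes each library entry into its region while holding
the other regions at the parent groups, dropping entries identical to
the parent group; the shipped default library has 42 entries (R1 a–m,
R2 a–h, R3 a–i, R4 a–l) spanning ring-system swaps at R1, small
hydrophobic-cavity groups at R2/R3 and solvent-exposed amine
substituents at R4. Stage two keeps the top k (default 3) groups per
region by aggregate score (more negative is better; exact ties resolve
to the earlier library entry; the parent group is eligible) and crosses
them into the full Cartesian product, naming each compound
`C` + the 1-based group indices in region order. Named variants are
SMARTS-driven edits; the shipped methylene deletion removes the
benzylic CH₂ between the aryl ring and the ring amine and appends `-A`
to the name. Applying an edit whose pattern is absent — including
applying the same deletion twice — is an error.

## Ensemble scoring

Compounds are scored against every member of a receptor ensemble
(typically the cluster medoids); the aggregate is the minimum over
members, so adding a member can only improve or preserve a compound's
aggregate and member order never matters. Ranking sorts ascending by
aggregate with lexical tie-break on the name; the shortlist keeps
records at or below −10.00 kcal/mol by default.

External docking engines are not reimplemented. Externally computed
scores enter through a table-backed scorer (exact pair lookup, missing
pair = declared failure). A deterministic surrogate scorer —
single-point intermolecular LJ + Coulomb with a distance-dependent
dielectric ε(r) = 4r plus γ·ΔSASA, on one fixed-seed ETKDG conformer
rigidly backed off to a 2.8 Å closest contact — exists so the whole
pipeline is exercisable end to end with no external engine. Its scores
order poses sensibly (contact poses beat displaced ones) but are not
docking energies and are never compared against published docking
values.

## Synthetic data: what it emulates, and what it does not

The generator builds a straight poly-alanine-like chain (N, H, CA, C,
O, CB per residue, charges summing to zero per residue, standard-ish LJ
and Born radii) with a rigid ring-shaped multi-atom ligand placed on
the side-chain face. Backbone N–H vectors point perpendicular to the
chain plane so planted hydrogen-bond geometries stay clear of the
chain. Frames are i.i.d.: global isotropic Gaussian jitter per atom
(default sd 0.15 Å — deliberately smaller than a real RMSF because
uncorrelated per-atom noise stands in for *relative* fluctuations
between contacting atoms, which are much smaller than absolute ones),
planted contacts restored to a sampled distance along the pair axis,
and each planted hydrogen bond set to bound geometry with Bernoulli
probability equal to its target occupancy. Bound frames draw the
donor–acceptor distance from a ±3σ-truncated Gaussian below 3.5 Å and
the angle uniform in [150°, 180°); unbound frames use a distance above
3.5 Å and an angle in [60°, 110°), so the geometric criterion
classifies every frame unambiguously and the empirical occupancy is an
exact Bernoulli mean. The free azimuth of a placement is aimed at the
acceptor's resting position and re-drawn (bounded retries) if it lands
within 2.3 Å of another atom, keeping LJ energies finite; the retained
angle stays inside its prescribed band. Planted acceptor atoms are
exempt from the ligand's within-frame rigidity by construction.

Because frames are independent and fluctuations harmonic, passing
tests demonstrate correctness of the *estimators* (frame averages,
occupancies, covariance spectra, cluster recovery) — they do not
demonstrate robustness to autocorrelation, anharmonicity, conformational
gating or force-field error, all of which real trajectories have. The
harmonic-trajectory generator draws exact Boltzmann samples of
independent 3-D wells (variance k_BT/k per component), giving the
closed-form oracle for the entropy estimator.

## Window selection

An analysis window is [start, end] in ps with a frame stride. Striding
is anchored to the trajectory's native sampling grid (carried through
selections), which makes window selection idempotent: applying the same
window to its own output is the identity. When time stamps are absent
from the input file, frame times are assigned uniformly from a
configured spacing, since the multi-model PDB format carries none.

## Problem sizes

Defaults in tests and the acceptance script: 10-residue/8-ligand-atom
complexes, 60–2,000 frames for estimator checks, 10,000 frames for the
entropy oracle, 200 frames for cluster recovery, 960 SASA points
(96–240 for the surrogate scorer inside the toy pipeline). These sizes
were chosen so every property is measured well inside its sampling
tolerance while the whole suite stays desk-scale; all of them are
parameters, not limits of the implementation.

## Known limitations

- No Poisson–Boltzmann variant, no normal-mode entropy, no
  explicit-solvent energies, no alanine scanning, no three-trajectory
  protocol.
- No AMBER/GROMACS binary formats; multi-model PDB plus the plain-text
  topology format documented in `io.py` are the interchange formats.
- The surrogate scorer is a pipeline stand-in, not a docking method.
- Quasi-harmonic entropy needs frames ≫ 3 × atoms to be well
  conditioned; the implementation warns, but does not refuse, below
  that.
- π-alkyl classification is geometric/energetic; no aromaticity or
  orbital analysis of the receptor side.
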