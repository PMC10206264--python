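"""MM terms, generalized Born, SASA, entropy and decomposition."""

import numpy as np
import pytest

import bindsight as bs
from bindsight.gbsa import (COULOMB, HBAR, KB, KCAL_TO_AMU_A2_PS2,
                            born_radii, gb_energy, gb_energy_per_atom)
from bindsight.structures import AnalysisWindow, Trajectory


PARAMS = bs.GBParams()


def _pair_structure(sigma=3.4, eps=0.1, q1=0.0, q2=0.0, sep=4.0):
    atoms = [
        bs.Atom(serial=1, name="A1", element="C", residue_name="AAA",
                residue_index=1, chain_id="A", position=[0, 0, 0], charge=q1,
                lj_sigma=sigma, lj_epsilon=eps, mass=12.0, gb_radius=1.7),
        bs.Atom(serial=2, name="B1", element="C", residue_name="BBB",
                residue_index=1, chain_id="B", position=[sep, 0, 0],
                charge=q2, lj_sigma=sigma, lj_epsilon=eps, mass=12.0,
                gb_radius=1.7),
    ]
    return bs.Structure(atoms=atoms, groups={"receptor": {0}, "ligand": {1}})


class TestPairwiseMM:
    def test_lj_minimum_is_minus_epsilon(self):
        sigma, eps = 3.4, 0.25
        s = _pair_structure(sigma, eps, sep=2 ** (1 / 6) * sigma)
        e_vdw, _ = bs.pairwise_mm_terms(s, s.coords, [0], [1])
        assert e_vdw == pytest.approx(-eps, rel=1e-12)

    def test_coulomb_hand_value(self):
        s = _pair_structure(q1=1.0, q2=-1.0, sep=3.32)
        _, e_ele = bs.pairwise_mm_terms(s, s.coords, [0], [1])
        assert e_ele == pytest.approx(-COULOMB / 3.32, rel=1e-12)
        assert e_ele == pytest.approx(-100.02, abs=0.005)

    def test_empty_group_is_zero(self):
        s = _pair_structure()
        assert bs.pairwise_mm_terms(s, s.coords, [0], []) == (0.0, 0.0)

    def test_clash_raises(self):
        s = _pair_structure(sep=0.3)
        with pytest.raises(ValueError, match="clash"):
            bs.pairwise_mm_terms(s, s.coords, [0], [1])

    def test_matches_bruteforce_double_loop(self, small_complex):
        structure, _ = small_complex
        coords = structure.coords
        rec = structure.group_indices("receptor")
        lig = structure.group_indices("ligand")
        e_vdw, e_ele = bs.pairwise_mm_terms(structure, coords, rec, lig)
        ref_vdw = ref_ele = 0.0
        for i in rec:
            ai = structure.atoms[i]
            for j in lig:
                aj = structure.atoms[j]
                r = np.linalg.norm(ai.position - aj.position)
                sig = 0.5 * (ai.lj_sigma + aj.lj_sigma)
                eps = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
                ref_vdw += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
                ref_ele += COULOMB * ai.charge * aj.charge / r
        assert e_vdw == pytest.approx(ref_vdw, abs=1e-10)
        assert e_ele == pytest.approx(ref_ele, abs=1e-10)


class TestBornRadii:
    def test_isolated_atom_equals_intrinsic_minus_offset(self, born_ion):
        lig = born_ion.group_indices("ligand")
        radii = born_radii(born_ion, born_ion.coords, PARAMS, lig)
        rho = born_ion.atoms[lig[0]].gb_radius
        assert radii[0] == pytest.approx(rho - PARAMS.offset, rel=1e-12)

    def test_burial_monotonically_increases_radii(self):
        previous = None
        for sep in np.arange(6.0, 2.0, -0.5):
            s = _pair_structure(sep=sep)
            radii = born_radii(s, s.coords, PARAMS)
            if previous is not None:
                assert np.all(radii >= previous - 1e-12)
            previous = radii

    def test_protein_radii_sane(self, small_complex):
        structure, _ = small_complex
        radii = born_radii(structure, structure.coords, PARAMS)
        assert np.all(np.isfinite(radii))
        assert np.all(radii > 0.8)

    def test_nonpositive_intrinsic_radius_rejected(self):
        s = _pair_structure()
        s.atoms[0].gb_radius = 0.05
        with pytest.raises(ValueError):
            born_radii(s, s.coords, PARAMS)


class TestGBEnergy:
    def test_single_ion_reduces_to_born_formula(self, born_ion):
        lig = born_ion.group_indices("ligand")
        e = gb_energy(born_ion, born_ion.coords, lig, PARAMS)
        radius = born_ion.atoms[lig[0]].gb_radius - PARAMS.offset
        analytic = -0.5 * (1 - 1 / 78.5) * COULOMB / radius
        assert e == pytest.approx(analytic, rel=1e-6)

    def test_zero_charges_give_zero(self, small_complex):
        structure, _ = small_complex
        neutral = structure.copy()
        for a in neutral.atoms:
            a.charge = 0.0
        assert gb_energy(neutral, neutral.coords, params=PARAMS) == 0.0

    def test_three_atom_bruteforce_oracle(self):
        atoms = [bs.Atom(serial=i + 1, name=f"X{i}", element="O",
                         residue_name="AAA", residue_index=1, chain_id="A",
                         position=p, charge=q, lj_sigma=3.0, lj_epsilon=0.2,
                         mass=16.0, gb_radius=1.5)
                 for i, (p, q) in enumerate([
                     ([0, 0, 0], 0.4), ([2.8, 0, 0], -0.7),
                     ([1.0, 2.5, 0], 0.3)])]
        s = bs.Structure(atoms=atoms)
        e = gb_energy(s, s.coords, params=PARAMS)
        radii = born_radii(s, s.coords, PARAMS)
        q = s.charges
        pref = -0.5 * COULOMB * (1 - 1 / 78.5)
        ref = 0.0
        for i in range(3):
            for j in range(3):
                r2 = np.sum((s.coords[i] - s.coords[j]) ** 2)
                rr = radii[i] * radii[j]
                f = np.sqrt(r2 + rr * np.exp(-r2 / (4 * rr)))
                ref += pref * q[i] * q[j] / f
        assert e == pytest.approx(ref, abs=1e-10)

    def test_per_atom_attribution_sums_to_total(self, small_complex):
        structure, _ = small_complex
        per = gb_energy_per_atom(structure, structure.coords, params=PARAMS)
        total = gb_energy(structure, structure.coords, params=PARAMS)
        assert per.sum() == pytest.approx(total, abs=1e-10)


class TestSasa:
    def test_isolated_sphere_analytic(self, born_ion):
        lig = born_ion.group_indices("ligand")
        _, total = bs.sasa(born_ion, born_ion.coords, lig,
                           probe_radius=1.4, n_points=960)
        r = 2 ** (1 / 6) * born_ion.atoms[lig[0]].lj_sigma / 2
        assert total == pytest.approx(4 * np.pi * (r + 1.4) ** 2, rel=0.01)

    def test_fully_buried_atom_is_zero(self):
        # central atom enclosed by an octahedral cage of large spheres
        positions = [[0, 0, 0]] + [list(2.0 * np.array(v)) for v in
                                   [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                    (0, -1, 0), (0, 0, 1), (0, 0, -1)]]
        atoms = [bs.Atom(serial=i + 1, name=f"X{i}", element="C",
                         residue_name="AAA", residue_index=1, chain_id="A",
                         position=p, lj_sigma=0.0 if i == 0 else 6.0,
                         lj_epsilon=0.1, mass=12.0,
                         gb_radius=1.0 if i == 0 else 3.0)
                 for i, p in enumerate(positions)]
        s = bs.Structure(atoms=atoms)
        per, _ = bs.sasa(s, s.coords, probe_radius=1.4, n_points=960)
        assert per[0] == 0.0

    def test_two_sphere_self_convergence(self):
        s = _pair_structure(sep=3.0)
        _, coarse = bs.sasa(s, s.coords, n_points=960)
        _, fine = bs.sasa(s, s.coords, n_points=10000)
        assert coarse == pytest.approx(fine, rel=0.02)


class TestFrameBindingEnergy:
    def test_separation_limit(self, small_complex):
        structure, _ = small_complex
        coords = structure.coords
        lig = structure.group_indices("ligand")
        coords[lig] += np.array([500.0, 0.0, 0.0])
        delta = bs.frame_binding_energy(structure, coords, PARAMS)
        for term in (delta.E_vdW, delta.E_ele, delta.E_GB, delta.E_surf):
            assert abs(term) < 1e-3

    def test_gas_identity_exact(self, quiet_trajectory):
        structure, traj = quiet_trajectory
        delta = bs.frame_binding_energy(structure, traj.frames[0], PARAMS)
        assert delta.E_gas == delta.E_vdW + delta.E_ele
        assert delta.E_solv == delta.E_GB + delta.E_surf

    def test_gb_delta_matches_three_evaluations(self, quiet_trajectory):
        structure, traj = quiet_trajectory
        coords = traj.frames[3]
        rec = structure.group_indices("receptor")
        lig = structure.group_indices("ligand")
        both = np.concatenate([rec, lig])
        delta = bs.frame_binding_energy(structure, coords, PARAMS)
        ref = (gb_energy(structure, coords, both, PARAMS)
               - gb_energy(structure, coords, rec, PARAMS)
               - gb_energy(structure, coords, lig, PARAMS))
        assert delta.E_GB == pytest.approx(ref, abs=1e-10)


class TestQuasiHarmonicEntropy:
    def test_matches_analytic_harmonic_value(self):
        n_atoms, k, temp = 15, 10.0, 300.0
        traj = bs.generate_harmonic_trajectory(n_atoms, k, temp, 10000,
                                               seed=31)
        ts = bs.quasi_harmonic_entropy(traj, temperature=temp)
        mass = traj.structure.atoms[0].mass
        omega = np.sqrt(k * KCAL_TO_AMU_A2_PS2 / mass)
        x = HBAR * omega / (KB * temp)
        per_mode = KB * temp * (x / np.expm1(x) - np.log1p(-np.exp(-x)))
        analytic = (3 * n_atoms - 6) * per_mode  # six rigid modes discarded
        assert ts == pytest.approx(analytic, rel=0.02)

    def test_duplicating_frames_leaves_entropy_unchanged(self):
        traj = bs.generate_harmonic_trajectory(8, 6.0, 300.0, 2000, seed=2)
        doubled = Trajectory(structure=traj.structure,
                             frames=np.repeat(traj.frames, 2, axis=0),
                             frame_times=np.arange(2 * traj.n_frames,
                                                   dtype=float))
        a = bs.quasi_harmonic_entropy(traj, temperature=300.0)
        b = bs.quasi_harmonic_entropy(doubled, temperature=300.0)
        assert a == pytest.approx(b, rel=1e-9)


class TestAverageBindingEnergy:
    def test_delta_g_assembly_identities(self, quiet_trajectory):
        structure, traj = quiet_trajectory
        window = AnalysisWindow(0.0, traj.frame_times[-1], stride=6)
        bfe = bs.average_binding_energy(traj, window, PARAMS, entropy=-5.0)
        assert bfe.T_delta_S == -5.0
        assert bfe.enthalpy == bfe.delta.E_gas + bfe.delta.E_solv
        assert bfe.delta_G == bfe.enthalpy - bfe.T_delta_S

    def test_external_entropy_pass_through_vs_estimate(self, quiet_trajectory):
        structure, traj = quiet_trajectory
        window = AnalysisWindow(0.0, traj.frame_times[-1], stride=10)
        a = bs.average_binding_energy(traj, window, PARAMS, entropy=0.0)
        b = bs.average_binding_energy(traj, window, PARAMS,
                                      entropy_frames=6)
        # same enthalpy either way; only the entropy source differs
        assert a.enthalpy == pytest.approx(b.enthalpy, abs=1e-12)
        assert b.n_frames_entropy > 0


class TestDecomposition:
    def test_residue_sums_conserve_delta_enthalpy(self, quiet_trajectory):
        structure, traj = quiet_trajectory
        window = AnalysisWindow(0.0, traj.frame_times[-1], stride=10)
        contribs = bs.decompose_per_residue(traj, window, PARAMS)
        total = sum(c.d_subtotal for c in contribs)
        bfe = bs.average_binding_energy(traj, window, PARAMS, entropy=0.0)
        assert total == pytest.approx(bfe.enthalpy, abs=1e-3)

    def test_backbone_plus_sidechain_equals_subtotal(self, quiet_trajectory):
        structure, traj = quiet_trajectory
        window = AnalysisWindow(0.0, traj.frame_times[-1], stride=15)
        for c in bs.decompose_per_residue(traj, window, PARAMS):
            assert c.sidechain_subtotal + c.backbone_subtotal == \
                pytest.approx(c.d_subtotal, abs=1e-6)

    def test_key_flag_uses_threshold(self):
        rc = bs.ResidueContribution(
            chain_id="A", residue_index=43, residue_name="LYS",
            d_vdW=-0.81, d_ele=-7.62, d_GB=5.36, d_surf=-0.07,
            sidechain_subtotal=-2.77, backbone_subtotal=-0.37)
        assert rc.d_subtotal == pytest.approx(-3.14)
        assert abs(rc.d_subtotal) >= 0.50
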