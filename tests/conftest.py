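import numpy as np
import pytest

import bindsight as bs


@pytest.fixture(scope="session")
def small_complex():
    """Deterministic 10-residue complex with an 8-atom ligand."""
    spec = bs.SyntheticSpec(n_receptor_residues=10, n_ligand_atoms=8,
                            n_frames=300, seed=11)
    return bs.generate_complex(spec), spec


@pytest.fixture(scope="session")
def planted_trajectory(small_complex):
    """Trajectory with two planted H-bonds (occupancies 0.8 and 0.3)."""
    structure, spec = small_complex
    spec.planted_hbonds = bs.default_planted_hbonds(structure, [0.8, 0.3])
    traj = bs.generate_trajectory(structure, spec)
    return structure, spec, traj


@pytest.fixture(scope="session")
def quiet_trajectory(small_complex):
    """Fluctuation-only trajectory (no planted geometry) for energetics."""
    structure, _ = small_complex
    spec = bs.SyntheticSpec(n_receptor_residues=10, n_ligand_atoms=8,
                            n_frames=60, seed=23)
    return structure, bs.generate_trajectory(structure, spec)


@pytest.fixture(scope="session")
def born_ion():
    """Single +1 ion as the analytic generalized-Born limit case."""
    spec = bs.SyntheticSpec(n_receptor_residues=1, n_ligand_atoms=1,
                            ligand_net_charge=1.0, seed=5)
    return bs.generate_complex(spec)


def horn_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Independent best-fit RMSD oracle: Horn's closed-form quaternion
    method (largest eigenvalue of the 4x4 key matrix)."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    m = pc.T @ qc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(pc ** 2) + np.sum(qc ** 2) - 2.0 * lam) / len(p)
    return float(np.sqrt(max(msd, 0.0)))
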