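"""Single-trajectory MM/GBSA binding free energies with per-residue
decomposition.

The binding free energy is assembled end-state style::

    dG_bind = dE_vdW + dE_ele + dE_GB + dE_surf - T*dS
            = dE_gas  +  dE_solv  - T*dS
            = dH - T*dS

where every delta is complex - receptor - ligand, with receptor and ligand
coordinates extracted from the same complex frame (single-trajectory
protocol), so intramolecular bonded terms cancel exactly and only
intermolecular molecular-mechanics terms are evaluated.

Polar solvation uses the generalized Born model in the Still pairwise form
with OBC-II effective radii (HCT pairwise descreening integrals, tanh
rescaling with alpha=1.0, beta=0.8, gamma=4.85, radius offset 0.09 A).
The nonpolar term is gamma*SASA + beta with Shrake-Rupley surface areas.
The entropy term is quasi-harmonic (mass-weighted covariance, quantum
harmonic-oscillator mode entropies, six smallest modes discarded as rigid
body), with a pass-through for externally computed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as sc

from .structures import (AnalysisWindow, ResidueKey, Structure, Trajectory,
                         select_window)
from .trajectory import _iterated_mean_fit

logger = logging.getLogger(__name__)

__all__ = [
    "GBParams",
    "EnergyBreakdown",
    "BindingFreeEnergy",
    "ResidueContribution",
    "pairwise_mm_terms",
    "born_radii",
    "gb_energy",
    "sasa",
    "frame_binding_energy",
    "average_binding_energy",
    "quasi_harmonic_entropy",
    "decompose_per_residue",
]

COULOMB = 332.0637  # kcal*A/(mol*e^2)
KB = 0.0019872041  # kcal/mol/K
# hbar in kcal*ps/mol, for angular frequencies in rad/ps
HBAR = sc.hbar * sc.Avogadro / (sc.calorie * 1000.0) * 1e12
# 1 kcal/mol in amu*A^2/ps^2
KCAL_TO_AMU_A2_PS2 = 418.4

MIN_PAIR_DISTANCE = 0.5  # A; closer pairs signal broken geometry

# HCT descreening scale factors by element (AMBER GB convention)
_GB_SCREEN = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "F": 0.88,
              "P": 0.86, "S": 0.96}
_GB_SCREEN_DEFAULT = 0.80


@dataclass(frozen=True)
class GBParams:
    """Implicit-solvent and accounting parameters.

    Defaults follow the common MM/GBSA tool conventions: interior
    dielectric 1, exterior 78.5, OBC-II scaling constants, 0.09 A radius
    offset, surface tension 0.0072 kcal/(mol*A^2) with zero offset, 1.4 A
    probe, 300 K.
    """

    interior_dielectric: float = 1.0
    exterior_dielectric: float = 78.5
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85
    offset: float = 0.09  # A
    surface_tension: float = 0.0072  # kcal/(mol*A^2)
    surface_offset: float = 0.0  # kcal/mol
    probe_radius: float = 1.4  # A
    temperature: float = 300.0  # K
    sasa_points: int = 960

    def __post_init__(self) -> None:
        if self.interior_dielectric <= 0 or self.exterior_dielectric <= 0:
            raise ValueError("dielectrics must be positive")
        if self.exterior_dielectric <= self.interior_dielectric:
            raise ValueError("exterior dielectric must exceed interior")


@dataclass
class EnergyBreakdown:
    """MM/GBSA terms for one context (complex, receptor, ligand or delta).

    ``E_gas`` and ``E_solv`` are derived sums, so the accounting identities
    E_gas = E_vdW + E_ele and E_solv = E_GB + E_surf hold by construction.
    """

    E_vdW: float
    E_ele: float
    E_GB: float
    E_surf: float
    context: str = "delta"

    @property
    def E_gas(self) -> float:
        return self.E_vdW + self.E_ele

    @property
    def E_solv(self) -> float:
        return self.E_GB + self.E_surf

    @property
    def enthalpy(self) -> float:
        return self.E_gas + self.E_solv

    @property
    def polar(self) -> float:
        """Polar part of the binding energy: E_ele + E_GB."""
        return self.E_ele + self.E_GB

    @property
    def nonpolar(self) -> float:
        """Nonpolar part of the binding energy: E_vdW + E_surf."""
        return self.E_vdW + self.E_surf


@dataclass
class BindingFreeEnergy:
    """Frame-averaged binding free energy, dG = dH - T*dS."""

    delta: EnergyBreakdown
    T_delta_S: float
    sd: dict[str, float] = field(default_factory=dict)
    n_frames_energy: int = 0
    n_frames_entropy: int = 0

    @property
    def enthalpy(self) -> float:
        return self.delta.E_gas + self.delta.E_solv

    @property
    def delta_G(self) -> float:
        return self.enthalpy - self.T_delta_S


@dataclass
class ResidueContribution:
    """Per-residue share of the binding enthalpy, split by term and by
    backbone/side chain."""

    chain_id: str
    residue_index: int
    residue_name: str
    d_vdW: float
    d_ele: float
    d_GB: float
    d_surf: float
    sidechain_subtotal: float
    backbone_subtotal: float
    is_key: bool = False

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_index, self.residue_name)

    @property
    def d_subtotal(self) -> float:
        return self.d_vdW + self.d_ele + self.d_GB + self.d_surf


# ---------------------------------------------------------------------------
# Molecular-mechanics pair terms
# ---------------------------------------------------------------------------

def _pair_matrices(structure: Structure, coords: np.ndarray,
                   group_a: np.ndarray, group_b: np.ndarray,
                   interior_dielectric: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(E_vdW, E_ele) pair-energy matrices between two disjoint groups."""
    ca = coords[group_a]
    cb = coords[group_b]
    r = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    if r.size and r.min() < MIN_PAIR_DISTANCE:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise ValueError(
            f"clash: atoms {group_a[i]} and {group_b[j]} at {r[i, j]:.3f} A")
    sig_a = structure.array("lj_sigma")[group_a]
    sig_b = structure.array("lj_sigma")[group_b]
    eps_a = structure.array("lj_epsilon")[group_a]
    eps_b = structure.array("lj_epsilon")[group_b]
    sig = 0.5 * (sig_a[:, None] + sig_b[None, :])  # Lorentz-Berthelot
    eps = np.sqrt(eps_a[:, None] * eps_b[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(r > 0, (sig / r) ** 6, 0.0)
    e_vdw = 4.0 * eps * (sr6 ** 2 - sr6)
    q_a = structure.charges[group_a]
    q_b = structure.charges[group_b]
    e_ele = COULOMB * q_a[:, None] * q_b[None, :] / (interior_dielectric * r)
    return e_vdw, e_ele


def pairwise_mm_terms(structure: Structure, coords: np.ndarray,
                      group_a: np.ndarray, group_b: np.ndarray,
                      params: GBParams = GBParams()) -> tuple[float, float]:
    """Total intermolecular (E_vdW, E_ele) in kcal/mol between two disjoint
    atom groups; Lorentz-Berthelot combination, no cutoff."""
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if len(group_a) == 0 or len(group_b) == 0:
        return 0.0, 0.0
    if set(group_a.tolist()) & set(group_b.tolist()):
        raise ValueError("groups must be disjoint")
    e_vdw, e_ele = _pair_matrices(structure, coords, group_a, group_b,
                                  params.interior_dielectric)
    return float(e_vdw.sum()), float(e_ele.sum())


# ---------------------------------------------------------------------------
# Generalized Born
# ---------------------------------------------------------------------------

def born_radii(structure: Structure, coords: np.ndarray,
               params: GBParams = GBParams(),
               indices: np.ndarray | None = None) -> np.ndarray:
    """OBC-II effective Born radii (A) for the atoms in ``indices``.

    Only atoms inside ``indices`` descreen each other, so radii for an
    isolated receptor or ligand are computed on that group alone.  An
    isolated atom's effective radius equals its intrinsic radius minus the
    offset; burial (closer neighbours) can only increase it.
    """
    idx = (np.arange(structure.n_atoms) if indices is None
           else np.asarray(indices, dtype=int))
    rho = structure.array("gb_radius")[idx]
    if np.any(rho - params.offset <= 0):
        raise ValueError("intrinsic Born radius must exceed the offset")
    elements = [structure.atoms[int(i)].element for i in idx]
    screen = np.array([_GB_SCREEN.get(e, _GB_SCREEN_DEFAULT) for e in elements])
    pos = coords[idx]
    n = len(idx)
    rho_off = rho - params.offset
    sr = screen * rho_off  # scaled, offset radii
    radii = np.empty(n)
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    for i in range(n):
        r = np.delete(dist[i], i)
        s = np.delete(sr, i)
        oi = rho_off[i]
        # HCT pairwise descreening integral
        mask = oi < r + s
        r_m, s_m = r[mask], s[mask]
        L = np.maximum(oi, np.abs(r_m - s_m))
        U = r_m + s_m
        term = (1.0 / L - 1.0 / U
                + 0.25 * r_m * (1.0 / U ** 2 - 1.0 / L ** 2)
                + 0.5 / r_m * np.log(L / U)
                + 0.25 * s_m ** 2 / r_m * (1.0 / L ** 2 - 1.0 / U ** 2))
        inner = oi < s_m - r_m
        term = term + np.where(inner, 2.0 * (1.0 / oi - 1.0 / L), 0.0)
        psi = 0.5 * oi * term.sum()
        t = np.tanh(params.obc_alpha * psi - params.obc_beta * psi ** 2
                    + params.obc_gamma * psi ** 3)
        inv = 1.0 / oi - t / rho[i]
        if inv <= 0:
            raise ValueError(f"nonpositive effective Born radius for atom {idx[i]}")
        radii[i] = 1.0 / inv
    return radii


def gb_energy(structure: Structure, coords: np.ndarray,
              group: np.ndarray | None = None,
              params: GBParams = GBParams(),
              _per_atom: bool = False) -> float | np.ndarray:
    """Still pairwise generalized-Born polar solvation energy (kcal/mol).

    E_GB = -1/2 (1/eps_in - 1/eps_out) * k * sum_ij q_i q_j / f_GB with
    f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))); the double sum runs
    over all ordered pairs including i = j (the Born self terms), so a
    single ion reduces to the analytic Born formula.
    """
    idx = (np.arange(structure.n_atoms) if group is None
           else np.asarray(group, dtype=int))
    if len(idx) == 0:
        return np.zeros(0) if _per_atom else 0.0
    radii = born_radii(structure, coords, params, idx)
    q = structure.charges[idx]
    pos = coords[idx]
    r2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    rr = radii[:, None] * radii[None, :]
    f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    pref = -0.5 * COULOMB * (1.0 / params.interior_dielectric
                             - 1.0 / params.exterior_dielectric)
    contrib = pref * q[:, None] * q[None, :] / f
    if _per_atom:
        return contrib.sum(axis=1)  # row sums: symmetric half-split per atom
    return float(contrib.sum())


def gb_energy_per_atom(structure: Structure, coords: np.ndarray,
                       group: np.ndarray | None = None,
                       params: GBParams = GBParams()) -> np.ndarray:
    """Per-atom attribution of E_GB (row sums of the pair matrix); sums
    exactly to :func:`gb_energy`."""
    return gb_energy(structure, coords, group, params, _per_atom=True)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

_SPHERE_CACHE: dict[int, np.ndarray] = {}


def _unit_sphere(n_points: int) -> np.ndarray:
    """Deterministic golden-spiral points on the unit sphere."""
    if n_points not in _SPHERE_CACHE:
        k = np.arange(n_points) + 0.5
        phi = np.arccos(1.0 - 2.0 * k / n_points)
        theta = np.pi * (1.0 + np.sqrt(5.0)) * k
        _SPHERE_CACHE[n_points] = np.column_stack([
            np.sin(phi) * np.cos(theta),
            np.sin(phi) * np.sin(theta),
            np.cos(phi)])
    return _SPHERE_CACHE[n_points]


def _atomic_radius(atom) -> float:
    """Hard-sphere radius for SASA: half the LJ minimum distance, falling
    back to the intrinsic Born radius when no LJ parameters are set."""
    if atom.lj_sigma > 0:
        return 2.0 ** (1.0 / 6.0) * atom.lj_sigma / 2.0
    return atom.gb_radius


def sasa(structure: Structure, coords: np.ndarray,
         group: np.ndarray | None = None,
         probe_radius: float = 1.4,
         n_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area (A^2).

    Returns (per-atom areas over ``group``, total).
    """
    idx = (np.arange(structure.n_atoms) if group is None
           else np.asarray(group, dtype=int))
    if len(idx) == 0:
        return np.zeros(0), 0.0
    radii = np.array([_atomic_radius(structure.atoms[int(i)]) for i in idx])
    pos = coords[idx]
    ext = radii + probe_radius
    sphere = _unit_sphere(n_points)
    per_atom = np.empty(len(idx))
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    for a in range(len(idx)):
        # neighbours whose extended spheres can occlude atom a
        nb = np.nonzero((dist[a] < ext[a] + ext) & (np.arange(len(idx)) != a))[0]
        pts = pos[a] + ext[a] * sphere
        if len(nb):
            d2 = np.sum((pts[:, None, :] - pos[nb][None, :, :]) ** 2, axis=-1)
            buried = np.any(d2 < (ext[nb] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[a] = 4.0 * np.pi * ext[a] ** 2 * frac
    return per_atom, float(per_atom.sum())


# ---------------------------------------------------------------------------
# Frame and trajectory binding energies
# ---------------------------------------------------------------------------

def frame_binding_energy(structure: Structure, coords: np.ndarray,
                         params: GBParams = GBParams()) -> EnergyBreakdown:
    """Single-frame delta = complex - receptor - ligand energy breakdown.

    Receptor and ligand coordinates are taken from the same complex frame,
    so bonded and intramolecular MM terms cancel and dE_vdW/dE_ele reduce
    to the intermolecular pair sums.  dE_GB and dE_surf are three-state
    differences with radii and surfaces recomputed per context.
    """
    rec = structure.group_indices("receptor")
    lig = structure.group_indices("ligand")
    both = np.concatenate([rec, lig])
    e_vdw, e_ele = pairwise_mm_terms(structure, coords, rec, lig, params)
    e_gb = (gb_energy(structure, coords, both, params)
            - gb_energy(structure, coords, rec, params)
            - gb_energy(structure, coords, lig, params))
    gamma, beta = params.surface_tension, params.surface_offset
    s_c = sasa(structure, coords, both, params.probe_radius, params.sasa_points)[1]
    s_r = sasa(structure, coords, rec, params.probe_radius, params.sasa_points)[1]
    s_l = sasa(structure, coords, lig, params.probe_radius, params.sasa_points)[1]
    e_surf = gamma * (s_c - s_r - s_l) - beta
    return EnergyBreakdown(E_vdW=e_vdw, E_ele=e_ele, E_GB=float(e_gb),
                           E_surf=float(e_surf), context="delta")


def quasi_harmonic_entropy(traj: Trajectory,
                           atom_subset: np.ndarray | None = None,
                           temperature: float = 300.0) -> float:
    """Quasi-harmonic configurational entropy as T*S (kcal/mol).

    Frames are superposed to their mean structure, the mass-weighted
    covariance matrix is diagonalised, each eigenvalue is treated as a
    harmonic mode of frequency omega = sqrt(k_B T / lambda) and assigned
    the quantum harmonic-oscillator entropy; the six smallest modes are
    discarded as residual rigid-body freedom.
    """
    idx = (np.arange(traj.structure.n_atoms) if atom_subset is None
           else np.asarray(atom_subset, dtype=int))
    masses = traj.structure.masses[idx]
    frames = traj.frames[:, idx, :]
    n_frames, m, _ = frames.shape
    if n_frames < 3 * m:
        logger.warning(
            "quasi-harmonic entropy: %d frames < 3 x %d atoms; estimate "
            "may be poorly conditioned", n_frames, m)
    if m >= 3:
        frames = _iterated_mean_fit(frames, np.arange(m))
    x = frames.reshape(n_frames, 3 * m)
    x = x - x.mean(axis=0)
    w = np.repeat(np.sqrt(masses), 3)
    cov = (x * w).T @ (x * w) / n_frames  # amu*A^2
    lam = np.linalg.eigvalsh(cov)
    lam = lam[::-1]  # descending
    n_discard = min(6, len(lam))
    lam = lam[: len(lam) - n_discard]
    lam = lam[lam > 1e-10]
    if len(lam) == 0:
        logger.warning("quasi-harmonic entropy: no usable modes; returning 0")
        return 0.0
    kt = KB * temperature
    omega = np.sqrt(kt * KCAL_TO_AMU_A2_PS2 / lam)  # rad/ps
    xred = HBAR * omega / kt
    ts_modes = kt * (xred / np.expm1(xred) - np.log1p(-np.exp(-xred)))
    return float(ts_modes.sum())


def average_binding_energy(traj: Trajectory, window: AnalysisWindow,
                           params: GBParams = GBParams(),
                           entropy: float | None = None,
                           entropy_frames: int = 100) -> BindingFreeEnergy:
    """Frame-averaged MM/GBSA binding free energy over a window.

    Each delta term is averaged with its standard deviation.  ``entropy``
    (as T*dS, kcal/mol) short-circuits the quasi-harmonic estimate, which
    otherwise uses a subsample of at most ``entropy_frames`` frames and
    computes T*dS = T*S(complex) - T*S(receptor) - T*S(ligand).
    """
    sub = select_window(traj, window)
    if sub.n_frames < 2:
        raise ValueError("need at least 2 frames in the analysis window")
    terms = {"E_vdW": [], "E_ele": [], "E_GB": [], "E_surf": []}
    for f in range(sub.n_frames):
        bd = frame_binding_energy(traj.structure, sub.frames[f], params)
        for k in terms:
            terms[k].append(getattr(bd, k))
    means = {k: float(np.mean(v)) for k, v in terms.items()}
    sds = {k: float(np.std(v)) for k, v in terms.items()}
    delta = EnergyBreakdown(**means, context="delta")

    if entropy is not None:
        t_ds = entropy
        n_ent = 0
    else:
        step = max(1, sub.n_frames // entropy_frames)
        ent_traj = Trajectory(structure=sub.structure,
                              frames=sub.frames[::step],
                              frame_times=sub.frame_times[::step],
                              native_dt=sub.native_dt)
        rec = traj.structure.group_indices("receptor")
        lig = traj.structure.group_indices("ligand")
        both = np.concatenate([rec, lig])
        t = params.temperature
        t_ds = (quasi_harmonic_entropy(ent_traj, both, t)
                - quasi_harmonic_entropy(ent_traj, rec, t)
                - quasi_harmonic_entropy(ent_traj, lig, t))
        n_ent = ent_traj.n_frames
    return BindingFreeEnergy(delta=delta, T_delta_S=float(t_ds), sd=sds,
                             n_frames_energy=sub.n_frames,
                             n_frames_entropy=n_ent)


# ---------------------------------------------------------------------------
# Per-residue decomposition
# ---------------------------------------------------------------------------

def decompose_per_residue(traj: Trajectory, window: AnalysisWindow,
                          params: GBParams = GBParams(),
                          key_threshold: float = 0.50
                          ) -> list[ResidueContribution]:
    """Per-residue share of the binding enthalpy, averaged over a window.

    Per frame, every intermolecular vdW/electrostatic pair energy is split
    half to each partner atom; the GB delta is attributed per atom as the
    difference of its symmetric pair-matrix row sums between the complex
    and the isolated context; the surface delta as gamma times the
    per-atom SASA difference.  Ligand-side halves accumulate under the
    ligand's own residue.  Residue sums over all atoms therefore conserve
    the total delta enthalpy frame by frame.  Residues whose mean subtotal
    magnitude reaches ``key_threshold`` (kcal/mol) are flagged as key.
    """
    structure = traj.structure
    sub = select_window(traj, window)
    rec = structure.group_indices("receptor")
    lig = structure.group_indices("ligand")
    both = np.concatenate([rec, lig])
    n = structure.n_atoms
    acc = {k: np.zeros(n) for k in ("vdw", "ele", "gb", "surf")}
    gamma = params.surface_tension

    for f in range(sub.n_frames):
        coords = sub.frames[f]
        e_vdw, e_ele = _pair_matrices(structure, coords, rec, lig,
                                      params.interior_dielectric)
        acc["vdw"][rec] += 0.5 * e_vdw.sum(axis=1)
        acc["vdw"][lig] += 0.5 * e_vdw.sum(axis=0)
        acc["ele"][rec] += 0.5 * e_ele.sum(axis=1)
        acc["ele"][lig] += 0.5 * e_ele.sum(axis=0)

        gb_c = gb_energy_per_atom(structure, coords, both, params)
        gb_r = gb_energy_per_atom(structure, coords, rec, params)
        gb_l = gb_energy_per_atom(structure, coords, lig, params)
        acc["gb"][both] += gb_c
        acc["gb"][rec] -= gb_r
        acc["gb"][lig] -= gb_l

        s_c = sasa(structure, coords, both, params.probe_radius,
                   params.sasa_points)[0]
        s_r = sasa(structure, coords, rec, params.probe_radius,
                   params.sasa_points)[0]
        s_l = sasa(structure, coords, lig, params.probe_radius,
                   params.sasa_points)[0]
        acc["surf"][both] += gamma * s_c
        acc["surf"][rec] -= gamma * s_r
        acc["surf"][lig] -= gamma * s_l

    for k in acc:
        acc[k] /= sub.n_frames

    per_res: dict[ResidueKey, dict[str, float]] = {}
    for i, atom in enumerate(structure.atoms):
        d = per_res.setdefault(atom.residue_key, {
            "vdw": 0.0, "ele": 0.0, "gb": 0.0, "surf": 0.0,
            "side": 0.0, "back": 0.0})
        atom_total = sum(acc[k][i] for k in ("vdw", "ele", "gb", "surf"))
        for k in ("vdw", "ele", "gb", "surf"):
            d[k] += acc[k][i]
        if atom.is_backbone:
            d["back"] += atom_total
        else:
            d["side"] += atom_total

    out = []
    for (chain, resid, resname), d in sorted(per_res.items()):
        rc = ResidueContribution(
            chain_id=chain, residue_index=resid, residue_name=resname,
            d_vdW=d["vdw"], d_ele=d["ele"], d_GB=d["gb"], d_surf=d["surf"],
            sidechain_subtotal=d["side"], backbone_subtotal=d["back"])
        rc.is_key = abs(rc.d_subtotal) >= key_threshold
        out.append(rc)
    return out
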