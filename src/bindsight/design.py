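"""Two-stage combinatorial R-group design.

Stage one enumerates single-region modifications of a four-region
scaffold (an ATP-competitive kinase-inhibitor chemotype: a hinge-binding
amine-pyrimidine core whose four substitution sites R1-R4 are varied one
at a time).  After scoring, the top-k groups per region are selected and
crossed into the full combination library, named ``C{r1}{r2}{r3}{r4}``
from the 1-based group indices.  Named variants (e.g. deletion of the
benzylic methylene linker, suffix ``-A``) are applied as SMARTS-driven
edits.

All SMILES handling goes through RDKit; assembled compounds are
canonicalized, which makes duplicate detection and the uniqueness
invariants exact.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "GroupEntry",
    "GroupLibrary",
    "Scaffold",
    "CompoundSpec",
    "VariantEdit",
    "METHYLENE_DELETION",
    "assemble_smiles",
    "enumerate_one_region",
    "select_top_groups",
    "combine_regions",
    "apply_variant",
    "parse_name",
    "default_scaffold",
    "default_libraries",
    "default_base_groups",
    "combination_scaffold",
    "combination_libraries",
]

REGION_ORDER = ("R1", "R2", "R3", "R4")
HYDROGEN_FRAGMENT = "[*][H]"


@dataclass(frozen=True)
class GroupEntry:
    """One R-group: a SMILES fragment with exactly one attachment point."""

    label: str
    smiles: str
    description: str = ""

    def canonical_fragment(self) -> str:
        if self.smiles == HYDROGEN_FRAGMENT:
            return HYDROGEN_FRAGMENT
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"entry {self.label}: invalid fragment SMILES "
                             f"{self.smiles!r}")
        if sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0) != 1:
            raise ValueError(
                f"entry {self.label}: fragment must have exactly one "
                f"attachment point")
        return Chem.MolToSmiles(mol)


@dataclass
class GroupLibrary:
    """Ordered R-group candidates for one region."""

    region: str
    entries: list[GroupEntry]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate labels in {self.region} library")
        for e in self.entries:
            e.canonical_fragment()  # validates

    def by_label(self, label: str) -> GroupEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(f"{self.region} has no entry {label!r}")


@dataclass(frozen=True)
class Scaffold:
    """Invariant core with four numbered attachment points ``[*:1]..[*:4]``.

    The attachment map numbers correspond to regions via ``region_points``.
    """

    smiles: str
    region_points: dict[str, int] = field(
        default_factory=lambda: {"R1": 1, "R2": 2, "R3": 3, "R4": 4})
    description: str = ""

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"invalid scaffold SMILES {self.smiles!r}")
        maps = sorted(a.GetAtomMapNum() for a in mol.GetAtoms()
                      if a.GetAtomicNum() == 0 and a.GetAtomMapNum())
        if maps != sorted(self.region_points.values()):
            raise ValueError(
                f"scaffold attachment points {maps} do not match "
                f"region_points {self.region_points}")


@dataclass
class CompoundSpec:
    """An assembled compound: group choice, name and canonical SMILES."""

    name: str
    group_choice: dict[str, str]  # region -> entry label
    smiles: str
    variant_tag: str = ""
    modified_region: str | None = None
    scores: dict[str, float] = field(default_factory=dict)
    aggregate_score: float | None = None

    @property
    def heavy_atoms(self) -> int:
        return Chem.MolFromSmiles(self.smiles).GetNumHeavyAtoms()


# ---------------------------------------------------------------------------
# Fragment assembly
# ---------------------------------------------------------------------------

def _find_dummy(mol: Chem.Mol, map_num: int | None = None) -> int:
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and (
                map_num is None or atom.GetAtomMapNum() == map_num):
            return atom.GetIdx()
    raise ValueError(f"no attachment point {map_num} found")


def assemble_smiles(scaffold: Scaffold,
                    groups: dict[str, GroupEntry]) -> str:
    """Substitute one fragment per region at the scaffold's attachment
    points; returns the canonical SMILES of the assembled molecule."""
    mol = Chem.MolFromSmiles(scaffold.smiles)
    for region in sorted(scaffold.region_points, key=scaffold.region_points.get):
        map_num = scaffold.region_points[region]
        entry = groups[region]
        dummy = _find_dummy(mol, map_num)
        if entry.smiles == HYDROGEN_FRAGMENT:
            rw = Chem.RWMol(mol)
            rw.RemoveAtom(dummy)
            mol = rw.GetMol()
        else:
            frag = Chem.MolFromSmiles(entry.smiles)
            if frag is None:
                raise ValueError(
                    f"entry {entry.label}: invalid fragment SMILES")
            fdummy = _find_dummy(frag)
            fnb = frag.GetAtomWithIdx(fdummy).GetNeighbors()[0].GetIdx()
            nb = mol.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
            offset = mol.GetNumAtoms()
            rw = Chem.RWMol(Chem.CombineMols(mol, frag))
            rw.AddBond(nb, fnb + offset, Chem.BondType.SINGLE)
            for idx in sorted((dummy, fdummy + offset), reverse=True):
                rw.RemoveAtom(idx)
            mol = rw.GetMol()
        Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _make_compound(scaffold: Scaffold, libraries: dict[str, GroupLibrary],
                   choice: dict[str, str], name: str,
                   modified_region: str | None = None) -> CompoundSpec:
    groups = {r: libraries[r].by_label(lbl) for r, lbl in choice.items()}
    smiles = assemble_smiles(scaffold, groups)
    return CompoundSpec(name=name, group_choice=dict(choice), smiles=smiles,
                        modified_region=modified_region)


# ---------------------------------------------------------------------------
# Stage 1: one-region enumeration
# ---------------------------------------------------------------------------

def enumerate_one_region(scaffold: Scaffold,
                         libraries: list[GroupLibrary],
                         base: dict[str, GroupEntry]) -> list[CompoundSpec]:
    """Substitute each library entry into its region while holding the
    other three regions at the base (parent-compound) groups.

    Entries whose fragment equals the base group of their region are
    dropped, so the compound count is the summed library sizes minus
    duplicates of the parent.
    """
    lib_map = {lib.region: lib for lib in libraries}
    base_frag = {r: e.canonical_fragment() for r, e in base.items()}
    compounds = []
    for region in REGION_ORDER:
        if region not in lib_map:
            continue
        for entry in lib_map[region].entries:
            if entry.canonical_fragment() == base_frag[region]:
                continue
            groups = dict(base)
            groups[region] = entry
            smiles = assemble_smiles(scaffold, groups)
            choice = {r: (entry.label if r == region else base[r].label)
                      for r in REGION_ORDER}
            compounds.append(CompoundSpec(
                name=entry.label, group_choice=choice, smiles=smiles,
                modified_region=region))
    return compounds


# ---------------------------------------------------------------------------
# Stage 2: top-k selection and full combination
# ---------------------------------------------------------------------------

def select_top_groups(scored: list[CompoundSpec],
                      libraries: list[GroupLibrary],
                      per_region: int = 3,
                      base: dict[str, GroupEntry] | None = None,
                      base_score: float | None = None
                      ) -> list[GroupLibrary]:
    """Keep the ``per_region`` best groups per region by aggregate score.

    Scores are kcal/mol, more negative = better; ties break in favour of
    the earlier library entry.  When ``base``/``base_score`` are supplied
    the parent compound's group competes in every region.
    """
    if per_region < 1:
        raise ValueError("per_region must be >= 1")
    lib_map = {lib.region: lib for lib in libraries}
    ranked: dict[str, list[tuple[float, int, GroupEntry]]] = {
        r: [] for r in lib_map}
    for c in scored:
        if c.aggregate_score is None:
            raise ValueError(f"compound {c.name} is unscored")
        region = c.modified_region
        if region is None or region not in lib_map:
            continue
        label = c.group_choice[region]
        lib = lib_map[region]
        order = [e.label for e in lib.entries].index(label)
        ranked[region].append((c.aggregate_score, order, lib.by_label(label)))
    if base is not None and base_score is not None:
        for region, entry in base.items():
            if region in ranked:
                # base group ranks ahead of any library entry on exact ties
                ranked[region].append((base_score, -1, entry))
    reduced = []
    for region in REGION_ORDER:
        if region not in ranked:
            continue
        ranked[region].sort(key=lambda t: (t[0], t[1]))
        top = [e for _, _, e in ranked[region][:per_region]]
        reduced.append(GroupLibrary(region=region, entries=top))
    return reduced


def combine_regions(scaffold: Scaffold,
                    reduced: list[GroupLibrary]) -> list[CompoundSpec]:
    """Full Cartesian product of the reduced libraries.

    Output size is the product of the per-region sizes; names are
    ``"C" + <1-based group indices in region order>`` (e.g. C1333 = first
    R1 group, third R2, third R3, third R4).
    """
    lib_map = {lib.region: lib for lib in reduced}
    regions = [r for r in REGION_ORDER if r in lib_map]
    index_ranges = [range(1, len(lib_map[r].entries) + 1) for r in regions]
    compounds = []
    names = set()
    for combo in itertools.product(*index_ranges):
        name = "C" + "".join(str(i) for i in combo)
        assert name not in names, f"name collision at {name}"
        names.add(name)
        groups = {r: lib_map[r].entries[i - 1] for r, i in zip(regions, combo)}
        smiles = assemble_smiles(scaffold, groups)
        choice = {r: groups[r].label for r in regions}
        compounds.append(CompoundSpec(name=name, group_choice=choice,
                                      smiles=smiles))
    return compounds


def parse_name(name: str, reduced: list[GroupLibrary]
               ) -> tuple[dict[str, str], str]:
    """Invert the combination naming scheme: ``C2213-A`` -> (group choice,
    variant tag)."""
    m = re.fullmatch(r"C(\d+)((?:-\w+)?)", name)
    if not m:
        raise ValueError(f"not a combination compound name: {name!r}")
    digits, tag = m.group(1), m.group(2)
    regions = [lib.region for lib in reduced]
    if len(digits) != len(regions):
        raise ValueError(f"{name!r} does not encode {len(regions)} regions")
    choice = {}
    for region, ch in zip(regions, digits):
        lib = next(l for l in reduced if l.region == region)
        idx = int(ch)
        if not 1 <= idx <= len(lib.entries):
            raise ValueError(f"{name!r}: index {idx} out of range for {region}")
        choice[region] = lib.entries[idx - 1].label
    return choice, tag


# ---------------------------------------------------------------------------
# Named variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantEdit:
    """A SMARTS-driven single-atom deletion with rebonding.

    ``smarts`` must match three mapped atoms (keep, delete, keep); the
    deleted atom's two flanking atoms are joined by a single bond.
    """

    tag: str
    smarts: str
    description: str = ""


#: deletion of the benzylic methylene between an aromatic ring and a ring
#: amine (e.g. benzene-CH2-piperazine -> benzene-piperazine)
METHYLENE_DELETION = VariantEdit(
    tag="-A",
    smarts="[c:1][CH2;D2:2][NX3;R:3]",
    description="remove the methylene linker between the aryl ring and the "
                "ring amine")


def apply_variant(compound: CompoundSpec,
                  variant: VariantEdit = METHYLENE_DELETION) -> CompoundSpec:
    """Apply a named edit, yielding e.g. ``C2213 -> C2213-A``.

    Raises ``ValueError`` when the edit pattern is absent (including when
    the same edit is applied twice)."""
    mol = Chem.MolFromSmiles(compound.smiles)
    patt = Chem.MolFromSmarts(variant.smarts)
    matches = mol.GetSubstructMatches(patt)
    if not matches:
        raise ValueError(
            f"variant {variant.tag}: pattern {variant.smarts!r} not found in "
            f"{compound.name}")
    keep_a, delete, keep_b = matches[0]
    rw = Chem.RWMol(mol)
    rw.AddBond(keep_a, keep_b, Chem.BondType.SINGLE)
    rw.RemoveAtom(delete)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return replace(compound,
                   name=compound.name + variant.tag,
                   smiles=Chem.MolToSmiles(out),
                   variant_tag=compound.variant_tag + variant.tag,
                   scores={}, aggregate_score=None)


# ---------------------------------------------------------------------------
# Shipped default chemistry
# ---------------------------------------------------------------------------

def default_scaffold() -> Scaffold:
    """One-region-stage scaffold: amine-pyrimidine hinge binder with the
    R1 ring system, the R2 pyrimidine substituent, the R3 aryl substituent
    and the R4 piperazine N-substituent as open positions."""
    return Scaffold(
        smiles="[*:1]c1nc(Nc2ccc(CN3CCN([*:4])CC3)c([*:3])c2)ncc1[*:2]",
        description="2-anilino-pyrimidine core; benzylic methylene to the "
                    "solvent-exposed piperazine")


def default_base_groups() -> dict[str, GroupEntry]:
    """Parent-compound (abemaciclib-analogue) group choice."""
    return {
        "R1": GroupEntry("R1-base", "[*]c1cc2c(cc1F)n(C(C)C)c(C)n2",
                         "4-fluoro-1-isopropyl-2-methylbenzimidazol-6-yl"),
        "R2": GroupEntry("R2-base", "[*]F", "fluoro"),
        "R3": GroupEntry("R3-base", HYDROGEN_FRAGMENT, "hydrogen"),
        "R4": GroupEntry("R4-base", "[*]CC", "ethyl"),
    }


# R1 ring-system cores x N-substituents; the benzimidazole -> azaindazole /
# triazolopyridine swaps probe the hydrogen-bond network around the K43
# pocket, the N-alkyl size probes the V27 hydrophobic contact.
_R1_CORES = {
    "benzimidazole": "[*]c1cc2c(cc1F)n({sub})c(C)n2",
    "imidazopyridine": "[*]c1cc2c(cn1)n({sub})c(C)n2",
    "triazolopyridine": "[*]c1cc2c(cn1)n({sub})nn2",
    "pyrazolopyridine": "[*]c1cc2cnn({sub})c2nc1",
}
_N_SUBS = {"isopropyl": "C(C)C", "cyclopropyl": "C1CC1",
           "cyclopentyl": "C1CCCC1"}


def default_libraries() -> list[GroupLibrary]:
    """The 42-entry one-region modification library (R1 a-m, R2 a-h,
    R3 a-i, R4 a-l)."""
    def core(c, s):
        return _R1_CORES[c].format(sub=_N_SUBS[s])

    r1 = GroupLibrary("R1", [
        GroupEntry("R1a", core("imidazopyridine", "isopropyl"),
                   "pyridine-fused imidazole, N-isopropyl"),
        GroupEntry("R1b", core("triazolopyridine", "isopropyl"),
                   "1,2,3-triazolopyridine, N-isopropyl"),
        GroupEntry("R1c", core("benzimidazole", "cyclopropyl"),
                   "fluorobenzimidazole, N-cyclopropyl"),
        GroupEntry("R1d", core("benzimidazole", "cyclopentyl"),
                   "fluorobenzimidazole, N-cyclopentyl"),
        GroupEntry("R1e", core("triazolopyridine", "cyclopropyl"),
                   "triazolopyridine, N-cyclopropyl"),
        GroupEntry("R1f", core("triazolopyridine", "cyclopentyl"),
                   "1-cyclopentyl-triazolopyridine"),
        GroupEntry("R1g", core("imidazopyridine", "cyclopropyl"),
                   "imidazopyridine, N-cyclopropyl"),
        GroupEntry("R1h", core("imidazopyridine", "cyclopentyl"),
                   "imidazopyridine, N-cyclopentyl"),
        GroupEntry("R1i", "[*]c1cc(C)n(C(C)C)n1", "1H-pyrazole, N-isopropyl"),
        GroupEntry("R1j", core("pyrazolopyridine", "isopropyl"),
                   "pyrazolopyridine, N-isopropyl"),
        GroupEntry("R1k", core("pyrazolopyridine", "cyclopropyl"),
                   "pyrazolopyridine, N-cyclopropyl"),
        GroupEntry("R1l", "[*]c1cc2c(cc1)n(C(C)C)c(C)n2",
                   "des-fluoro benzimidazole, N-isopropyl"),
        GroupEntry("R1m", core("pyrazolopyridine", "cyclopentyl"),
                   "1-cyclopentyl-pyrazolopyridine"),
    ])
    r2 = GroupLibrary("R2", [
        GroupEntry("R2a", "[*]C", "methyl"),
        GroupEntry("R2b", "[*]C1CC1", "cyclopropyl"),
        GroupEntry("R2c", HYDROGEN_FRAGMENT, "hydrogen"),
        GroupEntry("R2d", "[*]Cl", "chloro"),
        GroupEntry("R2e", "[*]C=O", "formyl"),
        GroupEntry("R2f", "[*]CC1CC1", "cyclopropylmethyl"),
        GroupEntry("R2g", "[*]C(F)(F)F", "trifluoromethyl"),
        GroupEntry("R2h", "[*]CC", "ethyl"),
    ])
    r3 = GroupLibrary("R3", [
        GroupEntry("R3a", "[*]N", "amino"),
        GroupEntry("R3b", "[*]Cl", "chloro"),
        GroupEntry("R3c", "[*]Br", "bromo"),
        GroupEntry("R3d", "[*]C#N", "cyano"),
        GroupEntry("R3e", "[*]F", "fluoro"),
        GroupEntry("R3f", "[*]C", "methyl"),
        GroupEntry("R3g", "[*]CC", "ethyl"),
        GroupEntry("R3h", "[*]O", "hydroxyl"),
        GroupEntry("R3i", "[*]OC", "methoxy"),
    ])
    r4 = GroupLibrary("R4", [
        GroupEntry("R4a", HYDROGEN_FRAGMENT, "hydrogen (secondary amine)"),
        GroupEntry("R4b", "[*]C(C)C", "isopropyl"),
        GroupEntry("R4c", "[*]C(C)=O", "acetyl"),
        GroupEntry("R4d", "[*]CCO", "2-hydroxyethyl"),
        GroupEntry("R4e", "[*]CCC", "propyl"),
        GroupEntry("R4f", "[*]C1CCCCC1", "cyclohexyl"),
        GroupEntry("R4g", "[*]C", "methyl"),
        GroupEntry("R4h", "[*]C(C)(C)C", "tert-butyl"),
        GroupEntry("R4i", "[*]C1CC1", "cyclopropyl"),
        GroupEntry("R4j", "[*]C1CCCC1", "cyclopentyl"),
        GroupEntry("R4k", "[*]CCF", "2-fluoroethyl"),
        GroupEntry("R4l", "[*]c1ccccc1", "phenyl"),
    ])
    return [r1, r2, r3, r4]


def combination_scaffold() -> Scaffold:
    """Combination-stage scaffold with the R1 ring fixed as
    pyrazolopyridine (its N-substituent open), the R2 position on the
    pyrimidine, R3 on the aniline ring, R4 on the piperazine nitrogen."""
    return Scaffold(
        smiles="[*:2]c1cnc(Nc2ccc(CN3CCN([*:4])CC3)c([*:3])c2)nc1-c1cc2cnn([*:1])c2nc1",
        description="pyrazolopyridinyl amine-pyrimidine; benzylic methylene "
                    "to the piperazine (deleted in -A variants)")


def combination_libraries() -> list[GroupLibrary]:
    """The reduced 3-per-region libraries used for the 81-compound cross
    (R1: isopropyl/cyclopropyl/cyclopentyl N-substituents; R2: H/F/methyl;
    R3: H/F/methoxy; R4: H/methyl/isopropyl)."""
    return [
        GroupLibrary("R1", [
            GroupEntry("R1-1", "[*]C(C)C", "isopropyl"),
            GroupEntry("R1-2", "[*]C1CC1", "cyclopropyl"),
            GroupEntry("R1-3", "[*]C1CCCC1", "cyclopentyl"),
        ]),
        GroupLibrary("R2", [
            GroupEntry("R2-1", HYDROGEN_FRAGMENT, "hydrogen"),
            GroupEntry("R2-2", "[*]F", "fluoro"),
            GroupEntry("R2-3", "[*]C", "methyl"),
        ]),
        GroupLibrary("R3", [
            GroupEntry("R3-1", HYDROGEN_FRAGMENT, "hydrogen"),
            GroupEntry("R3-2", "[*]F", "fluoro"),
            GroupEntry("R3-3", "[*]OC", "methoxy"),
        ]),
        GroupLibrary("R4", [
            GroupEntry("R4-1", HYDROGEN_FRAGMENT, "hydrogen"),
            GroupEntry("R4-2", "[*]C", "methyl"),
            GroupEntry("R4-3", "[*]C(C)C", "isopropyl"),
        ]),
    ]
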