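"""Region-annotated binding-model report.

Fuses per-residue enthalpy contributions, hydrogen-bond occupancies and
geometric monitors into the interaction summary that drives R-group
design: which residues anchor the ligand through stable hydrogen bonds,
which contact it through pi-alkyl interactions, and which oppose binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gbsa import ResidueContribution
from .structures import ResidueKey, Structure
from .trajectory import HBondRecord

__all__ = [
    "RegionMap",
    "InteractionThresholds",
    "BindingModelReport",
    "assign_regions",
    "classify_interactions",
]

INTERACTION_CLASSES = ("hydrogen-bond", "unstable-hydrogen-bond", "pi-alkyl",
                       "unfavorable")


@dataclass
class RegionMap:
    """Disjoint ligand atom sets defining the design regions R1-R4.

    Ligand atoms not claimed by any region are listed as linker atoms.
    """

    regions: dict[str, set[int]]
    annotations: dict[str, str] = field(default_factory=dict)
    linker: set[int] = field(default_factory=set)

    def region_of(self, atom_index: int) -> str | None:
        for name, members in self.regions.items():
            if atom_index in members:
                return name
        return None


def assign_regions(structure: Structure,
                   region_spec: dict[str, list[int]],
                   annotations: dict[str, str] | None = None) -> RegionMap:
    """Validate a user-supplied region partition of the ligand.

    Region atom sets must be disjoint and lie inside the ligand group;
    unassigned ligand atoms become linker atoms.
    """
    ligand = set(structure.group_indices("ligand").tolist())
    seen: dict[int, str] = {}
    regions: dict[str, set[int]] = {}
    for name, indices in region_spec.items():
        members = set(int(i) for i in indices)
        outside = members - ligand
        if outside:
            raise ValueError(
                f"region {name}: atoms {sorted(outside)} are not ligand atoms")
        for i in members:
            if i in seen:
                raise ValueError(
                    f"regions {seen[i]} and {name} overlap at atom {i}")
            seen[i] = name
        regions[name] = members
    linker = ligand - set(seen)
    return RegionMap(regions=regions, annotations=dict(annotations or {}),
                     linker=linker)


@dataclass(frozen=True)
class InteractionThresholds:
    """Class boundaries for the interaction report.

    Only the key-residue contribution threshold (0.50 kcal/mol) comes from
    the decomposition convention; the occupancy bands and the pi-alkyl
    distance are package defaults, all configurable.
    """

    key_threshold: float = 0.50  # kcal/mol, |subtotal| for key residues
    stable_occupancy: float = 50.0  # percent
    occupancy_floor: float = 10.0  # percent, below = no H-bond class
    pi_alkyl_distance: float = 4.5  # A, mean ring-carbon heavy-atom distance


@dataclass
class BindingModelReport:
    """Interaction classes per residue plus the filtered key lists."""

    key_residues: list[ResidueContribution]
    stable_hbonds: list[HBondRecord]
    residue_classes: dict[ResidueKey, str]
    region_contacts: dict[str, list[tuple[ResidueKey, str, float]]]
    thresholds: InteractionThresholds


def classify_interactions(contribs: list[ResidueContribution],
                          hbonds: list[HBondRecord],
                          monitors: dict[ResidueKey, float] | None = None,
                          thresholds: InteractionThresholds = InteractionThresholds(),
                          structure: Structure | None = None,
                          region_map: RegionMap | None = None
                          ) -> BindingModelReport:
    """Assign each contributing residue a single interaction class.

    Priority: a residue hosting a hydrogen bond at or above the stable
    occupancy is ``hydrogen-bond``; occupancy in [floor, stable) is
    ``unstable-hydrogen-bond``; otherwise a favorable residue (subtotal
    <= -key_threshold) whose mean ring-carbon distance (from ``monitors``)
    is within the pi-alkyl cutoff is ``pi-alkyl``; an opposing residue
    (subtotal >= +key_threshold) is ``unfavorable``.

    When ``structure`` and ``region_map`` are given, classified residues
    are mapped to the region containing the ligand atom involved in their
    hydrogen bond, yielding the per-region contact lists.
    """
    monitors = monitors or {}
    th = thresholds

    # residue -> best occupancy and the ligand atom involved
    best_occ: dict[ResidueKey, tuple[float, int]] = {}
    if structure is not None:
        ligand = set(structure.group_indices("ligand").tolist())
        for hb in hbonds:
            for idx, partner in ((hb.donor_index, hb.acceptor_index),
                                 (hb.acceptor_index, hb.donor_index)):
                if idx in ligand:
                    continue
                key = structure.atoms[idx].residue_key
                if hb.occupancy > best_occ.get(key, (-1.0, -1))[0]:
                    lig_atom = partner if partner in ligand else -1
                    best_occ[key] = (hb.occupancy, lig_atom)
    else:
        # fall back to parsing residue identity from the record labels
        for hb in hbonds:
            for label in (hb.donor_label, hb.acceptor_label):
                key = _key_from_label(label)
                if hb.occupancy > best_occ.get(key, (-1.0, -1))[0]:
                    best_occ[key] = (hb.occupancy, -1)

    classes: dict[ResidueKey, str] = {}
    region_contacts: dict[str, list[tuple[ResidueKey, str, float]]] = {}
    for rc in contribs:
        key = rc.residue_key
        occ, lig_atom = best_occ.get(key, (0.0, -1))
        dist = monitors.get(key, float("inf"))
        if occ >= th.stable_occupancy:
            cls = "hydrogen-bond"
        elif occ >= th.occupancy_floor:
            cls = "unstable-hydrogen-bond"
        elif rc.d_subtotal <= -th.key_threshold and dist <= th.pi_alkyl_distance:
            cls = "pi-alkyl"
        elif rc.d_subtotal >= th.key_threshold:
            cls = "unfavorable"
        else:
            continue
        classes[key] = cls
        if region_map is not None and lig_atom >= 0:
            region = region_map.region_of(lig_atom)
            if region is not None:
                region_contacts.setdefault(region, []).append(
                    (key, cls, dist if dist != float("inf") else float("nan")))

    key_residues = [rc for rc in contribs
                    if abs(rc.d_subtotal) >= th.key_threshold]
    stable = [hb for hb in hbonds if hb.occupancy >= th.stable_occupancy]
    return BindingModelReport(key_residues=key_residues, stable_hbonds=stable,
                              residue_classes=classes,
                              region_contacts=region_contacts, thresholds=th)


def _key_from_label(label: str) -> ResidueKey:
    chain, rest = label.split(":", 1)
    res, _ = rest.split("@", 1)
    name = res.rstrip("0123456789")
    index = int(res[len(name):])
    return (chain, index, name)
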