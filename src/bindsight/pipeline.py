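"""End-to-end orchestration: analyze -> model -> design -> score.

``run_pipeline`` chains the library stages over a single configuration and
writes deterministic TSV outputs plus a machine-readable manifest.  Given
the same configuration and seed the outputs are byte-identical; every
output file is traceable to its stage and to the configuration hash
recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as bio
from .design import (CompoundSpec, combination_libraries, combination_scaffold,
                     default_base_groups, default_libraries, default_scaffold,
                     enumerate_one_region, combine_regions, select_top_groups)
from .gbsa import GBParams, average_binding_energy, decompose_per_residue
from .model import InteractionThresholds, classify_interactions
from .scoring import (ReceptorEnsemble, SurrogateScorer, TableScorer,
                      load_score_table, rank_and_shortlist, score_compound)
from .structures import AnalysisWindow, Structure, Trajectory, select_window
from .synthetic import (SyntheticSpec, default_planted_hbonds,
                        generate_complex, generate_trajectory)
from .trajectory import (HBondCriteria, cluster_frames, detect_hbonds,
                         hbond_count_series, representative_structures,
                         rmsd_series, rmsf_per_residue)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "compare_candidates",
           "ComparisonTable"]


@dataclass
class PipelineConfig:
    """All pipeline tunables in one place.

    Either ``trajectory_path``/``topology_path`` point at input files, or
    (when both are ``None``) a synthetic complex is generated from the
    ``synthetic`` block.  Thresholds default to the standard analysis
    conventions: 0.50 kcal/mol key-residue contribution, 50% stable
    occupancy, -10.00 kcal/mol shortlist, 3 groups per region, 2 clusters.
    """

    trajectory_path: str | None = None
    topology_path: str | None = None
    structure_path: str | None = None
    score_table_path: str | None = None
    window_fraction: float = 0.2  # analyse the last fraction of the run
    window_stride: int = 1
    key_threshold: float = 0.50
    stable_occupancy: float = 50.0
    shortlist_threshold: float = -10.00
    per_region: int = 3
    n_clusters: int = 2
    cluster_max_frames: int = 100
    energy_frames: int = 50
    entropy_frames: int = 50
    surrogate_sasa_points: int = 240
    seed: int = 0
    gb: GBParams = field(default_factory=GBParams)
    synthetic: SyntheticSpec = field(default_factory=lambda: SyntheticSpec(
        n_receptor_residues=12, n_ligand_atoms=8, n_frames=200))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gb = GBParams(**raw.pop("gb", {}))
        synth_raw = raw.pop("synthetic", None)
        synth = (SyntheticSpec(**synth_raw) if synth_raw
                 else SyntheticSpec(n_receptor_residues=12, n_ligand_atoms=8,
                                    n_frames=200))
        return cls(gb=gb, synthetic=synth, **raw)

    def validate(self) -> None:
        for attr in ("trajectory_path", "topology_path", "structure_path",
                     "score_table_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if (self.trajectory_path is None) != (self.topology_path is None):
            raise ValueError(
                "trajectory_path and topology_path must be given together")
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must lie in (0, 1]")
        if self.per_region < 1 or self.n_clusters < 1:
            raise ValueError("per_region and n_clusters must be >= 1")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ComparisonTable:
    """Candidate binding free energies against a reference value."""

    rows: list[dict]
    pairwise: dict[tuple[str, str], float]


def compare_candidates(energies: dict[str, float],
                       reference: float) -> ComparisonTable:
    """Tabulate candidate dG values, their offsets from a reference
    (e.g. the experimental or parent-compound value) and all pairwise
    differences (kcal/mol)."""
    if not energies:
        raise ValueError("need at least one candidate")
    rows = [{"compound": name, "delta_G": dg,
             "diff_vs_reference": dg - reference}
            for name, dg in energies.items()]
    names = list(energies)
    pairwise = {(a, b): energies[a] - energies[b]
                for a in names for b in names if a != b}
    return ComparisonTable(rows=rows, pairwise=pairwise)


def _load_inputs(config: PipelineConfig
                 ) -> tuple[Structure, Trajectory, SyntheticSpec | None]:
    if config.trajectory_path is not None:
        if config.structure_path is None:
            raise ValueError("structure_path required with trajectory_path")
        structure = bio.read_structure(config.structure_path,
                                       config.topology_path)
        traj = bio.read_trajectory(config.trajectory_path, structure)
        return structure, traj, None
    spec = config.synthetic
    spec.seed = config.seed
    structure = generate_complex(spec)
    if not spec.planted_hbonds:
        spec.planted_hbonds = default_planted_hbonds(
            structure, [0.85, 0.45, 0.20])
    traj = generate_trajectory(structure, spec)
    return structure, traj, spec


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> Path:
    """Run all six stages and return the run directory.

    Stage outputs: ``inputs`` (structure + topology + ground truth),
    ``analysis`` (RMSD/RMSF/H-bonds/clusters), ``mmgbsa`` (energy terms +
    per-residue decomposition), ``report`` (interaction classes),
    ``design`` (library manifests + combination SMILES), ``scores``
    (ranked list + shortlist).  A failing stage aborts with its name;
    outputs of completed stages are retained.
    """
    config.validate()
    if out_dir is None:
        out_dir = Path(f"bindsight-run-{time.strftime('%Y%m%d-%H%M%S')}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    t_start = time.perf_counter()
    stage = "inputs"
    try:
        # ---- stage 1: inputs ------------------------------------------
        structure, traj, synth_spec = _load_inputs(config)
        bio.write_structure(structure, out / "complex.pdb")
        bio.write_topology(bio.topology_from_structure(structure),
                           out / "topology.txt")
        files = ["complex.pdb", "topology.txt"]
        if synth_spec is not None:
            truth = [{"kind": "hbond", "donor": hb.donor_index,
                      "acceptor": hb.acceptor_index,
                      "target": hb.target_occupancy}
                     for hb in synth_spec.planted_hbonds]
            bio.write_table(truth, out / "ground_truth.tsv", sort_key="donor")
            files.append("ground_truth.tsv")
        manifest[stage] = files
        logger.info("stage %s done (%.1fs)", stage,
                    time.perf_counter() - t_start)

        # ---- stage 2: analysis ----------------------------------------
        stage = "analysis"
        rec = structure.group_indices("receptor")
        lig = structure.group_indices("ligand")
        backbone = np.array([i for i in rec
                             if structure.atoms[i].is_backbone
                             and structure.atoms[i].element != "H"])
        rmsd = rmsd_series(traj, backbone)
        bio.write_table([{"frame": i + 1, "rmsd": float(v)}
                         for i, v in enumerate(rmsd)],
                        out / "rmsd.tsv", sort_key="frame")
        rmsf = rmsf_per_residue(traj, backbone)
        bio.write_table([{"chain": k[0], "residue_index": k[1],
                          "residue_name": k[2], "rmsf": v}
                         for k, v in rmsf.items()],
                        out / "rmsf.tsv", sort_key="residue_index")
        window = AnalysisWindow.last_fraction(traj, config.window_fraction,
                                              config.window_stride)
        wtraj = select_window(traj, window)
        hbonds = detect_hbonds(wtraj, HBondCriteria())
        bio.write_table([{"donor": h.donor_label, "acceptor": h.acceptor_label,
                          "occupancy": h.occupancy,
                          "mean_distance": h.mean_distance,
                          "mean_angle": h.mean_angle}
                         for h in hbonds], out / "hbonds.tsv")
        _, mean_n, sd_n = hbond_count_series(wtraj)
        stride = max(1, wtraj.n_frames // config.cluster_max_frames)
        clusters = cluster_frames(wtraj, backbone, config.n_clusters,
                                  stride=stride)
        bio.write_table([{"cluster": cid,
                          "population_pct": clusters.populations[cid],
                          "n_frames": clusters.counts[cid],
                          "medoid_frame": clusters.representative_frames[cid] + 1}
                         for cid in sorted(clusters.populations)],
                        out / "clusters.tsv", sort_key="cluster")
        manifest[stage] = ["rmsd.tsv", "rmsf.tsv", "hbonds.tsv", "clusters.tsv"]

        # ---- stage 3: mmgbsa ------------------------------------------
        stage = "mmgbsa"
        estride = max(1, wtraj.n_frames // config.energy_frames)
        ewindow = AnalysisWindow(window.start_time, window.end_time,
                                 stride=window.stride * estride)
        bfe = average_binding_energy(traj, ewindow, config.gb,
                                     entropy_frames=config.entropy_frames)
        rows = [
            {"term": "EvdW", "delta": bfe.delta.E_vdW, "sd": bfe.sd["E_vdW"]},
            {"term": "Eele", "delta": bfe.delta.E_ele, "sd": bfe.sd["E_ele"]},
            {"term": "EGB", "delta": bfe.delta.E_GB, "sd": bfe.sd["E_GB"]},
            {"term": "Esurf", "delta": bfe.delta.E_surf, "sd": bfe.sd["E_surf"]},
            {"term": "Egas", "delta": bfe.delta.E_gas, "sd": float("nan")},
            {"term": "Esolv", "delta": bfe.delta.E_solv, "sd": float("nan")},
            {"term": "enthalpy", "delta": bfe.enthalpy, "sd": float("nan")},
            {"term": "TdS", "delta": bfe.T_delta_S, "sd": float("nan")},
            {"term": "dG_bind", "delta": bfe.delta_G, "sd": float("nan")},
        ]
        bio.write_table(rows, out / "energy.tsv")
        contribs = decompose_per_residue(traj, ewindow, config.gb,
                                         key_threshold=config.key_threshold)
        bio.write_table([{
            "chain": c.chain_id, "residue_index": c.residue_index,
            "residue_name": c.residue_name, "dEvdW": c.d_vdW,
            "dEele": c.d_ele, "dEGB": c.d_GB, "dEsurf": c.d_surf,
            "dEsubtotal": c.d_subtotal, "sidechain": c.sidechain_subtotal,
            "backbone": c.backbone_subtotal, "key": c.is_key}
            for c in contribs], out / "decomposition.tsv",
            sort_key="residue_index")
        manifest[stage] = ["energy.tsv", "decomposition.tsv"]

        # ---- stage 4: report ------------------------------------------
        stage = "report"
        th = InteractionThresholds(key_threshold=config.key_threshold,
                                   stable_occupancy=config.stable_occupancy)
        report = classify_interactions(contribs, hbonds, thresholds=th,
                                       structure=structure)
        bio.write_table([{"chain": k[0], "residue_index": k[1],
                          "residue_name": k[2], "interaction": cls}
                         for k, cls in report.residue_classes.items()],
                        out / "binding_model.tsv", sort_key="residue_index")
        manifest[stage] = ["binding_model.tsv"]

        # ---- stage 5: design ------------------------------------------
        stage = "design"
        scaffold = default_scaffold()
        base = default_base_groups()
        libraries = default_libraries()
        one_region = enumerate_one_region(scaffold, libraries, base)
        medoids = representative_structures(wtraj, clusters, group="receptor")
        ensemble = ReceptorEnsemble(
            members=[(f"Cluster{cid}", s) for cid, s in sorted(medoids.items())],
            populations={f"Cluster{cid}": clusters.populations[cid]
                         for cid in clusters.populations})
        if config.score_table_path is not None:
            scorer = load_score_table(config.score_table_path)
        else:
            from dataclasses import replace as dc_replace
            pocket = traj.frames[0][lig].mean(axis=0)
            surrogate_params = dc_replace(
                config.gb, sasa_points=config.surrogate_sasa_points)
            scorer = SurrogateScorer(pocket_center=pocket,
                                     params=surrogate_params,
                                     seed=config.seed)
        for c in one_region:
            rec_score = score_compound(c, ensemble, scorer)
            c.scores = rec_score.per_member
            c.aggregate_score = rec_score.aggregate
        bio.write_table([{"name": c.name, "region": c.modified_region,
                          "score": c.aggregate_score, "smiles": c.smiles}
                         for c in one_region],
                        out / "one_region.tsv", sort_key="name")
        reduced = select_top_groups(one_region, libraries,
                                    per_region=config.per_region)
        combos = combine_regions(scaffold, reduced)
        (out / "compounds.smi").write_text(
            "".join(f"{c.name}\t{c.smiles}\n" for c in combos))
        bio.write_table([{"name": c.name, "smiles": c.smiles,
                          **{r: lbl for r, lbl in c.group_choice.items()}}
                         for c in combos],
                        out / "combination.tsv", sort_key="name")
        manifest[stage] = ["one_region.tsv", "compounds.smi", "combination.tsv"]

        # ---- stage 6: scores ------------------------------------------
        stage = "scores"
        records = []
        for c in combos:
            try:
                records.append(score_compound(c, ensemble, scorer))
            except RuntimeError:
                logger.warning("compound %s failed on every ensemble member",
                               c.name)
        ranked, shortlist = rank_and_shortlist(
            records, threshold=config.shortlist_threshold)
        bio.write_table([{"rank": i + 1, "name": r.name,
                          "aggregate": r.aggregate,
                          **{m: v for m, v in sorted(r.per_member.items())}}
                         for i, r in enumerate(ranked)], out / "ranked.tsv")
        bio.write_table([{"name": r.name, "aggregate": r.aggregate}
                         for r in shortlist], out / "shortlist.tsv")
        manifest[stage] = ["ranked.tsv", "shortlist.tsv"]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "stages": manifest,
            "summary": {"mean_hbond_count": mean_n, "sd_hbond_count": sd_n,
                        "delta_G": bfe.delta_G,
                        "n_shortlisted": len(shortlist)}}
    (out / "manifest.json").write_text(json.dumps(meta, indent=2,
                                                  sort_keys=True) + "\n")
    logger.info("pipeline complete in %.1fs -> %s",
                time.perf_counter() - t_start, out)
    return out
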