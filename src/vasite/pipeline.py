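"""End-to-end pipeline: ensemble → clusters → pockets → consensus → docking
→ pharmacology, driven by a single flat config with per-stage seeds.

Outputs mirror the analysis' reporting conventions: a cluster-occupancy
table (members, simulation %, rank), a consensus-site table (persistence,
residues within 5 Å, interface class, docked energy), a per-sequence tail
docking table (binding-energy range over conformers of varying
compactness), and a pharmacology summary.  Identical config + seeds give
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, consensus as consensus_mod, docking, pharm, pockets
from .structure_io import Ensemble, read_ligand_template, read_structure, write_structure
from .synthetic import (
    CavitySpec,
    TailSpec,
    make_toy_receptor,
    make_two_regime_ensemble,
    radius_of_gyration,
    receptor_ground_truth,
    sample_tail_conformers,
)

SCENARIOS = ("two_regime_ensemble", "multi_cavity_receptor", "tail_set")


@dataclass
class PipelineConfig:
    """All protocol constants of the pipeline, every one overridable."""

    # input: either a multi-model PDB path or a named synthetic scenario
    input_pdb: str = ""
    scenario: str = "two_regime_ensemble"
    n_frames: int = 40
    out_dir: str = "results/pipeline"

    # clustering
    cluster_cutoff: float = 1.0  # Å RMSD, single linkage
    superpose: bool = True
    representative_mode: str = "mean"

    # pocket detection
    probe_radius: float = 1.8
    burial_radius: float = 8.0
    burial_threshold: int = 55
    max_layers: int = 3
    merge_radius: float = 3.0
    hydrophobic_min_fraction: float = 0.5

    # consensus
    consensus_eps: float = 5.0
    consensus_min_pts: int = 1
    annotation_radius: float = 5.0

    # docking
    box_edge: float = 10.0
    grid_spacing: float = 0.375
    pose_rmsd_cutoff: float = 2.0
    n_restarts: int = 12
    n_local_steps: int = 150
    max_docked_sites: int = 2

    # tails
    tail_n_conformers: int = 50
    tail_dock_conformers: int = 4
    tail_grid_spacing: float = 0.75
    tail_margin: float = 4.0
    tail_sequences: list[str] = field(default_factory=list)  # empty → bundled set

    # pharmacology
    temperature: float = 310.0

    # seeds, one per stochastic stage
    seed_ensemble: int = 11
    seed_tails: int = 12
    seed_docking: int = 13

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # reports are location-independent
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_tail_sequences() -> dict[str, str]:
    with resources.files("vasite.data").joinpath("tail_sequences.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return dict(zip(df["isotype"], df["sequence"]))


def generate_fixture(scenario: str, seed: int, out_dir: str | Path) -> dict:
    """Write a named synthetic input bundle (PDB + ground-truth JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if scenario == "two_regime_ensemble":
        ensemble, truth = make_two_regime_ensemble(n_frames=251, boundary=126, seed=seed)
        write_structure(ensemble, out / "two_regime_ensemble.pdb")
        truth["seed"] = seed
        (out / "two_regime_ensemble.json").write_text(json.dumps(truth, indent=2))
        return {"pdb": str(out / "two_regime_ensemble.pdb"), "truth": truth}
    if scenario == "multi_cavity_receptor":
        specs = [
            CavitySpec(center=np.array([0.0, 0.0, 4.5])),
            CavitySpec(center=np.array([0.0, 0.0, -4.5]),
                       lining_hydrophobic_fraction=0.0),
        ]
        receptor = make_toy_receptor(specs, seed=seed)
        write_structure(receptor, out / "multi_cavity_receptor.pdb")
        truth = receptor_ground_truth(receptor)
        truth["seed"] = seed
        (out / "multi_cavity_receptor.json").write_text(json.dumps(truth, indent=2))
        return {"pdb": str(out / "multi_cavity_receptor.pdb"), "truth": truth}
    if scenario == "tail_set":
        sequences = load_tail_sequences()
        manifest = {}
        for i, (isotype, seq) in enumerate(sequences.items()):
            ens = sample_tail_conformers(TailSpec(seq, n_conformers=50, seed=seed + i))
            name = isotype.replace("/", "_").replace(" ", "")
            write_structure(ens, out / f"tails_{name}.pdb")
            manifest[isotype] = {"sequence": seq, "file": f"tails_{name}.pdb",
                                 "n_conformers": 50}
        (out / "tail_set.json").write_text(json.dumps(manifest, indent=2))
        return {"manifest": manifest}
    raise ValueError(f"unknown scenario {scenario!r}; choose one of {SCENARIOS}")


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle.

    Returns a dict of output paths plus the in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_digest": config.digest(),
                 "seeds": {"ensemble": config.seed_ensemble,
                           "tails": config.seed_tails,
                           "docking": config.seed_docking},
                 "stages": {}}
    if config.consensus_min_pts != 1:
        warnings.warn("consensus_min_pts != 1 deviates from the "
                      "minimum-group-size-1 consensus protocol")

    # ---- stage 1: ensemble -------------------------------------------------
    truth = None
    if config.input_pdb:
        ensemble = read_structure(config.input_pdb)
    else:
        if config.scenario != "two_regime_ensemble":
            raise ValueError("run_pipeline drives the two_regime_ensemble scenario; "
                             "other scenarios are fixture generators")
        ensemble, truth = make_two_regime_ensemble(
            n_frames=config.n_frames, boundary=config.n_frames // 2,
            seed=config.seed_ensemble)
    log["stages"]["ensemble"] = {"n_frames": ensemble.total_frames,
                                 "n_atoms": ensemble[0].n_atoms}

    # ---- stage 2: clustering ----------------------------------------------
    clusters = clustering.single_linkage_cluster(
        ensemble, cutoff=config.cluster_cutoff, superpose_first=config.superpose,
        representative_mode=config.representative_mode)
    table = clustering.cluster_table(clusters)
    cluster_path = out / "cluster_table.tsv"
    table.to_csv(cluster_path, sep="\t", index=False, float_format="%.2f")
    write_structure(
        Ensemble([dataclasses.replace(c.representative, frame_index=i)
                  for i, c in enumerate(clusters)]),
        out / "representatives.pdb")
    log["stages"]["clustering"] = {"n_clusters": len(clusters)}

    # ---- stage 3: per-conformation pockets --------------------------------
    sites_by_cluster = {}
    rows = []
    for cl in clusters:
        sites = pockets.detect_sites(
            cl.representative, source_conformation=cl.cluster_id,
            probe_radius=config.probe_radius, burial_radius=config.burial_radius,
            burial_threshold=config.burial_threshold, max_layers=config.max_layers,
            merge_radius=config.merge_radius, shell_radius=config.annotation_radius,
            min_fraction=config.hydrophobic_min_fraction)
        sites_by_cluster[cl.cluster_id] = sites
        for s in sites:
            rows.append({"cluster_id": cl.cluster_id,
                         "x": _fmt(s.center[0]), "y": _fmt(s.center[1]),
                         "z": _fmt(s.center[2]), "score": _fmt(s.score),
                         "hydrophobic_fraction": _fmt(s.hydrophobic_fraction)})
    sites_path = out / "site_predictions.tsv"
    pd.DataFrame(rows).to_csv(sites_path, sep="\t", index=False)
    log["stages"]["pockets"] = {"n_sites": sum(map(len, sites_by_cluster.values()))}

    # ---- stage 4: consensus -----------------------------------------------
    consensus_sites = consensus_mod.build_consensus(
        clusters, sites_by_cluster, eps=config.consensus_eps,
        min_pts=config.consensus_min_pts, annotation_radius=config.annotation_radius)
    log["stages"]["consensus"] = {"n_consensus_sites": len(consensus_sites)}

    # ---- stage 5: docking at the top persistent sites ---------------------
    ligand = read_ligand_template()
    by_id = {c.cluster_id: c for c in clusters}
    dock_energy = {}
    for site in consensus_sites[: config.max_docked_sites]:
        best_cluster = max(site.member_conformations,
                           key=lambda cid: by_id[cid].simulation_fraction)
        receptor = by_id[best_cluster].representative
        result = docking.dock_focused(
            receptor, ligand, center=site.center, box_edge=config.box_edge,
            grid_spacing=config.grid_spacing, n_restarts=config.n_restarts,
            n_local_steps=config.n_local_steps, seed=config.seed_docking + site.site_id)
        dock_energy[site.site_id] = result.reported_energy
    rows = []
    for site in consensus_sites:
        residues = ";".join(f"{lbl}:{name}{num}" for lbl, name, num in site.residues_within)
        rows.append({
            "site_id": site.site_id,
            "persistence_pct": f"{site.persistence:.2f}",
            "x": _fmt(site.center[0]), "y": _fmt(site.center[1]), "z": _fmt(site.center[2]),
            "n_conformations": len(site.member_conformations),
            "interface_class": site.interface_class or "n/a",
            "residues_within_5A": residues,
            "halothane_energy_kcal_mol": (_fmt(dock_energy[site.site_id])
                                          if site.site_id in dock_energy else ""),
        })
    consensus_path = out / "consensus_sites.tsv"
    pd.DataFrame(rows).to_csv(consensus_path, sep="\t", index=False)

    # ---- stage 6: tail docking --------------------------------------------
    sequences = (dict(enumerate(config.tail_sequences)) if config.tail_sequences
                 else load_tail_sequences())
    tail_rows = []
    for i, (isotype, seq) in enumerate(sequences.items()):
        conformers = sample_tail_conformers(
            TailSpec(seq, n_conformers=config.tail_n_conformers,
                     seed=config.seed_tails + i))
        picks = np.linspace(0, len(conformers) - 1, config.tail_dock_conformers).astype(int)
        energies, rgs = [], []
        for j in picks:
            result = docking.dock_blind(
                conformers[j], ligand, grid_spacing=config.tail_grid_spacing,
                margin=config.tail_margin, n_restarts=max(config.n_restarts // 2, 4),
                n_local_steps=config.n_local_steps,
                seed=config.seed_docking + 1000 + 10 * i + int(j))
            energies.append(result.reported_energy)
            rgs.append(radius_of_gyration(conformers[j]))
        tail_rows.append({
            "isotype": str(isotype), "sequence": seq,
            "n_docked_conformers": len(picks),
            "energy_min_kcal_mol": _fmt(min(energies)),
            "energy_max_kcal_mol": _fmt(max(energies)),
            "rg_min_A": _fmt(min(rgs)), "rg_max_A": _fmt(max(rgs)),
        })
    tails_path = out / "tail_docking.tsv"
    pd.DataFrame(tail_rows).to_csv(tails_path, sep="\t", index=False)
    log["stages"]["tails"] = {"n_sequences": len(tail_rows)}

    # ---- stage 7: pharmacology --------------------------------------------
    # only favorable (negative) energies are meaningful binding estimates
    favorable = {sid: e for sid, e in sorted(dock_energy.items()) if e < 0}
    pharm_report = {
        "temperature_K": config.temperature,
        "sites": {
            str(sid): {
                "delta_g_kcal_mol": round(e, 3),
                "kd_M": pharm.kd_from_energy(e, config.temperature),
                "occupancy_at_2MAC": pharm.occupancy(
                    pharm.MAC_CONCENTRATION_M[2], pharm.kd_from_energy(e, config.temperature)),
            }
            for sid, e in favorable.items()
        },
    }
    pharm_path = out / "pharmacology.json"
    pharm_path.write_text(json.dumps(pharm_report, indent=2, sort_keys=True))

    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    return {
        "cluster_table": str(cluster_path),
        "site_predictions": str(sites_path),
        "consensus_sites": str(consensus_path),
        "tail_docking": str(tails_path),
        "pharmacology": str(pharm_path),
        "run_log": str(log_path),
        "clusters": clusters,
        "consensus": consensus_sites,
        "truth": truth,
        "dock_energy": dock_energy,
    }
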