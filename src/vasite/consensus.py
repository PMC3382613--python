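"""Cross-conformation site consensus and persistence.

Per-conformation site predictions are grouped across the ensemble by
density-based clustering with a minimum group size of 1 and a neighbor
distance of 5 Å — which reduces to connected components of the ≤5 Å
proximity graph on site centers, with no noise points possible.  Each
consensus group gets a persistence: the summed simulation fractions of the
distinct dominant conformations in which the site was found, i.e. the
percentage of the trajectory during which the pocket exists.

Groups are annotated with the residues within 5 Å of the group center and
classified by lattice context (monomer body, intradimer, longitudinal or
lateral interface), and can be compared against curated residue sets of
known drug/nucleotide/ion sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .clustering import ConformationCluster
from .pockets import SitePrediction
from .structure_io import Conformation

INTERFACE_CLASSES = (
    "alpha-body", "beta-body", "intradimer", "longitudinal",
    "lateral-alpha", "lateral-beta", "lateral-mixed",
)


@dataclass
class MonomerInfo:
    """Lattice role of one monomer label: α or β, which dimer, which
    protofilament."""

    monomer_type: str  # "alpha" | "beta"
    dimer_index: int
    protofilament_index: int


@dataclass
class ConsensusSite:
    site_id: int
    center: np.ndarray
    members: dict[int, list[SitePrediction]] = field(default_factory=dict)
    persistence: float = 0.0  # percent of the simulation
    residues_within: list[tuple[str, str, int]] = field(default_factory=list)
    interface_class: str = ""

    @property
    def member_conformations(self) -> set[int]:
        return set(self.members)


def group_sites(per_conformation_sites: list[SitePrediction],
                eps: float = 5.0, min_pts: int = 1) -> list[ConsensusSite]:
    """Group site predictions across conformations (DBSCAN, minPts 1).

    With ``min_pts`` = 1 every site is a core point and the grouping equals
    connected components of the graph joining centers within ``eps``; the
    group center is the arithmetic mean of all member site centers.
    ``min_pts`` > 1 is accepted for experimentation but deviates from the
    reference protocol (a warning is raised) and may label sparse sites as
    noise (omitted from output).
    """
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    if min_pts > 1:
        import warnings

        warnings.warn("min_pts > 1 deviates from the minimum-group-size-1 protocol")
    if not per_conformation_sites:
        return []
    centers = np.array([s.center for s in per_conformation_sites])
    n = len(centers)
    tree = cKDTree(centers)
    pairs = tree.query_pairs(eps + 1e-9, output_type="ndarray")
    if len(pairs):
        graph = csr_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        graph = csr_matrix((n, n))
    _n_comp, labels = connected_components(graph, directed=False)

    if min_pts > 1:
        # DBSCAN semantics: core points need >= min_pts neighbors (incl. self)
        neighbor_counts = np.array([len(tree.query_ball_point(c, eps + 1e-9)) for c in centers])
        core = neighbor_counts >= min_pts
        labels = np.where(core | np.isin(labels, labels[core]), labels, -1)

    out = []
    for comp in sorted(set(labels) - {-1}):
        mask = labels == comp
        members: dict[int, list[SitePrediction]] = {}
        for site in (per_conformation_sites[i] for i in np.flatnonzero(mask)):
            members.setdefault(site.source_conformation, []).append(site)
        out.append(
            ConsensusSite(
                site_id=-1,
                center=centers[mask].mean(axis=0),
                members=members,
            )
        )
    return out


def persistence(site: ConsensusSite, clusters: list[ConformationCluster]) -> float:
    """Percent of the simulation in which the site exists.

    Sum of ``simulation_fraction`` over the *distinct* dominant
    conformations holding at least one member prediction; multiple member
    sites within one conformation count once.
    """
    frac = {c.cluster_id: c.simulation_fraction for c in clusters}
    unknown = site.member_conformations - set(frac)
    if unknown:
        raise ValueError(f"unknown cluster ids in consensus site: {sorted(unknown)}")
    return round(sum(frac[cid] for cid in site.member_conformations), 2)


def annotate_residues(site: ConsensusSite, reference: Conformation,
                      radius: float = 5.0) -> list[tuple[str, str, int]]:
    """Residues with ≥1 heavy atom within ``radius`` of the site center.

    Returns (monomer_label, residue_name, residue_number) sorted by
    monomer label then residue number; numbering is taken verbatim from
    the reference structure.
    """
    heavy = reference.select(reference.heavy_mask)
    if radius <= 0 or heavy.n_atoms == 0:
        return []
    tree = cKDTree(heavy.coord)
    idx = tree.query_ball_point(np.asarray(site.center, dtype=float), radius)
    seen = {}
    for i in idx:
        key = (str(heavy.monomer_label[i]), int(heavy.res_id[i]))
        seen[key] = (str(heavy.monomer_label[i]), str(heavy.res_name[i]), int(heavy.res_id[i]))
    return [seen[k] for k in sorted(seen)]


def classify_interface(residues: list[tuple[str, str, int]],
                       lattice: dict[str, MonomerInfo]) -> str:
    """Classify a residue set by its lattice context.

    One monomer → that monomer's body class; α and β of the same dimer →
    intradimer; different dimers on one protofilament → longitudinal;
    different protofilaments → lateral (suffixed by the monomer types
    involved).
    """
    if not residues:
        raise ValueError("unclassifiable: empty residue list")
    infos = []
    for label, _name, _num in residues:
        if label not in lattice:
            raise ValueError(f"monomer label {label!r} missing from lattice map")
        infos.append(lattice[label])
    types = {i.monomer_type for i in infos}
    dimers = {(i.protofilament_index, i.dimer_index) for i in infos}
    protofilaments = {i.protofilament_index for i in infos}
    if len(protofilaments) > 1:
        if types == {"alpha"}:
            return "lateral-alpha"
        if types == {"beta"}:
            return "lateral-beta"
        return "lateral-mixed"
    if len(dimers) > 1:
        return "longitudinal"
    if types == {"alpha", "beta"}:
        return "intradimer"
    return "alpha-body" if types == {"alpha"} else "beta-body"


# --------------------------------------------------------------------------
# reference-site comparison
# --------------------------------------------------------------------------

def load_reference_sites(path=None) -> dict[str, list[str]]:
    """Named residue sets of known binding pockets (``aV181``-style codes)."""
    if path is None:
        text = resources.files("vasite.data").joinpath("reference_sites.json").read_text()
    else:
        text = open(path).read()
    return json.loads(text)["sets"]


def _residue_key(code: str) -> tuple[str, int]:
    """'bL219' → ('beta', 219)."""
    monomer = {"a": "alpha", "b": "beta"}[code[0]]
    return monomer, int(code[2:])


def compare_reference_sites(site: ConsensusSite,
                            reference_sets: dict[str, list[str]],
                            monomer_types: dict[str, str] | None = None) -> dict[str, dict]:
    """Overlap of a site's annotated residues with each reference set.

    ``monomer_types`` maps the site's monomer labels to "alpha"/"beta"
    (default: label prefix before any digit, lowercase).  Overlap is on
    (monomer type, residue number)."""
    def mono_type(label: str) -> str:
        if monomer_types and label in monomer_types:
            return monomer_types[label]
        return label.rstrip("0123456789").lower()

    annotated = {(mono_type(lbl), num) for lbl, _name, num in site.residues_within}
    report = {}
    for name, codes in reference_sets.items():
        ref = {_residue_key(c) for c in codes}
        hits = sorted(annotated & ref)
        report[name] = {"overlap": len(hits), "residues": [f"{m}{n}" for m, n in hits]}
    return report


# --------------------------------------------------------------------------
# ensemble-level driver
# --------------------------------------------------------------------------

def build_consensus(clusters: list[ConformationCluster],
                    sites_by_cluster: dict[int, list[SitePrediction]],
                    eps: float = 5.0, min_pts: int = 1,
                    annotation_radius: float = 5.0,
                    lattice: dict[str, MonomerInfo] | None = None) -> list[ConsensusSite]:
    """Group per-cluster sites, compute persistence, annotate and rank.

    The annotation reference is the representative of the highest-fraction
    conformation among each site's members.  Site ids are assigned in
    descending persistence order (ties broken by center)."""
    all_sites = [s for sites in sites_by_cluster.values() for s in sites]
    consensus = group_sites(all_sites, eps=eps, min_pts=min_pts)
    by_id = {c.cluster_id: c for c in clusters}
    for site in consensus:
        site.persistence = persistence(site, clusters)
        best = max(site.member_conformations, key=lambda cid: by_id[cid].simulation_fraction)
        site.residues_within = annotate_residues(site, by_id[best].representative,
                                                 radius=annotation_radius)
        if lattice and site.residues_within:
            site.interface_class = classify_interface(site.residues_within, lattice)
    consensus.sort(key=lambda s: (-s.persistence, tuple(np.round(s.center, 9))))
    for i, site in enumerate(consensus, start=1):
        site.site_id = i
    return consensus
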