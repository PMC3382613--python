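"""Probe-sphere detection of buried hydrophobic pockets.

A single conformation is coated with probe spheres: an initial layer is
grid-seeded against the molecular surface (clash-free positions touching at
least three atoms), and further layers accrete onto previously kept probes.
Each probe's burial count — the number of receptor heavy atoms within a
burial radius — must reach a threshold for the probe to survive a layer,
so only probes inside crevices and cavities remain.  Surviving probes are
merged into candidate sites, and sites are kept only if the residues lining
them are sufficiently hydrophobic: volatile anesthetics occupy preexisting
non-polar cavities, so polar pockets are rejected outright.

Defaults (probe 1.8 Å, burial radius 8 Å, burial threshold 55 heavy atoms,
3 accretion layers) follow the probe-sphere cavity-detection literature;
every one is a configuration key.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure_io import Conformation

_DEFAULT_ATOM_RADIUS = 1.7
_CLASH_TOLERANCE = 0.5
_CONTACT_TOLERANCE = 0.5
_GRID_SPACING = 0.5
_TIE_EPS = 1e-9


@dataclass
class ProbeSphere:
    center: np.ndarray
    radius: float
    burial_count: int
    layer: int


@dataclass
class SitePrediction:
    """A candidate anesthetic site on one conformation."""

    center: np.ndarray
    score: float  # summed burial counts of member probes
    hydrophobic_fraction: float = float("nan")
    source_conformation: int = -1
    n_probes: int = 1


def _atom_radii(receptor: Conformation) -> np.ndarray:
    r = np.asarray(receptor.radius, dtype=float)
    return np.where(r > 0, r, _DEFAULT_ATOM_RADIUS)


def coat_surface(receptor: Conformation, probe_radius: float = 1.8,
                 burial_radius: float = 8.0, burial_threshold: int = 55,
                 max_layers: int = 3, heavy_only: bool = True) -> list[ProbeSphere]:
    """Coat a conformation with buried probe spheres.

    Layer 0 probes are candidate grid points (0.5 Å spacing) that are free
    of clashes and contact ≥3 atoms; layers k>0 accrete clash-free grid
    points adjacent to surviving probes.  Probes whose burial count falls
    below ``burial_threshold`` are discarded at every layer.
    """
    if receptor.n_atoms == 0:
        raise ValueError("empty receptor")
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    conf = receptor.select(receptor.heavy_mask) if heavy_only else receptor
    coords = conf.coord
    radii = _atom_radii(conf)
    tree = cKDTree(coords)
    r_max = float(radii.max())
    clash_dist = radii + probe_radius - _CLASH_TOLERANCE
    contact_dist = radii + probe_radius + _CONTACT_TOLERANCE

    lo = coords.min(axis=0) - (probe_radius + 1.0)
    hi = coords.max(axis=0) + (probe_radius + 1.0)
    axes = [np.arange(lo[d], hi[d] + _GRID_SPACING, _GRID_SPACING) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    def admissible(points: np.ndarray, min_contacts: int) -> np.ndarray:
        """Mask of points that are clash-free and touch >= min_contacts atoms."""
        keep = np.zeros(len(points), dtype=bool)
        neighbor_lists = tree.query_ball_point(
            points, r_max + probe_radius + _CONTACT_TOLERANCE
        )
        for idx, neigh in enumerate(neighbor_lists):
            if not neigh:
                continue
            neigh = np.asarray(neigh)
            d = np.linalg.norm(coords[neigh] - points[idx], axis=1)
            if np.any(d < clash_dist[neigh]):
                continue
            if np.count_nonzero(d <= contact_dist[neigh]) >= min_contacts:
                keep[idx] = True
        return keep

    def burial(points: np.ndarray) -> np.ndarray:
        return np.array([len(n) for n in tree.query_ball_point(points, burial_radius)])

    # pre-filter: only grid points near the surface can contact any atom
    dmin, _ = tree.query(grid, k=1)
    surface_grid = grid[dmin <= r_max + probe_radius + _CONTACT_TOLERANCE]

    # layer 0: grid-seeded surface coat
    candidates = surface_grid
    keep = admissible(candidates, min_contacts=3)
    layer_pts = candidates[keep]
    buried = burial(layer_pts)
    ok = buried >= burial_threshold
    probes = [
        ProbeSphere(center=p, radius=probe_radius, burial_count=int(b), layer=0)
        for p, b in zip(layer_pts[ok], buried[ok])
    ]
    accepted = {tuple(np.round(p.center / _GRID_SPACING).astype(int)) for p in probes}

    prev_layer = [p.center for p in probes]
    for layer in range(1, max_layers):
        if not prev_layer:
            break
        prev = np.asarray(prev_layer)
        probe_tree = cKDTree(prev)
        adjacent = probe_tree.query_ball_point(surface_grid, 2.0 * probe_radius)
        cand = np.array(
            [
                surface_grid[i]
                for i, n in enumerate(adjacent)
                if n and tuple(np.round(surface_grid[i] / _GRID_SPACING).astype(int)) not in accepted
            ]
        )
        if len(cand) == 0:
            break
        keep = admissible(cand, min_contacts=2)
        pts = cand[keep]
        if len(pts) == 0:
            break
        buried = burial(pts)
        ok = buried >= burial_threshold
        new = [
            ProbeSphere(center=p, radius=probe_radius, burial_count=int(b), layer=layer)
            for p, b in zip(pts[ok], buried[ok])
        ]
        if not new:
            break
        probes.extend(new)
        accepted.update(
            tuple(np.round(p.center / _GRID_SPACING).astype(int)) for p in new
        )
        prev_layer = [p.center for p in new]
    return probes


def extract_sites(probes: list[ProbeSphere], merge_radius: float = 3.0,
                  source_conformation: int = -1) -> list[SitePrediction]:
    """Merge probes within ``merge_radius`` into site predictions.

    Merging is by connected components of the probe proximity graph; the
    site center is the burial-weighted centroid (pulled toward the deepest
    probes) and the score the summed burial counts.  Output is sorted by
    descending score, then lexicographic center, for determinism.
    """
    if not probes:
        return []
    centers = np.array([p.center for p in probes])
    weights = np.array([p.burial_count for p in probes], dtype=float)
    tree = cKDTree(centers)
    pairs = tree.query_pairs(merge_radius + _TIE_EPS, output_type="ndarray")
    n = len(probes)
    if len(pairs):
        data = np.ones(len(pairs))
        graph = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        graph = csr_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    sites = []
    for comp in range(n_comp):
        mask = labels == comp
        w = weights[mask]
        center = (centers[mask] * w[:, None]).sum(axis=0) / w.sum()
        sites.append(
            SitePrediction(
                center=center,
                score=float(w.sum()),
                source_conformation=source_conformation,
                n_probes=int(mask.sum()),
            )
        )
    sites.sort(key=lambda s: (-s.score, tuple(np.round(s.center, 9))))
    return sites


def hydrophobicity_filter(sites: list[SitePrediction], receptor: Conformation,
                          shell_radius: float = 5.0,
                          min_fraction: float = 0.5) -> list[SitePrediction]:
    """Keep sites whose lining is hydrophobic enough.

    For each site, ``hydrophobic_fraction`` is the number of hydrophobic
    heavy atoms within ``shell_radius`` of the site center over all heavy
    atoms in that shell; sites pass iff fraction ≥ min_fraction (inclusive).
    Sites with no atoms in the shell are dropped with a warning.
    """
    heavy = receptor.select(receptor.heavy_mask)
    tree = cKDTree(heavy.coord)
    hydro = heavy.hydrophobic_heavy_mask
    kept = []
    for site in sites:
        neigh = tree.query_ball_point(site.center, shell_radius)
        if not neigh:
            warnings.warn(f"site at {np.round(site.center, 2)} has no atoms within "
                          f"{shell_radius} Å; dropped")
            continue
        frac = float(np.count_nonzero(hydro[neigh])) / len(neigh)
        site.hydrophobic_fraction = frac
        if frac >= min_fraction - _TIE_EPS:
            kept.append(site)
    return kept


def detect_sites(receptor: Conformation, source_conformation: int = -1,
                 probe_radius: float = 1.8, burial_radius: float = 8.0,
                 burial_threshold: int = 55, max_layers: int = 3,
                 merge_radius: float = 3.0, shell_radius: float = 5.0,
                 min_fraction: float = 0.5) -> list[SitePrediction]:
    """coat → merge → hydrophobicity-filter on one conformation."""
    probes = coat_surface(receptor, probe_radius, burial_radius,
                          burial_threshold, max_layers)
    sites = extract_sites(probes, merge_radius, source_conformation)
    return hydrophobicity_filter(sites, receptor, shell_radius, min_fraction)


def grid_scan_oracle(receptor: Conformation, probe_radius: float = 1.8,
                     burial_radius: float = 8.0, burial_threshold: int = 55,
                     spacing: float = 0.5) -> np.ndarray:
    """Exhaustive reference scan: every clash-free grid point whose burial
    count reaches the threshold.  Used to validate the layered coat."""
    conf = receptor.select(receptor.heavy_mask)
    coords = conf.coord
    radii = _atom_radii(conf)
    tree = cKDTree(coords)
    lo = coords.min(axis=0) - (probe_radius + 1.0)
    hi = coords.max(axis=0) + (probe_radius + 1.0)
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    out = []
    clash_dist = radii + probe_radius - _CLASH_TOLERANCE
    for point, neigh in zip(grid, tree.query_ball_point(grid, burial_radius)):
        if len(neigh) < burial_threshold:
            continue
        idx = np.asarray(neigh)
        d = np.linalg.norm(coords[idx] - point, axis=1)
        if np.any(d < clash_dist[idx]):
            continue
        out.append(point)
    return np.asarray(out).reshape(-1, 3)
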