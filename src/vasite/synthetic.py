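"""Synthetic structure generators.

Everything the downstream pipeline needs as input is generated here under
explicit seeds: toy receptors with engineered buried hydrophobic cavities,
perturbed conformational ensembles with a stable backbone and mobile side
groups (optionally split into two distinguishable regimes), self-avoiding
coarse-grained C-terminal tail conformers spanning a range of compactness,
and small-molecule ligands built from internal-coordinate (Z-matrix)
templates.

Ground truth (cavity centers, lining residue ids, regime schedules) is
emitted alongside the structures so downstream tests are self-checking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Conformation, Ensemble, LigandTemplate, StructureError

# one atom per pseudo-residue; toy atoms are carbon-like
_TOY_RADIUS = 1.5
_TOY_EPSILON = 0.086
_LINING_DENSITY = 0.2  # atoms/A^2 on cavity linings

_HYDROPHOBIC_POOL = ["LEU", "ILE", "VAL", "PHE", "MET", "ALA", "CYS"]
_POLAR_POOL = ["ASP", "GLU", "LYS", "ARG", "SER", "ASN", "GLN"]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass
class CavitySpec:
    """An engineered spherical pocket: chamber of radius ``depth/2`` at
    ``center``, opening outward through a mouth of ``mouth_radius``."""

    center: np.ndarray
    mouth_radius: float = 2.0
    depth: float = 7.0
    lining_hydrophobic_fraction: float = 1.0
    lining_residue_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not 0.0 <= self.lining_hydrophobic_fraction <= 1.0:
            raise ValueError("lining_hydrophobic_fraction must be in [0, 1]")

    @property
    def chamber_radius(self) -> float:
        return self.depth / 2.0


@dataclass
class TailSpec:
    """A C-terminal tail sequence and how many conformers to sample."""

    sequence: str
    n_conformers: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n nearly evenly spaced unit vectors (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _draw_residue_names(rng: np.random.Generator, n: int, hydrophobic_fraction: float,
                        pool: list[str] | None = None) -> np.ndarray:
    if pool:
        return np.array([pool[i % len(pool)] for i in range(n)], dtype="U3")
    n_hydro = int(round(hydrophobic_fraction * n))
    names = [_HYDROPHOBIC_POOL[i % len(_HYDROPHOBIC_POOL)] for i in range(n_hydro)]
    names += [_POLAR_POOL[i % len(_POLAR_POOL)] for i in range(n - n_hydro)]
    names = np.array(names, dtype="U3")
    rng.shuffle(names)
    return names


def make_toy_receptor(specs: list[CavitySpec], shell_radius: float = 10.0,
                      atom_density: float = 0.12, seed: int = 0) -> Conformation:
    """Build a pseudo-protein: a filled ball of atoms with carved cavities.

    The body is a stack of concentric atom shells (outermost at
    ``shell_radius``, each of areal density ``atom_density``) so that, as in
    a real protein, there is no hollow interior; each cavity is a spherical
    chamber carved out of the body, walled by a dense lining whose residues
    are drawn to match ``lining_hydrophobic_fraction``, and opened outward
    through a mouth of ``mouth_radius``.  Ground truth (cavity centers,
    chamber radii, lining residue id ranges) is stored as JSON in the
    conformation label; parse it back with :func:`receptor_ground_truth`.
    """
    for a in range(len(specs)):
        for b in range(a + 1, len(specs)):
            gap = np.linalg.norm(specs[a].center - specs[b].center)
            if gap < specs[a].chamber_radius + specs[b].chamber_radius + 2.0:
                raise StructureError(f"cavities {a} and {b} overlap")
    rng = np.random.default_rng(seed)

    # solid body: concentric shells every 2 A out to shell_radius
    body = []
    r = shell_radius
    while r > 1.0:
        n_r = max(int(round(4 * np.pi * r**2 * atom_density)), 6)
        body.append(r * _fibonacci_sphere(n_r))
        r -= 2.0
    body.append(np.zeros((1, 3)))
    body = np.concatenate(body)
    body += rng.normal(scale=0.15, size=body.shape)

    # carve chambers out of the body
    keep = np.ones(len(body), dtype=bool)
    for spec in specs:
        if np.linalg.norm(spec.center) + spec.chamber_radius > shell_radius - 0.4:
            raise StructureError("cavity chamber protrudes through the shell")
        keep &= np.linalg.norm(body - spec.center, axis=1) > spec.chamber_radius + 0.8
    body = body[keep]
    n_body = len(body)

    coords = [body]
    res_names = [_draw_residue_names(rng, n_body, 0.5)]
    truth: dict = {"shell_radius": shell_radius, "cavities": []}
    n_before = n_body

    for spec in specs:
        r = spec.chamber_radius
        n_lin = int(round(4 * np.pi * r**2 * _LINING_DENSITY))
        lining = spec.center + r * _fibonacci_sphere(n_lin)
        lining += rng.normal(scale=0.08, size=lining.shape)
        # open the lining at the mouth
        outward = spec.center / max(np.linalg.norm(spec.center), 1e-9)
        mouth_point = spec.center + r * outward
        keep = np.linalg.norm(lining - mouth_point, axis=1) > spec.mouth_radius
        lining = lining[keep]
        names = _draw_residue_names(rng, len(lining), spec.lining_hydrophobic_fraction,
                                    spec.lining_residue_names or None)
        truth["cavities"].append(
            {
                "center": [float(x) for x in spec.center],
                "chamber_radius": r,
                "mouth_radius": spec.mouth_radius,
                "lining_hydrophobic_fraction": spec.lining_hydrophobic_fraction,
                "lining_residues": [n_before + 1, n_before + len(lining)],
            }
        )
        coords.append(lining)
        res_names.append(names)
        n_before += len(lining)

    coord = np.concatenate(coords)
    res_name = np.concatenate(res_names)
    n = len(coord)
    table = {"LEU", "ILE", "VAL", "PHE", "MET", "ALA", "CYS"}
    charge = np.where(
        np.isin(res_name, list(table)), 0.0,
        np.where(np.arange(n) % 2 == 0, 0.15, -0.15),
    )
    return Conformation(
        serial=np.arange(1, n + 1),
        name=np.full(n, "CA", dtype="U4"),
        element=np.full(n, "C", dtype="U2"),
        res_name=res_name,
        res_id=np.arange(1, n + 1),
        chain_id=np.full(n, "A", dtype="U2"),
        coord=coord,
        radius=np.full(n, _TOY_RADIUS),
        partial_charge=charge,
        epsilon=np.full(n, _TOY_EPSILON),
        frame_index=0,
        label=json.dumps(truth),
    )


def receptor_ground_truth(receptor: Conformation) -> dict:
    """Parse the ground-truth JSON embedded in a toy receptor's label."""
    return json.loads(receptor.label)


# --------------------------------------------------------------------------
# perturbed ensembles
# --------------------------------------------------------------------------

def _bounded_noise(rng: np.random.Generator, n: int, amp: float) -> np.ndarray:
    """Displacements uniform in the ball of radius ``amp`` (per-atom bound)."""
    if amp <= 0:
        return np.zeros((n, 3))
    v = rng.normal(size=(n, 3))
    v /= np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)
    return v * (amp * rng.random((n, 1)) ** (1 / 3))


def perturb_ensemble(base: Conformation, n_frames: int, sidechain_amp: float = 0.8,
                     backbone_amp: float = 0.2, seed: int = 0,
                     backbone_mask: np.ndarray | None = None,
                     regime_boundary: int | None = None,
                     regime_mask: np.ndarray | None = None,
                     regime_offset: np.ndarray | None = None) -> Ensemble:
    """Generate an ensemble of noisy copies of ``base``.

    Backbone atoms (default: names N/CA/C/O) are displaced by at most
    ``backbone_amp``, all others by at most ``sidechain_amp`` — emulating a
    trajectory with a stable backbone and mobile side chains.  If a regime
    schedule is given, frames ``>= regime_boundary`` additionally shift the
    atoms in ``regime_mask`` by ``regime_offset``, producing two
    distinguishable conformational clusters.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    if backbone_mask is None:
        backbone_mask = np.isin(base.name, ["N", "CA", "C", "O"])
    amp = np.where(backbone_mask, backbone_amp, sidechain_amp)[:, None]

    frames = []
    for f in range(n_frames):
        noise = _bounded_noise(rng, base.n_atoms, 1.0) * amp
        coord = base.coord + noise
        if regime_boundary is not None and f >= regime_boundary:
            mask = regime_mask if regime_mask is not None else np.ones(base.n_atoms, bool)
            coord = coord.copy()
            coord[mask] += np.asarray(regime_offset, dtype=float)
        frames.append(base.with_coords(coord, frame_index=f, label=f"frame{f}"))
    return Ensemble(frames)


def make_two_regime_ensemble(n_frames: int = 251, boundary: int = 126,
                             noise_amp: float = 0.1, seed: int = 0,
                             shell_radius: float = 14.0):
    """Toy-receptor ensemble in which one cavity closes mid-trajectory.

    Frames ``< boundary`` carry two open hydrophobic cavities; in frames
    ``>= boundary`` the second cavity's lining collapses inward, blocking
    probe placement there, and the whole body undergoes a small
    volume-preserving anisotropic strain (a convex deformation that
    separates the two regimes by more than the 1 Å clustering cutoff
    without creating new pockets).
    Returns ``(ensemble, ground_truth)`` where the ground truth records
    cavity centers, the regime boundary, and which cavity is regime-gated.
    """
    # cavity 0: large (halothane-sized) and always open; cavity 1: gated
    specs = [
        CavitySpec(center=np.array([0.0, 0.0, 3.0]), depth=10.0),
        CavitySpec(center=np.array([0.0, 0.0, -8.5]), depth=7.0),
    ]
    receptor = make_toy_receptor(specs, shell_radius=shell_radius, seed=seed)
    truth = receptor_ground_truth(receptor)
    lo, hi = truth["cavities"][1]["lining_residues"]
    gated = (receptor.res_id >= lo) & (receptor.res_id <= hi)
    center = np.asarray(truth["cavities"][1]["center"])
    r_open = truth["cavities"][1]["chamber_radius"]

    closed = receptor.coord.copy()
    rel = closed[gated] - center
    unit_rel = rel / np.maximum(np.linalg.norm(rel, axis=1, keepdims=True), 1e-9)
    n_gated = int(gated.sum())
    # scatter the lining through the chamber volume so no clash-free probe
    # position survives anywhere inside the closed cavity
    fill_radius = (r_open - 0.3) * ((np.arange(n_gated) + 0.5) / n_gated) ** (1 / 3)
    closed[gated] = center + unit_rel * fill_radius[:, None]
    # volume-preserving anisotropic strain: stretches the body along z and
    # compresses x/y, adding >1 A of RMSD without opening interior voids
    strain = 1.25
    closed[:, 2] *= strain
    closed[:, :2] /= np.sqrt(strain)

    rng = np.random.default_rng(seed + 1)
    frames = []
    for f in range(n_frames):
        ref = receptor.coord if f < boundary else closed
        coord = ref + _bounded_noise(rng, receptor.n_atoms, noise_amp)
        frames.append(receptor.with_coords(coord, frame_index=f, label=f"frame{f}"))
    truth["regime_boundary"] = boundary
    truth["n_frames"] = n_frames
    truth["gated_cavity"] = 1
    return Ensemble(frames), truth


# --------------------------------------------------------------------------
# tail conformers
# --------------------------------------------------------------------------

_CA_BOND = 3.8  # A, consecutive pseudo-CA distance
_SC_BOND = 2.4  # A, side-chain pseudo-atom offset
_MIN_NONBONDED = 2.0


def _tail_min_nonbonded(coord: np.ndarray, n_res: int) -> float:
    """Minimum distance over nonbonded pairs of a 2-atoms-per-residue tail.

    Bonded (excluded) pairs: CA(i)-CA(i+1), CA(i)-SC(i)."""
    n = len(coord)
    d = np.linalg.norm(coord[:, None] - coord[None, :], axis=-1)
    d[np.arange(n), np.arange(n)] = np.inf
    ca = np.arange(n_res) * 2
    sc = ca + 1
    d[ca[:-1], ca[1:]] = np.inf
    d[ca[1:], ca[:-1]] = np.inf
    d[ca, sc] = np.inf
    d[sc, ca] = np.inf
    return float(d.min())


def _sample_tail_walk(n_res: int, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One self-avoiding 2-atoms/residue chain; kappa in [0,1] sets
    directional persistence (1 = extended, 0 = maximally coiled)."""
    for _attempt in range(200):
        ca = np.zeros((n_res, 3))
        direction = np.array([1.0, 0.0, 0.0])
        ok = True
        for i in range(1, n_res):
            for _try in range(60):
                rand = rng.normal(size=3)
                rand /= np.linalg.norm(rand)
                cand = kappa * direction + (1 - kappa) * rand
                cand /= np.linalg.norm(cand)
                pos = ca[i - 1] + _CA_BOND * cand
                if i < 2 or np.min(np.linalg.norm(ca[: i - 1] - pos, axis=1)) >= _MIN_NONBONDED:
                    break
            else:
                ok = False
                break
            ca[i] = pos
            direction = cand
        if not ok:
            continue
        # side-chain pseudo-atoms: perpendicular-ish to the local chain,
        # choosing the least crowded of several candidate directions
        coord = np.empty((2 * n_res, 3))
        placed = list(ca)
        for i in range(n_res):
            prev_v = ca[i] - ca[i - 1] if i > 0 else ca[1] - ca[0]
            best_pos, best_clearance = None, -1.0
            for _ in range(8):
                perp = np.cross(prev_v, rng.normal(size=3))
                nrm = np.linalg.norm(perp)
                if nrm < 1e-9:
                    continue
                cand = ca[i] + _SC_BOND * perp / nrm
                others = np.array([p for j, p in enumerate(placed) if j != i])
                clearance = np.min(np.linalg.norm(others - cand, axis=1))
                if clearance > best_clearance:
                    best_pos, best_clearance = cand, clearance
            coord[2 * i] = ca[i]
            coord[2 * i + 1] = best_pos
            placed.append(best_pos)
        if _tail_min_nonbonded(coord, n_res) >= _MIN_NONBONDED:
            return coord
    raise StructureError(
        f"self-avoiding tail sampling failed after bounded retries (kappa={kappa})"
    )


def sample_tail_conformers(spec: TailSpec) -> Ensemble:
    """Sample self-avoiding coarse-grained conformers of one tail sequence.

    Each residue contributes a CA and a side-chain pseudo-atom.  Conformers
    sweep a directional-persistence schedule so that the set spans at least
    a 1.5x ratio in radius of gyration between the most extended and most
    compact members.
    """
    rng = np.random.default_rng(spec.seed)
    n_res = len(spec.sequence)
    res3 = np.array(
        [_ONE_TO_THREE.get(c.upper(), "UNK") for c in spec.sequence], dtype="U3"
    )
    kappas = (
        np.linspace(0.95, 0.0, spec.n_conformers)
        if spec.n_conformers > 1
        else np.array([0.5])
    )
    frames = []
    for f, kappa in enumerate(kappas):
        coord = _sample_tail_walk(n_res, float(kappa), rng)
        n = 2 * n_res
        frames.append(
            Conformation(
                serial=np.arange(1, n + 1),
                name=np.array(["CA", "SC"] * n_res, dtype="U4"),
                element=np.full(n, "C", dtype="U2"),
                res_name=np.repeat(res3, 2),
                res_id=np.repeat(np.arange(1, n_res + 1), 2),
                chain_id=np.full(n, "T", dtype="U2"),
                coord=coord,
                radius=np.full(n, _TOY_RADIUS),
                epsilon=np.full(n, _TOY_EPSILON),
                partial_charge=np.tile([0.0, -0.1], n_res),
                frame_index=f,
                label=f"{spec.sequence}:{f}",
            )
        )
    return Ensemble(frames)


def radius_of_gyration(conf: Conformation) -> float:
    c = conf.coord - conf.coord.mean(axis=0)
    return float(np.sqrt((c**2).sum(axis=1).mean()))


# --------------------------------------------------------------------------
# ligand from internal coordinates
# --------------------------------------------------------------------------

def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees (IUPAC sign, right-handed)."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    a = np.asarray(p0, float) - np.asarray(p1, float)
    b = np.asarray(p2, float) - np.asarray(p1, float)
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def zmatrix_to_cartesian(zmatrix, torsion_offsets: dict[int, float] | None = None) -> np.ndarray:
    """Convert a Z-matrix to Cartesian coordinates (NeRF construction).

    ``torsion_offsets`` maps zmatrix row index → dihedral increment in
    degrees, used to drive rotatable torsions during docking.
    """
    offsets = torsion_offsets or {}
    coords = np.zeros((len(zmatrix), 3))
    for k, (length, angle, dihedral, refs) in enumerate(zmatrix):
        if k == 0:
            continue
        if k == 1:
            coords[1] = coords[refs[0]] + np.array([length, 0.0, 0.0])
            continue
        phi = dihedral + offsets.get(k, 0.0)
        theta = np.radians(angle)
        if angle <= 0.0:
            raise StructureError(f"zmatrix row {k}: bond angle 0 leaves the frame undefined")
        i, j = refs[0], refs[1]
        u = coords[j] - coords[i]
        u = u / np.linalg.norm(u)
        if k == 2 or abs(angle - 180.0) < 1e-9:
            if abs(angle - 180.0) < 1e-9:
                coords[k] = coords[i] - length * u
                continue
            # first angle-defining atom: place in the xy-plane
            perp = np.cross(u, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(perp) < 1e-9:
                perp = np.cross(u, np.array([0.0, 1.0, 0.0]))
            perp = perp / np.linalg.norm(perp)
            coords[k] = coords[i] + length * (np.cos(theta) * u + np.sin(theta) * perp)
            continue
        l = refs[2]
        bc = coords[i] - coords[j]
        bc = bc / np.linalg.norm(bc)
        n = np.cross(coords[j] - coords[l], bc)
        n = n / np.linalg.norm(n)
        p = np.cross(n, bc)
        phi_r = np.radians(phi)
        d = length * (
            -np.cos(theta) * bc
            + np.sin(theta) * (np.cos(phi_r) * p + np.sin(phi_r) * n)
        )
        coords[k] = coords[i] + d
    return coords


def internal_coords(coords: np.ndarray, zmatrix) -> list[tuple[float, float, float]]:
    """Recompute (length, angle, dihedral) rows from Cartesian coordinates."""
    out = []
    for k, (_l, _a, _d, refs) in enumerate(zmatrix):
        length = angle = dihedral = 0.0
        if k >= 1:
            length = float(np.linalg.norm(coords[k] - coords[refs[0]]))
        if k >= 2:
            angle = bond_angle(coords[k], coords[refs[0]], coords[refs[1]])
        if k >= 3 and len(refs) >= 3:
            dihedral = dihedral_angle(coords[k], coords[refs[0]], coords[refs[1]], coords[refs[2]])
        out.append((length, angle, dihedral))
    return out


def build_ligand(template: LigandTemplate,
                 torsion_offsets: dict[int, float] | None = None) -> Conformation:
    """Materialise a ligand template as a Cartesian conformation."""
    coords = zmatrix_to_cartesian(template.zmatrix, torsion_offsets)
    n = template.n_atoms
    return Conformation(
        serial=np.arange(1, n + 1),
        name=np.array([a[0] for a in template.atoms], dtype="U4"),
        element=template.element_array,
        res_name=np.full(n, "LIG", dtype="U3"),
        res_id=np.ones(n, dtype=int),
        chain_id=np.full(n, "L", dtype="U2"),
        coord=coords,
        radius=np.array([a[2] for a in template.atoms], dtype=float),
        partial_charge=template.charge_array,
        frame_index=0,
        label="ligand",
    )
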