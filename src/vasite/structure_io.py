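"""Structure and ligand I/O, per-atom parameters, residue hydrophobicity.

Coordinate conventions used throughout the package: Ångström, right-handed,
as-in-file — structures are never recentred or renumbered on read.  Residue
numbering is preserved verbatim so that site annotations can be compared
directly against published residue schemes.  All distance-based operations
downstream default to heavy atoms only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb


class StructureError(ValueError):
    """Raised for malformed or inconsistent structure input."""


# --------------------------------------------------------------------------
# hydrophobicity
# --------------------------------------------------------------------------

def _load_hydropathy_table() -> dict[str, float]:
    with resources.files("vasite.data").joinpath("hydrophobicity.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return dict(zip(df["residue"], df["kd_index"].astype(float)))


_KYTE_DOOLITTLE: dict[str, float] | None = None


def hydropathy_table() -> dict[str, float]:
    """Kyte–Doolittle hydropathy indices, loaded from the bundled config."""
    global _KYTE_DOOLITTLE
    if _KYTE_DOOLITTLE is None:
        _KYTE_DOOLITTLE = _load_hydropathy_table()
    return _KYTE_DOOLITTLE


def classify_hydrophobic(residue_name: str, table: dict[str, float] | None = None) -> bool:
    """True if the residue's hydropathy index is positive.

    Unknown residue codes are treated as not hydrophobic and produce a
    warning rather than an error, so that synthetic or modified residues
    pass through annotation unharmed.
    """
    table = table if table is not None else hydropathy_table()
    code = residue_name.strip().upper()
    if code not in table:
        warnings.warn(f"unknown residue code {code!r}: treated as not hydrophobic")
        return False
    return table[code] > 0.0


# --------------------------------------------------------------------------
# core containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom record; a convenience view onto a Conformation row."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    monomer_label: str
    position: np.ndarray
    radius: float = 0.0
    partial_charge: float = 0.0
    is_hydrophobic_heavy: bool = False


@dataclass
class Conformation:
    """One structure snapshot: parallel per-atom arrays plus a frame index.

    Atom order is stable across all frames of one ensemble; the arrays are
    the canonical storage and `atom(i)` materialises an :class:`Atom` view.
    """

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray
    monomer_label: np.ndarray = None  # type: ignore[assignment]
    radius: np.ndarray = None  # type: ignore[assignment]
    partial_charge: np.ndarray = None  # type: ignore[assignment]
    epsilon: np.ndarray = None  # type: ignore[assignment]
    frame_index: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        n = len(self.serial)
        self.coord = np.asarray(self.coord, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coord)):
            raise StructureError("non-finite coordinates")
        if self.monomer_label is None:
            self.monomer_label = self.chain_id.astype("U16")
        if self.radius is None:
            self.radius = np.zeros(n)
        if self.partial_charge is None:
            self.partial_charge = np.zeros(n)
        if self.epsilon is None:
            self.epsilon = np.zeros(n)

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.char.upper(self.element.astype("U2")) != "H"

    @property
    def hydrophobic_heavy_mask(self) -> np.ndarray:
        table = hydropathy_table()
        hydro = np.array([table.get(r.strip().upper(), -1.0) > 0 for r in self.res_name])
        return hydro & self.heavy_mask

    def atom(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            element=str(self.element[i]),
            residue_name=str(self.res_name[i]),
            residue_number=int(self.res_id[i]),
            chain_id=str(self.chain_id[i]),
            monomer_label=str(self.monomer_label[i]),
            position=self.coord[i].copy(),
            radius=float(self.radius[i]),
            partial_charge=float(self.partial_charge[i]),
            is_hydrophobic_heavy=bool(self.hydrophobic_heavy_mask[i]),
        )

    def select(self, mask: np.ndarray) -> "Conformation":
        return Conformation(
            serial=self.serial[mask],
            name=self.name[mask],
            element=self.element[mask],
            res_name=self.res_name[mask],
            res_id=self.res_id[mask],
            chain_id=self.chain_id[mask],
            coord=self.coord[mask],
            monomer_label=self.monomer_label[mask],
            radius=self.radius[mask],
            partial_charge=self.partial_charge[mask],
            epsilon=self.epsilon[mask],
            frame_index=self.frame_index,
            label=self.label,
        )

    def with_coords(self, coord: np.ndarray, frame_index: int | None = None,
                    label: str | None = None) -> "Conformation":
        return replace(
            self,
            coord=np.array(coord, dtype=float),
            frame_index=self.frame_index if frame_index is None else frame_index,
            label=self.label if label is None else label,
        )

    def same_atoms(self, other: "Conformation") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.name, other.name)
            and np.array_equal(self.res_id, other.res_id)
            and np.array_equal(self.chain_id, other.chain_id)
        )


@dataclass
class Ensemble:
    """Ordered conformations with unique, dense frame indices."""

    conformations: list[Conformation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.conformations:
            first = self.conformations[0]
            for conf in self.conformations[1:]:
                if not first.same_atoms(conf):
                    raise StructureError("inconsistent atom identity across frames")
            idx = sorted(c.frame_index for c in self.conformations)
            if idx != list(range(len(idx))):
                raise StructureError("frame_index values must be unique and dense")

    @property
    def total_frames(self) -> int:
        return len(self.conformations)

    def __len__(self) -> int:
        return len(self.conformations)

    def __getitem__(self, i: int) -> Conformation:
        return self.conformations[i]

    def __iter__(self):
        return iter(self.conformations)


# --------------------------------------------------------------------------
# PDB read / write
# --------------------------------------------------------------------------

def _find_bad_atom_line(path: Path) -> int | None:
    """Scan a PDB file for the first ATOM/HETATM record whose fixed-width
    coordinate fields do not parse."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    return lineno
    return None


def read_structure(path: str | Path, model_policy: str = "all",
                   monomer_map: dict[str, str] | None = None) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    ``model_policy`` is ``"all"`` (one conformation per MODEL block) or
    ``"first"``.  Chain IDs and residue numbers are preserved verbatim.
    ``monomer_map`` optionally maps chain IDs to lattice monomer labels
    (e.g. ``{"A": "alpha1", "B": "beta1"}``).
    """
    path = Path(path)
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        if model_policy == "first":
            arrays = [pdb_file.get_structure(model=1)]
        else:
            n_models = pdb_file.get_model_count()
            arrays = [pdb_file.get_structure(model=m) for m in range(1, n_models + 1)]
    except Exception as exc:  # pin the failure to a line where possible
        bad = _find_bad_atom_line(path)
        if bad is not None:
            raise StructureError(f"{path}: unreadable ATOM/HETATM record at line {bad}") from exc
        raise StructureError(f"{path}: {exc}") from exc

    counts = {arr.array_length() for arr in arrays}
    if len(counts) != 1:
        raise StructureError(
            f"{path}: MODEL blocks have inconsistent atom counts {sorted(counts)}"
        )

    conformations = []
    for frame, arr in enumerate(arrays):
        chains = arr.chain_id.astype("U2")
        labels = (
            np.array([monomer_map.get(c, c) for c in chains], dtype="U16")
            if monomer_map
            else chains.astype("U16")
        )
        conformations.append(
            Conformation(
                serial=np.arange(1, arr.array_length() + 1),
                name=arr.atom_name.astype("U4"),
                element=arr.element.astype("U2"),
                res_name=arr.res_name.astype("U3"),
                res_id=arr.res_id.astype(int),
                chain_id=chains,
                coord=np.asarray(arr.coord, dtype=float),
                monomer_label=labels,
                frame_index=frame,
                label=path.stem,
            )
        )
    return Ensemble(conformations)


def write_structure(ensemble: Ensemble | Conformation, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (coordinates at 1e-3 Å)."""
    if isinstance(ensemble, Conformation):
        ensemble = Ensemble([replace(ensemble, frame_index=0)])
    ref = ensemble[0]
    n = ref.n_atoms
    arrays = []
    for conf in ensemble:
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(conf.coord, dtype=np.float32)
        arr.atom_name = conf.name
        arr.element = conf.element
        arr.res_name = conf.res_name
        arr.res_id = conf.res_id
        arr.chain_id = conf.chain_id
        arr.hetero = np.zeros(n, dtype=bool)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# --------------------------------------------------------------------------
# per-atom parameters
# --------------------------------------------------------------------------

def load_element_params(path: str | Path | None = None) -> dict[str, tuple[float, float, float]]:
    """Element → (vdW radius Å, LJ well depth kcal/mol, default charge e)."""
    if path is None:
        fh = resources.files("vasite.data").joinpath("element_params.tsv").open()
    else:
        fh = open(path)
    with fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return {
        str(row.element).strip().upper(): (float(row.radius), float(row.epsilon), float(row.charge))
        for row in df.itertuples()
    }


def assign_params(conf: Conformation,
                  table: dict[str, tuple[float, float, float]],
                  charges: np.ndarray | None = None) -> Conformation:
    """Return a copy of ``conf`` with radius, well depth and charge assigned.

    ``charges`` overrides the table's default charges (used for ligands,
    whose partial charges come from their template, not the element table).
    """
    if not table:
        raise StructureError("empty element parameter table")
    elements = np.char.upper(conf.element.astype("U2"))
    missing = sorted(set(elements) - set(table))
    if missing:
        raise StructureError(f"elements absent from parameter table: {missing}")
    radius = np.array([table[e][0] for e in elements])
    epsilon = np.array([table[e][1] for e in elements])
    charge = (
        np.asarray(charges, dtype=float)
        if charges is not None
        else np.array([table[e][2] for e in elements])
    )
    if np.any(radius <= 0):
        raise StructureError("non-positive vdW radius in parameter table")
    out = replace(conf)
    out.radius = radius
    out.epsilon = epsilon
    out.partial_charge = charge
    return out


def assign_atom_params(atom: Atom, table: dict[str, tuple[float, float, float]]) -> Atom:
    """Single-atom form of :func:`assign_params`."""
    if not table:
        raise StructureError("empty element parameter table")
    key = atom.element.strip().upper()
    if key not in table:
        raise StructureError(f"elements absent from parameter table: [{key!r}]")
    radius, _eps, charge = table[key]
    return replace(atom, radius=radius, partial_charge=charge)


# --------------------------------------------------------------------------
# ligand templates
# --------------------------------------------------------------------------

@dataclass
class LigandTemplate:
    """Small-molecule definition in internal coordinates.

    ``zmatrix`` row k holds (bond_length Å, bond_angle deg, dihedral deg,
    (i, j, l)) — atom k is placed at distance from atom i, angle through
    atoms (k, i, j), dihedral through (k, i, j, l); rows 0–2 use the
    degenerate subset of references.  ``rotatable_torsions`` lists zmatrix
    row indices whose dihedral is a searchable degree of freedom.
    """

    atoms: list[tuple[str, str, float, float]]  # (name, element, radius, charge)
    zmatrix: list[tuple[float, float, float, tuple[int, ...]]]
    rotatable_torsions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for k, (length, angle, _dihedral, refs) in enumerate(self.zmatrix):
            if k > 0 and length <= 0:
                raise StructureError(f"zmatrix row {k}: bond length must be > 0")
            if k > 1 and not (0.0 < angle <= 180.0):
                raise StructureError(f"zmatrix row {k}: bond angle must be in (0, 180]")
            if any(r >= k for r in refs):
                raise StructureError(f"zmatrix row {k} references a later atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def element_array(self) -> np.ndarray:
        return np.array([a[1] for a in self.atoms], dtype="U2")

    @property
    def charge_array(self) -> np.ndarray:
        return np.array([a[3] for a in self.atoms], dtype=float)


def read_ligand_template(path: str | Path | None = None) -> LigandTemplate:
    """Read a ligand template from JSON; default is the bundled halothane."""
    if path is None:
        text = resources.files("vasite.data").joinpath("halothane.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    atoms = [(a["name"], a["element"], float(a["radius"]), float(a["charge"]))
             for a in raw["atoms"]]
    zmatrix = [
        (float(r["length"]), float(r["angle"]), float(r["dihedral"]), tuple(r["refs"]))
        for r in raw["zmatrix"]
    ]
    return LigandTemplate(atoms=atoms, zmatrix=zmatrix,
                          rotatable_torsions=list(raw.get("rotatable_torsions", [])))
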