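{
  "comment": "Halothane (2-bromo-2-chloro-1,1,1-trifluoroethane) internal-coordinate template. Bond lengths (A), angles/dihedrals (deg) are standard ab-initio-quality gas-phase values; partial charges (e) are approximate and sum to zero. Row k refs (i,j,l): distance to i, angle k-i-j, dihedral k-i-j-l. Rotating the dihedral of row 5 (H on C2 about the C1-C2 bond) turns the whole CHClBr group: the single rotatable torsion.",
  "atoms": [
    {"name": "C1", "element": "C", "radius": 1.908, "charge": 0.45},
    {"name": "C2", "element": "C", "radius": 1.908, "charge": -0.06},
    {"name": "F1", "element": "F", "radius": 1.750, "charge": -0.16},
    {"name": "F2", "element": "F", "radius": 1.750, "charge": -0.16},
    {"name": "F3", "element": "F", "radius": 1.750, "charge": -0.16},
    {"name": "H1", "element": "H", "radius": 1.387, "charge": 0.12},
    {"name": "CL1", "element": "CL", "radius": 1.948, "charge": -0.04},
    {"name": "BR1", "element": "BR", "radius": 2.220, "charge": 0.01}
  ],
  "zmatrix": [
    {"length": 0.0, "angle": 0.0, "dihedral": 0.0, "refs": []},
    {"length": 1.545, "angle": 0.0, "dihedral": 0.0, "refs": [0]},
    {"length": 1.335, "angle": 110.5, "dihedral": 0.0, "refs": [0, 1]},
    {"length": 1.335, "angle": 110.5, "dihedral": 120.0, "refs": [0, 1, 2]},
    {"length": 1.335, "angle": 110.5, "dihedral": -120.0, "refs": [0, 1, 2]},
    {"length": 1.090, "angle": 108.5, "dihedral": 60.0, "refs": [1, 0, 2]},
    {"length": 1.770, "angle": 110.0, "dihedral": 120.0, "refs": [1, 0, 5]},
    {"length": 1.940, "angle": 110.5, "dihedral": -120.0, "refs": [1, 0, 5]}
  ],
  "rotatable_torsions": [5]
}
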