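# Element nonbonded parameters for the LJ+Coulomb scorer.
# radius = rmin/2 in Angstrom, epsilon = LJ well depth in kcal/mol,
# charge = default partial charge in e (ligand charges come from templates).
element	radius	epsilon	charge
C	1.908	0.086	0.0
H	1.387	0.016	0.0
N	1.824	0.170	0.0
O	1.661	0.210	0.0
S	2.000	0.250	0.0
F	1.750	0.061	0.0
CL	1.948	0.265	0.0
BR	2.220	0.320	0.0
P	2.100	0.200	0.0
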