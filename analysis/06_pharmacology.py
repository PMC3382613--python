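#!/usr/bin/env python
"""Concentration and occupancy arithmetic for anesthetic-tubulin binding.

Reproduces the published back-of-envelope pharmacology from its stated
inputs: 10^9 tubulin dimers per neuron and 10^11 neurons in a 1.4 L brain
give ~120 µM tubulin; the two most persistent published site energies
(-2.54 and -3.12 kcal/mol) give Kd ≈ 16 and 6 mM at 310 K; and 250-500 µM
halothane (≈1-2 MAC) gives a fractional occupancy of roughly 2-8% and 1-2
halothane molecules per dimer.
"""

import argparse
import json
from pathlib import Path

from vasite.pharm import (
    MAC_CONCENTRATION_M,
    brain_concentration,
    kd_from_energy,
    molecules_per_dimer,
    occupancy,
    round_sig,
)

PERSISTENT_SITE_ENERGIES = {"weak": -2.54, "strong": -3.12}  # kcal/mol


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--temperature", type=float, default=310.0)
    parser.add_argument("--out", type=Path, default=Path("results/pharmacology"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    conc = brain_concentration(1e9, 1e11, 1.4)
    print(f"brain tubulin concentration: {conc * 1e6:.1f} µM "
          f"(~{round_sig(conc * 1e6, 2):.0f} µM)")

    report = {"temperature_K": args.temperature,
              "brain_tubulin_uM": round_sig(conc * 1e6, 2), "sites": {}}
    for label, delta_g in PERSISTENT_SITE_ENERGIES.items():
        kd = kd_from_energy(delta_g, args.temperature)
        entry = {"delta_g_kcal_mol": delta_g, "kd_mM": round_sig(kd * 1e3, 2)}
        print(f"{label} persistent site (ΔG = {delta_g} kcal/mol): "
              f"Kd = {kd * 1e3:.2f} mM")
        for mac, ligand in sorted(MAC_CONCENTRATION_M.items()):
            theta = occupancy(ligand, kd)
            entry[f"occupancy_pct_at_{mac}MAC"] = round_sig(100 * theta, 2)
            print(f"  occupancy at {mac} MAC ({ligand * 1e6:.0f} µM): "
                  f"{100 * theta:.1f}%")
        report["sites"][label] = entry

    for mac, ligand in sorted(MAC_CONCENTRATION_M.items()):
        ratio = molecules_per_dimer(ligand, 240e-6)
        report[f"halothane_per_dimer_at_{mac}MAC"] = round_sig(ratio, 2)
        print(f"halothane molecules per dimer at {mac} MAC "
              f"(240 µM neuronal tubulin): {ratio:.1f}")

    (args.out / "pharmacology.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    print(f"wrote {args.out}/pharmacology.json")


if __name__ == "__main__":
    main()
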