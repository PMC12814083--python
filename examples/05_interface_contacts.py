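"""Interface characterization of a two-chain protein complex.

Loads a complex (here a synthetic one written to PDB), computes the
residue-residue contact map at the 4.0 Å heavy-atom cutoff, per-residue
contact-density profiles, and minimum distances from every ligand-chain
residue to named catalytic residues — the analysis used to judge whether a
ligand docks in a substrate-like pose near an enzyme's active site.
"""

import tempfile
from pathlib import Path

from kgora.contacts import (
    catalytic_distances,
    compute_contact_map,
    contact_density,
    load_structure,
    nearest_ligand_residues,
    write_pdb,
)
from kgora.synthetic import generate_complex

tmp = Path(tempfile.mkdtemp(prefix="kgora_contacts_"))
pdb_path = tmp / "complex.pdb"
write_pdb(generate_complex(30, 60, seed=1), pdb_path)

model = load_structure(pdb_path)  # hydrogens/waters stripped on load
cmap = compute_contact_map(model, "A", "B", cutoff=4.0)
profile = contact_density(cmap, "A")

print(f"chains: {sorted(model.chains)}; "
      f"{len(model.chains['A'])} ligand residues, {len(model.chains['B'])} receptor residues")
print(f"{len(cmap.contacts)} residue-residue contacts at <= 4.0 Å")
hot = sorted(profile.counts.items(), key=lambda kv: -kv[1])[:3]
print("highest-density ligand residues:",
      ", ".join(f"A{num}{ic} ({n} contacts)" for (num, ic), n in hot))

catalytic = [("B", 10), ("B", 25), ("B", 40)]
table = catalytic_distances(model, "A", catalytic)
print()
print(nearest_ligand_residues(table).to_string(index=False))
print()
print("Per catalytic residue, the nearest ligand residue and its minimum "
      "heavy-atom distance; distances of ~3-4 Å indicate direct "
      "substrate-like engagement of the catalytic pocket.")
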