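"""Residue-level interface contact analysis on a protein complex structure.

Given a PDB file of a complex (e.g. a disordered ligand chain docked onto an
enzyme), this module computes minimum heavy-atom distances between residues
of two chains, residue-residue contact maps at a distance cutoff (inclusive
4.0 Å by default), per-residue contact-density profiles, and minimum
distances from every ligand residue to named catalytic residues — the
standard characterization of a putative substrate-like binding interface.

Heavy atoms are all non-hydrogen atoms, identified from the element field
(with an atom-name fallback for PDB dialects lacking element columns).
Waters are dropped on load; alternate locations are resolved by highest
occupancy, then altloc label order.  Residues are keyed by (chain, author
residue number, insertion code).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

ResidueKey = tuple[int, str]  # (author residue number, insertion code)

_WATER_NAMES = {"HOH", "WAT", "DOD"}
# atom-name fallback: names starting with H/D (after leading digits) are hydrogens
_HYDROGEN_ELEMENTS = {"H", "D"}


class StructureFormatError(ValueError):
    """The file cannot be parsed as PDB."""


class SelectionError(KeyError):
    """A requested chain or residue is absent from the model."""


@dataclass(frozen=True)
class Residue:
    number: int
    icode: str
    name: str
    atom_names: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3) heavy-atom coordinates, Å

    @property
    def key(self) -> ResidueKey:
        return (self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.name}{self.number}{self.icode}".strip()


@dataclass(frozen=True)
class StructureModel:
    """Heavy-atom model: chain id -> ordered residues."""

    chains: dict[str, tuple[Residue, ...]]

    def chain(self, chain_id: str) -> tuple[Residue, ...]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise SelectionError(
                f"chain {chain_id!r} not in model (has {sorted(self.chains)})"
            ) from None

    def residue(self, chain_id: str, key: ResidueKey | int) -> Residue:
        if isinstance(key, int):
            key = (key, "")
        for res in self.chain(chain_id):
            if res.key == key:
                return res
        raise SelectionError(f"residue {key} not in chain {chain_id!r}")


def _is_hydrogen(element: str, atom_name: str) -> bool:
    el = element.strip().upper()
    if el:
        return el in _HYDROGEN_ELEMENTS
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() in _HYDROGEN_ELEMENTS


def load_structure(
    pdb_path: str | Path,
    model_index: int = 0,
    altloc_policy: str = "occupancy",
) -> StructureModel:
    """Parse a PDB file into a heavy-atom :class:`StructureModel`.

    Takes the model at ``model_index`` (first by default); strips hydrogens,
    deuteriums and waters; resolves disordered atoms by highest occupancy
    then altloc label order.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    if altloc_policy != "occupancy":
        raise ValueError(f"unsupported altloc policy {altloc_policy!r}")
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("model", str(pdb_path))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {pdb_path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureFormatError(f"no models in {pdb_path}")
    if model_index >= len(models):
        raise SelectionError(f"model index {model_index} out of range ({len(models)} models)")
    model = models[model_index]

    chains: dict[str, tuple[Residue, ...]] = {}
    for chain in model:
        residues = []
        for res in chain:
            hetflag, resnum, icode = res.id
            if res.resname.strip() in _WATER_NAMES:
                continue
            names, coords = [], []
            for atom in res.get_unpacked_list():
                if _is_hydrogen(atom.element or "", atom.get_name()):
                    continue
                names.append((atom.get_name(), atom.get_altloc(), atom.get_occupancy()))
                coords.append(atom.get_coord())
            if not names:
                continue
            # altloc resolution: group by atom name, keep highest occupancy
            # then smallest altloc label
            by_name: dict[str, tuple[float, str, int]] = {}
            for idx, (name, altloc, occ) in enumerate(names):
                occ = 1.0 if occ is None else float(occ)
                current = by_name.get(name)
                cand = (-occ, altloc or " ", idx)
                if current is None or cand < current:
                    by_name[name] = cand
            kept = sorted(by_name.items(), key=lambda kv: kv[1][2])
            atom_names = tuple(name for name, _ in kept)
            xyz = np.array([coords[meta[2]] for _, meta in kept], dtype=float)
            if not np.all(np.isfinite(xyz)):
                raise StructureFormatError(
                    f"non-finite coordinates in residue {res.resname}{resnum}"
                )
            residues.append(
                Residue(
                    number=int(resnum),
                    icode=icode.strip(),
                    name=res.resname.strip(),
                    atom_names=atom_names,
                    coords=xyz,
                )
            )
        if residues:
            chains[chain.id.strip() or chain.id] = tuple(residues)
    if not chains:
        raise SelectionError(f"no non-water residues found in {pdb_path}")
    return StructureModel(chains=chains)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Minimal PDB writer (ATOM records, element from atom name)."""
    serial = 1
    with open(path, "w") as fh:
        for chain_id in model.chains:
            for res in model.chains[chain_id]:
                for name, xyz in zip(res.atom_names, res.coords):
                    element = name.strip().lstrip("0123456789")[:1].upper()
                    fh.write(
                        f"ATOM  {serial:5d} {name:^4s}"
                        f"{res.name:>4s} {chain_id:1s}{res.number:4d}{res.icode or ' ':1s}   "
                        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
                    )
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


def min_residue_distance(
    model: StructureModel,
    chain_a: str,
    res_a: ResidueKey | int,
    chain_b: str,
    res_b: ResidueKey | int,
) -> float:
    """Minimum Euclidean distance over all heavy-atom pairs, in Å."""
    a = model.residue(chain_a, res_a)
    b = model.residue(chain_b, res_b)
    return float(cdist(a.coords, b.coords).min())


@dataclass(frozen=True)
class ContactMap:
    """Residue pairs of (chain_a, chain_b) within ``cutoff`` Å (inclusive)."""

    chain_a: str
    chain_b: str
    cutoff: float
    contacts: frozenset[tuple[ResidueKey, ResidueKey]]
    residues_a: tuple[ResidueKey, ...] = field(default_factory=tuple)
    residues_b: tuple[ResidueKey, ...] = field(default_factory=tuple)


def compute_contact_map(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff: float = 4.0,
) -> ContactMap:
    """All residue pairs whose minimum heavy-atom distance is <= cutoff."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    residues_a = model.chain(chain_a)
    residues_b = model.chain(chain_b)
    coords_b = [r.coords for r in residues_b]
    contacts = set()
    for ra in residues_a:
        for rb, cb in zip(residues_b, coords_b):
            if cdist(ra.coords, cb).min() <= cutoff:
                contacts.add((ra.key, rb.key))
    return ContactMap(
        chain_a=chain_a,
        chain_b=chain_b,
        cutoff=cutoff,
        contacts=frozenset(contacts),
        residues_a=tuple(r.key for r in residues_a),
        residues_b=tuple(r.key for r in residues_b),
    )


@dataclass(frozen=True)
class ContactDensityProfile:
    chain_id: str
    counts: dict[ResidueKey, int]  # every chain residue, zeros included

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def contact_density(cmap: ContactMap, chain: str) -> ContactDensityProfile:
    """Per-residue count of contact partners on the opposite chain."""
    if chain == cmap.chain_a:
        residues, side = cmap.residues_a, 0
    elif chain == cmap.chain_b:
        residues, side = cmap.residues_b, 1
    else:
        raise SelectionError(f"chain {chain!r} is not a side of this contact map")
    counts = {key: 0 for key in residues}
    for pair in cmap.contacts:
        counts[pair[side]] += 1
    return ContactDensityProfile(chain_id=chain, counts=counts)


def catalytic_distances(
    model: StructureModel,
    ligand_chain: str,
    catalytic: Sequence[tuple[str, ResidueKey | int]],
) -> pd.DataFrame:
    """Minimum heavy-atom distance from every ligand residue to each catalytic residue.

    Returns a tidy table with columns ligand_residue (label), ligand_number,
    catalytic_chain, catalytic_residue (label), distance (Å).
    """
    if not catalytic:
        raise ValueError("need at least one catalytic residue")
    cat_res = [(chain, model.residue(chain, key)) for chain, key in catalytic]
    rows = []
    for lig in model.chain(ligand_chain):
        for chain, res in cat_res:
            rows.append(
                {
                    "ligand_residue": lig.label,
                    "ligand_number": lig.number,
                    "ligand_icode": lig.icode,
                    "catalytic_chain": chain,
                    "catalytic_residue": res.label,
                    "distance": float(cdist(lig.coords, res.coords).min()),
                }
            )
    return pd.DataFrame(rows)


def nearest_ligand_residues(table: pd.DataFrame) -> pd.DataFrame:
    """Per catalytic residue, the closest ligand residue from a distance table."""
    idx = table.groupby("catalytic_residue")["distance"].idxmin()
    return table.loc[idx].reset_index(drop=True)


def contact_map_to_frame(cmap: ContactMap, model: StructureModel) -> pd.DataFrame:
    label_a = {r.key: r.label for r in model.chain(cmap.chain_a)}
    label_b = {r.key: r.label for r in model.chain(cmap.chain_b)}
    rows = []
    for ka, kb in sorted(cmap.contacts):
        rows.append(
            {
                "res_a": label_a[ka],
                "res_b": label_b[kb],
                "min_distance": min_residue_distance(
                    model, cmap.chain_a, ka, cmap.chain_b, kb
                ),
            }
        )
    return pd.DataFrame(rows, columns=["res_a", "res_b", "min_distance"])


def plot_contact_density(profile: ContactDensityProfile, path: str | Path) -> None:
    """Bar plot of the per-residue contact counts (optional convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    numbers = [k[0] for k in profile.counts]
    values = list(profile.counts.values())
    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.bar(numbers, values, width=1.0)
    ax.set_xlabel(f"chain {profile.chain_id} residue")
    ax.set_ylabel("contacts")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
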