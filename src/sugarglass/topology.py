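"""Per-atom identity records: molecule membership, species and H-bonding role.

The topology is the authority on chemistry.  Which hydrogen is covalently
bound to which oxygen comes from the sidecar table (or from a name
convention), never from geometry — distance-based bond perception is
unreliable in dense glasses where non-bonded O···H contacts approach
covalent distances.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SPECIES = ("trehalose", "water", "other")
ROLES = ("acceptor_oxygen", "donor_hydrogen", "inert")

#: default residue-name -> species map used by :func:`infer_topology`
DEFAULT_RESIDUE_MAP: dict[str, str] = {
    "HOH": "water",
    "TIP3": "water",
    "WAT": "water",
    "SOL": "water",
    "TRE": "trehalose",
    "TREH": "trehalose",
    "BGLC": "trehalose",
}

SIDECAR_COLUMNS = [
    "atom_index",
    "molecule_id",
    "species",
    "role",
    "atom_name",
    "parent_oxygen",
]


class TopologyError(ValueError):
    """Raised when atom records violate a topology invariant."""


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom: where it lives and what it can do in an H-bond."""

    atom_index: int
    molecule_id: int
    species: str
    role: str
    atom_name: str
    parent_oxygen: int | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise TopologyError(f"unknown species {self.species!r}")
        if self.role not in ROLES:
            raise TopologyError(f"unknown role {self.role!r}")
        if self.role == "donor_hydrogen" and self.parent_oxygen is None:
            raise TopologyError(
                f"atom {self.atom_index} ({self.atom_name}): donor hydrogen "
                "requires parent_oxygen"
            )


class Topology:
    """Validated, indexed collection of :class:`AtomRecord`.

    Provides the integer index arrays the detectors consume: donor
    hydrogens, their parent oxygens, acceptor oxygens, and per-atom /
    per-molecule species codes.
    """

    def __init__(self, records: Sequence[AtomRecord]):
        records = list(records)
        self._validate(records)
        self.records = records
        n = len(records)
        self.n_atoms = n
        self.molecule_id = np.array([r.molecule_id for r in records], dtype=np.int64)
        self.atom_names = np.array([r.atom_name for r in records], dtype=object)
        self.species = np.array([r.species for r in records], dtype=object)
        self.role = np.array([r.role for r in records], dtype=object)
        self.parent_oxygen = np.array(
            [r.parent_oxygen if r.parent_oxygen is not None else -1 for r in records],
            dtype=np.int64,
        )
        self.donor_hydrogens = np.flatnonzero(self.role == "donor_hydrogen")
        self.acceptor_oxygens = np.flatnonzero(self.role == "acceptor_oxygen")
        # molecule-level species lookup
        mols: dict[int, str] = {}
        for r in records:
            mols.setdefault(r.molecule_id, r.species)
        self.molecule_species: dict[int, str] = mols
        self.molecule_ids = np.array(sorted(mols), dtype=np.int64)
        self.n_trehalose = sum(1 for s in mols.values() if s == "trehalose")
        self.n_water = sum(1 for s in mols.values() if s == "water")

    def __len__(self) -> int:
        return self.n_atoms

    @staticmethod
    def _validate(records: Sequence[AtomRecord]) -> None:
        idx = [r.atom_index for r in records]
        if sorted(idx) != list(range(len(records))):
            dupes = sorted({i for i in idx if idx.count(i) > 1})
            if dupes:
                raise TopologyError(f"duplicate atom_index values: {dupes[:5]}")
            raise TopologyError("atom_index values must be contiguous from 0")
        by_index = {r.atom_index: r for r in records}
        per_mol_roles: dict[int, list[str]] = {}
        per_mol_species: dict[int, set[str]] = {}
        for r in records:
            per_mol_roles.setdefault(r.molecule_id, []).append(r.role)
            per_mol_species.setdefault(r.molecule_id, set()).add(r.species)
            if r.role == "donor_hydrogen":
                parent = by_index.get(r.parent_oxygen)
                if parent is None:
                    raise TopologyError(
                        f"atom {r.atom_index}: parent_oxygen {r.parent_oxygen} "
                        "does not exist"
                    )
                if parent.molecule_id != r.molecule_id:
                    raise TopologyError(
                        f"atom {r.atom_index}: parent oxygen {parent.atom_index} "
                        f"belongs to molecule {parent.molecule_id}, "
                        f"not {r.molecule_id}"
                    )
                if parent.role != "acceptor_oxygen":
                    raise TopologyError(
                        f"atom {r.atom_index}: parent atom {parent.atom_index} "
                        "is not an acceptor_oxygen"
                    )
        for mol, species in per_mol_species.items():
            if len(species) > 1:
                raise TopologyError(f"molecule {mol} mixes species {sorted(species)}")
            if species == {"water"}:
                roles = per_mol_roles[mol]
                n_o = roles.count("acceptor_oxygen")
                n_h = roles.count("donor_hydrogen")
                if (n_o, n_h) != (1, 2):
                    raise TopologyError(
                        f"water molecule {mol} must have 1 oxygen and "
                        f"2 hydrogens, found {n_o} O / {n_h} H"
                    )

    # ------------------------------------------------------------------ io
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Topology":
        missing = [c for c in SIDECAR_COLUMNS[:5] if c not in df.columns]
        if missing:
            raise TopologyError(f"topology table missing columns: {missing}")
        records = []
        for row in df.itertuples(index=False):
            parent = getattr(row, "parent_oxygen", None)
            if parent is None or (isinstance(parent, float) and np.isnan(parent)) or (
                isinstance(parent, str) and parent.strip() in ("", "-", "NA")
            ):
                parent = None
            else:
                parent = int(parent)
            records.append(
                AtomRecord(
                    atom_index=int(row.atom_index),
                    molecule_id=int(row.molecule_id),
                    species=str(row.species),
                    role=str(row.role),
                    atom_name=str(row.atom_name),
                    parent_oxygen=parent,
                )
            )
        return cls(records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "atom_index": [r.atom_index for r in self.records],
                "molecule_id": [r.molecule_id for r in self.records],
                "species": [r.species for r in self.records],
                "role": [r.role for r in self.records],
                "atom_name": [r.atom_name for r in self.records],
                "parent_oxygen": [
                    r.parent_oxygen if r.parent_oxygen is not None else ""
                    for r in self.records
                ],
            }
        )


def read_topology(path: str | os.PathLike | io.IOBase) -> Topology:
    """Read the tab/whitespace-delimited topology sidecar.

    The table must carry a header with the columns
    ``atom_index molecule_id species role atom_name parent_oxygen``
    (``parent_oxygen`` empty or ``-`` for non-hydrogens).
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"parent_oxygen": "object"})
    return Topology.from_dataframe(df)


def write_topology(path: str | os.PathLike, topology: Topology) -> None:
    topology.to_dataframe().to_csv(path, sep="\t", index=False)


def infer_topology(
    atom_names: Sequence[str],
    residue_names: Sequence[str],
    residue_ids: Sequence[int],
    residue_map: Mapping[str, str] | None = None,
) -> Topology:
    """Build a topology from PDB-style names by convention, not geometry.

    Conventions (overridable through ``residue_map``): residues named
    HOH/TIP3/WAT/SOL are water, TRE-like residues are trehalose; within a
    water, ``O*`` is the oxygen and ``H*`` the two hydrogens; within
    trehalose, ``O*`` atoms are acceptor oxygens and ``HO*`` atoms are
    hydroxyl hydrogens whose parent is the oxygen with the matching suffix
    (``HO16`` -> ``O16``).  Everything else is inert.
    """
    residue_map = dict(DEFAULT_RESIDUE_MAP if residue_map is None else residue_map)
    n = len(atom_names)
    if not (len(residue_names) == len(residue_ids) == n):
        raise TopologyError("atom_names, residue_names, residue_ids length mismatch")

    unknown = sorted(
        {rn for rn in residue_names if rn not in residue_map}
    )
    if unknown:
        raise TopologyError(
            f"no species mapping for residue name(s) {unknown}; "
            "extend the residue map"
        )

    # group atoms by residue occurrence (resid changes delimit molecules)
    mol_of_atom = np.zeros(n, dtype=np.int64)
    mol = -1
    prev = None
    for i, rid in enumerate(residue_ids):
        if rid != prev:
            mol += 1
            prev = rid
        mol_of_atom[i] = mol

    members: dict[int, list[int]] = {}
    for i, m in enumerate(mol_of_atom):
        members.setdefault(int(m), []).append(i)

    records: list[AtomRecord] = []
    for i in range(n):
        name = str(atom_names[i]).strip()
        species = residue_map[residue_names[i]]
        mol_id = int(mol_of_atom[i])
        same_mol = members[mol_id]
        role = "inert"
        parent: int | None = None
        if species == "water":
            if name.upper().startswith("O"):
                role = "acceptor_oxygen"
            elif name.upper().startswith("H"):
                role = "donor_hydrogen"
                oxy = [j for j in same_mol if str(atom_names[j]).upper().startswith("O")]
                if not oxy:
                    raise TopologyError(
                        f"water molecule {mol_id} has hydrogen {name} but no oxygen"
                    )
                parent = int(oxy[0])
        elif species == "trehalose":
            if name.upper().startswith("HO"):
                role = "donor_hydrogen"
                suffix = name[2:]
                target = "O" + suffix
                oxy = [j for j in same_mol if str(atom_names[j]).strip() == target]
                if not oxy:
                    raise TopologyError(
                        f"hydroxyl hydrogen {name} in molecule {mol_id}: "
                        f"no oxygen named {target} in the same residue"
                    )
                parent = int(oxy[0])
            elif name.upper().startswith("O"):
                role = "acceptor_oxygen"
        records.append(
            AtomRecord(
                atom_index=i,
                molecule_id=mol_id,
                species=species,
                role=role,
                atom_name=name,
                parent_oxygen=parent,
            )
        )
    return Topology(records)
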