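"""Structural substrate: PDB parsing, solvent accessibility, interface and surface detection.

A protein complex is represented as a :class:`StructureModel`, a thin wrapper
around a :class:`biotite.structure.AtomArray` holding heavy atoms only.
Interface residues are defined by buried solvent-accessible surface area
(ΔASA > 0.1 Å² on complexation) and surface residues by relative accessibility
(residue SASA over an extended-state reference) ≥ 5%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structural input."""


class ResidueKey(NamedTuple):
    """Unique identifier of one residue: (chain_id, residue_number, insertion_code)."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""


# Per-element van der Waals radii (Å).  Values follow the Bondi/NACCESS-style
# single-atom convention; hydrogens are normally absent from the model anyway.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Maximum accessible surface area per residue type (Å²), theoretical values for
# X in an extended Gly-X-Gly context (Tien et al. 2013).  Used to normalise
# residue SASA into relative accessibility.
MAX_ASA_EXTENDED: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    """One heavy atom, as exposed at the API boundary."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    coordinates: np.ndarray
    occupancy: float
    mass: float

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.residue_number, self.insertion_code)


class StructureModel:
    """Heavy atoms grouped into residues and chains.

    Wraps a biotite ``AtomArray`` and adds residue-level indexing keyed by
    :class:`ResidueKey`.
    """

    def __init__(self, array: struc.AtomArray):
        if array.array_length() == 0:
            raise StructureError("structure contains no atoms")
        if "occupancy" not in array.get_annotation_categories():
            array = array.copy()
            array.set_annotation("occupancy", np.ones(array.array_length()))
        self.array = array
        keys = [
            ResidueKey(str(c), int(r), str(i))
            for c, r, i in zip(array.chain_id, array.res_id, array.ins_code)
        ]
        self._atom_keys = keys
        self._residue_order: list[ResidueKey] = []
        self._residue_atoms: dict[ResidueKey, list[int]] = {}
        for idx, key in enumerate(keys):
            if key not in self._residue_atoms:
                self._residue_atoms[key] = []
                self._residue_order.append(key)
            self._residue_atoms[key].append(idx)

    # -- basic accessors -------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.array.chain_id:
            seen.setdefault(str(c), None)
        return list(seen)

    def residue_keys(self, chain_ids: Iterable[str] | None = None) -> list[ResidueKey]:
        if chain_ids is None:
            return list(self._residue_order)
        wanted = set(chain_ids)
        return [k for k in self._residue_order if k.chain_id in wanted]

    def __len__(self) -> int:
        return len(self._residue_order)

    @property
    def n_atoms(self) -> int:
        return self.array.array_length()

    def residue_atom_indices(self, key: ResidueKey) -> list[int]:
        try:
            return self._residue_atoms[key]
        except KeyError:
            raise StructureError(f"residue {key} not in structure") from None

    def residue_name(self, key: ResidueKey) -> str:
        return str(self.array.res_name[self.residue_atom_indices(key)[0]])

    def residue_names(self, keys: Iterable[ResidueKey] | None = None) -> dict[ResidueKey, str]:
        if keys is None:
            keys = self._residue_order
        return {k: self.residue_name(k) for k in keys}

    def atoms(self) -> list[Atom]:
        arr = self.array
        return [
            Atom(
                chain_id=str(arr.chain_id[i]),
                residue_number=int(arr.res_id[i]),
                insertion_code=str(arr.ins_code[i]),
                residue_name=str(arr.res_name[i]),
                atom_name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                coordinates=np.asarray(arr.coord[i], dtype=float),
                occupancy=float(arr.occupancy[i]),
                mass=atomic_mass(str(arr.element[i])),
            )
            for i in range(arr.array_length())
        ]

    def subset(self, chain_ids: Iterable[str]) -> "StructureModel":
        """New model restricted to the given chains."""
        wanted = set(chain_ids)
        present = set(self.chain_ids)
        missing = wanted - present
        if missing:
            raise StructureError(f"chains not present in structure: {sorted(missing)}")
        mask = np.array([c in wanted for c in self.array.chain_id])
        return StructureModel(self.array[mask])

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain in residue order ('X' for nonstandard)."""
        letters = []
        for key in self.residue_keys([chain_id]):
            letters.append(THREE_TO_ONE.get(self.residue_name(key), "X"))
        if not letters:
            raise StructureError(f"chain {chain_id!r} not in structure")
        return "".join(letters)

    def residue_centers(
        self,
        keys: Iterable[ResidueKey] | None = None,
        scheme: str = "mass",
    ) -> dict[ResidueKey, np.ndarray]:
        if keys is None:
            keys = self._residue_order
        return {
            k: residue_center(self.array[self.residue_atom_indices(k)], scheme=scheme)
            for k in keys
        }


@dataclass
class InterfaceRecord:
    """Interface residues of the two partners with per-residue buried area (Å²)."""

    partner_a: set[ResidueKey]
    partner_b: set[ResidueKey]
    delta_asa: dict[ResidueKey, float]
    chain_partition: tuple[tuple[str, ...], tuple[str, ...]]

    @property
    def residues(self) -> set[ResidueKey]:
        return self.partner_a | self.partner_b

    def buried_area(self, partner: str = "a") -> float:
        members = self.partner_a if partner == "a" else self.partner_b
        return float(sum(self.delta_asa[k] for k in members))


@dataclass
class SurfaceSet:
    """Residues on the protein surface with their relative accessibilities."""

    members: set[ResidueKey]
    relative_accessibility: dict[ResidueKey, float]
    threshold: float = 0.05


def atomic_mass(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise StructureError(f"no atomic mass tabulated for element {element!r}") from None


def read_structure(
    path,
    model_index: int = 1,
    include_het: bool = False,
) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Keeps heavy atoms only; for alternate locations the highest-occupancy
    conformer is retained; waters and (by default) non-polymer het-groups are
    excluded.  ``model_index`` selects one model (1-based) from multi-model files.
    """
    try:
        pdb = PDBFile.read(str(path))
        array = pdb.get_structure(
            model=model_index, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:  # biotite raises various parse errors
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    mask = array.element != "H"
    mask &= ~np.isin(array.res_name, list(_WATER_NAMES))
    if not include_het:
        mask &= ~array.hetero
    array = array[mask]
    if array.array_length() == 0:
        raise StructureError(f"model {model_index} of {path} contains no usable atoms")
    if not np.all(np.isfinite(array.coord)):
        raise StructureError(f"non-finite coordinates in {path}")
    return StructureModel(array)


def write_structure(model: StructureModel, path) -> None:
    """Write a model back to PDB (used by fixture generators and reports)."""
    pdb = PDBFile()
    pdb.set_structure(model.array)
    pdb.write(str(path))


def compute_sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    vdw_table: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    Shrake-Rupley numerical scheme with a deterministic Fibonacci point
    distribution on each atom sphere.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be at least 100")
    table = dict(VDW_RADII if vdw_table is None else vdw_table)
    elements = [str(e).upper() for e in structure.array.element]
    unknown = sorted({e for e in elements if e not in table})
    if unknown:
        raise StructureError(f"no vdW radius for element(s): {unknown}")
    radii = np.array([table[e] for e in elements])
    areas = struc.sasa(
        structure.array,
        probe_radius=probe_radius,
        point_number=n_points,
        vdw_radii=radii,
    )
    return np.asarray(areas, dtype=float)


def residue_sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    vdw_table: Mapping[str, float] | None = None,
) -> dict[ResidueKey, float]:
    """Residue-level SASA: sum of the residue's atomic areas."""
    atom_areas = compute_sasa(structure, probe_radius, n_points, vdw_table)
    return {
        key: float(atom_areas[structure.residue_atom_indices(key)].sum())
        for key in structure.residue_keys()
    }


def identify_interface(
    complex_model: StructureModel,
    group_a: Iterable[str],
    group_b: Iterable[str],
    burial_threshold: float = 0.1,
    probe_radius: float = 1.4,
    n_points: int = 960,
    vdw_table: Mapping[str, float] | None = None,
) -> InterfaceRecord:
    """Interface residues: those losing more than ``burial_threshold`` Å² of
    accessible area upon complexation (default 0.1 Å²).

    SASA of each chain group is computed in isolation and in the complex; the
    per-residue ΔASA is the summed atomic difference.
    """
    group_a = tuple(group_a)
    group_b = tuple(group_b)
    if not group_a or not group_b:
        raise ValueError("both chain groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("chain groups must be disjoint")

    kwargs = dict(probe_radius=probe_radius, n_points=n_points, vdw_table=vdw_table)
    joint = complex_model.subset(group_a + group_b)
    sasa_complex = residue_sasa(joint, **kwargs)

    partners: list[set[ResidueKey]] = []
    delta: dict[ResidueKey, float] = {}
    for group in (group_a, group_b):
        isolated = complex_model.subset(group)
        sasa_iso = residue_sasa(isolated, **kwargs)
        members: set[ResidueKey] = set()
        for key, area_iso in sasa_iso.items():
            d = area_iso - sasa_complex[key]
            if d > burial_threshold:
                members.add(key)
                delta[key] = float(d)
        partners.append(members)
    return InterfaceRecord(
        partner_a=partners[0],
        partner_b=partners[1],
        delta_asa=delta,
        chain_partition=(group_a, group_b),
    )


def surface_residues(
    chain_structure: StructureModel,
    rel_threshold: float = 0.05,
    reference_table: Mapping[str, float] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
    vdw_table: Mapping[str, float] | None = None,
) -> SurfaceSet:
    """Residues with relative accessibility at or above ``rel_threshold``.

    Relative accessibility is the residue SASA divided by the reference maximal
    accessibility of its residue type (extended-state values; configurable).
    """
    table = MAX_ASA_EXTENDED if reference_table is None else reference_table
    per_res = residue_sasa(chain_structure, probe_radius, n_points, vdw_table)
    rel: dict[ResidueKey, float] = {}
    for key, area in per_res.items():
        name = chain_structure.residue_name(key)
        if name not in table:
            raise StructureError(
                f"residue type {name!r} ({key}) absent from reference accessibility table"
            )
        rel[key] = area / table[name]
    members = {k for k, v in rel.items() if v >= rel_threshold}
    return SurfaceSet(members=members, relative_accessibility=rel, threshold=rel_threshold)


def residue_center(atoms: struc.AtomArray, scheme: str = "mass") -> np.ndarray:
    """Center of a residue's heavy atoms: mass-weighted (default) or geometric mean."""
    n = atoms.array_length()
    if n == 0:
        raise StructureError("cannot compute the center of an empty atom set")
    coords = np.asarray(atoms.coord, dtype=float)
    if scheme == "geometric":
        return coords.mean(axis=0)
    if scheme != "mass":
        raise ValueError(f"unknown center scheme {scheme!r}")
    masses = np.array([atomic_mass(str(e)) for e in atoms.element])
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def surface_report_frame(surface: SurfaceSet, model: StructureModel):
    """Surface report as a DataFrame: chain, resnum, icode, resname, rel_acc, member."""
    import pandas as pd

    rows = [
        {
            "chain": key.chain_id,
            "resnum": key.residue_number,
            "icode": key.insertion_code,
            "resname": model.residue_name(key),
            "rel_acc": rel,
            "member": key in surface.members,
        }
        for key, rel in sorted(surface.relative_accessibility.items())
    ]
    return pd.DataFrame(rows, columns=["chain", "resnum", "icode", "resname", "rel_acc", "member"])


def interface_report_frame(record: InterfaceRecord, model: StructureModel):
    """Interface record as a pandas DataFrame (chain, resnum, icode, resname, delta_asa, partner)."""
    import pandas as pd

    rows = []
    for partner, members in (("A", record.partner_a), ("B", record.partner_b)):
        for key in sorted(members):
            rows.append(
                {
                    "chain": key.chain_id,
                    "resnum": key.residue_number,
                    "icode": key.insertion_code,
                    "resname": model.residue_name(key),
                    "delta_asa": record.delta_asa[key],
                    "partner": partner,
                }
            )
    return pd.DataFrame(rows, columns=["chain", "resnum", "icode", "resname", "delta_asa", "partner"])
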