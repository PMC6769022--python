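"""Macromolecular coordinate model.

A deliberately small, explicit container for crystallographic protein
structures: ordered heavy-atom records with author residue numbering,
optional unit cell and space-group symmetry operators, and the residue-span
arithmetic used to measure loop and insertion lengths.

Parsing and writing of mmCIF/PDB goes through :mod:`gemmi`; everything
downstream of I/O works on plain numpy arrays and dataclasses so that the
numeric modules have no dependency on the reader.

Conventions
-----------
* Author residue numbering (1-based, with insertion codes) is the public
  convention everywhere.
* Hydrogens are dropped on read.  Alternate locations are resolved to the
  highest-occupancy conformer (ties broken by file order).
* Only the first model of a multi-model file is kept.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "RepeatAnnotation",
    "AtomSelection",
    "StructureError",
    "EmptySelectionError",
    "read_structure",
    "write_structure",
    "select_atoms",
    "assign_repeats",
    "apply_symmetry",
    "merge_structures",
    "span_residue_count",
    "read_repeat_table",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}


class StructureError(ValueError):
    """Raised for invalid structural input or selections."""


class EmptySelectionError(StructureError):
    """Raised when an atom selection matches nothing."""


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One heavy-atom coordinate record (author numbering)."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str  # "" when absent
    position: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise StructureError(f"non-finite position for atom {self.serial}")
        if not self.element:
            raise StructureError(f"empty element for atom {self.serial}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(
                f"occupancy {self.occupancy} outside [0,1] for atom {self.serial}"
            )

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain, author number, insertion code) — unique residue identity."""
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclasses.dataclass
class Structure:
    """Ordered atoms plus optional crystallographic frame.

    ``cell`` is (a, b, c, alpha, beta, gamma) in Å / degrees.
    ``symmetry_ops`` are (3x3 rotation, translation) pairs acting on
    fractional coordinates.
    """

    atoms: list[AtomRecord]
    cell: tuple[float, float, float, float, float, float] | None = None
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] = dataclasses.field(
        default_factory=list
    )
    spacegroup: str = ""
    name: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        """(n, 3) array of Cartesian coordinates in Å."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def chain_ids(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def polymer_residues(self, chain_id: str | None = None) -> list[tuple[str, int, str, str]]:
        """Ordered (chain, number, icode, resname) of polymer residues."""
        out: list[tuple[str, int, str, str]] = []
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if a.is_hetero or a.residue_name not in AA3_TO_1:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            key = a.residue_key
            if key not in seen:
                seen.add(key)
                out.append((a.chain_id, a.residue_number, a.insertion_code, a.residue_name))
        return out

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of the modeled polymer residues of a chain."""
        return "".join(
            AA3_TO_1[name] for _, _, _, name in self.polymer_residues(chain_id)
        )

    def residue_numbers(self, chain_id: str) -> list[int]:
        return [num for _, num, _, _ in self.polymer_residues(chain_id)]

    def orthogonalization_matrix(self) -> np.ndarray:
        """Fractional → Cartesian matrix from the six cell parameters."""
        if self.cell is None:
            raise StructureError("structure has no unit cell")
        a, b, c, al, be, ga = self.cell
        al, be, ga = (math.radians(x) for x in (al, be, ga))
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        v = math.sqrt(max(0.0, 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg))
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, c * v / sg],
            ]
        )


@dataclasses.dataclass(frozen=True)
class RepeatAnnotation:
    """Inclusive author-numbered span of one tandem repeat on one chain."""

    label: str
    chain_id: str
    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise StructureError(
                f"repeat {self.label}: start {self.start_residue} > end {self.end_residue}"
            )

    def contains(self, residue_number: int) -> bool:
        return self.start_residue <= residue_number <= self.end_residue


@dataclasses.dataclass
class AtomSelection:
    """Declarative atom filter.

    All criteria are conjunctive; ``None`` means "no constraint".
    ``residue_range`` is an inclusive (start, end) author-number span.
    """

    chains: set[str] | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: set[str] | None = None
    include_hetero: bool = True

    def matches(self, a: AtomRecord) -> bool:
        if self.chains is not None and a.chain_id not in self.chains:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not lo <= a.residue_number <= hi:
                return False
        if self.atom_names is not None and a.atom_name not in self.atom_names:
            return False
        if not self.include_hetero and a.is_hetero:
            return False
        return True


# ---------------------------------------------------------------------------
# I/O


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties to first."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        name = atom.name
        if name not in best:
            best[name] = atom
            order.append(name)
        elif atom.occ > best[name].occ:
            best[name] = atom
    return [best[n] for n in order]


def read_structure(path: str, fmt: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path:
        File to read.
    fmt:
        ``"pdb"`` or ``"mmcif"``; inferred from the extension when ``None``.

    Only heavy atoms of the first model are kept; waters and other
    non-polymer residues are flagged hetero; unit cell and symmetry
    operators are populated when the file provides them.
    """
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"pdb", "mmcif", "cif"}:
            raise StructureError(f"unknown format {fmt!r}: expected 'pdb' or 'mmcif'")
    try:
        if fmt in {"mmcif", "cif"}:
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
        else:
            st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models found")

    atoms: list[AtomRecord] = []
    serial = 0
    model = st[0]
    for chain in model:
        for residue in chain:
            is_water = residue.is_water()
            is_het = residue.het_flag == "H" or is_water
            for atom in _resolve_altlocs(residue):
                if atom.element.is_hydrogen:
                    continue
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        atom_name=atom.name,
                        element=atom.element.name.upper(),
                        residue_name=residue.name,
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=min(1.0, max(0.0, atom.occ)),
                        b_factor=atom.b_iso,
                        is_hetero=is_het,
                    )
                )
    if not atoms:
        raise StructureError(f"{path}: no atoms in first model")

    cell = None
    if st.cell and st.cell.a > 1.0:  # gemmi uses a dummy 1 Å cell for cell-less files
        cell = (st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    ops: list[tuple[np.ndarray, np.ndarray]] = []
    sg = st.find_spacegroup()
    if sg is not None:
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            ops.append((rot, tran))
    return Structure(
        atoms=atoms,
        cell=cell,
        symmetry_ops=ops,
        spacegroup=st.spacegroup_hm or "",
        name=st.name or path,
    )


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.name or "cadkit"
    if s.cell is not None:
        st.cell = gemmi.UnitCell(*s.cell)
    if s.spacegroup:
        st.spacegroup_hm = s.spacegroup
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for a in s.atoms:
        chain = chain_map.get(a.chain_id)
        if chain is None:
            chain = gemmi.Chain(a.chain_id)
            chain_map[a.chain_id] = chain
        if len(chain) == 0 or (
            chain[-1].seqid.num != a.residue_number
            or (chain[-1].seqid.icode or "").strip() != a.insertion_code
            or chain[-1].name != a.residue_name
        ):
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            res.het_flag = "H" if a.is_hetero else "A"
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element.capitalize())
        atom.pos = gemmi.Position(*a.position)
        atom.occ = a.occupancy
        atom.b_iso = a.b_factor
        chain[-1].add_atom(atom)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str, fmt: str | None = None) -> None:
    """Write PDB or mmCIF (inferred from extension when ``fmt`` is None)."""
    if fmt is None:
        fmt = "mmcif" if str(path).endswith((".cif", ".mmcif")) else "pdb"
    fmt = fmt.lower()
    st = _to_gemmi(s)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt in {"mmcif", "cif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        raise StructureError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Selection / annotation / symmetry


def select_atoms(s: Structure, spec: AtomSelection) -> Structure:
    """Return a new Structure with exactly the matching atoms, order kept.

    Raises :class:`EmptySelectionError` when nothing matches, and
    :class:`StructureError` when a requested chain does not exist at all.
    """
    if spec.chains is not None:
        present = set(s.chain_ids())
        missing = spec.chains - present
        if missing:
            raise StructureError(
                f"chain(s) {sorted(missing)} not present; have {sorted(present)}"
            )
    atoms = [a for a in s.atoms if spec.matches(a)]
    if not atoms:
        raise EmptySelectionError(f"selection {spec} matched no atoms")
    return Structure(atoms=atoms, cell=s.cell, symmetry_ops=list(s.symmetry_ops), spacegroup=s.spacegroup, name=s.name)


def assign_repeats(
    s: Structure, table: Sequence[RepeatAnnotation]
) -> dict[tuple[str, int, str], str]:
    """Map every polymer residue to a repeat label ("unassigned" if none).

    Validates that each annotation's chain exists and that spans on one
    chain do not overlap.
    """
    chains = set(s.chain_ids())
    by_chain: dict[str, list[RepeatAnnotation]] = {}
    for ann in table:
        if ann.chain_id not in chains:
            raise StructureError(f"repeat {ann.label}: chain {ann.chain_id!r} not in structure")
        by_chain.setdefault(ann.chain_id, []).append(ann)
    for chain_id, anns in by_chain.items():
        anns_sorted = sorted(anns, key=lambda a: a.start_residue)
        for prev, cur in zip(anns_sorted, anns_sorted[1:]):
            if cur.start_residue <= prev.end_residue:
                raise StructureError(
                    f"overlapping repeat spans on chain {chain_id}: "
                    f"{prev.label} ({prev.start_residue}-{prev.end_residue}) and "
                    f"{cur.label} ({cur.start_residue}-{cur.end_residue})"
                )
    mapping: dict[tuple[str, int, str], str] = {}
    for chain_id, num, icode, _ in s.polymer_residues():
        label = "unassigned"
        for ann in by_chain.get(chain_id, []):
            if ann.contains(num):
                label = ann.label
                break
        mapping[(chain_id, num, icode)] = label
    return mapping


def apply_symmetry(
    s: Structure,
    op_index: int,
    lattice_shift: tuple[int, int, int] = (0, 0, 0),
    chain_suffix: str | None = None,
) -> Structure:
    """Generate a symmetry mate.

    Positions are transformed fractional → rotated → translated (operator
    translation plus the integer lattice shift) → Cartesian.  Chain ids get
    a suffix so mates remain distinguishable from the original; by default
    ``-s<op_index>``.
    """
    if s.cell is None or not s.symmetry_ops:
        raise StructureError(
            "structure has no unit cell / symmetry operators; "
            "supply a pre-assembled multi-chain file instead"
        )
    if not 0 <= op_index < len(s.symmetry_ops):
        raise StructureError(
            f"operator index {op_index} out of range 0..{len(s.symmetry_ops) - 1}"
        )
    rot, tran = s.symmetry_ops[op_index]
    shift = np.asarray(lattice_shift, dtype=float)
    orth = s.orthogonalization_matrix()
    frac_of = np.linalg.inv(orth)
    suffix = chain_suffix if chain_suffix is not None else f"-s{op_index}"
    xyz = s.positions()
    frac = xyz @ frac_of.T
    frac = frac @ rot.T + tran + shift
    new_xyz = frac @ orth.T
    atoms = [
        dataclasses.replace(
            a,
            position=tuple(new_xyz[i]),
            chain_id=a.chain_id + suffix,
        )
        for i, a in enumerate(s.atoms)
    ]
    return Structure(atoms=atoms, cell=s.cell, symmetry_ops=list(s.symmetry_ops), spacegroup=s.spacegroup, name=s.name)


def merge_structures(parts: Iterable[Structure]) -> Structure:
    """Concatenate structures into one (chain ids must stay unique)."""
    parts = list(parts)
    if not parts:
        raise StructureError("nothing to merge")
    atoms: list[AtomRecord] = []
    seen_chains: set[str] = set()
    serial = 0
    for p in parts:
        dup = seen_chains & set(p.chain_ids())
        if dup:
            raise StructureError(f"duplicate chain ids on merge: {sorted(dup)}")
        seen_chains.update(p.chain_ids())
        for a in p.atoms:
            serial += 1
            atoms.append(dataclasses.replace(a, serial=serial))
    first = parts[0]
    return Structure(atoms=atoms, cell=first.cell, symmetry_ops=list(first.symmetry_ops), spacegroup=first.spacegroup, name=first.name)


def span_residue_count(
    s: Structure, chain_id: str, start_residue: int, end_residue: int
) -> int:
    """Distinct modeled polymer residues with author number in the span.

    Insertion-coded residues count individually; unmodeled residues do not
    count (the span is clipped to what is present).
    """
    if start_residue > end_residue:
        raise StructureError(f"span start {start_residue} > end {end_residue}")
    if chain_id not in s.chain_ids():
        raise StructureError(f"chain {chain_id!r} not in structure")
    return sum(
        1
        for _, num, _, _ in s.polymer_residues(chain_id)
        if start_residue <= num <= end_residue
    )


def read_repeat_table(path: str) -> list[RepeatAnnotation]:
    """Read a repeat-annotation CSV with columns label,chain,start,end."""
    import csv

    out: list[RepeatAnnotation] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                RepeatAnnotation(
                    label=row["label"].strip(),
                    chain_id=row["chain"].strip(),
                    start_residue=int(row["start"]),
                    end_residue=int(row["end"]),
                )
            )
    if not out:
        raise StructureError(f"{path}: empty repeat table")
    return out
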