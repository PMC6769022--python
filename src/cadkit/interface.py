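"""Buried-surface bookkeeping between two protomers.

The interface between protomers A and B is quantified by three SASA
evaluations — A alone, B alone, and the A∪B complex.  Each residue's buried
surface area (BSA) is its free-protomer SASA minus its in-complex SASA, and
the interface area is half the total SASA lost on complexation (the PISA
convention: for a symmetric dimer, one protomer's burial ≈ the interface
area).

Per-repeat decomposition attributes each residue's burial to the repeat of
the nearest heavy atom on the other protomer, which conserves the total by
construction: directional pair areas (e.g. EC1:EC4 = burial of EC1 residues
against partner EC4, averaged over the two protomers) plus an "other"
bucket sum to the interface area.

An interface larger than an empirical cutoff (default 856 Å²) is classified
as plausibly biological rather than crystal-packing scale.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sasa import SASAParams, compute_sasa
from .structures import (
    AtomSelection,
    RepeatAnnotation,
    Structure,
    StructureError,
    assign_repeats,
    select_atoms,
)

__all__ = [
    "InterfaceParams",
    "BuriedSurface",
    "SaltBridge",
    "InterfaceReport",
    "buried_surface",
    "interface_area",
    "interface_residues",
    "repeat_pair_areas",
    "composition",
    "detect_salt_bridges",
    "classify_interface",
    "default_residue_classes",
    "analyze_interface",
]

#: BSA below this (Å²) is treated as sampling noise, not contact.
BSA_NOISE_FLOOR = 1e-9

BIOLOGICAL = "plausible-biological"
CRYSTAL = "crystal-contact-scale"


def default_residue_classes() -> dict[str, str]:
    """Residue name → class ('hydrophobic' / 'charged' / 'hydrophilic')."""
    text = resources.files("cadkit.data").joinpath("residue_classes.json").read_text()
    classes = json.loads(text)["classes"]
    return {res: cls for cls, members in classes.items() for res in members}


@dataclasses.dataclass
class InterfaceParams:
    """Thresholds and class map for interface analysis."""

    residue_fraction_threshold: float = 0.20
    biological_cutoff: float = 856.0  # Å², empirical biological-vs-crystal cutoff
    salt_bridge_cutoff: float = 4.0  # Å
    class_map: dict[str, str] = dataclasses.field(default_factory=default_residue_classes)

    def __post_init__(self) -> None:
        if self.residue_fraction_threshold <= 0 or self.biological_cutoff <= 0 \
                or self.salt_bridge_cutoff <= 0:
            raise ValueError("interface thresholds must be positive")


@dataclasses.dataclass
class BuriedSurface:
    """Per-residue burial table for one two-protomer complex.

    ``table`` columns: protomer ('A'/'B'), chain, residue_number,
    insertion_code, residue_name, repeat_label, asa_free, asa_complex, bsa,
    partner_repeat_label.  bsa is clipped to 0 (sphere sampling can produce
    tiny negative differences).
    """

    table: pd.DataFrame
    chains_a: frozenset[str]
    chains_b: frozenset[str]

    def protomer(self, which: str) -> pd.DataFrame:
        return self.table[self.table["protomer"] == which]


@dataclasses.dataclass(frozen=True)
class SaltBridge:
    residue_a: tuple[str, int, str]  # (chain, number, resname)
    residue_b: tuple[str, int, str]
    atom_a: str
    atom_b: str
    distance: float


@dataclasses.dataclass
class InterfaceReport:
    total_area: float
    per_pair_area: dict[str, float]
    interface_residues: pd.DataFrame
    composition_overall: dict[str, float]
    composition_per_pair: dict[str, dict[str, float]]
    salt_bridges: list[SaltBridge]
    classification: str


# ---------------------------------------------------------------------------


def buried_surface(
    complex_structure: Structure,
    chains_a: set[str],
    chains_b: set[str],
    params: SASAParams | None = None,
    annotations: list[RepeatAnnotation] | None = None,
) -> BuriedSurface:
    """Per-residue buried surface area of protomer A against protomer B.

    Runs three SASA evaluations (A alone, B alone, complex) and, for every
    residue that buries area, assigns the repeat label of the nearest heavy
    atom of the other protomer (ties broken toward the smaller residue
    number).  Repeat labels default to "unassigned" when no annotation
    table is given.
    """
    if not chains_a or not chains_b:
        raise StructureError("both protomer chain sets must be non-empty")
    if chains_a & chains_b:
        raise StructureError(f"protomer chain sets overlap: {sorted(chains_a & chains_b)}")
    if params is None:
        params = SASAParams()

    part_a = select_atoms(complex_structure, AtomSelection(chains=set(chains_a)))
    part_b = select_atoms(complex_structure, AtomSelection(chains=set(chains_b)))
    both = select_atoms(complex_structure, AtomSelection(chains=set(chains_a | chains_b)))

    free_a = compute_sasa(part_a, params)
    free_b = compute_sasa(part_b, params)
    bound = compute_sasa(both, params)

    repeat_of = (
        assign_repeats(complex_structure, annotations) if annotations else {}
    )

    # heavy (non-hetero) atom coordinates per protomer for partner lookup
    def _protein_atoms(part: Structure):
        keep = [a for a in part.atoms if not a.is_hetero]
        coords = np.array([a.position for a in keep]).reshape(-1, 3)
        return keep, coords

    atoms_a, xyz_a = _protein_atoms(part_a)
    atoms_b, xyz_b = _protein_atoms(part_b)
    tree_a = cKDTree(xyz_a)
    tree_b = cKDTree(xyz_b)

    rows = []
    for which, free, part, other_tree, other_atoms in (
        ("A", free_a, part_a, tree_b, atoms_b),
        ("B", free_b, part_b, tree_a, atoms_a),
    ):
        res_atoms: dict[tuple[str, int, str], list] = {}
        for a in part.atoms:
            if not a.is_hetero:
                res_atoms.setdefault(a.residue_key, []).append(a)
        for key, asa_free in free.per_residue_area.items():
            asa_cplx = bound.per_residue_area.get(key, 0.0)
            bsa = max(0.0, asa_free - asa_cplx)
            partner = ""
            if bsa > BSA_NOISE_FLOOR:
                coords = np.array([a.position for a in res_atoms[key]])
                dists, idx = other_tree.query(coords)
                # nearest partner atom; tie-break toward smaller residue number
                order = np.lexsort(
                    (np.array([other_atoms[i].residue_number for i in idx]), dists)
                )
                partner_atom = other_atoms[idx[order[0]]]
                partner = repeat_of.get(partner_atom.residue_key, "unassigned")
            chain, num, icode = key
            rows.append(
                {
                    "protomer": which,
                    "chain": chain,
                    "residue_number": num,
                    "insertion_code": icode,
                    "residue_name": free.residue_names[key],
                    "repeat_label": repeat_of.get(key, "unassigned"),
                    "asa_free": asa_free,
                    "asa_complex": asa_cplx,
                    "bsa": bsa,
                    "partner_repeat_label": partner,
                }
            )
    table = pd.DataFrame(rows)
    return BuriedSurface(table=table, chains_a=frozenset(chains_a), chains_b=frozenset(chains_b))


def interface_area(b: BuriedSurface) -> float:
    """Interface area = half the total SASA both protomers lose (Å²)."""
    return float(b.table["bsa"].sum()) / 2.0


def interface_residues(b: BuriedSurface, threshold: float = 0.20) -> pd.DataFrame:
    """Residues burying at least ``threshold`` of their free-protomer SASA.

    Residues with zero accessible area never qualify.  The returned frame
    carries the burial fraction in column ``bsa_fraction``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    t = b.table.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(t["asa_free"] > 0, t["bsa"] / t["asa_free"], 0.0)
    t["bsa_fraction"] = frac
    out = t[(t["asa_free"] > 0) & (t["bsa_fraction"] >= threshold)]
    return out.reset_index(drop=True)


def repeat_pair_areas(b: BuriedSurface) -> dict[str, float]:
    """Directional repeat-pair decomposition of the interface area.

    Key "Ri:Rj" holds the burial of Ri residues whose nearest partner atom
    lies in Rj, summed over both protomers and halved — so for a symmetric
    dimer "EC1:EC4" and "EC4:EC1" are equal, and all keys (including
    "other" for unassigned burial) sum to :func:`interface_area`.
    """
    contact = b.table[b.table["bsa"] > BSA_NOISE_FLOOR]
    out: dict[str, float] = {}
    for (rep, partner), grp in contact.groupby(["repeat_label", "partner_repeat_label"]):
        if rep == "unassigned" or partner == "unassigned":
            key = "other"
        else:
            key = f"{rep}:{partner}"
        out[key] = out.get(key, 0.0) + float(grp["bsa"].sum()) / 2.0
    return out


def composition(
    b: BuriedSurface,
    class_map: dict[str, str] | None = None,
    pair: tuple[str, str] | None = None,
) -> dict[str, float]:
    """Fraction of buried area contributed by each residue class.

    With ``pair=(Ri, Rj)`` the tally is restricted to burial attributed to
    that repeat pair (both directions).  Fractions sum to 1.
    """
    if class_map is None:
        class_map = default_residue_classes()
    t = b.table[b.table["bsa"] > BSA_NOISE_FLOOR]
    if pair is not None:
        ri, rj = pair
        keep = ((t["repeat_label"] == ri) & (t["partner_repeat_label"] == rj)) | (
            (t["repeat_label"] == rj) & (t["partner_repeat_label"] == ri)
        )
        t = t[keep]
    unmapped = sorted(set(t["residue_name"]) - set(class_map))
    if unmapped:
        raise StructureError(f"residue name(s) not in class map: {unmapped}")
    total = float(t["bsa"].sum())
    out = {cls: 0.0 for cls in ("hydrophobic", "charged", "hydrophilic")}
    if total == 0.0:
        return out
    for name, grp in t.groupby("residue_name"):
        out[class_map[name]] += float(grp["bsa"].sum()) / total
    return out


# ---------------------------------------------------------------------------
# Salt bridges

_DONOR_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
}
_DONOR_ATOMS_HIS = {"HIS": {"ND1", "NE2"}}
_ACCEPTOR_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


def detect_salt_bridges(
    complex_structure: Structure,
    chains_a: set[str],
    chains_b: set[str],
    cutoff: float = 4.0,
    include_histidine: bool = False,
) -> list[SaltBridge]:
    """Inter-protomer salt bridges.

    A bridge is a basic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2;
    optionally His ND1/NE2) within ``cutoff`` Å of an acidic side-chain
    oxygen (Asp OD1/OD2, Glu OE1/OE2) on the other protomer.  One record
    per residue pair, at the minimal atom distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    donors = dict(_DONOR_ATOMS)
    if include_histidine:
        donors.update(_DONOR_ATOMS_HIS)

    def _pick(chains: set[str], spec: dict[str, set[str]]):
        out = []
        for a in complex_structure.atoms:
            if a.chain_id in chains and a.residue_name in spec \
                    and a.atom_name in spec[a.residue_name]:
                out.append(a)
        return out

    bridges: dict[tuple, SaltBridge] = {}
    for don_chains, acc_chains in ((chains_a, chains_b), (chains_b, chains_a)):
        don = _pick(don_chains, donors)
        acc = _pick(acc_chains, _ACCEPTOR_ATOMS)
        if not don or not acc:
            continue
        dxyz = np.array([a.position for a in don])
        axyz = np.array([a.position for a in acc])
        dist = np.linalg.norm(dxyz[:, None, :] - axyz[None, :, :], axis=2)
        for i, j in zip(*np.nonzero(dist <= cutoff)):
            d_at, a_at = don[i], acc[j]
            ra = (d_at.chain_id, d_at.residue_number, d_at.residue_name)
            rb = (a_at.chain_id, a_at.residue_number, a_at.residue_name)
            key = (ra, rb)
            d = float(dist[i, j])
            if key not in bridges or d < bridges[key].distance:
                bridges[key] = SaltBridge(ra, rb, d_at.atom_name, a_at.atom_name, d)
    return sorted(bridges.values(), key=lambda b: b.distance)


def classify_interface(area: float, cutoff: float = 856.0) -> str:
    """Biological vs crystal-contact call by strict area threshold."""
    if area < 0:
        raise ValueError("area must be >= 0")
    return BIOLOGICAL if area > cutoff else CRYSTAL


# ---------------------------------------------------------------------------


def analyze_interface(
    complex_structure: Structure,
    chains_a: set[str],
    chains_b: set[str],
    sasa_params: SASAParams | None = None,
    iface_params: InterfaceParams | None = None,
    annotations: list[RepeatAnnotation] | None = None,
) -> InterfaceReport:
    """Full interface characterization of one two-protomer complex."""
    if iface_params is None:
        iface_params = InterfaceParams()
    b = buried_surface(complex_structure, chains_a, chains_b, sasa_params, annotations)
    total = interface_area(b)
    pairs = repeat_pair_areas(b)
    residues = interface_residues(b, iface_params.residue_fraction_threshold)
    comp = composition(b, iface_params.class_map)
    comp_pairs: dict[str, dict[str, float]] = {}
    for key in pairs:
        if key == "other":
            continue
        ri, rj = key.split(":")
        comp_pairs[key] = composition(b, iface_params.class_map, pair=(ri, rj))
    bridges = detect_salt_bridges(
        complex_structure, chains_a, chains_b, iface_params.salt_bridge_cutoff
    )
    return InterfaceReport(
        total_area=total,
        per_pair_area=pairs,
        interface_residues=residues,
        composition_overall=comp,
        composition_per_pair=comp_pairs,
        salt_bridges=bridges,
        classification=classify_interface(total, iface_params.biological_cutoff),
    )
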