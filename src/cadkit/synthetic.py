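"""Synthetic fixtures with analytically known ground truth.

Every generator writes its payload in the same standard formats the real
pipeline reads (PDB, FASTA, CSV, PNG) plus a JSON manifest holding the
construction ground truth, so each analysis stage can be tested end to end
without downloading deposited structures:

* sphere systems with closed-form solvent-accessible areas (isolated
  sphere and two-intersecting-spheres spherical-cap formulas);
* idealized tandem-repeat "rods" whose consecutive repeats are rigid
  copies of one prolate Cα cloud placed with a prescribed azimuthal twist
  and polar tilt — the twist list is the exact ground truth for the
  azimuthal-angle ladder;
* antiparallel toy dimers in which only declared residues carry a
  partner-facing pseudo side-chain atom, so the contacting residue set and
  repeat pairs are known by construction;
* alignments with prescribed invariant columns;
* logistic melt curves with known midpoint, and disc images with known
  rasterized particle areas.

All randomness flows through one seeded generator per bundle; the same
seed and parameters reproduce byte-identical payloads.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os

import numpy as np

from .structures import AtomRecord, RepeatAnnotation, Structure, write_structure

__all__ = [
    "FixtureBundle",
    "isolated_sphere_area",
    "two_sphere_areas",
    "make_sphere_system",
    "make_repeat_rod",
    "make_toy_dimer",
    "make_alignment",
    "make_melt_curve",
    "make_bead_image",
]


@dataclasses.dataclass
class FixtureBundle:
    """Payload file paths, construction ground truth, and the seed used."""

    out_dir: str
    files: dict[str, str]
    truth: dict
    seed: int | None = None

    def write_manifest(self) -> str:
        path = os.path.join(self.out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(
                {"files": self.files, "truth": self.truth, "seed": self.seed},
                fh,
                indent=2,
                sort_keys=True,
                default=_jsonify,
            )
        return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")


# ---------------------------------------------------------------------------
# Analytic SASA ground truth (the independent oracle for sphere sampling)


def isolated_sphere_area(r_vdw: float, probe: float = 1.4) -> float:
    """4π(r+probe)² — SASA of one isolated atom."""
    return 4.0 * math.pi * (r_vdw + probe) ** 2


def two_sphere_areas(
    r1: float, r2: float, distance: float, probe: float = 1.4
) -> tuple[float, float]:
    """Closed-form accessible areas of two intersecting inflated spheres.

    Each sphere of inflated radius R_i = r_i + probe loses the spherical
    cap cut off by the other sphere: cap height on sphere 1 is
    h1 = R1 − (d² + R1² − R2²)/(2d), and the lost area is 2πR1·h1.
    """
    if distance <= 0:
        raise ValueError("sphere centers must be distinct")
    R1, R2 = r1 + probe, r2 + probe
    if distance >= R1 + R2:
        return 4 * math.pi * R1**2, 4 * math.pi * R2**2
    if distance <= abs(R1 - R2):  # one sphere engulfed
        if R1 < R2:
            return 0.0, 4 * math.pi * R2**2
        return 4 * math.pi * R1**2, 0.0
    x1 = (distance**2 + R1**2 - R2**2) / (2 * distance)
    x2 = distance - x1
    a1 = 4 * math.pi * R1**2 - 2 * math.pi * R1 * (R1 - x1)
    a2 = 4 * math.pi * R2**2 - 2 * math.pi * R2 * (R2 - x2)
    return a1, a2


def make_sphere_system(
    out_dir: str,
    elements: list[str],
    centers: list[tuple[float, float, float]],
    radii: dict[str, float] | None = None,
    probe: float = 1.4,
) -> FixtureBundle:
    """Write an atom cluster PDB with analytic per-sphere SASA truth.

    Truth is exact for one atom, for two atoms (cap formula), and for any
    number of mutually non-overlapping atoms; a system with three or more
    atoms that overlap pairwise is refused (no closed form implemented).
    """
    if len(elements) != len(centers):
        raise ValueError("elements and centers differ in length")
    if radii is None:
        from .sasa import default_radii

        radii = default_radii()
    pts = np.asarray(centers, dtype=float)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.allclose(pts[i], pts[j]):
                raise ValueError(f"atoms {i} and {j} share a center")
    rr = [radii[e.upper()] + probe for e in elements]
    overlaps = [
        (i, j)
        for i in range(len(pts))
        for j in range(i + 1, len(pts))
        if np.linalg.norm(pts[i] - pts[j]) < rr[i] + rr[j]
    ]
    if overlaps and len(pts) > 2:
        raise ValueError("analytic truth only covers <=2 overlapping spheres")

    if len(pts) == 2 and overlaps:
        d = float(np.linalg.norm(pts[0] - pts[1]))
        a1, a2 = two_sphere_areas(radii[elements[0].upper()], radii[elements[1].upper()], d, probe)
        per_atom = [a1, a2]
    else:
        per_atom = [isolated_sphere_area(radii[e.upper()], probe) for e in elements]

    atoms = [
        AtomRecord(
            serial=i + 1,
            atom_name=elements[i].upper(),
            element=elements[i].upper(),
            residue_name="SPH",
            chain_id="A",
            residue_number=i + 1,
            insertion_code="",
            position=tuple(pts[i]),
            is_hetero=False,
        )
        for i in range(len(pts))
    ]
    # SPH is not a polymer residue name; SASA works on atoms regardless.
    os.makedirs(out_dir, exist_ok=True)
    pdb_path = os.path.join(out_dir, "spheres.pdb")
    write_structure(Structure(atoms=atoms), pdb_path, "pdb")
    bundle = FixtureBundle(
        out_dir=out_dir,
        files={"structure": pdb_path},
        truth={
            "probe": probe,
            "per_atom_area": per_atom,
            "total_area": float(sum(per_atom)),
        },
    )
    bundle.write_manifest()
    return bundle


# ---------------------------------------------------------------------------
# Tandem-repeat rods


def _rot_z(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def _rot_y(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])


def _base_repeat_cloud(n_points: int, rng: np.random.Generator,
                       length: float = 30.0, width: float = 2.5) -> np.ndarray:
    """A prolate Cα cloud whose principal axis is exactly +z, N→C ascending."""
    z = np.linspace(-length / 2, length / 2, n_points) + rng.normal(0, 0.4, n_points)
    xy = rng.normal(0.0, width, size=(n_points, 2))
    cloud = np.column_stack([xy, z])
    cloud -= cloud.mean(axis=0)
    # rotate so the covariance's top eigenvector is exactly +z
    cov = cloud.T @ cloud / len(cloud)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, 2]
    if axis[2] < 0:
        axis = -axis
    v = np.cross(axis, [0.0, 0.0, 1.0])
    s = np.linalg.norm(v)
    c = float(axis[2])
    if s > 1e-12:
        k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]) / s
        rot = np.eye(3) + s * k + (1 - c) * (k @ k)
        cloud = cloud @ rot.T
    return cloud


def _ca_chain(coords: np.ndarray, chain_id: str, first_residue: int = 1,
              residue_name: str = "ALA") -> list[AtomRecord]:
    return [
        AtomRecord(
            serial=i + 1,
            atom_name="CA",
            element="C",
            residue_name=residue_name,
            chain_id=chain_id,
            residue_number=first_residue + i,
            insertion_code="",
            position=tuple(coords[i]),
        )
        for i in range(len(coords))
    ]


def make_repeat_rod(
    out_dir: str,
    n_repeats: int,
    residues_per_repeat: int = 40,
    twist_list: list[float] | None = None,
    tilt: float = 15.0,
    rise: float = 35.0,
    seed: int = 0,
) -> FixtureBundle:
    """Stack rigid copies of one prolate repeat with prescribed twists.

    Repeat k+1 is placed from repeat k by a rise along the local axis and a
    rotation tilting the axis by ``tilt`` degrees toward azimuth
    ``twist_list[k]``, so the azimuthal-angle ladder (measured against the
    bundled zero-twist two-repeat reference rod) recovers ``twist_list``
    exactly.  ``tilt = 0`` makes every φ degenerate by construction and is
    flagged in the truth record.
    """
    if twist_list is None:
        twist_list = []
    if len(twist_list) != max(0, n_repeats - 1):
        raise ValueError("twist_list must have n_repeats - 1 entries")
    if n_repeats < 1:
        raise ValueError("need at least one repeat")
    rng = np.random.default_rng(seed)
    base = _base_repeat_cloud(residues_per_repeat, rng)

    def build(twists: list[float]) -> np.ndarray:
        rot = np.eye(3)
        tran = np.zeros(3)
        clouds = [base.copy()]
        for t in twists:
            a = _rot_z(t) @ _rot_y(tilt) @ _rot_z(-t)
            tran = rot @ np.array([0.0, 0.0, rise]) + tran
            rot = rot @ a
            clouds.append(base @ rot.T + tran)
        return np.vstack(clouds)

    coords = build(list(twist_list))
    ref_coords = build([0.0]) if n_repeats >= 1 else None

    os.makedirs(out_dir, exist_ok=True)
    rod_path = os.path.join(out_dir, "rod.pdb")
    write_structure(Structure(atoms=_ca_chain(coords, "A")), rod_path, "pdb")
    ref_path = os.path.join(out_dir, "reference_rod.pdb")
    write_structure(Structure(atoms=_ca_chain(ref_coords, "A")), ref_path, "pdb")

    annotations = [
        RepeatAnnotation(
            label=f"R{k + 1}",
            chain_id="A",
            start_residue=k * residues_per_repeat + 1,
            end_residue=(k + 1) * residues_per_repeat,
        )
        for k in range(n_repeats)
    ]
    ann_path = os.path.join(out_dir, "repeats.csv")
    with open(ann_path, "w") as fh:
        fh.write("label,chain,start,end\n")
        for a in annotations:
            fh.write(f"{a.label},{a.chain_id},{a.start_residue},{a.end_residue}\n")
    ref_ann_path = os.path.join(out_dir, "reference_repeats.csv")
    with open(ref_ann_path, "w") as fh:
        fh.write("label,chain,start,end\n")
        fh.write(f"Z,A,1,{residues_per_repeat}\n")
        fh.write(f"X,A,{residues_per_repeat + 1},{2 * residues_per_repeat}\n")

    bundle = FixtureBundle(
        out_dir=out_dir,
        files={
            "rod": rod_path,
            "reference_rod": ref_path,
            "repeats": ann_path,
            "reference_repeats": ref_ann_path,
        },
        truth={
            "twists": list(twist_list),
            "tilt": tilt,
            "degenerate": tilt == 0.0 and n_repeats > 1,
            "n_repeats": n_repeats,
        },
        seed=seed,
    )
    bundle.write_manifest()
    return bundle


# ---------------------------------------------------------------------------
# Antiparallel toy dimers


def make_toy_dimer(
    out_dir: str,
    n_repeats: int = 4,
    residues_per_repeat: int = 10,
    contact_residues: list[int] | None = None,
    gap: float = 3.0,
    residue_name: str = "LEU",
    spacing: float = 3.8,
) -> FixtureBundle:
    """Two antiparallel Cα rods contacting only at declared residues.

    Chain A runs N→C along +z; chain B is the same rod reversed
    (antiparallel) and laterally offset.  Declared contact residues (chain
    A numbering) carry an extra pseudo side-chain atom pointing at the
    partner, placed so the opposing atom pair sits ``gap`` Å apart while
    every other inter-chain distance stays out of probe reach.  Truth
    records the contacting residue pairs and the repeat pairs they imply
    under the antiparallel register (residue i ↔ residue N+1−i).
    """
    if gap < 1.0:
        raise ValueError(f"gap {gap} Å < 1 Å: chains would clash")
    n = n_repeats * residues_per_repeat
    if contact_residues is None:
        contact_residues = list(range(1, n + 1))
    if any(not 1 <= r <= n for r in contact_residues):
        raise ValueError("contact residues outside chain")
    side = 4.5  # pseudo side-chain reach, Å
    offset = gap + 2 * side

    atoms: list[AtomRecord] = []
    serial = 0

    def add(chain, num, name, pos):
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial,
                atom_name=name,
                element="C",
                residue_name=residue_name,
                chain_id=chain,
                residue_number=num,
                insertion_code="",
                position=pos,
            )
        )

    contacts_b = {n + 1 - i for i in contact_residues}
    for i in range(1, n + 1):
        z = (i - 1) * spacing
        add("A", i, "CA", (0.0, 0.0, z))
        if i in contact_residues:
            add("A", i, "CB", (side, 0.0, z))
    for j in range(1, n + 1):
        z = (n - j) * spacing
        add("B", j, "CA", (offset, 0.0, z))
        if j in contacts_b:
            add("B", j, "CB", (offset - side, 0.0, z))

    repeat_of = lambda r: (r - 1) // residues_per_repeat + 1  # noqa: E731
    contact_pairs = sorted((i, n + 1 - i) for i in contact_residues)
    # burial is directional (both sides of each contact report a pair key)
    repeat_pairs = sorted(
        {(repeat_of(i), repeat_of(n + 1 - i)) for i in contact_residues}
        | {(repeat_of(n + 1 - i), repeat_of(i)) for i in contact_residues}
    )

    os.makedirs(out_dir, exist_ok=True)
    pdb_path = os.path.join(out_dir, "dimer.pdb")
    write_structure(Structure(atoms=atoms), pdb_path, "pdb")
    ann_path = os.path.join(out_dir, "repeats.csv")
    with open(ann_path, "w") as fh:
        fh.write("label,chain,start,end\n")
        for chain in ("A", "B"):
            for k in range(n_repeats):
                fh.write(
                    f"R{k + 1},{chain},{k * residues_per_repeat + 1},{(k + 1) * residues_per_repeat}\n"
                )
    bundle = FixtureBundle(
        out_dir=out_dir,
        files={"dimer": pdb_path, "repeats": ann_path},
        truth={
            "contact_pairs": [list(p) for p in contact_pairs],
            "repeat_pairs": [f"R{i}:R{j}" for i, j in repeat_pairs],
            "gap": gap,
            "n_residues_per_chain": n,
        },
    )
    bundle.write_manifest()
    return bundle


# ---------------------------------------------------------------------------
# Alignments, melt curves, bead images


def make_alignment(
    out_dir: str,
    n_seqs: int,
    length: int,
    conserved_columns: list[int] | None = None,
    seed: int = 0,
) -> FixtureBundle:
    """FASTA alignment with listed columns invariant, others uniform random.

    ``conserved_columns`` are 1-based.  The invariant residue of each
    conserved column is itself drawn (seeded) so fixtures vary.
    """
    if n_seqs < 2:
        raise ValueError("alignment needs at least 2 sequences")
    conserved = set(conserved_columns or [])
    if any(not 1 <= c <= length for c in conserved):
        raise ValueError("conserved column outside alignment")
    from .seqanalysis import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    fixed = {c: aa[rng.integers(len(aa))] for c in sorted(conserved)}
    rows = []
    for _ in range(n_seqs):
        row = aa[rng.integers(len(aa), size=length)]
        for c, res in fixed.items():
            row[c - 1] = res
        rows.append("".join(row))

    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "alignment.fasta")
    with open(path, "w") as fh:
        for i, row in enumerate(rows):
            fh.write(f">seq{i + 1}\n{row}\n")
    bundle = FixtureBundle(
        out_dir=out_dir,
        files={"alignment": path},
        truth={
            "conserved_columns": sorted(conserved),
            "n_seqs": n_seqs,
            "length": length,
        },
        seed=seed,
    )
    bundle.write_manifest()
    return bundle


def make_melt_curve(
    out_dir: str,
    tm: float = 55.0,
    slope: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_start: float = 10.0,
    t_stop: float = 95.0,
    t_step: float = 0.2,
) -> FixtureBundle:
    """CSV logistic melt curve with midpoint ``tm`` plus Gaussian noise."""
    if not t_start < tm < t_stop:
        raise ValueError("tm must lie inside the temperature range")
    rng = np.random.default_rng(seed)
    temps = np.arange(t_start, t_stop + t_step / 2, t_step)
    fluor = 1.0 / (1.0 + np.exp(-(temps - tm) / slope))
    if noise_sd > 0:
        fluor = fluor + rng.normal(0.0, noise_sd, len(temps))
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "melt.csv")
    with open(path, "w") as fh:
        fh.write("temperature,fluorescence\n")
        for t, f in zip(temps, fluor):
            fh.write(f"{t:.4f},{f:.8f}\n")
    bundle = FixtureBundle(
        out_dir=out_dir,
        files={"melt": path},
        truth={"tm": tm, "slope": slope, "noise_sd": noise_sd},
        seed=seed,
    )
    bundle.write_manifest()
    return bundle


def make_bead_image(
    out_dir: str,
    shape: tuple[int, int] = (256, 256),
    discs: list[tuple[int, int, int]] | None = None,  # (row, col, radius)
    noise_sd: float = 0.0,
    seed: int = 0,
    background: int = 40,
    foreground: int = 210,
) -> FixtureBundle:
    """Grayscale PNG with bright discs on a dark background.

    Truth records both the rasterized pixel count of each disc (the exact
    expectation for noise-free recovery) and the continuous πr² area.
    Discs must fit inside the image and must not overlap.
    """
    if discs is None:
        discs = [(shape[0] // 2, shape[1] // 2, 10)]
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    img = np.full(shape, float(background))
    pixel_areas = []
    for i, (r0, c0, rad) in enumerate(discs):
        if not (rad <= r0 < shape[0] - rad and rad <= c0 < shape[1] - rad):
            raise ValueError(f"disc {i} does not fit inside the image")
        for j, (r1, c1, rad1) in enumerate(discs[:i]):
            if math.hypot(r0 - r1, c0 - c1) <= rad + rad1:
                raise ValueError(f"discs {j} and {i} overlap")
        mask = (rows - r0) ** 2 + (cols - c0) ** 2 <= rad**2
        img[mask] = float(foreground)
        pixel_areas.append(int(mask.sum()))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape)
    img8 = np.clip(np.round(img), 0, 255).astype(np.uint8)

    from PIL import Image

    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "beads.png")
    Image.fromarray(img8, mode="L").save(path)
    bundle = FixtureBundle(
        out_dir=out_dir,
        files={"image": path},
        truth={
            "pixel_areas": pixel_areas,
            "continuous_areas": [math.pi * r**2 for _, _, r in discs],
            "n_discs": len(discs),
            "background": background,
            "foreground": foreground,
        },
        seed=seed,
    )
    bundle.write_manifest()
    return bundle
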