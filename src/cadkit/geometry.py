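"""Rigid-body superposition and tandem-repeat orientation geometry.

Two related tools live here:

* Kabsch least-squares superposition of Cα sets (optimal proper rotation
  via SVD) and the RMSD it implies — used to compare crystal forms.

* The azimuthal-angle ladder for tandem extracellular-cadherin (EC)
  repeats: a reference repeat's long axis defines +z, a second reference
  repeat's projected axis defines φ = 0, and for each consecutive repeat
  pair in the analyzed chain the N-terminal repeat is superposed onto the
  reference so that the azimuth φ of the C-terminal repeat's long axis
  (projected on the xy-plane, counterclockwise about +z viewed from +z,
  reported in (−180°, 180°]) characterizes the inter-repeat twist.

A repeat's long axis is the largest-eigenvalue eigenvector of the
unweighted Cα covariance, with its sign fixed to point from the
N-terminal-half centroid toward the C-terminal-half centroid.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .structures import RepeatAnnotation, Structure, StructureError

__all__ = [
    "Superposition",
    "AzimuthalProfile",
    "AzimuthEntry",
    "DegenerateGeometryError",
    "kabsch",
    "superpose_ca",
    "principal_axis",
    "azimuthal_profile",
]

#: Projected axis length (for a unit axis) below which φ is undefined.
PROJECTION_TOLERANCE = 0.02


class DegenerateGeometryError(ValueError):
    """Raised when a superposition or axis problem is ill-posed."""


@dataclasses.dataclass
class Superposition:
    """Optimal rigid map b ≈ rotation·a + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclasses.dataclass
class AzimuthEntry:
    repeat_label: str
    phi_degrees: float | None  # None when the projection is degenerate
    tilt_degrees: float
    defined: bool


@dataclasses.dataclass
class AzimuthalProfile:
    reference_description: str
    entries: list[AzimuthEntry]

    def phi(self, label: str) -> float | None:
        for e in self.entries:
            if e.repeat_label == label:
                return e.phi_degrees
        raise KeyError(label)


# ---------------------------------------------------------------------------


def kabsch(a: np.ndarray, b: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of point set ``a`` onto ``b``.

    Returns the proper rotation (det = +1) and translation minimizing
    ||R·a + t − b||, with the RMSD of the fit.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {a.shape} vs {b.shape}")
    n = len(a)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinearity check: rank of the centered set
    if np.linalg.matrix_rank(a0, tol=1e-8 * max(1.0, np.abs(a0).max())) < 2:
        raise DegenerateGeometryError("point set is collinear; rotation ill-determined")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cb - rot @ ca
    diff = a0 @ rot.T - b0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=n)


def _ca_map(s: Structure, chain: str) -> dict[tuple[int, str], np.ndarray]:
    out: dict[tuple[int, str], np.ndarray] = {}
    for a in s.atoms:
        if a.chain_id == chain and a.atom_name == "CA" and not a.is_hetero:
            out.setdefault((a.residue_number, a.insertion_code), np.array(a.position))
    if not out:
        raise StructureError(f"chain {chain!r} has no Cα atoms")
    return out


def superpose_ca(
    a: Structure,
    chain_a: str,
    b: Structure,
    chain_b: str,
    pairs: list[tuple[int, int]] | None = None,
) -> Superposition:
    """Kabsch superposition of chain_a's Cα trace onto chain_b's.

    By default the correspondence is the intersection of modeled residue
    numbers that carry a Cα in both chains (robust to different missing
    loops); an explicit residue-number pair list overrides it.
    """
    map_a = _ca_map(a, chain_a)
    map_b = _ca_map(b, chain_b)
    if pairs is None:
        shared = sorted(set(map_a) & set(map_b))
        if len(shared) < 3:
            raise DegenerateGeometryError(
                f"only {len(shared)} shared Cα residues between chains"
            )
        pa = np.array([map_a[k] for k in shared])
        pb = np.array([map_b[k] for k in shared])
    else:
        try:
            pa = np.array([map_a[(na, "")] for na, _ in pairs])
            pb = np.array([map_b[(nb, "")] for _, nb in pairs])
        except KeyError as exc:
            raise StructureError(f"pair residue {exc} lacks a Cα") from exc
    return kabsch(pa, pb)


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """Long axis of a point cloud (unit vector), N→C oriented.

    The axis is the largest-eigenvalue eigenvector of the centered
    covariance; its sign points from the centroid of the first half of the
    points toward the centroid of the second half (chain order = N→C).
    Warns when the top two eigenvalues are within 1% (axis ill-defined).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 3:
        raise DegenerateGeometryError("need >= 3 points in 3-D")
    centered = coords - coords.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise DegenerateGeometryError("all points coincident")
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[2] > 0 and (evals[2] - evals[1]) / evals[2] < 0.01:
        warnings.warn(
            "principal axis nearly degenerate (top eigenvalues within 1%)",
            stacklevel=2,
        )
    axis = evecs[:, 2]
    half = len(coords) // 2
    direction = coords[half:].mean(axis=0) - coords[:half].mean(axis=0)
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _minimal_rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v to +z along the great circle."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])  # 180° about x
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def _wrap_angle(deg: float) -> float:
    """Wrap to (−180, 180]."""
    wrapped = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def _repeat_ca(s: Structure, ann: RepeatAnnotation) -> np.ndarray:
    cas = [
        np.array(a.position)
        for a in s.atoms
        if a.chain_id == ann.chain_id
        and a.atom_name == "CA"
        and not a.is_hetero
        and ann.contains(a.residue_number)
    ]
    if len(cas) < 3:
        raise StructureError(f"repeat {ann.label}: fewer than 3 Cα atoms")
    return np.array(cas)


def azimuthal_profile(
    s: Structure,
    annotations: list[RepeatAnnotation],
    reference: Structure | None = None,
    reference_annotations: list[RepeatAnnotation] | None = None,
) -> AzimuthalProfile:
    """Azimuthal angle φ of each repeat about its N-terminal neighbour.

    The first two reference repeats build the frame: the first one's long
    axis becomes +z, the second one's projected axis becomes φ = 0 (+x).
    For each consecutive pair of annotated repeats in ``s``, the
    N-terminal repeat's Cα trace is superposed (order correspondence,
    truncated to the shorter repeat) onto the frame-aligned reference
    repeat, and the C-terminal repeat's long axis is projected on the
    xy-plane to read off φ and the polar tilt.

    With no external reference, the analyzed chain's own first two repeats
    serve as the frame (so the first pair reads φ = 0 by construction).
    """
    if len(annotations) < 2:
        raise StructureError("need at least two annotated repeats")
    if reference is None:
        reference = s
        reference_annotations = annotations[:2]
    if reference_annotations is None or len(reference_annotations) < 2:
        raise StructureError("reference needs two annotated repeats (z and φ=0)")

    ref_z_ann, ref_0_ann = reference_annotations[0], reference_annotations[1]
    ref_z = _repeat_ca(reference, ref_z_ann)
    ref_0 = _repeat_ca(reference, ref_0_ann)

    frame_rot = _minimal_rotation_to_z(principal_axis(ref_z))
    ref_z_aligned = (ref_z - ref_z.mean(axis=0)) @ frame_rot.T
    axis0 = frame_rot @ principal_axis(ref_0)
    proj0 = np.hypot(axis0[0], axis0[1])
    if proj0 < PROJECTION_TOLERANCE:
        raise DegenerateGeometryError(
            "φ=0 reference repeat is collinear with the z reference"
        )
    phi0 = np.degrees(np.arctan2(axis0[1], axis0[0]))

    entries: list[AzimuthEntry] = []
    for n_ann, c_ann in zip(annotations, annotations[1:]):
        ca_n = _repeat_ca(s, n_ann)
        ca_c = _repeat_ca(s, c_ann)
        m = min(len(ca_n), len(ref_z_aligned))
        sup = kabsch(ca_n[:m], ref_z_aligned[:m])
        axis = sup.rotation @ principal_axis(ca_c)
        proj = np.hypot(axis[0], axis[1])
        tilt = float(np.degrees(np.arccos(np.clip(axis[2], -1.0, 1.0))))
        if proj < PROJECTION_TOLERANCE:
            entries.append(AzimuthEntry(c_ann.label, None, tilt, False))
        else:
            phi = _wrap_angle(float(np.degrees(np.arctan2(axis[1], axis[0])) - phi0))
            entries.append(AzimuthEntry(c_ann.label, phi, tilt, True))
    desc = (
        f"z-axis: {ref_z_ann.label} of {reference.name or 'reference'}; "
        f"φ=0: {ref_0_ann.label}"
    )
    return AzimuthalProfile(reference_description=desc, entries=entries)
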