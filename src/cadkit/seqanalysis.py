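"""Alignment-based conservation, identity/similarity, insertions, motifs.

Conservation is scored per alignment column as 1 − H/ln 20, where H is the
Shannon entropy of the amino-acid frequencies in the column (gaps
excluded): an invariant column scores 1, a column uniform over all twenty
residues scores 0.  Scores are discretized into nine equal-width bins (the
familiar nine-level conservation coloring).  This is an entropy surrogate
for evolutionary-rate methods such as ConSurf — deterministic, alignment-
only, and documented as such; it does not model phylogeny.

Also here: SIAS-style percent identity/similarity matrices, detection of
query-specific insertions relative to a reference row (e.g. the δ-insertion
and DE-loop insertion that distinguish δ1 protocadherins), and simple motif
scans — N-glycosylation sequons N-X(≠P)-[S/T], C-mannosylation W-X-X-W, and
the canonical calcium-binding motifs of cadherin linkers (DXNDN, DXD,
DRE/DYE).
"""

from __future__ import annotations

import dataclasses
import math
import re
from collections import Counter

import numpy as np
from Bio import AlignIO

from .structures import AA3_TO_1, Structure, StructureError

__all__ = [
    "Alignment",
    "ConservationProfile",
    "MotifHit",
    "AlignmentError",
    "read_alignment",
    "conservation_scores",
    "map_alignment_to_structure",
    "identity_similarity",
    "find_insertions",
    "scan_glyco_sequons",
    "scan_calcium_motifs",
    "paint_conservation",
    "DEFAULT_SIMILARITY_GROUPS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = "-."

#: Default similarity grouping (configurable; mirrors common substitution sets).
DEFAULT_SIMILARITY_GROUPS = (
    "ILVM", "FWY", "KRH", "DE", "ST", "NQ", "AG", "C", "P",
)


class AlignmentError(ValueError):
    """Raised for malformed alignments or failed sequence/structure mapping."""


@dataclasses.dataclass
class Alignment:
    """Records of equal-length gapped sequences over the amino-acid alphabet."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences differ in count")
        if len(self.sequences) < 2:
            raise AlignmentError("alignment needs at least 2 records")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        allowed = set(AMINO_ACIDS + GAP_CHARS + "X")
        bad = sorted({c for s in self.sequences for c in s.upper()} - allowed)
        if bad:
            raise AlignmentError(f"illegal alignment characters: {bad}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise AlignmentError(f"sequence id {seq_id!r} not in alignment") from None

    def matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])


@dataclasses.dataclass
class ConservationProfile:
    """Per-column conservation: score in [0,1], nine-level bin, gap fraction."""

    scores: np.ndarray  # NaN where masked
    bins: np.ndarray  # 0 where masked, else 1..9
    gap_fractions: np.ndarray
    masked: np.ndarray  # True where gap fraction > mask threshold


@dataclasses.dataclass(frozen=True)
class MotifHit:
    motif: str
    position: int  # 1-based in the ungapped sequence
    matched: str


# ---------------------------------------------------------------------------


def read_alignment(path: str, fmt: str = "fasta") -> Alignment:
    """Read a FASTA or Clustal alignment file."""
    fmt = fmt.lower()
    if fmt not in {"fasta", "clustal"}:
        raise AlignmentError(f"unknown alignment format {fmt!r}")
    try:
        msa = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise AlignmentError(f"cannot parse {path} as {fmt}: {exc}") from exc
    return Alignment(
        ids=[rec.id for rec in msa], sequences=[str(rec.seq) for rec in msa]
    )


def conservation_scores(a: Alignment, mask_gap_fraction: float = 0.5) -> ConservationProfile:
    """Entropy-based conservation with nine equal-width bins.

    score = 1 − H/ln 20 over the column's non-gap residues; columns whose
    gap fraction exceeds ``mask_gap_fraction`` are masked (score NaN,
    bin 0).  bin = 1 + floor(9·score), clipped to 9, so an invariant
    column lands in bin 9 and a maximally variable one in bin 1.
    """
    n_rows = len(a.sequences)
    scores = np.full(a.n_columns, np.nan)
    bins = np.zeros(a.n_columns, dtype=int)
    gap_frac = np.zeros(a.n_columns)
    masked = np.zeros(a.n_columns, dtype=bool)
    for col in range(a.n_columns):
        column = [s[col] for s in a.sequences]
        residues = [c for c in column if c in AMINO_ACIDS]
        gap_frac[col] = 1.0 - len(residues) / n_rows
        if gap_frac[col] > mask_gap_fraction or not residues:
            masked[col] = True
            continue
        counts = Counter(residues)
        total = len(residues)
        h = -sum((c / total) * math.log(c / total) for c in counts.values())
        score = max(0.0, 1.0 - h / math.log(20.0))
        scores[col] = score
        bins[col] = min(9, 1 + int(score * 9.0))
    return ConservationProfile(scores=scores, bins=bins, gap_fractions=gap_frac, masked=masked)


def map_alignment_to_structure(
    a: Alignment,
    reference_id: str,
    s: Structure,
    chain_id: str,
    profile: ConservationProfile | None = None,
    numbering_offset: int = 0,
    max_mismatches: int = 5,
) -> dict[tuple[str, int, str], tuple[float, int]]:
    """Attach per-column conservation to modeled residues of a chain.

    Residue with author number n is matched to ungapped reference-sequence
    position n − ``numbering_offset`` (1-based); unmodeled residues simply
    receive no entry.  More than ``max_mismatches`` disagreements between
    structure residue types and the reference sequence abort with an error.
    Returns residue key → (score, bin); masked columns map to (nan, 0).
    """
    if profile is None:
        profile = conservation_scores(a)
    row = a.row(reference_id)
    # ungapped position (1-based) → alignment column
    pos_to_col: dict[int, int] = {}
    pos = 0
    for col, c in enumerate(row):
        if c not in GAP_CHARS:
            pos += 1
            pos_to_col[pos] = col
    ungapped = "".join(c for c in row if c not in GAP_CHARS)

    mapping: dict[tuple[str, int, str], tuple[float, int]] = {}
    mismatches = []
    for chain, num, icode, resname in s.polymer_residues(chain_id):
        p = num - numbering_offset
        if p < 1 or p > len(ungapped):
            continue
        letter = AA3_TO_1.get(resname, "X")
        if ungapped[p - 1] != letter:
            mismatches.append((num, letter, ungapped[p - 1]))
            continue
        col = pos_to_col[p]
        mapping[(chain, num, icode)] = (float(profile.scores[col]), int(profile.bins[col]))
    if len(mismatches) > max_mismatches:
        raise AlignmentError(
            f"{len(mismatches)} sequence/structure mismatches (limit {max_mismatches}): "
            f"first few {mismatches[:5]}"
        )
    return mapping


def identity_similarity(
    a: Alignment, groups: tuple[str, ...] = DEFAULT_SIMILARITY_GROUPS
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise percent identity and similarity matrices.

    Columns where both sequences are gapped are excluded from the
    denominator.  Identity counts equal non-gap residues; similarity
    additionally counts substitutions within one group.  Matrices are
    symmetric with 100 on the diagonal.
    """
    group_of: dict[str, int] = {}
    for gi, g in enumerate(groups):
        for c in g:
            group_of[c] = gi
    n = len(a.sequences)
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = a.sequences[i], a.sequences[j]
            scored = same = close = 0
            for ci, cj in zip(si, sj):
                gi_, gj_ = ci in GAP_CHARS, cj in GAP_CHARS
                if gi_ and gj_:
                    continue
                scored += 1
                if gi_ or gj_:
                    continue
                if ci == cj:
                    same += 1
                    close += 1
                elif group_of.get(ci, -1) == group_of.get(cj, -2):
                    close += 1
            ident[i, j] = ident[j, i] = 100.0 * same / scored if scored else 0.0
            simil[i, j] = simil[j, i] = 100.0 * close / scored if scored else 0.0
    return ident, simil


@dataclasses.dataclass(frozen=True)
class InsertionSpan:
    """Run of query residues absent from the reference row."""

    query_start: int  # 1-based ungapped query position
    query_end: int  # inclusive
    length: int
    sequence: str


def find_insertions(a: Alignment, query_id: str, reference_id: str) -> list[InsertionSpan]:
    """Maximal runs where the reference is gapped but the query is not."""
    q = a.row(query_id)
    r = a.row(reference_id)
    spans: list[InsertionSpan] = []
    qpos = 0
    run_start = None
    run_seq: list[str] = []
    for cq, cr in zip(q, r):
        q_res = cq not in GAP_CHARS
        if q_res:
            qpos += 1
        if q_res and cr in GAP_CHARS:
            if run_start is None:
                run_start = qpos
            run_seq.append(cq)
        else:
            if run_start is not None:
                spans.append(
                    InsertionSpan(run_start, run_start + len(run_seq) - 1, len(run_seq), "".join(run_seq))
                )
                run_start, run_seq = None, []
    if run_start is not None:
        spans.append(
            InsertionSpan(run_start, run_start + len(run_seq) - 1, len(run_seq), "".join(run_seq))
        )
    return spans


# ---------------------------------------------------------------------------
# Motif scans


def _check_ungapped(sequence: str) -> str:
    seq = sequence.upper()
    if any(c in GAP_CHARS for c in seq):
        raise AlignmentError("motif scans require an ungapped sequence")
    return seq


def scan_glyco_sequons(sequence: str) -> list[MotifHit]:
    """Glycosylation motif candidates (necessary conditions, not predictions).

    N-linked: N-X-[S/T] with X ≠ P (overlapping hits allowed).
    C-mannosylation: W-X-X-W, reported at the first tryptophan.
    """
    seq = _check_ungapped(sequence)
    hits: list[MotifHit] = []
    for m in re.finditer(r"N(?=[^P](S|T))", seq):
        hits.append(MotifHit("N-glycosylation", m.start() + 1, seq[m.start(): m.start() + 3]))
    for m in re.finditer(r"W(?=..W)", seq):
        hits.append(MotifHit("C-mannosylation", m.start() + 1, seq[m.start(): m.start() + 4]))
    return sorted(hits, key=lambda h: (h.position, h.motif))


def scan_calcium_motifs(sequence: str) -> list[MotifHit]:
    """Canonical calcium-binding linker motifs: DXNDN, DXD, DRE, DYE.

    Overlapping hits are allowed; a DXD hit entirely inside a DXNDN span is
    suppressed (it is part of the larger motif).
    """
    seq = _check_ungapped(sequence)
    hits: list[MotifHit] = []
    dxndn_spans: list[tuple[int, int]] = []
    for m in re.finditer(r"D(?=.NDN)", seq):
        start = m.start() + 1
        dxndn_spans.append((start, start + 4))
        hits.append(MotifHit("DXNDN", start, seq[m.start(): m.start() + 5]))
    for m in re.finditer(r"D(?=.D)", seq):
        start = m.start() + 1
        if any(lo <= start and start + 2 <= hi for lo, hi in dxndn_spans):
            continue
        hits.append(MotifHit("DXD", start, seq[m.start(): m.start() + 3]))
    for pat in ("DRE", "DYE"):
        for m in re.finditer(f"{pat[0]}(?={pat[1:]})", seq):
            hits.append(MotifHit(pat, m.start() + 1, seq[m.start(): m.start() + 3]))
    return sorted(hits, key=lambda h: (h.position, h.motif))


def paint_conservation(
    s: Structure,
    mapping: dict[tuple[str, int, str], tuple[float, int]],
    path: str,
) -> None:
    """Write a PDB copy with the conservation bin in the B-factor column."""
    import dataclasses as dc

    from .structures import write_structure

    atoms = [
        dc.replace(a, b_factor=float(mapping.get(a.residue_key, (0.0, 0))[1]))
        for a in s.atoms
    ]
    painted = dc.replace(s, atoms=atoms)
    write_structure(painted, path, "pdb")
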