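# Methods

`cadkit` quantifies how tandem extracellular-cadherin (EC) repeats form
adhesive interfaces. This note records the models implemented, the
parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not establish about real crystallographic data.

## Solvent-accessible surface area

SASA is computed by Shrake–Rupley sphere sampling: each heavy atom is
inflated by the probe radius (default 1.4 Å, a water-sized probe) and
covered with `n_points` quasi-uniform sphere points from a golden-angle
spiral. A point survives if it lies outside every neighbouring inflated
sphere; the atom's area is the surviving fraction of 4π(r_vdw + probe)².

Numerical choices:

* **Deterministic point set.** The spiral construction has no random
  element, so areas are bit-stable for fixed parameters. 960 points give
  <1% error against the closed-form area of an isolated sphere and <2%
  against the two-intersecting-spheres (spherical-cap) value; 3840 points
  change desk-scale totals by <1%.
* **Radius table.** One declared van der Waals table (C 1.70, N 1.55,
  O 1.52, S 1.80 Å, …) ships in `data/vdw_radii.json`. Published interface
  areas from servers such as PISA depend on undisclosed internal radii, so
  reproduction of printed values is expected only to ~10%; all areas here
  are reproducible exactly under the declared table. Unknown elements are
  an error unless a fallback radius is set, in which case they are flagged
  in the result.
* **Hetero exclusion.** Waters, ions and glycans are excluded by default:
  interface areas describe protein protomers, and sugars or buffer ions
  would dilute per-residue burial. A flag re-includes them.
* **Neighbour search** uses a k-d tree with cutoff 2×(max inflated
  radius), giving O(n·k) cost; a 3,000–4,000-atom dimer evaluates in
  seconds.

## Buried surface and interface bookkeeping

The interface between protomers A and B is derived from three SASA
evaluations — A alone, B alone, A∪B. A residue's buried surface area
(BSA) is its free-protomer SASA minus its in-complex SASA, clipped at zero
(sphere sampling can produce ~1e-9 negatives). The **interface area** is
half the total SASA lost by both protomers, the convention under which one
protomer's burial equals the interface area for a symmetric dimer.

* **Interface residues** are those burying ≥20% of their free-protomer
  accessible area (threshold configurable); residues with zero accessible
  area never qualify.
* **Per-repeat decomposition** attributes each residue's burial to the
  repeat of the nearest heavy atom on the other protomer (ties toward the
  smaller residue number). Pair keys are directional — `EC1:EC4` is the
  burial of EC1 residues against EC4 partners, averaged over the two
  protomers — so for a two-fold-symmetric dimer `EC1:EC4` and `EC4:EC1`
  are equal and all keys, plus an `other` bucket for unannotated burial,
  sum to the interface area by construction. Re-evaluating SASA on repeat
  subsets would not conserve the total; nearest-partner attribution does.
* **Composition** splits buried area by residue class. The default map —
  charged {Asp, Glu, Lys, Arg}; hydrophobic {Ala, Val, Leu, Ile, Met, Phe,
  Trp, Pro, Gly, Cys}; hydrophilic {Ser, Thr, Asn, Gln, Tyr, His} — is a
  calibration choice, fully configurable, and recorded in
  `data/residue_classes.json`.
* **Salt bridges** are inter-protomer pairs of a basic side-chain nitrogen
  (Lys NZ; Arg NE/NH1/NH2) within 4.0 Å of an acidic side-chain oxygen
  (Asp OD1/OD2, Glu OE1/OE2). Histidine is excluded by default because its
  charge is pH-dependent; a flag adds ND1/NE2.
* **Classification**: an interface strictly larger than 856 Å² (the
  empirical biological-vs-crystal-contact cutoff; configurable) is called
  `plausible-biological`, otherwise `crystal-contact-scale`. The boundary
  value itself classifies as crystal-scale.

## Superposition and azimuthal geometry

Cα superposition uses the Kabsch SVD solution with the proper-rotation
correction (det = +1 enforced), over the intersection of residue numbers
carrying a Cα in both chains — robust to structures with different
unmodeled loops. Fewer than three pairs, or a collinear set, is a
degenerate-geometry error.

A repeat's **long axis** is the largest-eigenvalue eigenvector of its
unweighted Cα covariance, signed to point from the N-terminal-half
centroid toward the C-terminal-half centroid. When the top two eigenvalues
agree within 1% the axis is ill-defined and a warning is attached.

The **azimuthal ladder** expresses inter-repeat twist: a reference
repeat's long axis defines +z and a second reference repeat's projected
axis defines φ = 0. For each consecutive repeat pair in the analyzed
chain, the N-terminal repeat is superposed (Kabsch, order correspondence
truncated to the shorter repeat) onto the frame-aligned reference repeat,
and φ of the C-terminal repeat's axis — projected on the xy-plane,
counterclockwise about +z viewed from +z, reported in (−180°, 180°] — is
read off, together with the polar tilt. The reference may be internal
(the chain's own first two repeats, so the first pair reads φ = 0 by
construction) or an external two-repeat structure; the frame used is
recorded in the output. Projected axis lengths below 0.02 (unit axis)
make φ undefined; the entry is flagged rather than reported.

## Conservation and sequence annotation

Column conservation is 1 − H/ln 20 with H the Shannon entropy of the
column's amino-acid frequencies, gaps excluded. This is an alignment-only
surrogate for evolutionary-rate methods (ConSurf-style): it ignores
phylogeny and treats all substitutions equally, but it is deterministic,
dependency-free and exactly testable (invariant column → 1; uniform
20-residue column → 0; half-half column → 1 − ln2/ln20). Columns with
more than 50% gaps are masked. Scores are discretized into nine
equal-width bins (1 = variable … 9 = invariant) for the familiar
nine-level coloring; equal-width rather than quantile binning keeps the
bin of a column independent of the rest of the alignment. Bins can be
painted into the B-factor column of a PDB copy for visualization.

Identity/similarity are percent scores over alignment columns excluding
double-gap positions; similarity adds within-group substitutions under a
configurable grouping (default {ILVM} {FWY} {KRH} {DE} {ST} {NQ} {AG} {C}
{P}). Insertions relative to a reference row are maximal runs of
reference-gap/query-residue columns, reported in ungapped query
coordinates — the operation that identifies lineage-specific inserts such
as the δ-insertion in EC4 of δ1 protocadherins.

Motif scans report necessary conditions, not predictions: N-glycosylation
sequons N-X(≠P)-[S/T] (overlaps allowed), C-mannosylation W-X-X-W, and
the calcium-binding linker motifs DXNDN, DXD, DRE, DYE (a DXD inside a
DXNDN span is suppressed as part of the larger motif). The positionally
defined linker motifs XEX/XDX are not scannable patterns (X matches
everything) and are deliberately not scanned globally.

Sequence-to-structure mapping assumes author residue number n corresponds
to ungapped reference-sequence position n (an offset parameter shifts
this); unmodeled residues are simply skipped, and more than a configurable
number of residue-type mismatches aborts the mapping.

## Assay quantification

* **Melting temperature**: the fluorescence trace is min–max normalized
  over the full sweep and Tm is the first upward 0.5-crossing, linearly
  interpolated between grid points. This makes Tm invariant under
  positive affine rescaling of the signal. Traces without an upward
  crossing (e.g. aggregation-dominated decays) raise a no-transition
  error rather than returning a number.
* **Bead aggregates**: images are thresholded (fixed value, or Otsu's
  histogram threshold when none is given — deterministic and
  parameter-free), components are labeled under 8-connectivity, blobs
  under `min_size` pixels are dropped, and per-particle pixel areas and
  their mean are reported. Replicate images are treated independently;
  the series helper returns mean-of-means ± SEM (ddof = 1). Touching
  aggregates are not split (no watershed); counts on dense fields are
  therefore lower bounds.

## Synthetic fixtures: what they establish

The generators emit payloads in the same standard formats the pipeline
reads (PDB, FASTA, CSV, PNG), with ground truth fixed by construction:

* **Sphere systems** give closed-form SASA targets (isolated sphere,
  two-sphere cap).
* **Repeat rods** stack rigid copies of one prolate Cα cloud; repeat k+1
  is placed from repeat k by a 35 Å rise and a rotation tilting the local
  axis by a polar angle (default 15°) toward the prescribed azimuth.
  Because every repeat is congruent and the base cloud's principal axis
  is exactly +z, the azimuthal ladder recovers the prescribed twists
  essentially exactly (observed ≲0.01°, tested at 2°) against the bundled
  zero-twist reference rod. A zero tilt makes φ degenerate by
  construction and is flagged.
* **Toy dimers** are two antiparallel Cα rods 3.8 Å spaced, with a
  partner-facing pseudo side-chain atom only on declared contact
  residues, placed so opposing atoms sit `gap` Å apart (default 3 Å)
  while everything else stays out of probe reach. The contacting residue
  set, the antiparallel register (residue i ↔ N+1−i), and hence the
  nonzero repeat pairs are exact ground truth. The construction is
  mirror-symmetric, so both protomers bury equal area up to sphere
  sampling (~1%).
* **Alignments, melt curves, disc images** have per-column classes,
  logistic midpoints, and rasterized pixel counts as truth.

These fixtures validate the arithmetic, conventions, and conservation
properties of every stage. They are deliberately not physical proteins:
no side chains beyond the pseudo atom, no β-sandwich geometry, no
realistic packing. Passing them shows the bookkeeping is right under the
declared conventions; it does not by itself show agreement with published
server-computed areas, which additionally depends on radii and sampling
choices those servers do not publish (hence the ~10% reproduction
tolerance adopted for printed interface areas). Analysis of deposited
entries runs through the identical code path via `cadkit report` with a
downloaded mmCIF, a repeat-boundary CSV (boundaries are taken as
configuration, not hard-coded), and either a second chain set or a
crystallographic symmetry operator for the partner.

## Problem sizes

Tests and the acceptance script use desk-scale inputs: 80-atom dimers,
six-repeat rods of 40 Cα each, 100-seed melt-curve ensembles, and
220×260 px images. The full suite runs in a few seconds; a complete
two-protomer analysis of a ~3,300-atom crystallographic dimer at 960
points per atom completes in well under a minute.

## Known limitations

* Entropy conservation has no evolutionary model; bins are the tool's own
  calibration, not ConSurf's.
* Per-pair attribution by nearest partner atom is one convention among
  several; totals are conserved, but pair splits near repeat boundaries
  can differ from subset-re-evaluation schemes.
* The azimuthal ladder's order-based Cα correspondence assumes repeats of
  comparable length; grossly truncated repeats should use an explicit
  correspondence.
* Symmetry expansion needs cell and operators in the input file (or a
  space-group name resolvable to standard operators); otherwise a
  pre-assembled two-chain file must be supplied.
* Tm is single-transition; multi-domain unfolding with two plateaus
  reports the first crossing only.
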