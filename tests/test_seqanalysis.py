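"""Conservation scoring, identity/similarity, insertions, motif scans."""

import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cadkit.seqanalysis import (
    Alignment,
    AlignmentError,
    conservation_scores,
    find_insertions,
    identity_similarity,
    map_alignment_to_structure,
    read_alignment,
    scan_calcium_motifs,
    scan_glyco_sequons,
)
from cadkit.structures import AtomRecord, Structure


def _aln(*seqs):
    return Alignment(ids=[f"s{i}" for i in range(len(seqs))], sequences=list(seqs))


class TestReaders:
    FASTA = ">a\nACDEF\n>b\nACDEY\n"
    CLUSTAL = (
        "CLUSTAL W (1.8) multiple sequence alignment\n\n"
        "a   ACDEF\nb   ACDEY\n"
    )

    def test_fasta_and_clustal_agree(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(self.FASTA)
        c = tmp_path / "a.aln"
        c.write_text(self.CLUSTAL)
        a1 = read_alignment(str(f), "fasta")
        a2 = read_alignment(str(c), "clustal")
        assert a1.sequences == a2.sequences == ["ACDEF", "ACDEY"]

    def test_ragged_alignment_rejected(self, tmp_path):
        f = tmp_path / "bad.fasta"
        f.write_text(">a\nACDEF\n>b\nAC\n")
        with pytest.raises(AlignmentError):
            read_alignment(str(f))

    def test_illegal_characters_named(self):
        with pytest.raises(AlignmentError, match="[1J]"):
            _aln("AC1EF", "ACJEF")

    def test_single_record_rejected(self):
        with pytest.raises(AlignmentError, match="at least 2"):
            Alignment(ids=["a"], sequences=["ACDEF"])


class TestConservation:
    def test_invariant_column_scores_one_bin_nine(self):
        prof = conservation_scores(_aln("D", "D", "D", "D"))
        assert prof.scores[0] == pytest.approx(1.0)
        assert prof.bins[0] == 9

    def test_uniform_column_scores_zero_bin_one(self):
        from cadkit.seqanalysis import AMINO_ACIDS

        prof = conservation_scores(_aln(*list(AMINO_ACIDS)))
        assert prof.scores[0] == pytest.approx(0.0, abs=1e-12)
        assert prof.bins[0] == 1

    def test_half_half_column_closed_form(self):
        prof = conservation_scores(_aln("A", "A", "V", "V"))
        assert prof.scores[0] == pytest.approx(1 - math.log(2) / math.log(20))

    def test_gappy_column_masked_above_half(self):
        prof = conservation_scores(_aln("AA", "A-", "A-", "A-"))
        assert not prof.masked[0]
        assert prof.masked[1]  # 75% gaps
        prof_half = conservation_scores(_aln("A-", "A-", "AA", "AA"))
        assert not prof_half.masked[1]  # exactly 50% gaps: kept

    def test_all_gap_column_masked_with_undefined_score(self):
        prof = conservation_scores(_aln("A-", "C-", "D-"))
        assert prof.masked[1]
        assert np.isnan(prof.scores[1])
        assert prof.bins[1] == 0

    def test_row_permutation_leaves_profile_unchanged(self):
        seqs = ["ACDEF", "AYDEF", "ACDWF", "ACDEF"]
        p1 = conservation_scores(_aln(*seqs))
        p2 = conservation_scores(_aln(*reversed(seqs)))
        assert np.allclose(p1.scores, p2.scores, equal_nan=True)

    def test_scores_bounded_and_bins_monotone(self):
        rng = np.random.default_rng(0)
        from cadkit.seqanalysis import AMINO_ACIDS

        seqs = [
            "".join(rng.choice(list(AMINO_ACIDS), size=40)) for _ in range(12)
        ]
        prof = conservation_scores(_aln(*seqs))
        ok = ~np.isnan(prof.scores)
        assert np.all(prof.scores[ok] >= 0) and np.all(prof.scores[ok] <= 1)
        order = np.argsort(prof.scores[ok])
        assert np.all(np.diff(prof.bins[ok][order]) >= 0)


class TestStructureMapping:
    def _structure(self, sequence, missing=(), chain="A"):
        from cadkit.structures import AA3_TO_1

        three = {v: k for k, v in AA3_TO_1.items() if len(k) == 3 and k != "MSE"}
        atoms = []
        for i, letter in enumerate(sequence, start=1):
            if i in missing:
                continue
            atoms.append(
                AtomRecord(i, "CA", "C", three[letter], chain, i, "", (float(i), 0.0, 0.0))
            )
        return Structure(atoms=atoms)

    def test_exact_match_maps_every_residue(self):
        aln = _aln("ACDEF", "ACDEY")
        s = self._structure("ACDEF")
        mapping = map_alignment_to_structure(aln, "s0", s, "A")
        assert len(mapping) == 5
        assert mapping[("A", 1, "")][1] == 9  # invariant A column

    def test_unmodeled_residues_are_skipped_not_fatal(self):
        aln = _aln("ACDEFGHIKL", "ACDEFGHIKL")
        s = self._structure("ACDEFGHIKL", missing=set(range(2, 10)))
        mapping = map_alignment_to_structure(aln, "s0", s, "A")
        assert set(mapping) == {("A", 1, ""), ("A", 10, "")}

    def test_too_many_mismatches_abort(self):
        aln = _aln("AAAAAAAAAA", "AAAAAAAAAA")
        s = self._structure("VVVVVVVVVV")
        with pytest.raises(AlignmentError, match="mismatch"):
            map_alignment_to_structure(aln, "s0", s, "A", max_mismatches=5)

    def test_absent_reference_id_is_an_error(self):
        aln = _aln("ACDEF", "ACDEY")
        with pytest.raises(AlignmentError, match="nope"):
            map_alignment_to_structure(aln, "nope", self._structure("ACDEF"), "A")

    def test_painted_pdb_carries_bins_in_b_factors(self, tmp_path):
        from cadkit.seqanalysis import paint_conservation
        from cadkit.structures import read_structure

        aln = _aln("ACDEF", "ACDEY")
        s = self._structure("ACDEF")
        mapping = map_alignment_to_structure(aln, "s0", s, "A")
        out = tmp_path / "painted.pdb"
        paint_conservation(s, mapping, str(out))
        back = read_structure(str(out))
        bins = {a.residue_number: a.b_factor for a in back.atoms}
        assert bins[1] == 9.0  # invariant column
        assert 0.0 <= bins[5] < 9.0  # F/Y column is variable


class TestIdentitySimilarity:
    def test_identical_pair_is_100_100(self):
        ident, simil = identity_similarity(_aln("ACDEF", "ACDEF"))
        assert ident[0, 1] == 100.0 and simil[0, 1] == 100.0

    def test_grouped_substitutions_count_as_similar_only(self):
        ident, simil = identity_similarity(_aln("AAAA", "VVVV"), groups=("AV",))
        assert ident[0, 1] == 0.0 and simil[0, 1] == 100.0

    def test_hand_counted_mixed_pair(self):
        # columns: A=A, A=A, D~E (grouped), '-'/'-' excluded -> 2/3 identity
        ident, simil = identity_similarity(_aln("AAD-", "AAE-"))
        assert ident[0, 1] == pytest.approx(100 * 2 / 3)
        assert simil[0, 1] == pytest.approx(100.0)

    def test_identity_never_exceeds_similarity(self):
        rng = np.random.default_rng(1)
        from cadkit.seqanalysis import AMINO_ACIDS

        seqs = ["".join(rng.choice(list(AMINO_ACIDS + "--"), size=30)) for _ in range(6)]
        ident, simil = identity_similarity(_aln(*seqs))
        assert np.all(ident <= simil + 1e-9)
        assert np.allclose(ident, ident.T) and np.allclose(simil, simil.T)


class TestInsertions:
    def test_simple_two_residue_insertion(self):
        spans = find_insertions(_aln("AC--GT", "ACWWGT"), "s1", "s0")
        assert len(spans) == 1
        assert (spans[0].query_start, spans[0].query_end, spans[0].length) == (3, 4, 2)
        assert spans[0].sequence == "WW"

    def test_no_gaps_no_insertions(self):
        assert find_insertions(_aln("ACGT", "ACGT"), "s1", "s0") == []

    def test_terminal_gap_span_clipped(self):
        spans = find_insertions(_aln("ACGT--", "ACGTWW"), "s1", "s0")
        assert len(spans) == 1
        assert (spans[0].query_start, spans[0].query_end) == (5, 6)

    def test_self_comparison_is_always_empty(self):
        for seq in ("ACGT", "A-C-G", "----", "WWWW"):
            assert find_insertions(_aln(seq, seq), "s0", "s1") == []

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from("AW-"), min_size=1, max_size=8))
    def test_matches_brute_force_scanner(self, ref_chars):
        """Enumerated gap placements agree with an independent column scan."""
        ref = "".join(ref_chars)
        query = "W" * len(ref)
        spans = find_insertions(_aln(ref, query), "s1", "s0")
        # brute force: walk columns, tracking query position
        expected = []
        qpos, run = 0, []
        for cq, cr in zip(query, ref):
            qpos += 1
            if cr == "-":
                run.append(qpos)
            else:
                if run:
                    expected.append((run[0], run[-1]))
                run = []
        if run:
            expected.append((run[0], run[-1]))
        assert [(s.query_start, s.query_end) for s in spans] == expected


class TestMotifScans:
    def test_n_sequon_hit_and_proline_veto(self):
        assert [h.position for h in scan_glyco_sequons("ANGSA")] == [2]
        assert scan_glyco_sequons("ANPSA") == []

    def test_overlapping_tryptophan_motifs(self):
        hits = [h.position for h in scan_glyco_sequons("WAAWAAW")]
        assert hits == [1, 4]

    def test_calcium_motif_suppression_and_overlap(self):
        hits = scan_calcium_motifs("ADINDNA")
        assert [(h.motif, h.position) for h in hits] == [("DXNDN", 2)]
        dxd = [h.position for h in scan_calcium_motifs("DADADAD")]
        assert dxd == [1, 3, 5]
        assert [(h.motif, h.position) for h in scan_calcium_motifs("DRE")] == [("DRE", 1)]

    def test_gapped_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            scan_glyco_sequons("AN-SA")

    @settings(max_examples=150, derandomize=True)
    @given(st.text(alphabet="NSTPWADREY", min_size=0, max_size=30))
    def test_sequon_scan_matches_regex_oracle(self, seq):
        got = [h.position for h in scan_glyco_sequons(seq) if h.motif == "N-glycosylation"]
        expected = [m.start() + 1 for m in re.finditer(r"(?=N[^P][ST])", seq)]
        assert got == expected

    @settings(max_examples=150, derandomize=True)
    @given(st.text(alphabet="DANRE", min_size=0, max_size=30))
    def test_calcium_scan_matches_brute_force(self, seq):
        got = {(h.motif, h.position) for h in scan_calcium_motifs(seq)}
        dxndn = {("DXNDN", i + 1) for i in range(len(seq) - 4)
                 if seq[i] == "D" and seq[i + 2: i + 5] == "NDN"}
        spans = [(p, p + 4) for _, p in dxndn]
        dxd = {("DXD", i + 1) for i in range(len(seq) - 2)
               if seq[i] == "D" and seq[i + 2] == "D"
               and not any(lo <= i + 1 and i + 3 <= hi for lo, hi in spans)}
        dre = {("DRE", i + 1) for i in range(len(seq) - 2) if seq[i: i + 3] == "DRE"}
        assert got == dxndn | dxd | dre
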