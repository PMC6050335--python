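"""Motif classifier: hand-labeled fixture suite, partition property,
window extraction, and methylation-aware re-ranking."""

import random

import pytest

from m6afold.errors import ValidationError
from m6afold.fold import SuboptEnsemble, enumerate_all_structures, subopt
from m6afold.motifs import (M6APenaltyTable, MotifCategory, PENALTIES_WITH_MG,
                            SiteWindow, WindowOutOfBounds, classify_motif,
                            extract_window, rerank_with_m6a,
                            reverse_complement)
from m6afold.structure import SecondaryStructure

from conftest import random_rna


def _st(seq, pairs):
    return SecondaryStructure(seq, frozenset(pairs))


# Hand-labeled classification fixtures. Each entry: sequence, pair list
# (1-based), focal-A index, expected category, expected (bulge_side,
# bulge_len), junctional flag. Labels were assigned by hand from the
# category definitions before running the classifier.
FIXTURES = [
    # --- canonical A–U pairs ------------------------------------------------
    ("basic 5' bulge",
     "GGCGACUUUCGAGUGCC", [(1, 17), (2, 16), (3, 15), (5, 14), (6, 13), (7, 12)],
     5, MotifCategory.FIVEB_AU, ("5p_of_a", 1), True),
    ("helix-interior A-U",
     "GGCAGCUUCGGCUGCC", [(1, 16), (2, 15), (3, 14), (4, 13), (5, 12), (6, 11)],
     4, MotifCategory.DUPLEX_AU, ("none", 0), False),
    ("3' bulge",
     "GGCAGCUCUUCGGAGUGCC",
     [(1, 19), (2, 18), (3, 17), (4, 16), (6, 15), (7, 14), (8, 13)],
     4, MotifCategory.AU_THREEB, ("3p_of_a", 1), True),
    ("bulge on the partner strand",
     "GGCACUCGAAAGUCGCC", [(1, 17), (2, 16), (3, 15), (4, 13), (5, 12), (6, 11)],
     4, MotifCategory.PARTNER_BULGE, ("partner", 1), True),
    ("two-nucleotide 5' bulge",
     "GGCGGACUCUUCGAGUGCC",
     [(1, 19), (2, 18), (3, 17), (6, 16), (7, 15), (8, 14), (9, 13)],
     6, MotifCategory.FIVEB_AU, ("5p_of_a", 2), True),
    ("G-U wobbles flank the pair (still duplex)",
     "GGCAGCUUCGGUUGCU", [(1, 16), (2, 15), (3, 14), (4, 13), (5, 12), (6, 11)],
     4, MotifCategory.DUPLEX_AU, ("none", 0), False),
    ("terminal pair at the molecule end, no bulge",
     "AGCUUCGGCU", [(1, 10), (2, 9), (3, 8)],
     1, MotifCategory.DUPLEX_AU, ("none", 0), True),
    ("A on the 3' strand, 5' bulge",
     "GGCUGCUUCGGCCAGCC", [(1, 17), (2, 16), (3, 15), (4, 14), (5, 12), (6, 11)],
     14, MotifCategory.FIVEB_AU, ("5p_of_a", 1), True),
    ("A on the 3' strand, 3' bulge",
     "GGCUGCUUCGAGCACGCC", [(1, 18), (2, 17), (3, 16), (4, 14), (5, 13), (6, 12)],
     14, MotifCategory.AU_THREEB, ("3p_of_a", 1), True),
    ("A on the 3' strand, bulge next to partner",
     "GGCCUGCUUCGGCAGCC", [(1, 17), (2, 16), (3, 15), (5, 14), (6, 13), (7, 12)],
     14, MotifCategory.PARTNER_BULGE, ("partner", 1), True),
    ("junctional pair inside a multiloop",
     "GGCAGCUUCGGCUAGGUUCGCCCC",
     [(1, 24), (2, 23), (4, 13), (5, 12), (6, 11), (15, 22), (16, 21)],
     4, MotifCategory.FIVEB_AU, ("5p_of_a", 1), True),
    ("last stem pair below the apical loop (loop counts as 3' bulge)",
     "GGCAUUCGUGCC", [(1, 12), (2, 11), (3, 10), (4, 9)],
     4, MotifCategory.AU_THREEB, ("3p_of_a", 4), True),
    # --- unpaired A ---------------------------------------------------------
    ("A inside the apical loop, no adjacent pair",
     "GGCGCUAAUGCGCC", [(1, 14), (2, 13), (3, 12), (4, 11), (5, 10)],
     7, MotifCategory.UNPAIRED, ("none", 0), False),
    ("bulged A between stacked helices (zero-width facing strand)",
     "GGAGCUUCGGCCC", [(1, 13), (2, 12), (4, 11), (5, 10)],
     3, MotifCategory.UNPAIRED, ("none", 0), False),
    ("loop A adjacent to the closing pair but facing a wide loop",
     "GGCAAAAGCC", [(1, 10), (2, 9), (3, 8)],
     4, MotifCategory.UNPAIRED, ("none", 0), False),
    ("fully single-stranded",
     "GGCAAAAGCC", [],
     4, MotifCategory.UNPAIRED, ("none", 0), False),
    # --- imputed mismatches (engines that refuse non-canonical pairs) ------
    ("1x1 internal loop: imputed A-C mismatch inside a helix",
     "GGCAGCUUCGGCCGCC", [(1, 16), (2, 15), (3, 14), (5, 12), (6, 11)],
     4, MotifCategory.DUPLEX_AY, ("none", 0), False),
    ("1x1 internal loop facing a U: imputed Watson-Crick partner",
     "GGCAGCUUCGGCUGCC", [(1, 16), (2, 15), (3, 14), (5, 12), (6, 11)],
     4, MotifCategory.DUPLEX_AU, ("none", 0), False),
    ("2x1 loop: imputed mismatch with 5' bulge",
     "GGCAAGCUUCGGCCGCC", [(1, 17), (2, 16), (3, 15), (6, 13), (7, 12)],
     5, MotifCategory.FIVEB_AY, ("5p_of_a", 1), True),
    ("2x1 loop: imputed mismatch with 3' bulge",
     "GGCAAGCUUCGGCCGCC", [(1, 17), (2, 16), (3, 15), (6, 13), (7, 12)],
     4, MotifCategory.AY_THREEB, ("3p_of_a", 1), True),
    # --- real non-canonical pairs (imported predictions) --------------------
    ("helix-interior A-G mismatch pair",
     "GGCAGCUUCGGCGGCC", [(1, 16), (2, 15), (3, 14), (4, 13), (5, 12), (6, 11)],
     4, MotifCategory.DUPLEX_AY, ("none", 0), False),
    ("junctional A-G pair, 5' bulge beats partner-side bulge",
     "GGCAGCUUCGGCGGCC", [(1, 16), (2, 15), (4, 13), (5, 12), (6, 11)],
     4, MotifCategory.FIVEB_AY, ("5p_of_a", 1), True),
]


class TestClassifierFixtures:
    @pytest.mark.parametrize("name,seq,pairs,a,cat,bulge,junctional",
                             [(f[0], *f[1:]) for f in FIXTURES],
                             ids=[f[0] for f in FIXTURES])
    def test_hand_labeled_structures(self, name, seq, pairs, a, cat, bulge,
                                     junctional):
        call = classify_motif(_st(seq, pairs), a)
        assert call.category == cat
        assert (call.bulge_side, call.bulge_len) == bulge
        assert call.junctional == junctional

    def test_suite_covers_all_categories(self):
        assert {f[4] for f in FIXTURES} == set(MotifCategory)
        assert len(FIXTURES) >= 20

    def test_non_a_focal_base_rejected(self):
        with pytest.raises(ValidationError):
            classify_motif(_st("GGGAAAACCC", [(1, 10)]), 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_motif(_st("GGGAAAACCC", []), 11)


class TestPartitionProperty:
    def test_every_structure_gets_exactly_one_category(self):
        """Exhaustive over all structures of random short sequences:
        classification never fails and always returns one category."""
        r = random.Random(424242)
        checked = 0
        for _ in range(25):
            seq = random_rna(r, r.randint(8, 14))
            a_positions = [i + 1 for i, b in enumerate(seq) if b == "A"]
            if not a_positions:
                continue
            for s in enumerate_all_structures(seq):
                for a in a_positions:
                    call = classify_motif(s, a)
                    assert call.category in MotifCategory
                    assert (call.partner is None) == (
                        call.category == MotifCategory.UNPAIRED)
                    checked += 1
        assert checked > 1000


class TestExtractWindow:
    TX = "".join("ACGU"[(i * 7 + 3) % 4] for i in range(100))

    def test_window_spans_expected_coordinates(self):
        tx = self.TX[:49] + "A" + self.TX[50:]
        w = extract_window(tx, 50, length=41, a_offset=21)
        assert w.sequence == tx[29:70]
        assert len(w.sequence) == 41
        assert w.sequence[20] == "A" and w.a_index == 21

    def test_alternative_window_geometry(self):
        tx = self.TX[:49] + "A" + self.TX[50:]
        w = extract_window(tx, 50, length=31, a_offset=11)
        assert w.sequence == tx[39:70]

    def test_site_near_edge_skipped(self):
        tx = "GGGGA" + self.TX[5:]
        with pytest.raises(WindowOutOfBounds):
            extract_window(tx, 5, length=41, a_offset=21)

    def test_non_a_site_rejected(self):
        tx = "G" * 60
        with pytest.raises(ValidationError):
            extract_window(tx, 30, length=41, a_offset=21)

    def test_minus_strand_uses_reverse_complement(self):
        tx = "GGGGG" + "U" * 30 + "GGGGG"   # U on + strand = A on - strand
        pos = 20
        w = extract_window(tx, pos, length=11, a_offset=6, strand="-")
        rc = reverse_complement(tx)
        assert w.sequence == rc[len(tx) - pos - 5:len(tx) - pos + 6]
        assert w.sequence[5] == "A"


class TestRerank:
    def _ens(self, seq, window=3.0):
        return subopt(seq, window=window)

    def test_zero_penalties_keep_order(self):
        ens = self._ens("GGCGACUUUCGAGUGCC")
        out = rerank_with_m6a(ens, 5, M6APenaltyTable(offsets={}))
        assert [s.pairs for s in out.ensemble] == [s.pairs for s in ens]
        assert not out.mfe_changed

    def test_default_offsets_flip_close_alternatives(self):
        """A duplex MFE 0.5 kcal/mol below a 5ʹ-bulge alternative flips after
        applying the +0.6 / −0.9 offsets (net swing 1.5 kcal/mol)."""
        seqs = {"duplex": "GGCAGCUUCGGCUGCC"}
        dup = SecondaryStructure(
            seqs["duplex"],
            frozenset([(1, 16), (2, 15), (3, 14), (4, 13), (5, 12), (6, 11)]),
            -10.0)
        alt = SecondaryStructure(
            seqs["duplex"],
            frozenset([(1, 16), (2, 15), (4, 13), (5, 12), (6, 11)]),
            -9.0)  # junctional with C3 bulged 5' of A4
        assert classify_motif(dup, 4).category == MotifCategory.DUPLEX_AU
        assert classify_motif(alt, 4).category == MotifCategory.FIVEB_AU
        ens = SuboptEnsemble([dup, alt], -10.0, 3.0)
        out = rerank_with_m6a(ens, 4, PENALTIES_WITH_MG)
        assert out.mfe_changed
        assert out.new_best.pairs == alt.pairs
        assert out.new_best.energy == pytest.approx(-9.9)
        assert out.ensemble[1].energy == pytest.approx(-9.4)

    def test_large_gap_not_flipped(self):
        dup = SecondaryStructure("GGCAGCUUCGGCUGCC",
                                 frozenset([(1, 16), (2, 15), (3, 14), (4, 13),
                                            (5, 12), (6, 11)]), -10.0)
        alt = SecondaryStructure("GGCAGCUUCGGCUGCC",
                                 frozenset([(1, 16), (2, 15), (4, 13),
                                            (5, 12), (6, 11)]), -6.5)
        ens = SuboptEnsemble([dup, alt], -10.0, 4.0)
        out = rerank_with_m6a(ens, 4, PENALTIES_WITH_MG)
        assert not out.mfe_changed

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValidationError):
            rerank_with_m6a(SuboptEnsemble([], 0.0, 0.0), 1)

    def test_penalty_tables_sign_conventions(self):
        assert PENALTIES_WITH_MG.offset(MotifCategory.FIVEB_AU) < 0
        assert PENALTIES_WITH_MG.offset(MotifCategory.DUPLEX_AU) > 0
        assert PENALTIES_WITH_MG.offset(MotifCategory.FIVEB_AY) == 0.0
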