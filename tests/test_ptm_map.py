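import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curtainkit.diffexp import SignificanceClass
from curtainkit.errors import ValidationError
from curtainkit.formats_io import PTMDatabase, PTMDatabaseEntry
from curtainkit.ptm_map import (UNALIGNED, AlignmentParams, RemappedSite,
                                SiteClass, align_isoforms, compare_sites,
                                extract_window, position_frequency_matrix,
                                remap_site, remap_site_detail)

from oracles import brute_force_align

AA = "ACDEFGHIKLMNPQRSTVWY"
seq_strategy = st.text(alphabet=AA, min_size=1, max_size=12)


class TestAlignIsoforms:
    def test_identical_sequences_identity_map(self):
        amap = align_isoforms("MKSASK", "MKSASK")
        assert amap.exp_to_canonical == {i: i for i in range(1, 7)}
        assert amap.identity_fraction == 1.0

    def test_nterminal_extension_shifts_all_positions(self):
        exp = "MKSASKLLDEQR"
        amap = align_isoforms(exp, "XYW" + exp)
        assert all(amap.exp_to_canonical[i] == i + 3
                   for i in range(1, len(exp) + 1))
        score, pairs = brute_force_align(exp, "XYW" + exp)
        assert amap.score == score
        assert [(p.exp_position, p.canonical_position)
                for p in amap.pairs] == pairs

    def test_internal_deletion_shifts_downstream_positions(self):
        canonical = "MKSASKLLDEQRTW"
        exp = canonical[:5] + canonical[7:]    # canonical 6-7 deleted in exp
        amap = align_isoforms(exp, canonical)
        mapping = amap.exp_to_canonical
        assert all(mapping[i] == i for i in range(1, 6))
        assert all(mapping[i] == i + 2 for i in range(6, len(exp) + 1))
        # deleted canonical positions are hit by no experimental position
        assert {6, 7}.isdisjoint(mapping.values())

    @given(seq_strategy, seq_strategy)
    @settings(max_examples=250, deadline=None)
    def test_matches_brute_force_dynamic_program(self, a, b):
        amap = align_isoforms(a, b)
        score, pairs = brute_force_align(a, b)
        assert amap.score == score
        assert [(p.exp_position, p.canonical_position)
                for p in amap.pairs] == pairs

    @given(seq_strategy, seq_strategy)
    @settings(max_examples=100, deadline=None)
    def test_mapping_is_strictly_monotone(self, a, b):
        amap = align_isoforms(a, b)
        items = sorted(amap.exp_to_canonical.items())
        for (p1, c1), (p2, c2) in zip(items, items[1:]):
            assert p1 < p2 and c1 < c2

    def test_match_mismatch_scheme(self):
        params = AlignmentParams(matrix=None, match=1.0, mismatch=-1.0,
                                 gap_open=-2.0, gap_extend=-1.0)
        amap = align_isoforms("ACGT", "ACGT", params)
        assert amap.score == 4.0

    def test_positive_gap_penalty_rejected(self):
        with pytest.raises(ValidationError):
            AlignmentParams(gap_open=1.0)

    def test_biopython_score_agreement(self):
        # independent cross-check of the scoring scheme on longer sequences
        from Bio import Align
        from Bio.Align import substitution_matrices
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -0.5
        aligner.mode = "global"
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), rng.integers(10, 60)))
            b = "".join(rng.choice(list(AA), rng.integers(10, 60)))
            assert align_isoforms(a, b).score == aligner.score(a, b)


class TestRemapSite:
    def test_identity_map_returns_same_position(self):
        amap = align_isoforms("A" * 150, "A" * 150)
        assert remap_site(amap, 139) == 139

    def test_offset_map_adds_the_offset(self):
        rng = np.random.default_rng(17)
        exp = "".join(rng.choice(list(AA), 150))
        prefix = "".join(rng.choice(list(AA), 11))
        amap = align_isoforms(exp, prefix + exp)
        assert remap_site(amap, 139) == 150
        assert all(remap_site(amap, i) == i + 11 for i in range(1, 151))

    def test_experimental_insertion_is_unaligned(self):
        canonical = "MKSASKLLDEQRTW"
        exp = canonical[:7] + "WWHHY" + canonical[7:]
        amap = align_isoforms(exp, canonical)
        inserted = [i for i in range(1, len(exp) + 1)
                    if i not in amap.exp_to_canonical]
        assert len(inserted) == 5
        assert all(remap_site(amap, i) is UNALIGNED for i in inserted)

    def test_out_of_range_position_is_error(self):
        amap = align_isoforms("MKSA", "MKSA")
        with pytest.raises(ValidationError):
            remap_site(amap, 5)
        with pytest.raises(ValidationError):
            remap_site(amap, 0)

    def test_detail_reports_both_residues(self):
        amap = align_isoforms("MKSA", "MKTA")
        d = remap_site_detail(amap, 3)
        assert (d.exp_residue, d.canonical_residue) == ("S", "T")
        assert not d.residue_match


class TestCompareSites:
    def _db(self, entries, name="dbA"):
        return PTMDatabase(source_name=name, entries=[
            PTMDatabaseEntry(accession="P1", position=p, residue=r,
                             modification=m) for p, r, m in entries])

    def _site(self, pos, residue="S", mod="Phospho", exp_pos=None):
        return RemappedSite(canonical_position=pos,
                            experimental_position=exp_pos or pos,
                            residue=residue, modification=mod,
                            accession="P1")

    def test_coincident_site_is_both(self):
        out = compare_sites([self._site(139)],
                            [self._db([(139, "S", "Phospho")])])
        assert out[139].site_class == SiteClass.BOTH
        assert out[139].db_presence == {"dbA": True}

    def test_disjoint_positions_split_classes(self):
        out = compare_sites([self._site(139)],
                            [self._db([(140, "S", "Phospho")])])
        assert out[139].site_class == SiteClass.EXPERIMENT_ONLY
        assert out[140].site_class == SiteClass.DATABASE_ONLY

    def test_selected_position_overrides_with_presence_recorded(self):
        out = compare_sites([self._site(139)],
                            [self._db([(139, "S", "Phospho")])],
                            selected_positions=[139])
        assert out[139].site_class == SiteClass.SELECTED
        assert out[139].db_presence == {"dbA": True}

    def test_modification_type_must_match_for_both(self):
        out = compare_sites([self._site(10, mod="GlyGly")],
                            [self._db([(10, "S", "Phospho")])])
        assert out[10].site_class == SiteClass.EXPERIMENT_ONLY

    def test_residue_conflict_demotes_both(self):
        out = compare_sites([self._site(10, residue="T")],
                            [self._db([(10, "S", "Phospho")])])
        assert out[10].site_class == SiteClass.EXPERIMENT_ONLY
        assert out[10].residue_conflict

    def test_significant_sites_carry_asterisk_flag(self):
        out = compare_sites(
            [self._site(139), self._site(150)],
            [self._db([(139, "S", "Phospho")])],
            significance={139: SignificanceClass.S_C,
                          150: SignificanceClass.NS_NC})
        assert out[139].significant
        assert not out[150].significant

    def test_classes_partition_all_positions(self):
        rng = np.random.default_rng(21)
        exp_pos = rng.choice(200, size=30, replace=False) + 1
        db_pos = rng.choice(200, size=30, replace=False) + 1
        sites = [self._site(int(p)) for p in exp_pos]
        db = self._db([(int(p), "S", "Phospho") for p in db_pos])
        out = compare_sites(sites, [db])
        assert set(out) == set(int(p) for p in exp_pos) | \
            set(int(p) for p in db_pos)
        for entry in out.values():
            assert entry.site_class in SiteClass

    def test_experimental_position_retained(self):
        out = compare_sites([self._site(150, exp_pos=139)], [])
        assert out[150].experimental_position == 139


class TestMotifWindows:
    @pytest.mark.parametrize("seq,pos,hw,expected", [
        ("ABCDEFG", 4, 2, "BCDEF"),
        ("ACDEFGH", 1, 3, "___ACDE"),
        ("ACDEFGH", 7, 3, "EFGH___"),
        ("ACDEFGH", 4, 0, "E"),
    ])
    def test_window_extraction_with_edge_padding(self, seq, pos, hw,
                                                 expected):
        w = extract_window(seq, pos, halfwidth=hw)
        assert w.window == expected
        assert len(w.window) == 2 * hw + 1
        assert w.center == seq[pos - 1]

    def test_default_window_is_15mer(self):
        w = extract_window("A" * 100, 50)
        assert len(w.window) == 15

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            extract_window("ACDE", 5)

    def test_pfm_column_sums_equal_window_count(self):
        rng = np.random.default_rng(33)
        windows = [extract_window("".join(rng.choice(list(AA), 31)), 16,
                                  halfwidth=7) for _ in range(100)]
        pfm = position_frequency_matrix(windows)
        assert pfm.shape == (21, 15)
        assert (pfm.sum(axis=0) == 100).all()

    def test_identical_windows_count_twice(self):
        w = extract_window("ACDEFGH", 4, halfwidth=2)
        pfm = position_frequency_matrix([w, w])
        assert pfm.loc["E", "2"] == 2
        assert pfm.to_numpy().sum() == 10

    def test_mixed_lengths_rejected(self):
        w1 = extract_window("ACDEFGH", 4, halfwidth=2)
        w2 = extract_window("ACDEFGH", 4, halfwidth=3)
        with pytest.raises(ValidationError):
            position_frequency_matrix([w1, w2])
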