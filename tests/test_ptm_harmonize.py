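import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curtainkit.errors import (ConfigurationError, MergeError,
                               ValidationError)
from curtainkit.formats_io import SequenceSet
from curtainkit import ptm_harmonize as ph


class TestParseProbabilityString:
    @pytest.mark.parametrize("s,peptide,sites", [
        ("AAS(0.98)PT(0.02)K", "AASPTK", [(3, "S", 0.98), (5, "T", 0.02)]),
        ("PEPTIDE", "PEPTIDE", []),
        ("S(1)", "S", [(1, "S", 1.0)]),
        ("S(0)K", "SK", [(1, "S", 0.0)]),
    ])
    def test_grammar(self, s, peptide, sites):
        ann = ph.parse_probability_string(s)
        assert ann.peptide == peptide
        assert list(ann.sites) == sites

    def test_square_brackets_normalized(self):
        ann = ph.parse_probability_string("AAS[0.98]PK")
        assert ann.sites == ((3, "S", 0.98),)

    @pytest.mark.parametrize("s", ["AAS(0.98", "AAS(1.5)K", "(0.9)AK",
                                   "AAS(zz)K", "AA S(0.9)"])
    def test_malformed_strings_rejected(self, s):
        with pytest.raises(ValidationError):
            ph.parse_probability_string(s)

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1,
                   max_size=30),
           st.data())
    @settings(max_examples=100, deadline=None)
    def test_round_trip_property(self, peptide, data):
        # plant annotations at random positions; parsing must recover them
        k = data.draw(st.integers(0, min(3, len(peptide))))
        positions = sorted(data.draw(st.sets(
            st.integers(1, len(peptide)), min_size=k, max_size=k)))
        probs = [round(data.draw(st.floats(0, 1)), 4) for _ in positions]
        out = []
        prev = 0
        for pos, p in zip(positions, probs):
            out.append(peptide[prev:pos] + f"({p})")
            prev = pos
        out.append(peptide[prev:])
        ann = ph.parse_probability_string("".join(out))
        assert ann.peptide == peptide
        assert [(pos, peptide[pos - 1], p) for pos, p in
                zip(positions, probs)] == list(ann.sites)


class TestConvertMaxQuant:
    def _frame(self, prob=0.99, mult_values=None):
        row = {"Protein": "P1;P2", "Position": 3, "Amino acid": "S",
               "Position in peptide": 2, "Localization prob": prob,
               "Localization probabilities": f"KS({prob})AK"}
        for mult in (1, 2, 3):
            row[f"Intensity S1___{mult}"] = (mult_values or
                                             {1: 100.0, 2: 20.0, 3: 3.0}
                                             )[mult]
        return pd.DataFrame([row])

    def test_basic_record(self):
        seqs = SequenceSet()
        seqs["P1"] = "MKSAK"
        [rec] = ph.convert_maxquant(self._frame(), sequences=seqs)
        assert rec.accession == "P1"
        assert rec.protein_group == "P1;P2"
        assert rec.position_in_protein == 3
        assert rec.residue == "S"
        assert rec.valid

    def test_low_probability_retained_not_filtered(self):
        [rec] = ph.convert_maxquant(self._frame(prob=0.5))
        assert rec.localization_probability == 0.5
        assert rec.valid

    @pytest.mark.parametrize("mult,expected", [(1, 100.0), (2, 20.0),
                                               (3, 3.0)])
    def test_multiplicity_selects_intensity_family(self, mult, expected):
        [rec] = ph.convert_maxquant(self._frame(), multiplicity=mult)
        assert rec.quant == {"S1": expected}

    def test_missing_probability_column_is_config_error(self):
        df = self._frame().drop(columns=["Localization prob"])
        with pytest.raises(ConfigurationError):
            ph.convert_maxquant(df)

    def test_protein_residue_mismatch_flagged_invalid(self):
        seqs = SequenceSet()
        seqs["P1"] = "MKAAK"   # position 3 is A, not S
        [rec] = ph.convert_maxquant(self._frame(), sequences=seqs)
        assert not rec.valid


class TestConvertMSFragger:
    def test_position_from_peptide_start(self):
        seqs = SequenceSet()
        seqs["P1"] = "MKSASK"
        df = pd.DataFrame([{"Protein ID": "P1",
                            "Modified Peptide": "SAS(0.9)K",
                            "Protein Start": 3, "Intensity S1": 5.0}])
        [rec] = ph.convert_msfragger(df, seqs)
        assert rec.position_in_protein == 5
        assert rec.residue == "S"
        assert rec.valid
        assert rec.quant == {"S1": 5.0}

    def test_start_one_in_peptide_one_gives_protein_position_one(self):
        seqs = SequenceSet()
        seqs["P1"] = "MKSASK"
        df = pd.DataFrame([{"Protein ID": "P1",
                            "Modified Peptide": "M(0.8)KS",
                            "Protein Start": 1}])
        [rec] = ph.convert_msfragger(df, seqs)
        assert rec.position_in_protein == 1
        assert rec.valid

    def test_peptide_not_matching_protein_flagged(self):
        seqs = SequenceSet()
        seqs["P1"] = "MKSASK"
        df = pd.DataFrame([{"Protein ID": "P1",
                            "Modified Peptide": "WWW(0.9)W",
                            "Protein Start": 2}])
        [rec] = ph.convert_msfragger(df, seqs)
        assert not rec.valid


class TestConvertSpectronaut:
    def _seqs(self):
        seqs = SequenceSet()
        seqs["P1"] = "MAGPLSRK"
        seqs["P2"] = "KAKAKA"
        return seqs

    def test_substring_placement(self):
        df = pd.DataFrame([{"PG.ProteinAccessions": "P1",
                            "EG.ModifiedPeptide": "GPLS(0.97)R",
                            "PTM.ModificationTitle": "Phospho"}])
        [rec] = ph.convert_spectronaut(df, self._seqs())
        assert rec.position_in_protein == 6
        assert not rec.ambiguous
        assert rec.valid

    def test_repeated_peptide_uses_first_occurrence_with_flag(self):
        df = pd.DataFrame([{"PG.ProteinAccessions": "P2",
                            "EG.ModifiedPeptide": "KAK(0.8)A",
                            "PTM.ModificationTitle": "GlyGly"}])
        [rec] = ph.convert_spectronaut(df, self._seqs())
        assert rec.ambiguous
        assert rec.position_in_protein == 3

    def test_absent_peptide_flagged_invalid(self):
        df = pd.DataFrame([{"PG.ProteinAccessions": "P1",
                            "EG.ModifiedPeptide": "WW(0.9)W",
                            "PTM.ModificationTitle": "Phospho"}])
        [rec] = ph.convert_spectronaut(df, self._seqs())
        assert not rec.valid

    def test_combined_file_splits_per_modification(self):
        df = pd.DataFrame([
            {"PG.ProteinAccessions": "P1",
             "EG.ModifiedPeptide": "GPLS(0.97)R",
             "PTM.ModificationTitle": "Phospho"},
            {"PG.ProteinAccessions": "P1",
             "EG.ModifiedPeptide": "MAGPLSRK(0.9)",
             "PTM.ModificationTitle": "GlyGly"},
        ])
        records = ph.convert_spectronaut(df, self._seqs())
        by_mod = ph.split_by_modification(records)
        assert set(by_mod) == {"Phospho", "GlyGly"}
        assert len(by_mod["Phospho"]) == len(by_mod["GlyGly"]) == 1


class TestConvertDiann:
    def _files(self):
        quant = pd.DataFrame([
            {"Precursor.Id": f"k{i}", "Protein.Group": "P1",
             "Peptide.Start": 3, "Intensity S1": 10.0 * i}
            for i in range(3)])
        prob = pd.DataFrame([
            {"Precursor.Id": f"k{i}", "Protein.Group": "P1",
             "Modified.Sequence": "SAS(0.9)K"}
            for i in range(3)])
        return quant, prob

    def test_three_shared_keys_merge_to_three_records(self):
        quant, prob = self._files()
        records, report = ph.convert_diann(quant, prob)
        assert len(records) == 3
        assert report.unmatched_quant == report.unmatched_prob == []
        assert all(r.position_in_protein == 5 for r in records)

    def test_unmatched_key_excluded_and_reported(self):
        quant, prob = self._files()
        quant = pd.concat([quant, pd.DataFrame([
            {"Precursor.Id": "only_q", "Protein.Group": "P1",
             "Peptide.Start": 1, "Intensity S1": 1.0}])])
        records, report = ph.convert_diann(quant, prob)
        assert len(records) == 3
        assert report.unmatched_quant == ["only_q"]

    def test_zero_overlap_is_merge_error(self):
        quant, prob = self._files()
        prob["Precursor.Id"] = ["x1", "x2", "x3"]
        with pytest.raises(MergeError):
            ph.convert_diann(quant, prob)

    def test_conflicting_accession_is_merge_error(self):
        quant, prob = self._files()
        prob.loc[0, "Protein.Group"] = "P9"
        with pytest.raises(MergeError):
            ph.convert_diann(quant, prob)


class TestFilterClass1:
    def _records(self, probs):
        return [ph.PTMSiteRecord(accession="P1", peptide="SK",
                                 position_in_peptide=1,
                                 position_in_protein=1, residue="S",
                                 localization_probability=p)
                for p in probs]

    def test_strictly_greater_than_default_threshold(self):
        kept = ph.filter_class1(self._records([0.99, 0.75, 0.74]))
        assert [r.localization_probability for r in kept] == [0.99]

    def test_zero_threshold_keeps_strictly_positive(self):
        kept = ph.filter_class1(self._records([0.0, 0.1, 1.0]), threshold=0)
        assert [r.localization_probability for r in kept] == [0.1, 1.0]

    def test_empty_input(self):
        assert ph.filter_class1([]) == []

    @given(st.lists(st.floats(0, 1), max_size=50),
           st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_recount(self, probs, threshold):
        kept = ph.filter_class1(self._records(probs), threshold=threshold)
        assert len(kept) == sum(1 for p in probs if p > threshold)


def test_sites_tsv_round_trip(ptm_fixture):
    records = ph.convert_maxquant(ptm_fixture.maxquant,
                                  sequences=ptm_fixture.exp_sequences)
    import io
    frame = ph.records_to_frame(records)
    assert len(frame) == len(records)
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    back = ph.read_sites_tsv(buf)
    assert [(r.accession, r.position_in_protein, r.residue) for r in back] \
        == [(r.accession, r.position_in_protein, r.residue)
            for r in records]
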