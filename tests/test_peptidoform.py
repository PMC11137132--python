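import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baitform.io_formats import PSMRecord, ProteinDB
from baitform.peptidoform import (
    DEFAULT_FIXED_MODS,
    ISOTOPE_SPACING,
    RESIDUE_MASSES,
    aggregate_counts,
    annotate_delta_mass,
    classify_modification_state,
    compute_coverage,
    is_isotopic_error,
    load_known_mods,
    make_peptidoform_key,
    matches_bait,
    peptide_relative_positions,
    read_count_matrix,
    round_delta,
    substitution_mods,
    summarize_enrichment,
    write_count_matrix,
)
from conftest import matrix_from_rows


class TestMakePeptidoformKey:
    def test_plus58(self):
        assert make_peptidoform_key("LVVVGAGGVGK", 58.0055).key == "LVVVGAGGVGK@+58.0"

    def test_unmodified(self):
        assert make_peptidoform_key("PEPTIDE", 0.0).key == "PEPTIDE@+0.0"

    def test_negative_zero_normalized(self):
        pf = make_peptidoform_key("PEPTIDE", -0.04)
        assert pf.delta_key == 0.0
        assert math.copysign(1.0, pf.delta_key) == 1.0
        assert pf.key == "PEPTIDE@+0.0"

    @pytest.mark.parametrize(
        "delta,expected",
        [(0.05, 0.1), (-0.05, -0.1), (0.04999, 0.0), (57.95, 58.0), (-9.04, -9.0)],
    )
    def test_ties_away_from_zero(self, delta, expected):
        assert round_delta(delta) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            make_peptidoform_key("PEPTIDE", float("nan"))

    @given(k=st.integers(-5000, 5000), eps=st.floats(-0.0499, 0.0499))
    @settings(max_examples=300)
    def test_rounding_stability_within_bin(self, k, eps):
        # a delta at a bin center tolerates any sub-half-bin jitter
        m = k / 10.0
        assert (
            make_peptidoform_key("PEP", m).key
            == make_peptidoform_key("PEP", m + eps).key
        )


class TestIsotopicError:
    @pytest.mark.parametrize("delta", [1.0033, 0.0, -1.0, 2.0067, 3.01, 0.04])
    def test_true_cases(self, delta):
        assert is_isotopic_error(delta)

    @pytest.mark.parametrize("delta", [58.0055, 43.0, 0.5, -9.0, 4.013, -2.0067])
    def test_false_cases(self, delta):
        # 4.013 (k=4) and -2.0067 (k=-2) lie outside the default k range
        assert not is_isotopic_error(delta)

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            is_isotopic_error(0.0, tolerance=0.0)


class TestClassifyModificationState:
    def _forms(self, deltas, peptide="PEPTIDE"):
        return [make_peptidoform_key(peptide, d) for d in deltas]

    def test_only_unmodified(self):
        assert classify_modification_state(self._forms([0.0])) == "unmodified"

    def test_multiple_states(self):
        forms = self._forms([0.0, 43.0, 58.0])
        assert classify_modification_state(forms) == "multiple"

    def test_isotopic_collapsed_to_unmodified(self):
        assert classify_modification_state(self._forms([1.0])) == "unmodified"
        assert classify_modification_state(self._forms([0.0, 1.0, 2.0])) == "unmodified"

    def test_single_modified(self):
        assert classify_modification_state(self._forms([58.0])) == "modified"

    def test_unmodified_plus_one_modified_is_multiple(self):
        assert classify_modification_state(self._forms([0.0, 58.0])) == "multiple"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_modification_state([])

    def test_mixed_peptides_rejected(self):
        forms = [make_peptidoform_key("AAAAAAA", 0.0), make_peptidoform_key("CCCCCCC", 0.0)]
        with pytest.raises(ValueError):
            classify_modification_state(forms)

    @given(st.permutations([0.0, 1.0, 43.0, 58.0, 15.99]))
    def test_order_invariant(self, deltas):
        assert classify_modification_state(self._forms(list(deltas))) == "multiple"


def _bait_record(sample, peptide="PEPTIDEK", delta=0.0, protein="P01112", gene="HRAS"):
    return PSMRecord(
        peptide=peptide, delta_mass=delta, sample_id=sample,
        assigned_protein=protein, gene=gene,
    )


class TestAggregateCounts:
    def test_simple_counting(self, design_2v2):
        records = [_bait_record("t1") for _ in range(5)]
        counts = aggregate_counts(records, design_2v2, scope="bait")
        assert counts.df.at["PEPTIDEK@+0.0", "t1"] == 5
        assert counts.df.at["PEPTIDEK@+0.0", "c1"] == 0

    def test_count_conservation(self, design_2v2):
        records = (
            [_bait_record("t1", delta=d) for d in (0.0, 0.01, 58.0, 43.0)]
            + [_bait_record("c1", "ELVISLIVESK", 2.0)]
            + [_bait_record("c2", protein="Q99999", gene="PREY1")]  # not bait
        )
        counts = aggregate_counts(records, design_2v2, scope="bait")
        n_bait = sum(1 for r in records if matches_bait(r, design_2v2))
        assert counts.df.values.sum() == n_bait == 5

    def test_disjoint_keys_zero_elsewhere(self, design_2v2):
        records = [_bait_record("t1", "AAAAAAA"), _bait_record("c1", "CCCCCCC")]
        counts = aggregate_counts(records, design_2v2)
        assert counts.df.at["AAAAAAA@+0.0", "c1"] == 0
        assert counts.df.at["CCCCCCC@+0.0", "t1"] == 0

    def test_isoform_suffix_matches_bait(self, design_2v2):
        rec = _bait_record("t1", protein="P01112-2", gene="")
        assert matches_bait(rec, design_2v2)
        counts = aggregate_counts([rec], design_2v2)
        assert counts.df.values.sum() == 1

    def test_gene_match_without_accession(self, design_2v2):
        rec = _bait_record("t1", protein="XTAG001", gene="HRAS")
        assert matches_bait(rec, design_2v2)

    def test_no_in_scope_warns_empty(self, design_2v2, caplog):
        records = [_bait_record("t1", protein="Q1", gene="PREY")]
        with caplog.at_level("WARNING"):
            counts = aggregate_counts(records, design_2v2, scope="bait")
        assert counts.df.shape[0] == 0
        assert list(counts.df.columns) == design_2v2.sample_ids

    def test_unknown_sample_rejected(self, design_2v2):
        with pytest.raises(ValueError, match="not in design"):
            aggregate_counts([_bait_record("nope")], design_2v2)

    def test_all_scope_counts_everything(self, design_2v2):
        records = [
            _bait_record("t1"),
            _bait_record("t1", protein="Q1", gene="PREY"),
        ]
        counts = aggregate_counts(records, design_2v2, scope="all")
        assert counts.df.values.sum() == 2


class TestCountMatrixTsvRoundtrip:
    def test_roundtrip(self, tmp_path):
        counts = matrix_from_rows(
            {("PEPTIDEK", 0.0): [1.5, 2.0], ("PEPTIDEK", 58.0): [0.0, 3.0]},
            ["s1", "s2"], normalized=True,
        )
        path = tmp_path / "m.tsv"
        write_count_matrix(counts, path)
        back = read_count_matrix(path)
        assert back.keys == counts.keys
        assert back.normalized is True
        assert (back.df.values == counts.df.values).all()


DB_SEQ = "MTEYKLVVVGAGGVGKSALT"


def _db():
    db = ProteinDB()
    db.add("P01112", "HRAS", DB_SEQ)
    return db


class TestCoverage:
    def test_half_coverage(self):
        db = ProteinDB()
        db.add("P1", "G1", "ABCDEFGHIJ")
        res = compute_coverage(["ABCDE"], db, "G1")
        assert res.percent_coverage == 50.0
        assert res.covered_positions == frozenset(range(1, 6))

    def test_full_sequence_is_100(self):
        db = _db()
        res = compute_coverage([DB_SEQ], db, "HRAS")
        assert res.percent_coverage == 100.0

    def test_unmatched_peptide_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            res = compute_coverage(["WWWWWWW"], _db(), "HRAS")
        assert res.percent_coverage == 0.0
        assert any("not found" in m for m in caplog.messages)

    def test_all_occurrences_counted(self):
        db = ProteinDB()
        db.add("P1", "G1", "ABABABCDCD")  # "ABAB" occurs at 1 and 3
        res = compute_coverage(["ABAB"], db, "G1")
        assert res.covered_positions == frozenset({1, 2, 3, 4, 5, 6})

    def test_longest_isoform_used(self):
        db = ProteinDB()
        db.add("P1-1", "G1", "ABCDE")
        db.add("P1-2", "G1", "ABCDEFGHIJ")
        assert compute_coverage(["ABCDE"], db, "G1").percent_coverage == 50.0

    def test_absent_gene_rejected(self):
        with pytest.raises(KeyError):
            compute_coverage(["AAA"], _db(), "NOPE")

    def test_bounds(self):
        res = compute_coverage(["MTEYK", "SALT"], _db(), "HRAS")
        assert 0.0 <= res.percent_coverage <= 100.0


class TestPeptidePositions:
    def test_midpoint_first_window(self):
        db = ProteinDB()
        db.add("P1", "G1", "A" * 189)
        # 11-mer at positions 1..11 of a 189-residue protein
        db2 = ProteinDB()
        db2.add("P1", "G1", "LVVVGAGGVGK" + "W" * 178)
        pos = peptide_relative_positions(["LVVVGAGGVGK"], db2, "G1")[0]
        assert (pos.start, pos.end) == (1, 11)
        assert pos.relative_midpoint == pytest.approx(((1 + 11) / 2) / 189)
        assert pos.relative_midpoint == pytest.approx(0.0317, abs=1e-4)

    def test_full_length_midpoint_near_half(self):
        db = ProteinDB()
        db.add("P1", "G1", "A" * 100)
        pos = peptide_relative_positions(["A" * 100], db, "G1")[0]
        # ((1+L)/2)/L -> 0.5 symmetric center (exact value (L+1)/(2L))
        assert pos.relative_midpoint == pytest.approx(0.5, abs=0.01)

    def test_two_peptides_two_entries(self):
        out = peptide_relative_positions(["MTEYK", "SALT"], _db(), "HRAS")
        assert len(out) == 2

    def test_nonmatching_omitted(self, caplog):
        with caplog.at_level("WARNING"):
            out = peptide_relative_positions(["WWWWWWW"], _db(), "HRAS")
        assert out == []


class TestAnnotateDeltaMass:
    def test_minus9_cysteic_displacement(self):
        annotations = annotate_delta_mass(-9.0, "C")
        hit = [a for a in annotations if "cysteic" in a.name]
        assert hit and hit[0].displaces_fixed == "carbamidomethyl"

    def test_minus25_sulfinic_displacement(self):
        annotations = annotate_delta_mass(-25.0, "C")
        hit = [a for a in annotations if "sulfinic" in a.name]
        assert hit and hit[0].displaces_fixed == "carbamidomethyl"

    def test_plus58_g_to_d(self):
        annotations = annotate_delta_mass(58.0, "G")
        assert any(a.name == "substitution G->D" for a in annotations)
        # localization on G excludes the isobaric A->E substitution
        assert not any(a.name == "substitution A->E" for a in annotations)

    def test_plus43_carbamylation(self):
        annotations = annotate_delta_mass(43.0, "N-term")
        assert any(a.name == "carbamylation" for a in annotations)

    def test_zero_is_unmodified(self):
        annotations = annotate_delta_mass(0.0, None)
        assert annotations[0].name == "unmodified"

    def test_isotopic_annotated(self):
        annotations = annotate_delta_mass(1.0, None)
        assert any(a.kind == "isotopic_error" for a in annotations)

    def test_empty_when_nothing_matches(self):
        assert annotate_delta_mass(500.123, "G", include_substitutions=False,
                                   known_mods=load_known_mods()) == []

    def test_invariant_to_table_order(self):
        mods = load_known_mods()
        fwd = annotate_delta_mass(-9.0, "C", known_mods=mods)
        rev = annotate_delta_mass(-9.0, "C", known_mods=list(reversed(mods)))
        assert fwd == rev

    def test_substitution_table_is_complete(self):
        subs = substitution_mods()
        # ordered pairs of distinct-mass residues (I/L are isobaric)
        assert len(subs) == 20 * 19 - 2
        by_name = {s.name: s for s in subs}
        assert by_name["substitution G->D"].mono_mass == pytest.approx(
            RESIDUE_MASSES["D"] - RESIDUE_MASSES["G"]
        )

    def test_unknown_residue_matches_any(self):
        annotations = annotate_delta_mass(15.99, "unknown")
        assert any(a.name == "oxidation" for a in annotations)

    def test_fixed_mod_not_applied_off_residue(self):
        # localized on M: no carbamidomethyl displacement candidates
        annotations = annotate_delta_mass(-9.0, "M")
        assert all(a.displaces_fixed is None for a in annotations)


class TestSummarizeEnrichment:
    def test_simple(self, design_2v2):
        records = [_bait_record("t1") for _ in range(100)]
        records += [
            PSMRecord(peptide="AAAAAAA", delta_mass=0.0, sample_id="t1",
                      assigned_protein=f"Q{i}", gene=f"PREY{i}")
            for i in range(3) for _ in range(5)
        ]
        summary = {s.sample_id: s for s in summarize_enrichment(records, design_2v2)}
        assert summary["t1"].bait_psm_count == 100
        assert summary["t1"].prey_psm_counts == (5, 5, 5)

    def test_no_preys(self, design_2v2):
        records = [_bait_record("c1")]
        summary = {s.sample_id: s for s in summarize_enrichment(records, design_2v2)}
        assert summary["c1"] .bait_psm_count == 1
        assert summary["c1"].prey_psm_counts == ()

    def test_generator_bait_exceeds_prey_median(self):
        from baitform.synthetic_data import SimConfig, generate_dataset

        ds = generate_dataset(SimConfig(seed=11))
        for s in summarize_enrichment(ds.all_records(), ds.design):
            preys = sorted(s.prey_psm_counts)
            median = preys[len(preys) // 2] if preys else 0
            assert s.bait_psm_count > median


def test_isotope_spacing_constant():
    assert ISOTOPE_SPACING == pytest.approx(1.00335, abs=1e-5)


def test_known_mods_resource_loads():
    mods = {m.name: m for m in load_known_mods()}
    assert mods["carbamylation"].mono_mass == pytest.approx(43.0058, abs=1e-3)
    assert "C" in mods["carbamidomethyl"].residues
    assert DEFAULT_FIXED_MODS[0].name == "carbamidomethyl"
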