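"""The APSF engine: pooled scoring, normalization, ranking, batch queries."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from ancac import (AA20, BatchFormatError, BatchGroup, DataError, Query,
                   Selection, UndefinedScoreError, apsf, count_amino_acids,
                   parse_batch, reference_apsf, score_batch, score_cogs,
                   select_all)
from conftest import make_dataset


def brute_force_apsf(records, features):
    """Independent oracle: concatenate every protein in scope and count."""
    blob = "".join(rec.aa_seq for rec in records)
    counts, total = count_amino_acids(blob)
    selected = sum(counts.get(f, 0) for f in features)
    return selected, total, 100.0 * selected / total


class TestApsf:
    def test_pooled_hand_count(self):
        ds = make_dataset(["KKR", "KA"])
        res = apsf(ds, ds.sequences, "amino_acid", {"K"})
        assert (res.selected, res.total, res.apsf) == (3, 5, 60.0)

    def test_all_twenty_features_sum_to_hundred(self, small_synth):
        res = apsf(small_synth, small_synth.sequences, "amino_acid", set(AA20))
        assert res.apsf == pytest.approx(100.0, abs=1e-9)

    def test_protein_only_codon_scope_is_undefined(self):
        ds = make_dataset(["MK", "MR"])
        with pytest.raises(UndefinedScoreError) as exc:
            apsf(ds, ds.sequences, "codon", {"ATG"})
        assert exc.value.n_skipped == 2

    def test_pooling_is_length_weighted_not_mean_of_percentages(self):
        ds = make_dataset(["K" * 9 + "A", "AK"])  # 90% and 50% K
        pooled = apsf(ds, ds.sequences, "amino_acid", {"K"})
        assert pooled.apsf == pytest.approx(100.0 * 10 / 12)
        mean = apsf(ds, ds.sequences, "amino_acid", {"K"}, mean_of_sequences=True)
        assert mean.apsf == pytest.approx((90.0 + 50.0) / 2)

    def test_monotone_in_feature_set(self, small_synth):
        scope = small_synth.sequences[:20]
        prev_sel, prev_apsf = 0, 0.0
        feats = set()
        for aa in "KRHED":
            feats.add(aa)
            res = apsf(small_synth, scope, "amino_acid", feats)
            assert res.selected >= prev_sel
            assert res.apsf >= prev_apsf - 1e-12
            prev_sel, prev_apsf = res.selected, res.apsf

    def test_permutation_invariance(self, small_synth):
        scope = list(small_synth.sequences[:30])
        res1 = apsf(small_synth, scope, "amino_acid", {"K", "R"})
        rng = random.Random(7)
        rng.shuffle(scope)
        assert apsf(small_synth, scope, "amino_acid", {"K", "R"}) == res1

    def test_oracle_equivalence_on_random_scopes(self, small_synth):
        rng = random.Random(20260925)
        for _ in range(100):
            n = rng.randint(1, len(small_synth.sequences))
            scope = rng.sample(small_synth.sequences, n)
            features = set(rng.sample(AA20, rng.randint(1, 5)))
            res = apsf(small_synth, scope, "amino_acid", features)
            sel, tot, pct = brute_force_apsf(scope, features)
            assert (res.selected, res.total) == (sel, tot)
            assert res.apsf == pct  # identical float arithmetic on identical ints

    def test_stop_codons_rejected_without_flag(self, small_synth):
        with pytest.raises(DataError, match="include_stops"):
            apsf(small_synth, small_synth.sequences, "codon", {"TAA"})
        res = apsf(small_synth, small_synth.sequences, "codon", {"TAA"},
                   include_stops=True)
        assert res.selected > 0


class TestReference:
    def test_full_selection_makes_modes_coincide(self, small_synth):
        sel = select_all(small_synth)
        q_db = Query("amino_acid", frozenset("K"), sel, "whole_database")
        q_sel = Query("amino_acid", frozenset("K"), sel, "selected_organisms")
        assert reference_apsf(small_synth, q_db) == reference_apsf(small_synth, q_sel)

    def test_single_organism_reference_is_its_pooled_frequency(self, small_synth):
        oid = sorted(small_synth.organisms)[0]
        sel = Selection(frozenset([oid]), ("manual",))
        q = Query("amino_acid", frozenset("K"), sel, "selected_organisms")
        ref = reference_apsf(small_synth, q)
        records = [r for r in small_synth.sequences if r.organism_id == oid]
        _, _, expected = brute_force_apsf(records, {"K"})
        assert ref.apsf == pytest.approx(expected)


class TestScoreCogs:
    def test_all_features_full_selection_scores_one(self, small_synth):
        q = Query("amino_acid", frozenset(AA20), select_all(small_synth),
                  "whole_database")
        rows = score_cogs(small_synth, q)
        assert len(rows) == len(small_synth.cogs)
        assert all(r.score == pytest.approx(1.0) for r in rows)

    def test_ranking_sorted_with_cog_id_tiebreak(self, small_synth):
        q = Query("amino_acid", frozenset("KRH"), select_all(small_synth),
                  "whole_database")
        rows = score_cogs(small_synth, q)
        keys = [(-r.score, r.group_label) for r in rows]
        assert keys == sorted(keys)

    def test_subgrouping_by_species_multiplies_rows(self, mini_dataset):
        sel = Selection(frozenset(["org1", "org2", "org3"]), ("manual",))
        q = Query("amino_acid", frozenset("K"), sel, "none",
                  subgroup_rank="species", cog_scope=("COG0002",))
        rows = score_cogs(mini_dataset, q)
        assert len(rows) == 3
        assert {r.subgroup for r in rows} == {"Genus1 sp1", "Genus2 sp2",
                                              "Genus3 sp3"}

    def test_unknown_cog_scope(self, small_synth):
        q = Query("amino_acid", frozenset("K"), select_all(small_synth),
                  cog_scope=("COG9999",))
        with pytest.raises(DataError, match="COG9999"):
            score_cogs(small_synth, q)

    def test_selection_restricts_scope(self, mini_dataset):
        sel = Selection(frozenset(["org1"]), ("manual",))
        q = Query("amino_acid", frozenset("K"), sel)
        rows = score_cogs(mini_dataset, q)
        assert all(r.n_sequences == 1 for r in rows)


class TestBatch:
    def test_grammar(self):
        groups = parse_batch("# comment\n\nArgPath:R:COG0001,COG0002\n"
                             "Mixed : K,R : COG0003 COG0004\n")
        assert groups[0] == BatchGroup("ArgPath", frozenset("R"),
                                       ("COG0001", "COG0002"))
        assert groups[1].features == frozenset("KR")
        assert groups[1].cog_ids == ("COG0003", "COG0004")

    @pytest.mark.parametrize("text,match", [
        ("X::", "empty field"),
        ("no colons here", "NAME:FEATURES:COG_LIST"),
        ("G:K:cog-1", "bad COG id"),
        ("G:Z9:COG0001", "invalid"),
        ("G:K:COG0001\nG:R:COG0002", "duplicate"),
    ])
    def test_malformed_lines(self, text, match):
        with pytest.raises(BatchFormatError, match=match):
            parse_batch(text)

    def test_unknown_cog_against_catalogue(self, small_synth):
        with pytest.raises(BatchFormatError, match="COG9999"):
            parse_batch("G:K:COG9999", small_synth)

    def test_pooled_group_score(self):
        # 2 COGs, pooled K count 5 of 50 residues -> APSF 10.0
        ds = make_dataset(["K" * 3 + "A" * 22], cog_id="COG0001")
        ds.cogs["COG0002"] = type(ds.cogs["COG0001"])("COG0002", "t")
        from ancac import SequenceRecord
        ds.add_sequence(SequenceRecord("org1", "COG0002", "p9", "g9",
                                       "K" * 2 + "A" * 23, ""))
        rows = score_batch(ds, [BatchGroup("G", frozenset("K"),
                                           ("COG0001", "COG0002"))],
                           normalization="none")
        row = rows[0]
        assert (row.selected_feature_count, row.total_feature_count) == (5, 50)
        assert row.apsf == pytest.approx(10.0)

    def test_singleton_group_equals_per_cog_row(self, small_synth):
        sel = select_all(small_synth)
        q = Query("amino_acid", frozenset("KR"), sel, "whole_database",
                  cog_scope=("COG0003",))
        cog_row = score_cogs(small_synth, q)[0]
        batch_row = score_batch(small_synth,
                                [BatchGroup("solo", frozenset("KR"), ("COG0003",))],
                                sel, "whole_database")[0]
        assert batch_row.score == pytest.approx(cog_row.score)
        assert batch_row.selected_feature_count == cog_row.selected_feature_count

    def test_subgrouped_batch_shape(self, small_synth):
        rows = score_batch(small_synth,
                           [BatchGroup("G", frozenset("K"), ("COG0001", "COG0002"))],
                           subgroup_rank="species")
        assert len(rows) == len(small_synth.organisms)  # one species each


class TestQueryValidation:
    def test_rejects_bad_features(self, small_synth):
        with pytest.raises(DataError):
            Query("amino_acid", frozenset("Z"), select_all(small_synth))
        with pytest.raises(DataError):
            Query("nucleotide", frozenset("U"), select_all(small_synth))
        with pytest.raises(DataError, match="normalization"):
            Query("amino_acid", frozenset("K"), select_all(small_synth), "fancy")


@given(st.sets(st.sampled_from(AA20), min_size=1, max_size=6))
@settings(max_examples=50, deadline=None)
def test_apsf_never_exceeds_total(features):
    ds = make_dataset(["MKRVHAE", "MMKKRR"])
    res = apsf(ds, ds.sequences, "amino_acid", features)
    assert 0 <= res.selected <= res.total
    assert 0.0 <= res.apsf <= 100.0
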