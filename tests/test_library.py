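import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editcode import fold as fe
from editcode import library as lib


@pytest.fixture()
def toy():
    # editing site at 3; positions 2 and 4 are A so the A->G exclusion bites
    return lib.Substrate(name="toy", wt_sequence="GAAAGGGAAAACCCCC", editing_site=3)


class TestMutations:
    def test_format_parse_roundtrip(self):
        muts = (
            lib.Substitution(5, "G", "C"),
            lib.Insertion(7, "ACG"),
            lib.Deletion(9, 2),
        )
        assert lib.parse_mutations(lib.format_mutations(muts)) == muts

    def test_parse_wt(self):
        assert lib.parse_mutations("") == ()
        assert lib.parse_mutations("WT") == ()

    def test_parse_malformed(self):
        with pytest.raises(ValueError):
            lib.parse_mutations("5:GC")

    def test_apply_substitution_checks_ref(self, toy):
        with pytest.raises(ValueError, match="reference mismatch"):
            lib.apply_mutations(toy.wt_sequence, [lib.Substitution(1, "A", "C")])

    def test_apply_indels(self, toy):
        seq = lib.apply_mutations("GAAAG", [lib.Insertion(2, "CC"), lib.Deletion(4, 1)])
        assert seq == "GACCAG"

    def test_site_index_shifts(self, toy):
        assert lib.variant_site_index(toy, (lib.Insertion(1, "GG"),)) == 5
        assert lib.variant_site_index(toy, (lib.Deletion(1, 1),)) == 2
        assert lib.variant_site_index(toy, (lib.Insertion(10, "G"),)) == 3

    def test_site_cannot_be_deleted(self, toy):
        with pytest.raises(lib.DesignError):
            lib.variant_site_index(toy, (lib.Deletion(2, 3),))

    def test_site_cannot_be_substituted(self, toy):
        with pytest.raises(lib.DesignError):
            lib.VariantRecord.from_mutations(toy, (lib.Substitution(3, "A", "C"),))


class TestSubstrate:
    def test_site_must_be_adenosine(self):
        with pytest.raises(ValueError, match="adenosine"):
            lib.Substrate(name="x", wt_sequence="GGGG", editing_site=1)

    def test_constraint_length_checked(self):
        with pytest.raises(ValueError):
            lib.Substrate(name="x", wt_sequence="GAAAC", editing_site=2, constraint="..")


class TestZscore:
    def test_wt_is_exactly_zero(self):
        recs = [
            lib.VariantRecord("WT", (), "GAAAC").with_editing([0.5]),
            lib.VariantRecord("a", (), "GAAAC").with_editing([0.7]),
            lib.VariantRecord("b", (), "GAAAC").with_editing([0.3]),
        ]
        out = lib.zscore_library(recs, 0.5)
        assert out[0].zscore == 0.0

    def test_derived_arithmetic(self):
        # ELs {0.5 (WT), 0.7, 0.3, 0.5}: S = sqrt(0.02), Z(0.7) = 0.2/S
        els = [0.5, 0.7, 0.3, 0.5]
        recs = [
            lib.VariantRecord(f"v{i}", (), "GAAAC").with_editing([el])
            for i, el in enumerate(els)
        ]
        out = lib.zscore_library(recs, 0.5)
        assert lib.library_stats(recs, 0.5).s == pytest.approx(
            math.sqrt(0.02), abs=1e-15
        )
        assert out[1].zscore == pytest.approx(1.4142135623730951, abs=1e-12)

    def test_population_not_sample_sd(self):
        recs = [
            lib.VariantRecord(f"v{i}", (), "GAAAC").with_editing([el])
            for i, el in enumerate([0.2, 0.4])
        ]
        assert lib.library_stats(recs, 0.2).s == pytest.approx(0.1)  # /N, not /(N-1)

    def test_degenerate_library(self):
        recs = [
            lib.VariantRecord(f"v{i}", (), "GAAAC").with_editing([0.4])
            for i in range(3)
        ]
        with pytest.raises(lib.DegenerateLibraryError):
            lib.zscore_library(recs, 0.4)

    def test_mean_identity(self):
        # mean of (Z_i * S + EL_WT) equals the mean editing level
        els = [0.1, 0.5, 0.62, 0.9, 0.33]
        recs = [
            lib.VariantRecord(f"v{i}", (), "GAAAC").with_editing([el])
            for i, el in enumerate(els)
        ]
        out = lib.zscore_library(recs, 0.5)
        s = lib.library_stats(recs, 0.5).s
        recon = [v.zscore * s + 0.5 for v in out]
        assert np.mean(recon) == pytest.approx(np.mean(els), abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(st.floats(0.05, 0.8), min_size=3, max_size=8, unique=True),
        st.floats(-0.04, 0.19),
    )
    def test_translation_invariance(self, els, shift):
        recs = [
            lib.VariantRecord(f"v{i}", (), "GAAAC").with_editing([el])
            for i, el in enumerate(els)
        ]
        shifted = [
            lib.VariantRecord(f"v{i}", (), "GAAAC").with_editing([el + shift])
            for i, el in enumerate(els)
        ]
        z1 = [v.zscore for v in lib.zscore_library(recs, els[0])]
        z2 = [v.zscore for v in lib.zscore_library(shifted, els[0] + shift)]
        assert z1 == pytest.approx(z2, abs=1e-9)


class TestClassify:
    WT_DB = "(((....)))"

    def test_transition_no_change(self):
        mc = lib.classify_mutation(
            lib.Substitution(5, "A", "G"), self.WT_DB, self.WT_DB
        )
        assert mc is lib.MutationClass.TRANSITION

    def test_transversion_break(self):
        # pair (3, 8) lost, everything else identical
        mc = lib.classify_mutation(
            lib.Substitution(3, "C", "G"), self.WT_DB, "((......))"
        )
        assert mc is lib.MutationClass.TRANSVERSION_BREAK

    def test_transversion_shift_new_pair(self):
        mc = lib.classify_mutation(
            lib.Substitution(5, "U", "A"), "..........", "(........)"
        )
        assert mc is lib.MutationClass.TRANSVERSION_SHIFT

    def test_transition_shift_multiple_breaks(self):
        mc = lib.classify_mutation(
            lib.Substitution(2, "G", "A"), self.WT_DB, ".........."
        )
        assert mc is lib.MutationClass.TRANSITION_SHIFT

    def test_all_six_reachable(self, tiny_substrate, model):
        wt_db, _ = fe.fold_mfe(tiny_substrate.wt_sequence, model)
        seen = set()
        design = lib.DesignSpec(region=(1, tiny_substrate.length))
        for v in lib.enumerate_designed_variants(tiny_substrate, design):
            var_db, _ = fe.fold_mfe(v.sequence, model)
            seen.add(lib.classify_mutation(v.mutations[0], wt_db, var_db))
        assert seen <= set(lib.MutationClass)

    def test_rejects_multi_mutation(self):
        with pytest.raises(TypeError):
            lib.classify_mutation((1, 2), self.WT_DB, self.WT_DB)


class TestDesign:
    def test_all_singles_count(self, toy):
        # region of 10 positions away from the site: 10 x 3 substitutions
        out = lib.enumerate_designed_variants(
            toy, lib.DesignSpec(region=(6, 15), exclude_ag_adjacent=False)
        )
        assert len(out) == 30

    def test_ag_adjacent_exclusion(self, toy):
        # region includes site-1 and site+1, both ref = A: 30 - 2 = 28
        out = lib.enumerate_designed_variants(toy, lib.DesignSpec(region=(2, 12)))
        no_excl = lib.enumerate_designed_variants(
            toy, lib.DesignSpec(region=(2, 12), exclude_ag_adjacent=False)
        )
        assert len(no_excl) == 30
        assert len(out) == 28

    def test_compensatory_keeps_stem_pairable(self, toy, model):
        # WT pairs (5, 16) G:C etc. fold first to find a real stem pair
        db, _ = fe.fold_mfe(toy.wt_sequence, model)
        i, j = fe.dotbracket_pairs(db)[0]
        design = lib.DesignSpec(
            region=(1, toy.length), singles=False,
            compensatory_pairs=((i + 1, j + 1),),
        )
        out = lib.enumerate_designed_variants(toy, design)
        assert out
        for v in out:
            a = v.sequence[i]
            b = v.sequence[j]
            assert model.pair_energy(a, b) is not None
            structs = fe.brute_force_fold(v.sequence, model)
            paired = [
                s for s, e in structs if (i, j) in fe.dotbracket_pairs(s)
            ]
            assert paired, "stem pair must remain realizable"

    def test_region_out_of_bounds(self, toy):
        with pytest.raises(lib.DesignError):
            lib.enumerate_designed_variants(toy, lib.DesignSpec(region=(1, 99)))

    def test_deduplicated(self, toy):
        out = lib.enumerate_designed_variants(toy, lib.DesignSpec(region=(6, 15)))
        assert len({v.sequence for v in out}) == len(out)


class TestReadAssignment:
    def test_binomial_recovery(self, toy, rng):
        v = lib.VariantRecord.from_mutations(toy, (lib.Substitution(6, "G", "C"),))
        coverage, true = 2000, 0.40
        n_g = rng.binomial(coverage, true)
        reads = []
        site = 3
        for k in range(coverage):
            base = "G" if k < n_g else "A"
            reads.append(v.sequence[: site - 1] + base + v.sequence[site:])
        df = lib.assign_reads_to_variants(reads, toy, [v])
        se = math.sqrt(true * (1 - true) / coverage)
        assert abs(df.loc[v.id, "editing_level"] - true) < 3 * se
        assert df.loc[v.id, "n_reads"] == coverage

    def test_mismatch_outside_signatures_unassigned(self, toy):
        v = lib.VariantRecord.from_mutations(toy, (lib.Substitution(6, "G", "C"),))
        bad = "U" + v.sequence[1:]
        df = lib.assign_reads_to_variants([bad], toy, [v])
        assert df.attrs["unassigned"] == 1
        assert df["n_reads"].sum() == 0

    def test_wt_reads_assigned_to_wt(self, toy):
        wt = lib.VariantRecord("WT", (), toy.wt_sequence)
        v = lib.VariantRecord.from_mutations(toy, (lib.Substitution(6, "G", "C"),))
        df = lib.assign_reads_to_variants([toy.wt_sequence] * 5, toy, [wt, v])
        assert df.loc["WT", "n_reads"] == 5
        assert df.loc[v.id, "n_reads"] == 0

    def test_low_coverage_flag(self, toy):
        wt = lib.VariantRecord("WT", (), toy.wt_sequence)
        df = lib.assign_reads_to_variants([toy.wt_sequence] * 5, toy, [wt], min_reads=10)
        assert bool(df.loc["WT", "low_coverage"])

    def test_ambiguous_signatures_rejected(self, toy):
        a = lib.VariantRecord("a", (), toy.wt_sequence)
        b = lib.VariantRecord("b", (), toy.wt_sequence)
        with pytest.raises(lib.DesignError, match="ambiguous"):
            lib.assign_reads_to_variants([], toy, [a, b])

    def test_editing_g_over_a_plus_g(self, toy):
        wt = lib.VariantRecord("WT", (), toy.wt_sequence)
        site = 3
        mk = lambda b: toy.wt_sequence[: site - 1] + b + toy.wt_sequence[site:]
        reads = [mk("G")] * 3 + [mk("A")] * 7 + [mk("C")] * 2  # C ignored in denominator
        df = lib.assign_reads_to_variants(reads, toy, [wt])
        assert df.loc["WT", "editing_level"] == pytest.approx(0.3)
        assert df.loc["WT", "n_reads"] == 12


class TestLibraryIO:
    def test_roundtrip(self, toy, tmp_path):
        recs = [
            lib.VariantRecord("WT", (), toy.wt_sequence).with_editing([0.5, 0.52]),
            lib.VariantRecord.from_mutations(
                toy, (lib.Substitution(6, "G", "C"),)
            ).with_editing([0.1, 0.2], zscore=-1.5),
        ]
        path = tmp_path / "lib.tsv"
        lib.save_library(recs, path)
        back = lib.load_library(path, toy)
        assert [v.id for v in back] == [v.id for v in recs]
        assert back[0].editing_levels == (0.5, 0.52)
        assert back[1].mutations == recs[1].mutations
        assert back[1].sequence == recs[1].sequence
        assert back[1].zscore == -1.5

    def test_malformed_row_line_number(self, toy, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tmutations\trep1\nv1\t6:G>Z>Q\t0.5\n")
        with pytest.raises(ValueError, match="line 2"):
            lib.load_library(path, toy)

    def test_empty_file_warns(self, toy, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            out = lib.load_library(path, toy)
        assert out == []
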