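import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iaspls.errors import DataError
from iaspls.features import (
    BLOCK_ORDER,
    CodonReference,
    FeatureConfig,
    FeatureMatrix,
    block_widths,
    build_feature_matrix,
    codon_usage_indices,
    default_codon_reference,
    dinucleotide_property_profile,
    feature_names,
    gc3s_composition,
    gc_content,
    kmer_frequencies,
    load_codon_usage,
    load_dinucleotide_properties,
    protein_properties,
    rho_statistic,
    zcurve_features,
)
from iaspls.seqio import DnaSequence

from oracle_utils import (
    dinuc_profile_oracle,
    gc_oracle,
    kmer_freq_oracle,
    random_dna,
    rho_oracle,
    zcurve_oracle,
)

DINUCS = ["".join(d) for d in itertools.product("ACGT", repeat=2)]


def seq(bases, ident="s"):
    return DnaSequence(ident, bases)


class TestKmerFrequencies:
    def test_poly_a_k1(self):
        np.testing.assert_array_equal(
            kmer_frequencies(seq("AAAA"), 1), [1.0, 0.0, 0.0, 0.0]
        )

    def test_acgt_k2(self):
        freqs = kmer_frequencies(seq("ACGT"), 2)
        expected = np.zeros(16)
        for m in ("AC", "CG", "GT"):
            idx = 4 * "ACGT".index(m[0]) + "ACGT".index(m[1])
            expected[idx] = 1 / 3
        np.testing.assert_allclose(freqs, expected)

    def test_matches_sliding_window_oracle(self, rng):
        bases = random_dna(rng, 1000)
        np.testing.assert_allclose(
            kmer_frequencies(seq(bases), 3), kmer_freq_oracle(bases, 3)
        )

    def test_ambiguous_windows_skipped(self):
        # windows covering the N are dropped from the denominator
        freqs = kmer_frequencies(seq("AANAA"), 2)
        assert freqs[0] == 1.0  # only AA windows remain

    def test_no_valid_window_error(self):
        with pytest.raises(DataError, match="nowin"):
            kmer_frequencies(seq("NNNN", "nowin"), 2)

    def test_invalid_k(self):
        with pytest.raises(DataError, match="k must"):
            kmer_frequencies(seq("ACGT"), 4)

    @given(st.text(alphabet="ACGT", min_size=3, max_size=200), st.sampled_from([1, 2, 3]))
    @settings(max_examples=50, deadline=None)
    def test_frequencies_sum_to_one(self, bases, k):
        freqs = kmer_frequencies(seq(bases), k)
        assert np.all(freqs >= 0) and np.all(freqs <= 1)
        assert freqs.sum() == pytest.approx(1.0)


class TestZcurve:
    def test_length_252(self):
        assert zcurve_features(seq("ACGTACGTACGT")).shape == (252,)

    def test_poly_a_k1_components(self):
        z = zcurve_features(seq("A" * 30))
        # phase-independent k=1 triple occupies the first three slots
        np.testing.assert_allclose(z[:3], [1.0, 1.0, 1.0])

    def test_balanced_sequence_k1_zero(self):
        z = zcurve_features(seq("ACGTACGTACGT"))
        np.testing.assert_allclose(z[:3], [0.0, 0.0, 0.0], atol=1e-12)

    def test_matches_counting_oracle(self, rng):
        for _ in range(10):
            bases = random_dna(rng, int(rng.integers(60, 400)))
            np.testing.assert_allclose(
                zcurve_features(seq(bases)), zcurve_oracle(bases), atol=1e-12
            )

    def test_oracle_with_ambiguity(self, rng):
        bases = random_dna(rng, 300, ambiguous_rate=0.05)
        np.testing.assert_allclose(
            zcurve_features(seq(bases)), zcurve_oracle(bases), atol=1e-12
        )

    def test_components_bounded(self, rng):
        z = zcurve_features(seq(random_dna(rng, 200)))
        assert np.all(z >= -1.0) and np.all(z <= 1.0)

    def test_too_short(self):
        with pytest.raises(DataError):
            zcurve_features(seq("AC"))


class TestGcContent:
    def test_all_gc(self):
        assert gc_content(seq("GGCC")) == 1.0

    def test_no_gc(self):
        assert gc_content(seq("ATAT")) == 0.0

    def test_matches_brute_force(self, rng):
        bases = random_dna(rng, 500, ambiguous_rate=0.05)
        assert gc_content(seq(bases)) == pytest.approx(gc_oracle(bases))

    def test_all_ambiguous(self):
        with pytest.raises(DataError):
            gc_content(seq("NNN"))


class TestGc3s:
    def test_hand_count(self):
        np.testing.assert_allclose(
            gc3s_composition(seq("ATGGCA")), [0.5, 0.0, 0.5, 0.0]
        )

    def test_poly_a(self):
        np.testing.assert_allclose(gc3s_composition(seq("AAAAAA")), [1, 0, 0, 0])

    def test_trailing_partial_codon_ignored(self):
        np.testing.assert_array_equal(
            gc3s_composition(seq("ATGGCAT")), gc3s_composition(seq("ATGGCA"))
        )

    def test_no_complete_codon(self):
        with pytest.raises(DataError):
            gc3s_composition(seq("AT"))

    def test_sums_to_one(self, rng):
        comp = gc3s_composition(seq(random_dna(rng, 99)))
        assert comp.sum() == pytest.approx(1.0)


class TestCodonUsageIndices:
    def test_all_optimal(self):
        ref = CodonReference(
            w={"GCA": 1.0, "GCG": 0.5}, optimal=frozenset({"GCA"})
        )
        fop, cai = codon_usage_indices(seq("GCAGCAGCA"), ref)
        assert fop == 1.0 and cai == pytest.approx(1.0)

    def test_identity_reference_gives_cai_one(self, rng):
        from iaspls.features import GENETIC_CODE

        ref = CodonReference(
            w={c: 1.0 for c in GENETIC_CODE}, optimal=frozenset()
        )
        bases = random_dna(rng, 300)
        _, cai = codon_usage_indices(seq(bases), ref)
        assert cai == pytest.approx(1.0)

    def test_toy_geometric_mean(self):
        ref = CodonReference(w={"GCA": 1.0, "GCG": 0.5}, optimal=frozenset({"GCA"}))
        fop, cai = codon_usage_indices(seq("GCAGCG"), ref)
        assert cai == pytest.approx(np.sqrt(0.5))
        assert fop == pytest.approx(0.5)

    def test_missing_reference(self):
        with pytest.raises(DataError, match="reference"):
            codon_usage_indices(seq("GCAGCA"), None)

    def test_zero_countable_codons(self):
        ref = CodonReference(w={"GCA": 1.0}, optimal=frozenset())
        with pytest.raises(DataError, match="countable"):
            codon_usage_indices(seq("TTTTTT"), ref)

    def test_from_counts_structure(self):
        counts = {"GCA": 10, "GCG": 5, "GCC": 0, "GCT": 0}
        ref = CodonReference.from_counts(counts)
        assert ref.w["GCA"] == 1.0
        assert ref.w["GCG"] == 0.5
        assert ref.w["GCC"] == 0.01  # floored
        assert "GCA" in ref.optimal
        # zero-count families are excluded entirely
        assert "TTT" not in ref.w

    def test_default_reference_loads(self):
        ref = default_codon_reference()
        assert all(0 < v <= 1 for v in ref.w.values())
        assert len(ref.optimal) > 10


class TestProteinProperties:
    def test_poly_phe_aromatic(self):
        hydro, arom = protein_properties(seq("TTT" * 5))
        assert arom == 1.0

    def test_poly_gly_not_aromatic(self):
        _, arom = protein_properties(seq("GGT" * 5))
        assert arom == 0.0

    def test_hydropathy_is_table_lookup(self):
        from Bio.SeqUtils.ProtParamData import kd

        hydro, _ = protein_properties(seq("TTT" * 5))
        assert hydro == pytest.approx(kd["F"])

    def test_stop_codons_skipped_not_truncating(self):
        # TAA in the middle: translation continues past it
        hydro1, _ = protein_properties(seq("TTTTAATTT"))
        hydro2, _ = protein_properties(seq("TTTTTT"))
        assert hydro1 == pytest.approx(hydro2)

    def test_all_stops_error(self):
        with pytest.raises(DataError):
            protein_properties(seq("TAATAG"))


class TestRho:
    def test_hand_count(self):
        rho = rho_statistic(seq("ACAC"))
        idx = DINUCS.index("AC")
        assert rho[idx] == pytest.approx((2 / 3) / 0.25)

    def test_absent_base_convention(self):
        rho = rho_statistic(seq("AGAGAG"))
        for i, d in enumerate(DINUCS):
            if "C" in d:
                assert rho[i] == 0.0

    def test_long_uniform_near_one(self):
        values = []
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            rho = rho_statistic(seq(random_dna(rng, 10_000)))
            values.append(rho)
        assert np.all(np.abs(np.array(values) - 1.0) < 0.15)

    def test_matches_oracle(self, rng):
        bases = random_dna(rng, 400, ambiguous_rate=0.05)
        np.testing.assert_allclose(rho_statistic(seq(bases)), rho_oracle(bases))


class TestDinucleotideProfile:
    def test_constant_property(self, rng):
        table = pd.DataFrame({"c5": [5.0] * 16, "c2": [2.0] * 16}, index=DINUCS)
        profile = dinucleotide_property_profile(seq(random_dna(rng, 100)), table)
        np.testing.assert_allclose(profile, [5.0, 2.0])

    def test_single_window_is_row(self):
        table = pd.DataFrame(
            np.arange(32, dtype=float).reshape(16, 2), index=DINUCS
        )
        profile = dinucleotide_property_profile(seq("AA"), table)
        np.testing.assert_allclose(profile, table.loc["AA"].to_numpy())

    def test_matches_window_average_oracle(self, rng):
        table = load_dinucleotide_properties()
        bases = random_dna(rng, 300, ambiguous_rate=0.05)
        np.testing.assert_allclose(
            dinucleotide_property_profile(seq(bases), table),
            dinuc_profile_oracle(bases, table),
        )

    def test_missing_dinucleotide_listed(self, rng):
        table = pd.DataFrame({"x": [1.0] * 15}, index=DINUCS[:-1])
        with pytest.raises(DataError, match="TT"):
            dinucleotide_property_profile(seq("ACGT"), table)


class TestFeatureMatrix:
    def test_default_width_426(self, rng):
        seqs = [seq(random_dna(rng, 90), f"s{i}") for i in range(3)]
        fm = build_feature_matrix(seqs)
        assert fm.shape == (3, 426)
        widths = block_widths(FeatureConfig())
        assert sum(widths.values()) == 426
        assert widths["zcurve"] == 252 and widths["kmer"] == 84

    def test_kmer_only_width_84(self, rng):
        config = FeatureConfig(enabled_blocks=("kmer",))
        fm = build_feature_matrix([seq(random_dna(rng, 90))], config)
        assert fm.shape[1] == 84

    def test_rows_in_input_order(self, rng):
        seqs = [seq(random_dna(rng, 90), f"s{i}") for i in range(4)]
        fm = build_feature_matrix(seqs)
        assert fm.row_ids == [s.id for s in seqs]

    def test_deterministic(self, rng):
        seqs = [seq(random_dna(rng, 120), f"s{i}") for i in range(3)]
        a = build_feature_matrix(seqs)
        b = build_feature_matrix(seqs)
        assert np.array_equal(a.values, b.values)
        assert a.column_names == b.column_names

    def test_column_names_pure_function_of_config(self):
        assert feature_names(FeatureConfig()) == feature_names(FeatureConfig())

    def test_block_order_canonicalized(self):
        config = FeatureConfig(enabled_blocks=("rho", "kmer"))
        assert config.enabled_blocks == ("kmer", "rho")

    def test_unknown_block(self):
        with pytest.raises(DataError, match="unknown"):
            FeatureConfig(enabled_blocks=("bogus",))

    def test_empty_input(self):
        with pytest.raises(DataError, match="zero sequences"):
            build_feature_matrix([])

    def test_failure_names_sequence_and_block(self):
        bad = DnaSequence("shorty", "AANAANAANAAN")  # no valid codon window
        with pytest.raises(DataError, match=r"shorty.*zcurve"):
            build_feature_matrix([bad, bad])

    def test_no_nan_inf(self, random_sequences):
        fm = build_feature_matrix(random_sequences[:20])
        assert np.isfinite(fm.values).all()

    def test_tsv_round_trip(self, tmp_path, rng):
        seqs = [seq(random_dna(rng, 90), f"s{i}") for i in range(3)]
        fm = build_feature_matrix(seqs, FeatureConfig(enabled_blocks=("kmer", "rho")))
        path = tmp_path / "features.tsv"
        fm.to_tsv(path)
        back = FeatureMatrix.from_tsv(path)
        assert back.column_names == fm.column_names
        assert back.row_ids == fm.row_ids
        np.testing.assert_allclose(back.values, fm.values, rtol=1e-10)

    def test_reference_built_from_positive_labels(self, rng):
        seqs = [
            DnaSequence("p", "GCAGCAGCAGCAGCAGCA" * 4, label=1),
            DnaSequence("n", random_dna(rng, 72), label=-1),
        ]
        fm = build_feature_matrix(seqs, FeatureConfig(enabled_blocks=("gc_cai",)))
        cai_col = fm.column_names.index("cai")
        assert fm.values[0, cai_col] == pytest.approx(1.0)

    def test_usage_table_normalized(self):
        usage = load_codon_usage()
        assert sum(usage.values()) == pytest.approx(1.0)
        assert len(usage) == 64


class TestBlockOracles:
    """Every block agrees with its naive reimplementation on random data."""

    def test_all_blocks_on_random_sequences(self, random_sequences):
        table = load_dinucleotide_properties()
        for s in random_sequences[:25]:
            np.testing.assert_allclose(
                zcurve_features(s), zcurve_oracle(s.bases), atol=1e-12
            )
            for k in (1, 2, 3):
                np.testing.assert_allclose(
                    kmer_frequencies(s, k), kmer_freq_oracle(s.bases, k)
                )
            assert gc_content(s) == pytest.approx(gc_oracle(s.bases))
            np.testing.assert_allclose(rho_statistic(s), rho_oracle(s.bases))
            np.testing.assert_allclose(
                dinucleotide_property_profile(s, table),
                dinuc_profile_oracle(s.bases, table),
            )
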