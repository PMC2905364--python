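import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gigatree.alignment import (
    AlignmentError,
    FamilyAlignment,
    SaturationError,
    compute_weights,
    jc_distance,
    jc_stddev,
    pairwise_distances,
    species_from_id,
    trim_alignment,
)

from conftest import make_alignment


class TestFamilyAlignment:
    def test_species_from_uniprot_style_suffix(self):
        assert species_from_id("MTHFR_HUMAN") == "HUMAN"
        assert species_from_id("ABC1_XYZ_MOUSE") == "MOUSE"

    def test_id_without_separator_rejected(self):
        with pytest.raises(AlignmentError):
            species_from_id("noseparator")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError, match="unequal"):
            make_alignment({"a_SP": "AC", "b_SQ": "ACD"})

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError, match="unique"):
            FamilyAlignment(["a_SP", "a_SP"], ["SP", "SP"], ["AC", "AC"])


class TestWeights:
    def test_identical_sequences_uniform(self):
        aln = make_alignment({f"s{i}_SP{i}": "ACDEF" for i in range(4)})
        w = compute_weights(aln)
        assert all(abs(w[i] - 1.0) < 1e-12 for i in aln.ids)

    def test_single_sequence(self):
        w = compute_weights(make_alignment({"s_SP": "ACD"}))
        assert w["s_SP"] == pytest.approx(1.0)

    def test_divergent_sequence_upweighted(self):
        aln = make_alignment(
            {
                "a_S1": "ACDEFGHIKL",
                "b_S2": "ACDEFGHIKL",
                "c_S3": "ACDEFGHIKL",
                "t_S4": "MNPQRSTVWY",
            }
        )
        w = compute_weights(aln)
        assert w["t_S4"] > w["a_S1"]
        assert w["a_S1"] == pytest.approx(w["b_S2"])
        assert sum(w.weights.values()) == pytest.approx(4.0)


class TestTrim:
    def test_gapless_alignment_fully_kept(self):
        aln = make_alignment({"a_S1": "ACDEF", "b_S2": "ACDEV"})
        trimmed = trim_alignment(aln, compute_weights(aln))
        assert trimmed.kept_columns == [0, 1, 2, 3, 4]

    def test_quarter_gapped_column_removed(self):
        aln = make_alignment(
            {"a_S1": "ACD", "b_S2": "A-D", "c_S3": "ACD", "d_S4": "ACD"}
        )
        # equal weights: gap fraction 0.25 > 0.15 at column 1
        trimmed = trim_alignment(aln, compute_weights(aln))
        assert trimmed.kept_columns == [0, 2]

    def test_tenth_gapped_column_kept(self):
        records = {f"s{i}_SP{i:02d}": "ACD" for i in range(9)}
        records["g_SP99"] = "A-D"
        aln = make_alignment(records)
        trimmed = trim_alignment(aln, compute_weights(aln))
        assert trimmed.kept_columns == [0, 1, 2]

    def test_trimming_idempotent(self):
        aln = make_alignment(
            {"a_S1": "AC-DE", "b_S2": "A--DE", "c_S3": "ACDDE", "d_S4": "AC.DE"}
        )
        weights = compute_weights(aln)
        first = trim_alignment(aln, weights)
        again_aln = FamilyAlignment(
            list(first.ids),
            list(first.species),
            ["".join(s[j] for j in first.kept_columns) for s in aln.sequences],
        )
        second = trim_alignment(again_aln, weights)
        assert second.kept_columns == list(range(first.length))

    def test_ambiguity_characters_count_as_gaps(self):
        aln = make_alignment(
            {"a_S1": "AXD", "b_S2": "ABD", "c_S3": "AZD", "d_S4": "A*D"}
        )
        trimmed = trim_alignment(aln, compute_weights(aln))
        assert trimmed.kept_columns == [0, 2]


class TestPairwiseDistances:
    def test_identical_sequences_zero(self):
        trimmed = trim_alignment(
            (aln := make_alignment({"a_S1": "ACDEF", "b_S2": "ACDEF"})),
            compute_weights(aln),
        )
        dm = pairwise_distances(trimmed)
        assert dm.p[0, 1] == 0.0
        assert dm.n[0, 1] == 5

    def test_one_difference_in_three(self):
        aln = make_alignment({"a_S1": "AAC", "b_S2": "ADC"})
        dm = pairwise_distances(trim_alignment(aln, compute_weights(aln)))
        assert dm.p[0, 1] == pytest.approx(1 / 3)
        assert dm.n[0, 1] == 3

    def test_pairwise_complete_sites_only(self):
        # gap column survives trimming at threshold-friendly weights is not
        # needed: build the trimmed matrix directly from an ungapped pair plus
        # a permissive config
        aln = make_alignment({"a_S1": "A-C", "b_S2": "ADC", "c_S3": "ADC",
                              "d_S4": "ADC", "e_S5": "ADC", "f_S6": "ADC",
                              "g_S7": "ADC"})
        dm = pairwise_distances(trim_alignment(aln, compute_weights(aln)))
        assert dm.n[0, 1] == 2  # columns 1 and 3 of the original pair
        assert dm.p[0, 1] == 0.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        seqs = {
            f"s{i}_SP{i:02d}": "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30)
            )
            for i in range(6)
        }
        dm = pairwise_distances(
            trim_alignment((aln := make_alignment(seqs)), compute_weights(aln))
        )
        assert np.allclose(dm.p, dm.p.T)
        assert (dm.p >= 0).all() and (dm.p <= 1).all()
        assert (np.diag(dm.p) == 0).all()


class TestJukesCantor:
    def test_zero_distance(self):
        assert jc_distance(0.0) == 0.0
        assert jc_stddev(0.0, 100) == 0.0

    def test_protein_closed_form(self):
        # d = -(19/20) ln(1 - (20/19) * 0.1), evaluated independently
        assert jc_distance(0.1, 20) == pytest.approx(0.105664353354713, abs=1e-12)

    def test_nucleotide_closed_form(self):
        assert jc_distance(0.3, 4) == pytest.approx(
            -0.75 * math.log(1 - 0.3 / 0.75), abs=1e-12
        )

    def test_stddev_closed_form(self):
        expected = math.sqrt(0.1 * 0.9 / (100 * (1 - 0.1 * 20 / 19) ** 2))
        assert jc_stddev(0.1, 100, 20) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.03353, abs=1e-5)

    def test_quadrupling_sites_halves_stddev(self):
        assert jc_stddev(0.2, 400) == pytest.approx(jc_stddev(0.2, 100) / 2)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jc_distance(0.95, 20)
        with pytest.raises(SaturationError):
            jc_stddev(0.96, 100, 20)

    def test_zero_sites_raises(self):
        with pytest.raises(ValueError):
            jc_stddev(0.1, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p=st.floats(0.0, 0.949), n=st.integers(1, 10_000))
    def test_correction_dominates_p_and_sd_decreases_in_n(self, p, n):
        assert jc_distance(p, 20) >= p - 1e-15  # float slack at denormal p
        assert jc_stddev(p, n, 20) >= jc_stddev(p, n + 1, 20)
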