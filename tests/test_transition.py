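import numpy as np
import pytest

from mtrap.alphabet import N_PAIRS, pair_code, pair_code_from_label
from mtrap.simulate import GeneratorSpec, synthetic_markov_corpus
from mtrap.transition import (
    CorpusError,
    TransitionCounts,
    TransitionMatrixError,
    build_transition_matrix,
    compute_sequence_weights,
    count_transitions,
    estimate_transition_probabilities,
    read_transition_matrix,
    train_transition_matrix,
    write_transition_matrix,
)


class TestSequenceWeights:
    def test_unique_sequences_have_unit_weight(self):
        corpus = compute_sequence_weights([("AC", "DE"), ("FG", "HI")])
        assert all(w == 1.0 for w in corpus.weight.values())

    @pytest.mark.parametrize("copies,expected", [(4, 0.5), (2, 2 ** -0.5)])
    def test_repeated_sequence_downweighted(self, copies, expected):
        alignments = [("ACDE", f"AC{x}E") for x in "EFGH"[:copies]]
        corpus = compute_sequence_weights(alignments)
        assert corpus.multiplicity["ACDE"] == copies
        assert corpus.weight["ACDE"] == pytest.approx(expected)

    def test_multiplicity_counts_degapped_strings(self):
        corpus = compute_sequence_weights([("A-CD", "AECD"), ("ACD", "AFE")])
        assert corpus.multiplicity["ACD"] == 2

    def test_empty_corpus_rejected(self):
        with pytest.raises(CorpusError, match="empty"):
            compute_sequence_weights([])

    def test_gap_gap_column_rejected(self):
        with pytest.raises(CorpusError, match="gap-gap"):
            compute_sequence_weights([("A-C", "A-C")])


class TestCountTransitions:
    def test_single_adjacent_pair_counted_with_swap(self):
        corpus = compute_sequence_weights([("AC", "DE")])
        counts = count_transitions(corpus).counts
        assert counts[pair_code("A", "D"), pair_code("C", "E")] == pytest.approx(1.0)
        assert counts[pair_code("D", "A"), pair_code("E", "C")] == pytest.approx(1.0)
        assert counts.sum() == pytest.approx(2.0)

    def test_identical_members_count_as_two_occurrences(self):
        # both members degap to "AC": multiplicity 2, pair weight 1/2,
        # and the swap lands on the same symmetric entry
        corpus = compute_sequence_weights([("AC", "AC")])
        assert corpus.weight["AC"] == pytest.approx(2 ** -0.5)
        counts = count_transitions(corpus).counts
        assert counts[pair_code("A", "A"), pair_code("C", "C")] == pytest.approx(1.0)

    def test_gap_columns_counted_with_swaps(self):
        corpus = compute_sequence_weights([("A-C", "AGC")])
        counts = count_transitions(corpus).counts
        aa, gap_g = pair_code("A", "A"), pair_code("-", "G")
        g_gap, cc = pair_code("G", "-"), pair_code("C", "C")
        assert counts[aa, gap_g] == pytest.approx(1.0)
        assert counts[gap_g, cc] == pytest.approx(1.0)
        assert counts[aa, g_gap] == pytest.approx(1.0)  # swapped orientation
        assert counts[g_gap, cc] == pytest.approx(1.0)
        assert counts.sum() == pytest.approx(4.0)

    def test_length_one_alignments_yield_no_transitions(self):
        corpus = compute_sequence_weights([("A", "C"), ("D", "E")])
        assert count_transitions(corpus).counts.sum() == 0.0

    def test_swapping_all_members_leaves_counts_unchanged(self):
        alignments = [("AC-DE", "AFGD-"), ("GGH", "G-H")]
        fwd = count_transitions(compute_sequence_weights(alignments)).counts
        rev = count_transitions(
            compute_sequence_weights([(b, a) for a, b in alignments])
        ).counts
        assert np.allclose(fwd, rev)


class TestEstimateProbabilities:
    def _counts(self, entries):
        counts = np.zeros((N_PAIRS, N_PAIRS))
        for (u, v), value in entries.items():
            counts[pair_code_from_label(u), pair_code_from_label(v)] = value
        return TransitionCounts(counts)

    def test_equal_weights_split_evenly(self):
        probs = estimate_transition_probabilities(
            self._counts({("AA", "CC"): 1.0, ("AA", "DD"): 1.0}), pseudocount=0.0
        )
        u = pair_code_from_label("AA")
        assert probs.probs[u, pair_code_from_label("CC")] == pytest.approx(0.5)
        assert probs.probs[u, pair_code_from_label("DD")] == pytest.approx(0.5)

    def test_three_to_one_split(self):
        probs = estimate_transition_probabilities(
            self._counts({("AA", "CC"): 3.0, ("AA", "DD"): 1.0}), pseudocount=0.0
        )
        assert probs.probs[pair_code_from_label("AA"), pair_code_from_label("CC")] == pytest.approx(0.75)

    def test_supported_rows_sum_to_one(self):
        probs = estimate_transition_probabilities(
            self._counts({("AA", "CC"): 2.5, ("A-", "-C"): 0.7}), pseudocount=1.0
        )
        sums = probs.probs[probs.support].sum(axis=1)
        assert np.all(np.abs(sums - 1.0) < 1e-12)

    def test_support_requires_raw_observations(self):
        probs = estimate_transition_probabilities(
            self._counts({("AA", "CC"): 1.0}), pseudocount=1.0
        )
        assert probs.support.sum() == 1  # smoothing creates no new support

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            estimate_transition_probabilities(self._counts({}), pseudocount=-0.1)


class TestBuildTransitionMatrix:
    def test_two_point_row_maps_to_endpoints(self):
        counts = np.zeros((N_PAIRS, N_PAIRS))
        u = pair_code_from_label("AA")
        counts[u, pair_code_from_label("CC")] = 3.0
        counts[u, pair_code_from_label("DD")] = 1.0
        probs = estimate_transition_probabilities(TransitionCounts(counts), 0.0)
        t = build_transition_matrix(probs)
        assert t.quantity(u, pair_code_from_label("CC")) == 0.0  # most probable
        assert t.quantity(u, pair_code_from_label("DD")) == 1.0  # least probable

    def test_uniform_row_is_uninformative(self):
        counts = np.zeros((N_PAIRS, N_PAIRS))
        u = pair_code_from_label("AA")
        for lbl in ("CC", "DD", "EE"):
            counts[u, pair_code_from_label(lbl)] = 2.0
        probs = estimate_transition_probabilities(TransitionCounts(counts), 0.0)
        t = build_transition_matrix(probs)
        for lbl in ("CC", "DD", "EE"):
            assert t.quantity(u, pair_code_from_label(lbl)) == 0.0

    def test_unobserved_rows_and_zero_prob_targets_fill_with_one(self):
        counts = np.zeros((N_PAIRS, N_PAIRS))
        u = pair_code_from_label("AA")
        counts[u, pair_code_from_label("CC")] = 1.0
        counts[u, pair_code_from_label("DD")] = 2.0
        probs = estimate_transition_probabilities(TransitionCounts(counts), 0.0)
        t = build_transition_matrix(probs)
        assert t.quantity(pair_code_from_label("WW"), pair_code_from_label("AA")) == 1.0
        assert t.quantity(u, pair_code_from_label("YY")) == 1.0  # p = 0 target

    def test_quantities_within_unit_interval(self):
        alignments = [("ACDEFG", "ACD-FG"), ("KLMN", "KLMN"), ("WYV", "W-V")]
        t = train_transition_matrix(alignments, pseudocount=1.0)
        assert t.quantities.min() >= 0.0 and t.quantities.max() <= 1.0


class TestEstimatorProperties:
    def test_corpus_swap_symmetry(self):
        alignments = [("AC-DE", "AFGD-"), ("GGHKL", "G-HK-"), ("MNP", "MNP")]
        t_fwd = train_transition_matrix(alignments, 1.0)
        t_rev = train_transition_matrix([(b, a) for a, b in alignments], 1.0)
        assert np.allclose(t_fwd.quantities, t_rev.quantities, atol=1e-12)

    def test_duplicating_corpus_4x_halves_weights_and_keeps_probs(self):
        alignments = [("ACDE", "AC-E"), ("FGHI", "FGHI")]
        base = compute_sequence_weights(alignments)
        quad = compute_sequence_weights(alignments * 4)
        for seq, w in base.weight.items():
            assert quad.weight[seq] == pytest.approx(w / 2.0)
        p_base = estimate_transition_probabilities(count_transitions(base), 0.0)
        p_quad = estimate_transition_probabilities(count_transitions(quad), 0.0)
        assert np.allclose(p_base.probs, p_quad.probs, atol=1e-12)

    def test_parameter_recovery_on_markov_corpus(self, markov_truth_and_corpus):
        """p̂ within 0.02 of truth at >= 1e5 adjacent-pair observations."""
        truth, alignments = markov_truth_and_corpus
        counts = count_transitions(compute_sequence_weights(alignments))
        probs = estimate_transition_probabilities(counts, pseudocount=0.0)
        max_err = 0.0
        for src, row in truth.items():
            u = pair_code_from_label(src)
            for dst, p_true in row.items():
                p_hat = probs.probs[u, pair_code_from_label(dst)]
                max_err = max(max_err, abs(p_hat - p_true))
        assert max_err < 0.02


class TestSerialization:
    def test_round_trip(self, tmp_path):
        t = train_transition_matrix([("ACDE", "AC-E"), ("FGHI", "FGHI")], 1.0,
                                    metadata={"corpus": "unit-test"})
        path = tmp_path / "t.tsv"
        write_transition_matrix(t, path)
        back = read_transition_matrix(path)
        assert np.allclose(back.quantities, t.quantities, atol=1e-12)
        assert back.metadata["corpus"] == "unit-test"

    def test_out_of_range_value_rejected(self, tmp_path):
        t = train_transition_matrix([("ACDE", "AC-E")], 1.0)
        path = tmp_path / "t.tsv"
        write_transition_matrix(t, path)
        text = path.read_text().replace("\t1\t", "\t1.5\t", 1)
        path.write_text(text)
        with pytest.raises(TransitionMatrixError, match=r"\[0, 1\]"):
            read_transition_matrix(path)

    def test_truncated_payload_rejected(self, tmp_path):
        t = train_transition_matrix([("ACDE", "AC-E")], 1.0)
        path = tmp_path / "t.tsv"
        write_transition_matrix(t, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop one pair row
        with pytest.raises(TransitionMatrixError, match="expected"):
            read_transition_matrix(path)


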