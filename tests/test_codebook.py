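"""Codebook construction and decoding, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest

from cortexmap.codebook import (BLANK, Codebook, assign_genes, build_codebook,
                                decode_trace, decode_traces,
                                estimate_misidentification, read_codebook_csv,
                                write_codebook_csv)
from cortexmap.synthetic import generate_traces


def hamming(a, b):
    return int(np.sum(np.asarray(a) != np.asarray(b)))


def exhaustive_max_code(n_bits, weight, min_distance):
    """Oracle: maximum constant-weight code size by exhaustive search
    (only feasible for tiny parameters)."""
    words = [np.array(w) for w in itertools.product([0, 1], repeat=n_bits)
             if sum(w) == weight]
    best = 0
    # branch and bound over subsets, lexicographic
    def extend(sel, start):
        nonlocal best
        best = max(best, len(sel))
        for i in range(start, len(words)):
            if all(hamming(words[i], s) >= min_distance for s in sel):
                extend(sel + [words[i]], i + 1)
    extend([], 0)
    return best


class TestBuild:
    def test_single_weight4_word_on_4_bits(self):
        cb = build_codebook(n_bits=4, weight=4, min_distance=4,
                            n_codewords_requested=1, n_restarts=1, n_improve=0)
        assert len(cb) == 1
        assert cb.codewords.tolist() == [[1, 1, 1, 1]]

    def test_six_bit_code_attains_exhaustive_maximum(self):
        # C(6,3) = 20 candidate words; the true maximum is found by brute force
        oracle = exhaustive_max_code(6, 3, 4)
        assert oracle == 4
        with pytest.warns(UserWarning, match="attained"):
            cb = build_codebook(n_bits=6, weight=3, min_distance=4,
                                n_codewords_requested=10, seed=0)
        assert len(cb) == oracle
        cb.validate()

    def test_infeasible_parameters_raise(self):
        with pytest.raises(ValueError):
            build_codebook(n_bits=4, weight=6, min_distance=4)
        with pytest.raises(ValueError):
            build_codebook(min_distance=3)  # odd distance

    def test_deterministic_given_seed(self):
        a = build_codebook(n_codewords_requested=100, seed=3, n_restarts=2,
                           n_improve=2)
        b = build_codebook(n_codewords_requested=100, seed=3, n_restarts=2,
                           n_improve=2)
        assert np.array_equal(a.codewords, b.codewords)

    def test_invariants_checked_exhaustively(self, small_codebook):
        C = small_codebook.codewords
        assert np.all(C.sum(axis=1) == 4)
        for i in range(len(C)):
            for j in range(i + 1, len(C)):
                assert hamming(C[i], C[j]) >= 4


class TestAssign:
    def test_blank_arithmetic(self, small_codebook):
        assert small_codebook.n_blanks == 60
        assert len(small_codebook.genes) == len(small_codebook) - 60

    def test_zero_genes_all_blank(self, small_codebook):
        cb = assign_genes(small_codebook, [])
        assert cb.n_blanks == len(cb)

    def test_small_book_three_genes_one_blank(self):
        cb = build_codebook(n_bits=6, weight=3, min_distance=4,
                            n_codewords_requested=4, n_restarts=1, n_improve=0)
        cb = assign_genes(cb, ["a", "b", "c"])
        assert cb.n_blanks == 1

    def test_too_many_genes_raise(self):
        cb = build_codebook(n_bits=6, weight=3, min_distance=4,
                            n_codewords_requested=4, n_restarts=1, n_improve=0)
        with pytest.raises(ValueError):
            assign_genes(cb, [f"g{i}" for i in range(len(cb) + 1)])


class TestDecode:
    def test_exact_codeword_zero_corrections(self, small_codebook):
        res = decode_trace(small_codebook.codewords[0].astype(float),
                           small_codebook)
        assert res.label == small_codebook.assignment[0]
        assert res.corrected_bits == 0
        assert res.distance < 1e-12

    def test_every_single_bit_flip_recovered(self, small_codebook):
        """Min distance 4 makes radius-1 Hamming balls disjoint, so all
        single flips must decode to the original codeword — exhaustively."""
        C = small_codebook.codewords
        flips, truth = [], []
        for i in range(len(C)):
            for b in range(C.shape[1]):
                t = C[i].astype(float).copy()
                t[b] = 1 - t[b]
                flips.append(t)
                truth.append(small_codebook.assignment[i])
        res = decode_traces(np.array(flips), small_codebook)
        assert (res["label"].to_numpy() == np.array(truth, dtype=object)).all()
        assert (res["corrected_bits"] == 1).all()

    def test_all_zero_trace_rejected(self, small_codebook):
        # unit-normalization is undefined at 0; distance to every codeword is 1
        res = decode_trace(np.zeros(24), small_codebook)
        assert res.rejected

    def test_two_bit_moved_error_rejected(self, small_codebook):
        t = small_codebook.codewords[0].astype(float).copy()
        on = np.where(t == 1)[0][0]
        off = np.where(t == 0)[0][0]
        t[on], t[off] = 0, 1
        coincides = bool((small_codebook.codewords == t).all(axis=1).any())
        res = decode_trace(t, small_codebook)
        # a moved bit either lands exactly on another codeword or is rejected
        assert res.rejected != coincides

    def test_wrong_trace_length_raises(self, small_codebook):
        with pytest.raises(ValueError):
            decode_trace(np.ones(23), small_codebook)

    def test_decoder_agrees_with_bruteforce_oracle(self, small_codebook, rng):
        """Vectorized nearest-barcode search against a plain loop."""
        traces = rng.uniform(0, 1.2, size=(1000, 24))
        res = decode_traces(traces, small_codebook, max_distance_threshold=2.0)
        Cn = small_codebook.codewords / np.linalg.norm(
            small_codebook.codewords, axis=1, keepdims=True)
        for t, (_, row) in zip(traces, res.iterrows()):
            tn = t / np.linalg.norm(t)
            d = np.linalg.norm(Cn - tn, axis=1)
            assert np.isclose(row["distance"], d.min(), atol=1e-9)


class TestMisidentification:
    def test_no_noise_no_blank_hits(self, small_codebook):
        gene_ids = [i for i, a in enumerate(small_codebook.assignment)
                    if a != BLANK]
        traces, _ = generate_traces(small_codebook, gene_ids, seed=0)
        summary = estimate_misidentification(
            decode_traces(traces, small_codebook), small_codebook)
        assert summary["blank_mean_count"] == 0
        assert summary["gene_mean_count"] > 0

    def test_two_bit_errors_hit_blanks(self, small_codebook, rng):
        gene_ids = [i for i, a in enumerate(small_codebook.assignment)
                    if a != BLANK]
        ids = list(rng.choice(gene_ids, size=4000))
        traces, _ = generate_traces(small_codebook, ids, flip_prob_10=0.08,
                                    flip_prob_01=0.08, seed=1)
        summary = estimate_misidentification(
            decode_traces(traces, small_codebook), small_codebook)
        assert summary["blank_mean_count"] > 0

    def test_ratio_decreases_as_threshold_tightens(self, small_codebook, rng):
        gene_ids = [i for i, a in enumerate(small_codebook.assignment)
                    if a != BLANK]
        ids = list(rng.choice(gene_ids, size=4000))
        traces, _ = generate_traces(small_codebook, ids, flip_prob_10=0.08,
                                    flip_prob_01=0.04, intensity_noise=0.15,
                                    seed=2)
        ratios = []
        for thr in (0.7, 0.52, 0.35):
            res = decode_traces(traces, small_codebook,
                                max_distance_threshold=thr)
            if (res["label"] != "rejected").sum() == 0:
                continue
            ratios.append(estimate_misidentification(
                res, small_codebook)["blank_gene_ratio"])
        assert all(b <= a + 1e-12 for a, b in zip(ratios, ratios[1:]))

    def test_zero_events_raise(self, small_codebook):
        import pandas as pd
        empty = pd.DataFrame({"label": ["rejected"], "distance": [1.0],
                              "corrected_bits": [0]})
        with pytest.raises(ValueError):
            estimate_misidentification(empty, small_codebook)


def test_csv_round_trip(tmp_path, small_codebook):
    path = tmp_path / "codebook.csv"
    write_codebook_csv(small_codebook, path)
    back = read_codebook_csv(path)
    assert np.array_equal(back.codewords, small_codebook.codewords)
    assert back.assignment == small_codebook.assignment
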