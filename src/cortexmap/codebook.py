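"""Error-robust barcode codebooks and trace decoding.

MERFISH reads each RNA species as a binary barcode over hybridization
rounds.  Barcodes form a constant-weight code with a minimum pairwise
Hamming distance of 4, which makes every single-bit readout error
correctable (radius-1 Hamming balls around codewords are disjoint) and
every two-bit error detectable.  Codewords left unassigned to genes
("blanks") measure the false-positive rate of decoding.

The code construction here is a greedy search over all weight-`w` words
with randomized restarts, optionally refined by a ruin-and-recreate local
search.  Two weight-`w` words are at Hamming distance >= 4 exactly when
their supports share at most ``w - 2`` positions, which is the check used
throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BLANK = "blank"

__all__ = [
    "BLANK",
    "Codebook",
    "DecodeResult",
    "build_codebook",
    "assign_genes",
    "decode_trace",
    "decode_traces",
    "estimate_misidentification",
    "write_codebook_csv",
    "read_codebook_csv",
]


@dataclass
class Codebook:
    """A set of binary barcodes with weight/distance guarantees.

    Attributes
    ----------
    n_bits, weight, min_distance
        Code parameters (default scheme: 24 bits, weight 4, distance 4).
    codewords
        ``(n_codewords, n_bits)`` uint8 array of 0/1 vectors.
    assignment
        Per-codeword label: a gene name or :data:`BLANK`.
    """

    n_bits: int
    weight: int
    min_distance: int
    codewords: np.ndarray
    assignment: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codewords = np.asarray(self.codewords, dtype=np.uint8)
        if not self.assignment:
            self.assignment = [BLANK] * len(self.codewords)

    def __len__(self) -> int:
        return len(self.codewords)

    @property
    def genes(self) -> list[str]:
        return [a for a in self.assignment if a != BLANK]

    @property
    def n_blanks(self) -> int:
        return sum(a == BLANK for a in self.assignment)

    def validate(self) -> None:
        """Exhaustively check the weight and pairwise-distance invariants."""
        w = self.codewords.sum(axis=1)
        if not np.all(w == self.weight):
            raise ValueError("codeword with wrong Hamming weight")
        C = self.codewords.astype(np.int32)
        overlap = C @ C.T
        np.fill_diagonal(overlap, 0)
        # distance = 2*(weight - overlap) for equal-weight words
        if overlap.size and overlap.max() > self.weight - self.min_distance // 2:
            raise ValueError("codeword pair below minimum Hamming distance")
        if len(self.assignment) != len(self.codewords):
            raise ValueError("assignment does not cover all codewords")
        genes = self.genes
        if len(genes) != len(set(genes)):
            raise ValueError("duplicate gene labels")


@dataclass
class DecodeResult:
    """Per-trace decoding outcome.

    ``label`` is the matched gene/blank name or ``"rejected"``;
    ``distance`` the Euclidean distance between unit-normalized trace and
    best codeword; ``corrected_bits`` the number of bits (0 or 1) by which
    the binarized trace differed from the matched codeword.
    """

    label: str
    distance: float
    corrected_bits: int

    @property
    def rejected(self) -> bool:
        return self.label == "rejected"


def _all_weight_words(n_bits: int, weight: int) -> np.ndarray:
    combos = list(itertools.combinations(range(n_bits), weight))
    M = np.zeros((len(combos), n_bits), dtype=np.int32)
    for i, c in enumerate(combos):
        M[i, list(c)] = 1
    return M


def _greedy(words: np.ndarray, order: np.ndarray, max_overlap: int,
            seed_sel: list[int] | None = None) -> list[int]:
    sel = list(seed_sel) if seed_sel else []
    S = words[sel] if sel else np.zeros((0, words.shape[1]), dtype=np.int32)
    selected = set(sel)
    for i in order:
        if i in selected:
            continue
        c = words[i]
        if S.shape[0] == 0 or int((S @ c).max()) <= max_overlap:
            sel.append(int(i))
            S = np.vstack([S, c])
    return sel


def build_codebook(n_bits: int = 24, weight: int = 4, min_distance: int = 4,
                   n_codewords_requested: int = 476, seed: int = 0,
                   n_restarts: int = 20, n_improve: int = 100) -> Codebook:
    """Search for a constant-weight, minimum-distance code.

    Greedy accumulation over all ``C(n_bits, weight)`` candidate words in
    lexicographic order plus ``n_restarts - 1`` shuffled orders, keeping
    the largest code found; then ``n_improve`` ruin-and-recreate rounds
    (drop a random ~6% of codewords and re-greedy) that never shrink the
    code.  Deterministic for a fixed seed.

    The search stops early once ``n_codewords_requested`` is reached.  If
    the budget is exhausted below the request a warning reports the
    attained size; the codebook is still returned and valid.
    """
    if weight > n_bits:
        raise ValueError(f"weight {weight} exceeds n_bits {n_bits}")
    if min_distance < 2 or min_distance % 2 != 0:
        raise ValueError("min_distance must be even and >= 2")
    if n_codewords_requested < 1:
        raise ValueError("n_codewords_requested must be >= 1")
    max_overlap = weight - min_distance // 2
    if max_overlap < 0:
        raise ValueError(
            f"min_distance {min_distance} unattainable at weight {weight}")
    words = _all_weight_words(n_bits, weight)
    rng = np.random.default_rng(seed)

    best = _greedy(words, np.arange(len(words)), max_overlap)
    for _ in range(max(0, n_restarts - 1)):
        if len(best) >= n_codewords_requested:
            break
        cand = _greedy(words, rng.permutation(len(words)), max_overlap)
        if len(cand) > len(best):
            best = cand
    for _ in range(n_improve):
        if len(best) >= n_codewords_requested:
            break
        keep = [i for i in best if rng.random() > 0.06]
        cand = _greedy(words, rng.permutation(len(words)), max_overlap, keep)
        if len(cand) >= len(best):
            best = cand

    if len(best) > n_codewords_requested:
        best = best[:n_codewords_requested]
    if len(best) < n_codewords_requested:
        warnings.warn(
            f"codebook search attained {len(best)} codewords, below the "
            f"requested {n_codewords_requested}; scale the gene panel to fit",
            stacklevel=2)
    cb = Codebook(n_bits=n_bits, weight=weight, min_distance=min_distance,
                  codewords=words[best].astype(np.uint8))
    cb.validate()
    return cb


def assign_genes(codebook: Codebook, gene_names: list[str], seed: int = 0) -> Codebook:
    """Assign genes to a seed-shuffled subset of codewords; rest are blanks."""
    if len(gene_names) > len(codebook):
        raise ValueError(
            f"{len(gene_names)} genes exceed {len(codebook)} codewords")
    if len(set(gene_names)) != len(gene_names):
        raise ValueError("gene names must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(codebook))
    assignment = [BLANK] * len(codebook)
    for g, i in zip(gene_names, order):
        assignment[i] = g
    return Codebook(n_bits=codebook.n_bits, weight=codebook.weight,
                    min_distance=codebook.min_distance,
                    codewords=codebook.codewords.copy(),
                    assignment=assignment)


def _unit_rows(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


# Euclidean distance on unit-normalized vectors: 0.52 accepts a weight-4
# word with one bit flipped (distance ~0.518 for a 1->0 flip, ~0.460 for
# 0->1) and rejects two-bit errors (>= ~0.7).
DEFAULT_DISTANCE_THRESHOLD = 0.52


def decode_traces(traces: np.ndarray, codebook: Codebook,
                  max_distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
                  ) -> pd.DataFrame:
    """Match each intensity trace to its nearest codeword.

    Both traces and codewords are L2-normalized; a trace is matched to the
    codeword at minimum Euclidean distance, and rejected if that distance
    exceeds the threshold or if the binarized trace differs from the match
    in more than one bit (keeping the single-error-correction contract).

    Returns a DataFrame with columns ``label``, ``distance``,
    ``corrected_bits``.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[1] != codebook.n_bits:
        raise ValueError(
            f"trace length {traces.shape[1]} != n_bits {codebook.n_bits}")
    C = _unit_rows(codebook.codewords.astype(float))
    T = _unit_rows(traces)
    # squared distances via the Gram trick; rows all unit norm
    d2 = np.maximum(2.0 - 2.0 * (T @ C.T), 0.0)
    best = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(T)), best])
    binar = (traces >= 0.5).astype(np.int8)
    hamming = np.abs(binar - codebook.codewords[best].astype(np.int8)).sum(axis=1)
    ok = (dist <= max_distance_threshold) & (hamming <= 1)
    labels = np.where(ok, np.asarray(codebook.assignment, dtype=object)[best],
                      "rejected")
    return pd.DataFrame({
        "label": labels,
        "distance": dist,
        "corrected_bits": np.where(ok, hamming, 0).astype(int),
    })


def decode_trace(trace: np.ndarray, codebook: Codebook,
                 max_distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
                 ) -> DecodeResult:
    """Decode a single 24-value trace (see :func:`decode_traces`)."""
    row = decode_traces(np.asarray(trace, dtype=float)[None, :], codebook,
                        max_distance_threshold).iloc[0]
    return DecodeResult(label=row["label"], distance=float(row["distance"]),
                        corrected_bits=int(row["corrected_bits"]))


def estimate_misidentification(decode_results: pd.DataFrame,
                               codebook: Codebook) -> dict:
    """Blank-based false-positive summary.

    Counts decoded events per barcode label and returns the mean count per
    blank barcode, the mean count per gene barcode, and their ratio (the
    misidentification metric; 0 when no blanks were hit).
    """
    accepted = decode_results[decode_results["label"] != "rejected"]
    if len(accepted) == 0:
        raise ValueError("no decoded events")
    counts = accepted["label"].value_counts()
    blank_labels = [a for a in codebook.assignment if a == BLANK]
    gene_labels = codebook.genes
    n_blank_codes = len(blank_labels)
    # all blanks share one label; total blank events / number of blank codes
    blank_total = int(counts.get(BLANK, 0))
    blank_mean = blank_total / n_blank_codes if n_blank_codes else float("nan")
    gene_mean = (float(np.mean([counts.get(g, 0) for g in gene_labels]))
                 if gene_labels else float("nan"))
    ratio = blank_mean / gene_mean if gene_mean and gene_mean > 0 else float("inf")
    return {
        "blank_mean_count": blank_mean,
        "gene_mean_count": gene_mean,
        "blank_gene_ratio": ratio,
        "n_decoded": int(len(accepted)),
        "n_rejected": int((decode_results["label"] == "rejected").sum()),
    }


def write_codebook_csv(codebook: Codebook, path) -> None:
    """Write the de-facto MERFISH codebook layout: name,id,barcode."""
    rows = []
    for i, (word, name) in enumerate(zip(codebook.codewords, codebook.assignment)):
        rows.append({"name": name, "id": i,
                     "barcode": "".join(str(int(b)) for b in word)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_codebook_csv(path, weight: int | None = None,
                      min_distance: int = 4) -> Codebook:
    df = pd.read_csv(path, dtype={"barcode": str})
    words = np.array([[int(ch) for ch in b] for b in df["barcode"]], dtype=np.uint8)
    w = int(words[0].sum()) if weight is None else weight
    cb = Codebook(n_bits=words.shape[1], weight=w, min_distance=min_distance,
                  codewords=words, assignment=list(df["name"]))
    cb.validate()
    return cb
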