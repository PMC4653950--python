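"""Sequence helpers: 2-bit codes, complements, A/T masks, k-mer catalogs.

Bases are coded A=0, C=1, G=2, T=3; anything else is 4 (ambiguous).
All coordinates are 0-based.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
AMBIG = 4

_ENCODE = np.full(256, AMBIG, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# complement of codes 0..4 (ambiguous maps to itself)
COMPLEMENT = np.array([T, G, C, A, AMBIG], dtype=np.uint8)


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes][::-1]


def at_mask(codes: np.ndarray) -> np.ndarray:
    """Boolean mask: True where the base is A or T."""
    return (codes == A) | (codes == T)


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer (forward strand), length ``len(codes)-k+1``.

    Ambiguous bases are treated as A; callers on synthetic genomes never see
    them.  k must satisfy 2k <= 63 bits (k <= 31).
    """
    c = np.where(codes >= AMBIG, 0, codes).astype(np.int64)
    n = len(c) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    # windowed dot product; k*n ops, fine for genomes of a few Mb
    win = np.lib.stride_tricks.sliding_window_view(c, k)
    return win @ powers


def duplicated_kmer_mask(codes: np.ndarray, k: int = 25) -> np.ndarray:
    """True at k-mer start i when that k-mer occurs >=2 times genome-wide.

    Occurrences are counted on the canonical form (lexicographic minimum of
    the k-mer and its reverse complement), mimicking what a read mapper
    would flag as multi-mapping.
    """
    fwd = kmer_codes(codes, k)
    comp = COMPLEMENT[np.where(codes >= AMBIG, 0, codes)]
    rc = kmer_codes(comp[::-1], k)[::-1]  # rc[i] = code of revcomp of k-mer at i
    canon = np.minimum(fwd, rc)
    uniq, inv, counts = np.unique(canon, return_inverse=True, return_counts=True)
    return counts[inv] >= 2
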