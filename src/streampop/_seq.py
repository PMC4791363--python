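"""Low-level nucleotide utilities: encoding, reverse complement, canonical k-mers.

Canonical k-mer collapsing pools each word with its reverse complement,
because the strand of an assembled contig is arbitrary.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

BASES = "ACGT"

_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes A=0 C=1 G=2 T=3; ambiguous bases -> -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def codes_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=8)
def canonical_kmer_table(k: int) -> tuple[np.ndarray, tuple[str, ...]]:
    """Map every numeric k-mer code in [0, 4**k) to its canonical class.

    Returns (class_index, kmers): ``class_index[code]`` is the canonical
    class of that word, and ``kmers`` lists the canonical (lexicographically
    smaller of word/revcomp) k-mer string per class, in sorted order.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = 4**k
    codes = np.arange(n)
    # digits of each code, most-significant base first
    digits = np.empty((k, n), dtype=np.int64)
    rem = codes.copy()
    for j in range(k - 1, -1, -1):
        digits[j] = rem % 4
        rem //= 4
    # reverse complement: complement digits (3 - d), reverse their order
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        rc = rc * 4 + (3 - digits[k - 1 - j])
    canon = np.minimum(codes, rc)
    classes, class_index = np.unique(canon, return_inverse=True)
    kmers = []
    for c in classes:
        word = "".join(BASES[(c >> (2 * (k - 1 - j))) & 3] for j in range(k))
        kmers.append(word)
    return class_index.astype(np.int64), tuple(kmers)


def kmer_class_counts(seq: str, k: int) -> np.ndarray:
    """Counts of canonical k-mer classes over sliding windows of ``seq``.

    Windows containing ambiguous bases are skipped.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    codes = seq_to_codes(seq)
    n_win = len(codes) - k + 1
    valid = np.ones(n_win, dtype=bool)
    word = np.zeros(n_win, dtype=np.int64)
    ok = codes >= 0
    for j in range(k):
        valid &= ok[j : j + n_win]
        word = word * 4 + np.where(ok[j : j + n_win], codes[j : j + n_win], 0)
    class_index, kmers = canonical_kmer_table(k)
    counts = np.bincount(class_index[word[valid]], minlength=len(kmers))
    return counts.astype(np.int64)
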