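"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
_CODE = {b: i for i, b in enumerate(DNA)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte value -> 0..3 code (A,C,G,T), 4 for anything else (N etc.)
BYTE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _i in _CODE.items():
    BYTE_TO_CODE[ord(_b)] = _i
    BYTE_TO_CODE[ord(_b.lower())] = _i


def validate_dna(seq: str, length: int | None = None, name: str = "sequence") -> str:
    if not seq or any(b not in _CODE for b in seq):
        raise ValueError(f"{name} {seq!r} must be non-empty over {{A,C,G,T}}")
    if length is not None and len(seq) != length:
        raise ValueError(f"{name} {seq!r} must have length {length}, got {len(seq)}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"hamming distance requires equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def encode_kmer(seq: str) -> int:
    """Pack an ACGT k-mer into an integer rank (big-endian, 2 bits/base)."""
    rank = 0
    for b in seq:
        rank = (rank << 2) | _CODE[b]
    return rank


def decode_kmer(rank: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(DNA[(rank >> shift) & 3])
    return "".join(out)


def seq_to_codes(seq: str) -> np.ndarray:
    """Map a base string to uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return BYTE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def phred_string(qual: int, length: int) -> str:
    return chr(qual + 33) * length
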