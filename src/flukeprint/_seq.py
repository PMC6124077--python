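"""Low-level nucleotide sequence helpers shared by the pipeline stages.

Sequences are plain upper-case ``str`` at module boundaries; hot loops use
``numpy`` uint8 views of the ASCII bytes.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: ASCII codes for the four bases, indexed 0..3 (A, C, G, T).
BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

N_BYTE = ord("N")
PHRED_OFFSET = 33


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """ASCII-byte view of a sequence as a uint8 array (no copy of semantics)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    """Number of differing positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    if not a:
        return 0
    return int(np.count_nonzero(encode(a) != encode(b)))


def phred_array(qual: str) -> np.ndarray:
    """Phred scores (int array) from a Phred+33 quality string."""
    q = encode(qual).astype(np.int64) - PHRED_OFFSET
    if q.size and (q.min() < 0 or q.max() > 93):
        raise ValueError("quality characters outside Phred+33 range")
    return q


def phred_string(scores: np.ndarray) -> str:
    clipped = np.clip(np.asarray(scores, dtype=np.int64), 0, 93)
    return decode((clipped + PHRED_OFFSET).astype(np.uint8))


def indices_to_str(idx: np.ndarray) -> str:
    """Map an array of base indices (0..3) to an ACGT string."""
    return decode(BASE_BYTES[idx])
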