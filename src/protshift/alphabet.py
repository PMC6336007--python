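"""The 20-letter amino-acid alphabet plus gap and unknown symbols.

All downstream statistics operate on a closed alphabet: the 20 standard
residues, ``-`` for alignment gaps and ``X`` for anything else (ambiguity
codes, selenocysteine, stops). Sequences are stored as plain strings;
numeric code matrices are used for the vectorised column operations.
"""
from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
UNKNOWN: str = "X"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

VALID_CHARS = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}

GAP_BYTE = ord(GAP)
UNKNOWN_BYTE = ord(UNKNOWN)
AA_BYTES = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8).copy()

# byte value -> residue code 0..19, or -1 for gap/unknown/anything else
AA_CODE_LOOKUP = np.full(256, -1, dtype=np.int16)
AA_CODE_LOOKUP[AA_BYTES] = np.arange(20)


def seq_to_bytes(seq: str) -> np.ndarray:
    """Encode a residue string as a uint8 array (one byte per column)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def codes_to_seq(codes: np.ndarray, gap_mask: np.ndarray | None = None) -> str:
    """Decode residue codes (0..19) to a string, with optional gap positions."""
    out = AA_BYTES[codes]
    if gap_mask is not None:
        out = out.copy()
        out[gap_mask] = GAP_BYTE
    return out.tobytes().decode("ascii")
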