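"""Shared DNA sequence helpers (encoding, reverse complement, IUPAC codes)."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement; accepts IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 indices 0..3; reject other letters."""
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc.args[0]!r} in sequence") from None


def decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)
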