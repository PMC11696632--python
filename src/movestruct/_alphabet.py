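"""Alphabet constants shared across the index.

Order is ``$ < A < C < G < T``: the sentinel must compare smaller than every
other character so that sorting rotations of the terminated text is the same
as sorting its suffixes.
"""

from __future__ import annotations

import numpy as np

SENTINEL = "$"
ALPHABET = "$ACGT"  # code i = position in this string
SIGMA = len(ALPHABET)
DNA = "ACGT"

CHAR_TO_CODE = {c: i for i, c in enumerate(ALPHABET)}
CODE_TO_CHAR = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# byte -> code lookup; 255 marks characters outside the alphabet
_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _c, _i in CHAR_TO_CODE.items():
    _BYTE_TO_CODE[ord(_c)] = _i


def encode(s: str) -> np.ndarray:
    """Map a string over ``$ACGT`` to an array of integer codes."""
    codes = _BYTE_TO_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"character {s[bad]!r} at offset {bad} is outside {ALPHABET!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    return CODE_TO_CHAR[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string (ACGT only)."""
    return s.translate(_COMPLEMENT)[::-1]
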