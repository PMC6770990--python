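"""Small shared helpers: 2-bit base coding, reverse complement, gzip-aware
open, and half-up decimal rounding."""
from __future__ import annotations

import gzip
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

# base codes: A=0, C=1, G=2, T=3; 4 marks anything else (N, IUPAC codes,
# read separators).  The numeric order matches lexicographic ACGT order, so
# min() on codes equals min() on strings.
BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
INVALID = np.uint8(4)

_ENCODE_LUT = np.full(256, INVALID, dtype=np.uint8)
for _i, _ch in enumerate(b"ACGT"):
    _ENCODE_LUT[_ch] = _i
    _ENCODE_LUT[_ch + 32] = _i  # lowercase

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (4 = non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode_codes(codes: np.ndarray) -> str:
    """Decode uint8 base codes (all < 4) back to an ACGT string."""
    return BASE_BYTES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (np.uint8(3) - codes)[::-1]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed tables conventionally do
    (Python's built-in round() is banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def xopen(path, mode: str = "rt"):
    """Open a text file, transparently decompressing ``.gz``."""
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, mode)
    return open(p, mode)
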