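"""Low-level nucleotide sequence helpers.

Sequences cross the public API as plain ``A/C/G/T`` strings; internally most
routines work on ``uint8`` code arrays (A=0, C=1, G=2, T=3) so that read
simulation and alignment comparison stay vectorized.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 code array (A=0,C=1,G=2,T=3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if codes.max(initial=0) > 3:
        bad = chr(raw[int(np.argmax(codes > 3))])
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an A/C/G/T string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (complement of c is 3 - c)."""
    return (3 - codes)[::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
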