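"""Small shared helpers for nucleotide sequences.

Sequences are handled as plain Python strings at the API surface and as
uint8 code arrays (A=0, C=1, G=2, T=3, anything else = 255) internally.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (255 for non-ACGT)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Reverse complement (case preserved, N kept as N)."""
    return seq.translate(_COMP)[::-1]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; codes >= 4 become 'N'."""
    lut = np.frombuffer(b"ACGT" + b"N" * 252, dtype=np.uint8)
    return lut[np.minimum(codes, 4)].tobytes().decode("ascii")
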