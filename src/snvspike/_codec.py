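"""Base <-> integer-code conversion shared by the simulator and pileup engine.

Sequences are held internally as ``uint8`` arrays with A=0, C=1, G=2, T=3
(the tie-break order used throughout); strings appear only at I/O edges.
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
    """Encode an A/C/G/T string (case-insensitive) to uint8 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode uint8 base codes back to a string."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")
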