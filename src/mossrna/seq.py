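"""Small sequence utilities shared across the pipeline.

All sequences are handled as uppercase DNA strings over {A,C,G,T} (plus N
in raw reads).  RNA is used only transiently inside the folding backends.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: integer codes used by vectorised scoring (A=0, C=1, G=2, T=3)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def transcribe(seq: str) -> str:
    """DNA -> RNA (T -> U)."""
    return seq.replace("T", "U")


def encode(seq: str) -> np.ndarray:
    """Encode ACGT to 0..3; any other character becomes -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def is_wc_pair(a: str, b: str) -> bool:
    """Watson-Crick pair between two DNA bases (A:T, C:G)."""
    return complement_base(a) == b


def is_wobble_pair(a: str, b: str) -> bool:
    """G:U wobble (G:T in DNA space), in either orientation."""
    return (a, b) in (("G", "T"), ("T", "G"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
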