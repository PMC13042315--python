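"""Internal nucleotide-array helpers shared by the simulator, caller and distances.

Sequences are held as uint8 codes: A=0, C=1, G=2, T=3. Code 4 marks anything
that is not an unambiguous base (N, IUPAC ambiguity, gap) and is treated as
missing by every consumer.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MISSING = 4

_ENC = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

# purine (A,G) flag per code; transversions change this flag
IS_PURINE = np.array([True, False, True, False, False])


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (non-ACGT -> missing)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENC[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an uppercase string (missing -> N)."""
    return _DEC[codes].tobytes().decode("ascii")


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length).astype(np.uint8)


def mutate_sites(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    """In place, change each given position to a uniformly chosen *different* base."""
    if positions.size == 0:
        return
    shift = rng.integers(1, 4, size=positions.size).astype(np.uint8)
    seq[positions] = (seq[positions] + shift) % 4
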