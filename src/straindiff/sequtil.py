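"""Small shared sequence helpers (alphabet, reverse complement, random DNA)."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. nucleotide string with expected GC content ``gc``."""
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return codes.tobytes().decode("ascii")


def validate_dna(seq: str, *, context: str = "sequence") -> None:
    """Reject characters outside {A,C,G,T,N}, reporting the 1-based position."""
    for i, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise ValueError(
                f"illegal character {ch!r} in {context} at position {i + 1}"
            )
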