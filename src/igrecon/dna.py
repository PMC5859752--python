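"""Small nucleotide-sequence helpers shared across the package."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMP = str.maketrans("ACGTN", "TGCAN")

# 2-bit base codes; N gets 4 and poisons any k-mer window containing it.
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = None


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= DNA_ALPHABET


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0 C=1 G=2 T=3, N/other=4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def translate(seq: str) -> str:
    """Translate a nucleotide string codon-by-codon (trailing partial codon dropped)."""
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data import CodonTable

        fwd = CodonTable.standard_dna_table.forward_table
        _CODON_TABLE = dict(fwd)
        for stop in CodonTable.standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(_CODON_TABLE.get(seq[i : i + 3], "X"))
    return "".join(out)


def has_stop_in_frame(seq: str, start: int, end: int) -> bool:
    """True if any stop codon lies fully inside seq[start:end] in the frame anchored at start."""
    for i in range(start, end - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return True
    return False


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
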