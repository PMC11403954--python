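"""Small sequence helpers (standard genetic code via Biopython)."""
from __future__ import annotations

from Bio.Seq import Seq

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def complement(base: str) -> str:
    return base.translate(_COMP)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide sequence with the standard genetic code."""
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    return str(Seq(seq).translate())


def translate_codon(codon: str) -> str:
    if len(codon) != 3:
        raise ValueError("codon must be 3 bases")
    return str(Seq(codon).translate())
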