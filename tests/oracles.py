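"""Independent brute-force oracles used by the tests.

Deliberately avoids polarfix internals and Biopython: the genetic code
is written out as a literal table and every computation is a plain
Python loop, so agreement with the package is a real cross-check.
"""
from __future__ import annotations

_T = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def translate(seq: str) -> str:
    assert len(seq) % 3 == 0
    return "".join(_T[seq[i : i + 3]] for i in range(0, len(seq), 3))


def extract_cds(reference: dict[str, str], gene) -> str:
    """Splice the coding sequence 5'->3' on the coding strand."""
    genomic = "".join(reference[gene.contig][s:e] for s, e in gene.cds_intervals)
    return genomic if gene.strand == "+" else revcomp(genomic)


def protein_with_substitution(
    reference: dict[str, str], gene, pos: int, allele: str
) -> str:
    """Translate the CDS after substituting ``allele`` at contig
    position ``pos`` — the extract-substitute-translate oracle."""
    seq = reference[gene.contig]
    mutated = seq[:pos] + allele + seq[pos + 1 :]
    return translate(extract_cds({gene.contig: mutated}, gene))


def brute_force_damage_counts(reads, reference):
    """Per-position C->T (from 5') and G->A (from 3') mismatch and
    opportunity counts via plain loops."""
    max_len = max(len(r.sequence) for r in reads)
    ct = [[0, 0] for _ in range(max_len)]  # [mismatches, opportunities]
    ga = [[0, 0] for _ in range(max_len)]
    for r in reads:
        ref = reference[r.contig]
        L = len(r.sequence)
        for p in range(L):
            ref_base = ref[r.start + p]
            read_base = r.sequence[p]
            if ref_base == "C":
                ct[p][1] += 1
                if read_base == "T":
                    ct[p][0] += 1
            if ref_base == "G":
                q = L - 1 - p  # position from the 3' end
                ga[q][1] += 1
                if read_base == "A":
                    ga[q][0] += 1
    return ct, ga


def brute_force_base_counts(reads, positions):
    """Pileup via plain loops: {(contig, pos, sample): {base: count}}."""
    acc = {}
    for r in reads:
        for contig, pos in positions:
            if r.contig == contig and r.start <= pos < r.start + len(r.sequence):
                base = r.sequence[pos - r.start]
                key = (contig, pos, r.sample_id)
                acc.setdefault(key, {"A": 0, "C": 0, "G": 0, "T": 0})
                acc[key][base] += 1
    return acc
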