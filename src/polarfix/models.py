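"""Core domain types shared across pipeline stages.

Coordinates are 0-based half-open internally; all on-disk formats
(VCF, GFF3) use their native 1-based conventions and are converted at
the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

BASES = ("A", "C", "G", "T")

#: A diploid genotype is an unordered pair of allele strings, or None if
#: missing / masked. Phase is never used by any stage.
Genotype = Optional[tuple[str, str]]


class Species(str, Enum):
    POLAR = "polar"
    BROWN = "brown"
    OUTGROUP = "outgroup"


class Era(str, Enum):
    MODERN = "modern"
    ANCIENT = "ancient"


@dataclass(frozen=True)
class SampleMeta:
    """One column of the genotype matrix."""

    sample_id: str
    species: Species
    era: Era
    outgroup_taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


@dataclass
class GeneModel:
    """A single-transcript gene: sorted, non-overlapping CDS intervals.

    Intervals are 0-based half-open on the contig, stored in ascending
    genomic order regardless of strand.
    """

    name: str
    contig: str
    strand: str
    cds_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ivals = sorted(tuple(iv) for iv in self.cds_intervals)
        for (s0, e0), (s1, e1) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping CDS intervals in {self.name}")
        for s, e in ivals:
            if not (0 <= s < e):
                raise ValueError(f"bad interval ({s},{e}) in {self.name}")
        self.cds_intervals = ivals

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def start(self) -> int:
        return self.cds_intervals[0][0]

    @property
    def end(self) -> int:
        return self.cds_intervals[-1][1]

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.cds_intervals)

    def cds_index(self, pos: int) -> Optional[int]:
        """0-based position within the coding sequence (5'->3' on the
        coding strand), or None if pos is not in the CDS."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos < e:
                rank = offset + (pos - s)
                if self.strand == "+":
                    return rank
                return self.coding_length - 1 - rank
            offset += e - s
        return None

    def genomic_position(self, cds_idx: int) -> int:
        """Inverse of :meth:`cds_index`."""
        if not (0 <= cds_idx < self.coding_length):
            raise IndexError(cds_idx)
        rank = cds_idx if self.strand == "+" else self.coding_length - 1 - cds_idx
        offset = 0
        for s, e in self.cds_intervals:
            if rank < offset + (e - s):
                return s + (rank - offset)
            offset += e - s
        raise AssertionError("unreachable")


@dataclass
class SiteCall:
    """One variant site with per-sample genotypes and depths.

    ``genotypes`` and ``depths`` are ordered to match the sample
    metadata list used to read / generate the matrix.
    """

    contig: str
    pos: int  # 0-based
    ref_allele: str
    alt_alleles: list[str]
    genotypes: list[Genotype]
    depths: np.ndarray  # int per sample, -1 = unknown

    def __post_init__(self) -> None:
        alleles = [self.ref_allele, *self.alt_alleles]
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"duplicate alleles at {self.contig}:{self.pos}")
        self.depths = np.asarray(self.depths, dtype=int)
        if len(self.genotypes) != len(self.depths):
            raise ValueError("genotypes / depths length mismatch")

    @property
    def alleles(self) -> list[str]:
        return [self.ref_allele, *self.alt_alleles]

    def observed_alleles(self) -> set[str]:
        out: set[str] = set()
        for gt in self.genotypes:
            if gt is not None:
                out.update(gt)
        return out


@dataclass(frozen=True)
class BaseCountRecord:
    """Per-site, per-sample read counts for each base."""

    contig: str
    pos: int  # 0-based
    sample_id: str
    n_a: int
    n_c: int
    n_g: int
    n_t: int

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_c, self.n_g, self.n_t) < 0:
            raise ValueError("negative base count")

    def count(self, base: str) -> int:
        return {"A": self.n_a, "C": self.n_c, "G": self.n_g, "T": self.n_t}[base]

    @property
    def total(self) -> int:
        return self.n_a + self.n_c + self.n_g + self.n_t


@dataclass(frozen=True)
class AncientRead:
    """A simulated single-end read, exactly aligned (no indels)."""

    sample_id: str
    contig: str
    start: int  # 0-based leftmost reference position
    sequence: str

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """Coding effect of a biallelic substitution."""

    gene: str
    codon_index: int          # 0-based codon ordinal within the CDS
    codon_position: int       # 1..3 within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    @property
    def is_nonsynonymous(self) -> bool:
        return self.ref_aa != self.alt_aa
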