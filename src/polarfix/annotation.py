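"""Candidate-site filter cascade.

Per-individual depth masking, allelic-state classification, coding-effect
annotation, and the final candidate selection. Every site receives
exactly one primary filter fate, so fates always partition the input.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from ._seq import complement, translate_codon
from .models import GeneModel, SampleMeta, SiteAnnotation, SiteCall, Species, Era


class FilterFate(str, Enum):
    RETAINED = "retained"
    MULTIALLELIC = "multiallelic"
    MONOMORPHIC = "monomorphic"
    NON_CODING = "non_coding"
    SYNONYMOUS = "synonymous"
    LOW_CALLABLE = "low_callable"


@dataclass(frozen=True)
class FilterThresholds:
    """Depth and completeness guards applied before fixation calls."""

    min_depth: int = 4
    min_callable_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0 < self.min_callable_fraction <= 1):
            raise ValueError("min_callable_fraction must be in (0, 1]")


def apply_depth_mask(
    sites: Sequence[SiteCall], thresholds: FilterThresholds
) -> list[SiteCall]:
    """Mask genotypes below the per-individual depth threshold.

    Depths are left untouched, so the operation is idempotent. An
    unknown depth (-1) also masks the genotype: a call whose coverage
    cannot be verified is not trusted.
    """
    out = []
    for site in sites:
        masked = copy.copy(site)
        masked.genotypes = [
            gt if d >= thresholds.min_depth else None
            for gt, d in zip(site.genotypes, site.depths)
        ]
        masked.depths = site.depths.copy()
        out.append(masked)
    return out


class AllelicState(str, Enum):
    MONOMORPHIC = "monomorphic"
    BIALLELIC = "biallelic"
    MULTIALLELIC = "multiallelic"


def classify_allelic_state(site: SiteCall) -> AllelicState:
    """State from alleles observed in non-missing genotypes across all
    samples; a listed-but-unobserved ALT does not count."""
    n = len(site.observed_alleles())
    if n <= 1:
        return AllelicState.MONOMORPHIC
    if n == 2:
        return AllelicState.BIALLELIC
    return AllelicState.MULTIALLELIC


def annotate_coding_effect(
    site: SiteCall,
    gene_models: Sequence[GeneModel],
    reference: dict[str, str],
    alt_allele: Optional[str] = None,
) -> Optional[SiteAnnotation]:
    """Annotate the coding effect of the substitution at ``site``.

    Returns None for sites outside every CDS. Minus-strand genes are
    handled by complementing the contig alleles into coding-strand
    codons before translation.
    """
    gene = next(
        (
            g
            for g in gene_models
            if g.contig == site.contig and g.contains(site.pos)
        ),
        None,
    )
    if gene is None:
        return None
    ref_seq = reference[site.contig]
    if ref_seq[site.pos] != site.ref_allele:
        raise ValueError(
            f"reference mismatch at {site.contig}:{site.pos + 1}: "
            f"FASTA has {ref_seq[site.pos]}, site says {site.ref_allele}"
        )
    if alt_allele is None:
        alt_allele = site.alt_alleles[0]

    cds_idx = gene.cds_index(site.pos)
    assert cds_idx is not None
    codon_index = cds_idx // 3
    within = cds_idx % 3
    codon_pos = [gene.genomic_position(codon_index * 3 + k) for k in range(3)]
    if gene.strand == "+":
        ref_codon = "".join(ref_seq[p] for p in codon_pos)
        alt_base = alt_allele
    else:
        ref_codon = "".join(complement(ref_seq[p]) for p in codon_pos)
        alt_base = complement(alt_allele)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    return SiteAnnotation(
        gene=gene.name,
        codon_index=codon_index,
        codon_position=within + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=translate_codon(ref_codon),
        alt_aa=translate_codon(alt_codon),
    )


@dataclass
class SiteFate:
    site: SiteCall
    fate: FilterFate
    annotation: Optional[SiteAnnotation]
    allelic_state: AllelicState
    callable_fraction_polar: float
    callable_fraction_brown: float


def _callable_fraction(site: SiteCall, indices: np.ndarray) -> float:
    if len(indices) == 0:
        return 0.0
    called = sum(1 for i in indices if site.genotypes[i] is not None)
    return called / len(indices)


def select_candidate_sites(
    sites: Sequence[SiteCall],
    metadata: Sequence[SampleMeta],
    gene_models: Sequence[GeneModel],
    reference: dict[str, str],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[SiteFate]:
    """Run the full cascade. Input must already be depth-masked.

    A site is retained iff it is biallelic, non-synonymous inside a
    candidate gene's CDS, and each modern species group (polar, brown)
    has at least ``min_callable_fraction`` callable individuals. The
    fates are assigned with a fixed priority so each site gets exactly
    one: multiallelic > monomorphic > non_coding > synonymous >
    low_callable > retained.
    """
    polar_idx = np.array(
        [
            i
            for i, s in enumerate(metadata)
            if s.species == Species.POLAR and s.era == Era.MODERN
        ]
    )
    brown_idx = np.array(
        [
            i
            for i, s in enumerate(metadata)
            if s.species == Species.BROWN and s.era == Era.MODERN
        ]
    )
    out: list[SiteFate] = []
    for site in sites:
        state = classify_allelic_state(site)
        frac_p = _callable_fraction(site, polar_idx)
        frac_b = _callable_fraction(site, brown_idx)
        annotation = None
        if state == AllelicState.MULTIALLELIC:
            fate = FilterFate.MULTIALLELIC
        elif state == AllelicState.MONOMORPHIC:
            fate = FilterFate.MONOMORPHIC
        else:
            observed = site.observed_alleles()
            alt = next(
                (a for a in site.alleles if a != site.ref_allele and a in observed),
                site.alt_alleles[0],
            )
            annotation = annotate_coding_effect(
                site, gene_models, reference, alt_allele=alt
            )
            if annotation is None:
                fate = FilterFate.NON_CODING
            elif not annotation.is_nonsynonymous:
                fate = FilterFate.SYNONYMOUS
            elif (
                frac_p < thresholds.min_callable_fraction
                or frac_b < thresholds.min_callable_fraction
            ):
                fate = FilterFate.LOW_CALLABLE
            else:
                fate = FilterFate.RETAINED
        out.append(
            SiteFate(
                site=site,
                fate=fate,
                annotation=annotation,
                allelic_state=state,
                callable_fraction_polar=frac_p,
                callable_fraction_brown=frac_b,
            )
        )
    return out
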