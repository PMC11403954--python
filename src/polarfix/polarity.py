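"""Outgroup polarization, polar fixation calls, and origin classes.

The ancestral allele is the allele the two outgroup individuals carry
homozygously. A site where an outgroup carries the allele fixed in all
polar bears is removed outright; a heterozygous outgroup counts as
carrying both alleles, so the removal rule fires conservatively.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .models import Era, Genotype, SampleMeta, SiteCall, Species


class RemovalReason(str, Enum):
    OUTGROUP_CARRIES_POLAR_ALLELE = "outgroup_carries_polar_allele"
    OUTGROUP_MISSING = "outgroup_missing"
    OUTGROUP_DISCORDANT = "outgroup_discordant"


class Origin(str, Enum):
    STANDING_VARIATION = "standing_variation"
    DE_NOVO = "de_novo"
    NOT_FIXED = "not_fixed"
    REMOVED = "removed"


@dataclass(frozen=True)
class PolarityCall:
    ancestral: Optional[str]
    derived: Optional[str]
    outgroup_states: tuple[Genotype, ...]
    removal_reason: Optional[RemovalReason] = None

    def __post_init__(self) -> None:
        if self.ancestral is not None and self.ancestral == self.derived:
            raise ValueError("ancestral and derived alleles must differ")


@dataclass(frozen=True)
class FixationCall:
    is_fixed: bool
    fixed_allele: Optional[str]
    callable_count: int


@dataclass(frozen=True)
class OriginClass:
    origin: Origin
    brown_derived_count: int
    brown_called_alleles: int

    @property
    def brown_derived_freq(self) -> Optional[float]:
        if self.brown_called_alleles == 0:
            return None
        return self.brown_derived_count / self.brown_called_alleles


def sample_indices(
    metadata: Sequence[SampleMeta], species: Species, era: Optional[Era] = None
) -> list[int]:
    return [
        i
        for i, s in enumerate(metadata)
        if s.species == species and (era is None or s.era == era)
    ]


def determine_ancestral(
    site: SiteCall,
    outgroup_genotypes: Sequence[Genotype],
    polar_fixed_allele: Optional[str] = None,
    allow_single_outgroup: bool = False,
) -> PolarityCall:
    """Polarize a biallelic site from the outgroup genotypes.

    ``polar_fixed_allele`` is the allele fixed across all callable
    modern polar bears, if any; its presence in either outgroup triggers
    removal. Both outgroups are required by default; with
    ``allow_single_outgroup`` a single homozygous outgroup suffices.
    """
    states = tuple(outgroup_genotypes)
    present = [g for g in states if g is not None]
    if polar_fixed_allele is not None and any(
        polar_fixed_allele in g for g in present
    ):
        return PolarityCall(
            ancestral=None,
            derived=None,
            outgroup_states=states,
            removal_reason=RemovalReason.OUTGROUP_CARRIES_POLAR_ALLELE,
        )
    required = 1 if allow_single_outgroup else len(states)
    if len(present) < max(required, 1):
        return PolarityCall(
            ancestral=None,
            derived=None,
            outgroup_states=states,
            removal_reason=RemovalReason.OUTGROUP_MISSING,
        )
    hom_alleles = {g[0] for g in present if g[0] == g[1]}
    has_het = any(g[0] != g[1] for g in present)
    if has_het or len(hom_alleles) != 1:
        return PolarityCall(
            ancestral=None,
            derived=None,
            outgroup_states=states,
            removal_reason=RemovalReason.OUTGROUP_DISCORDANT,
        )
    ancestral = hom_alleles.pop()
    site_alleles = site.observed_alleles() or set(site.alleles)
    others = sorted(site_alleles - {ancestral})
    derived = others[0] if len(others) == 1 else None
    return PolarityCall(ancestral=ancestral, derived=derived, outgroup_states=states)


def assess_polar_fixation(
    site: SiteCall, polar_modern_indices: Sequence[int]
) -> FixationCall:
    """Fixed iff every callable modern polar bear is homozygous for the
    same allele (zero callable individuals is not a fixation)."""
    called = [
        site.genotypes[i] for i in polar_modern_indices if site.genotypes[i] is not None
    ]
    if not called:
        return FixationCall(is_fixed=False, fixed_allele=None, callable_count=0)
    alleles = {a for gt in called for a in gt}
    if len(alleles) == 1:
        return FixationCall(
            is_fixed=True, fixed_allele=alleles.pop(), callable_count=len(called)
        )
    return FixationCall(is_fixed=False, fixed_allele=None, callable_count=len(called))


def brown_derived_frequency(
    site: SiteCall, brown_indices: Sequence[int], derived: Optional[str]
) -> tuple[int, int]:
    """(derived allele count, called allele count) over brown bears."""
    count = 0
    called = 0
    for i in brown_indices:
        gt = site.genotypes[i]
        if gt is None:
            continue
        called += 2
        if derived is not None:
            count += sum(1 for a in gt if a == derived)
    return count, called


def classify_origin(
    fixation: FixationCall,
    polarity: PolarityCall,
    brown_derived_count: int,
    brown_called_alleles: int,
) -> OriginClass:
    """standing_variation / de_novo / not_fixed / removed.

    Removal reasons only apply to sites that are fixed in modern polar
    bears: a non-fixed site is reported as not_fixed regardless of
    outgroup state, which keeps the partition unambiguous.
    """
    if not fixation.is_fixed:
        return OriginClass(Origin.NOT_FIXED, brown_derived_count, brown_called_alleles)
    if polarity.removal_reason is not None or polarity.ancestral is None:
        return OriginClass(Origin.REMOVED, brown_derived_count, brown_called_alleles)
    if fixation.fixed_allele == polarity.ancestral:
        # polar bears fixed for the ancestral allele: nothing derived fixed
        return OriginClass(Origin.NOT_FIXED, brown_derived_count, brown_called_alleles)
    if brown_derived_count > 0:
        return OriginClass(
            Origin.STANDING_VARIATION, brown_derived_count, brown_called_alleles
        )
    return OriginClass(Origin.DE_NOVO, brown_derived_count, brown_called_alleles)


def classify_sites(
    sites: Sequence[SiteCall],
    metadata: Sequence[SampleMeta],
    genes_by_contig: dict[str, str] | None = None,
    allow_single_outgroup: bool = False,
) -> pd.DataFrame:
    """Run polarization + fixation + origin over retained candidates.

    Returns one row per site with ancestral/derived alleles, the origin
    class, brown-bear derived counts and any removal reason.
    """
    polar_idx = sample_indices(metadata, Species.POLAR, Era.MODERN)
    brown_idx = sample_indices(metadata, Species.BROWN, Era.MODERN)
    out_idx = sample_indices(metadata, Species.OUTGROUP)
    rows = []
    for site in sites:
        fixation = assess_polar_fixation(site, polar_idx)
        polarity = determine_ancestral(
            site,
            [site.genotypes[i] for i in out_idx],
            polar_fixed_allele=fixation.fixed_allele,
            allow_single_outgroup=allow_single_outgroup,
        )
        bd, bc = brown_derived_frequency(site, brown_idx, polarity.derived)
        origin = classify_origin(fixation, polarity, bd, bc)
        gene = (genes_by_contig or {}).get(site.contig, "")
        rows.append(
            {
                "gene": gene,
                "contig": site.contig,
                "pos": site.pos,
                "ancestral": polarity.ancestral or "",
                "derived": polarity.derived or "",
                "origin_class": origin.origin.value,
                "removal_reason": (
                    polarity.removal_reason.value if polarity.removal_reason else ""
                ),
                "is_fixed": fixation.is_fixed,
                "fixed_allele": fixation.fixed_allele or "",
                "polar_callable": fixation.callable_count,
                "brown_derived_count": bd,
                "brown_called_alleles": bc,
                "brown_derived_freq": origin.brown_derived_freq,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "contig",
            "pos",
            "ancestral",
            "derived",
            "origin_class",
            "removal_reason",
            "is_fixed",
            "fixed_allele",
            "polar_callable",
            "brown_derived_count",
            "brown_called_alleles",
            "brown_derived_freq",
        ],
    )


def summarize_by_gene(classifications: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of fixed / pre-fixed / post-fixed sites.

    Expects a classification table already joined with timing classes
    (column ``timing_class``; absent values allowed for unfixed sites).
    Genes with zero fixed sites are listed with zero counts.
    """
    if classifications.empty:
        return pd.DataFrame(
            columns=["gene", "n_fixed", "n_pre_fixed", "n_post_fixed", "n_unresolved"]
        )
    fixed_mask = classifications["origin_class"].isin(
        [Origin.STANDING_VARIATION.value, Origin.DE_NOVO.value]
    )
    rows = []
    for gene, grp in classifications.groupby("gene", sort=True):
        fixed = grp[fixed_mask.loc[grp.index]]
        timing = fixed.get("timing_class", pd.Series(dtype=str))
        rows.append(
            {
                "gene": gene,
                "n_fixed": len(fixed),
                "n_pre_fixed": int((timing == "pre_fixed").sum()),
                "n_post_fixed": int((timing == "post_fixed").sum()),
                "n_unresolved": int((timing == "unresolved").sum()),
            }
        )
    return pd.DataFrame(rows)
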