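"""Per-gene dosage PCA checking polar/brown differentiation.

Works on hard genotype calls encoded as derived/alt-allele dosages
0/1/2 with mean imputation of missing entries — a deliberate
simplification of likelihood-based PCA, adequate at the depths the
simulator produces. Outgroups and ancient samples are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotation import AllelicState, classify_allelic_state
from .models import Era, GeneModel, SampleMeta, SiteCall, Species

SEPARATION_CAP = 1e6


@dataclass
class DosageMatrix:
    matrix: np.ndarray           # samples x sites, centered, imputed
    sample_ids: list[str]
    site_keys: list[tuple[str, int]]
    column_means: np.ndarray     # mean observed dosage before centering
    completeness: np.ndarray     # per retained column


@dataclass
class PcaResult:
    coordinates: np.ndarray      # samples x components
    eigenvalues: np.ndarray      # descending
    sample_ids: list[str]


def extract_gene_region(
    sites: Sequence[SiteCall],
    gene: GeneModel,
    flank: int = 50_000,
    contig_length: Optional[int] = None,
) -> list[SiteCall]:
    """Sites within [gene_start - flank, gene_end + flank), clamped to
    the contig bounds."""
    lo = max(gene.start - flank, 0)
    hi = gene.end + flank
    if contig_length is not None:
        hi = min(hi, contig_length)
    return [s for s in sites if s.contig == gene.contig and lo <= s.pos < hi]


def build_dosage_matrix(
    sites: Sequence[SiteCall],
    metadata: Sequence[SampleMeta],
    completeness: float = 0.95,
    min_maf: float = 0.0,
) -> Optional[DosageMatrix]:
    """Centered, mean-imputed dosage matrix over modern polar + brown.

    Multiallelic and monomorphic columns are dropped, as are columns
    below the completeness threshold or the minor-allele-frequency
    floor. Returns None if no column survives.
    """
    keep_idx = [
        i
        for i, s in enumerate(metadata)
        if s.era == Era.MODERN and s.species in (Species.POLAR, Species.BROWN)
    ]
    sample_ids = [metadata[i].sample_id for i in keep_idx]
    n = len(keep_idx)
    columns = []
    keys = []
    means = []
    comps = []
    for site in sites:
        if classify_allelic_state(site) != AllelicState.BIALLELIC:
            continue
        observed = sorted(site.observed_alleles())
        # dosage counts the non-reference observed allele; if the
        # reference allele is unobserved, count the second allele
        counted = next((a for a in observed if a != site.ref_allele), observed[-1])
        col = np.full(n, np.nan)
        for row, i in enumerate(keep_idx):
            gt = site.genotypes[i]
            if gt is not None:
                col[row] = sum(1 for a in gt if a == counted)
        mask = ~np.isnan(col)
        comp = mask.mean()
        if comp < completeness or not mask.any():
            continue
        mean = col[mask].mean()
        af = mean / 2.0
        if min(af, 1 - af) < min_maf or mean in (0.0, 2.0):
            continue
        if np.nanvar(col) == 0:
            continue
        col = np.where(mask, col, mean) - mean
        columns.append(col)
        keys.append((site.contig, site.pos))
        means.append(mean)
        comps.append(comp)
    if not columns:
        return None
    return DosageMatrix(
        matrix=np.column_stack(columns),
        sample_ids=sample_ids,
        site_keys=keys,
        column_means=np.array(means),
        completeness=np.array(comps),
    )


def pca(dosage: DosageMatrix) -> PcaResult:
    """Principal axes of the sample covariance of the centered matrix.

    Eigenvalues are scaled so their sum equals the total column variance
    (mean squared deviation per sample, summed over columns).
    """
    X = dosage.matrix
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s**2 / n
    coordinates = u * s
    return PcaResult(
        coordinates=coordinates,
        eigenvalues=eigenvalues,
        sample_ids=dosage.sample_ids,
    )


def species_separation(
    result: PcaResult, metadata: Sequence[SampleMeta]
) -> float:
    """Distance between polar and brown centroids on PC1, divided by the
    pooled within-species standard deviation on PC1. Returns
    SEPARATION_CAP when the within-species spread is zero, NaN when a
    species group is absent or the result is degenerate."""
    species_of = {
        s.sample_id: s.species for s in metadata if s.era == Era.MODERN
    }
    pc1 = result.coordinates[:, 0]
    polar = np.array(
        [
            x
            for x, sid in zip(pc1, result.sample_ids)
            if species_of.get(sid) == Species.POLAR
        ]
    )
    brown = np.array(
        [
            x
            for x, sid in zip(pc1, result.sample_ids)
            if species_of.get(sid) == Species.BROWN
        ]
    )
    if len(polar) == 0 or len(brown) == 0 or result.eigenvalues[0] == 0:
        return float("nan")
    dist = abs(polar.mean() - brown.mean())
    pooled_var = (
        len(polar) * polar.var() + len(brown) * brown.var()
    ) / (len(polar) + len(brown))
    if pooled_var == 0:
        return SEPARATION_CAP if dist > 0 else float("nan")
    return min(dist / np.sqrt(pooled_var), SEPARATION_CAP)
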