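"""Self-contained synthetic study generator.

Emits a reference, gene models, a genotype cohort (modern polar bears
fixed for planted derived alleles, brown bears segregating at planted
frequencies, two outgroups, ancient individuals with terminal
deamination damage), per-site ancient read counts, raw simulated reads,
and a truth table recording every planted site class — the oracle for
recovery tests.

Everything is driven by a single integer seed and is byte-identically
reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from ._seq import complement
from .annotation import annotate_coding_effect
from .models import (
    AncientRead,
    BaseCountRecord,
    Era,
    GeneModel,
    Genotype,
    SampleMeta,
    SiteCall,
    Species,
)

_U8 = {b: np.uint8(ord(b)) for b in "ACGT"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

DAMAGE_CONTIG = "damage_ctrl"
#: minimum separation between planted sites on one contig; twice the
#: read length guarantees per-site pileups never mix targeted reads.
_MIN_SPACING_FACTOR = 2


class SiteClass(str, Enum):
    FIXED_PRE = "fixed_pre"
    FIXED_POST = "fixed_post"
    FIXED_DENOVO = "fixed_denovo"
    SEGREGATING_POLAR = "segregating_polar"
    NO_FIXED_SITE_BACKGROUND = "no_fixed_site_background"
    SYNONYMOUS_BG = "synonymous_bg"
    LOW_DEPTH_BG = "low_depth_bg"
    TRIALLELIC_BG = "triallelic_bg"
    OUTGROUP_CONFLICT_BG = "outgroup_conflict_bg"


FIXED_CLASSES = (SiteClass.FIXED_PRE, SiteClass.FIXED_POST, SiteClass.FIXED_DENOVO)

#: classes that must be plantable as non-synonymous coding changes
_CODING_CLASSES = FIXED_CLASSES + (
    SiteClass.SEGREGATING_POLAR,
    SiteClass.LOW_DEPTH_BG,
    SiteClass.TRIALLELIC_BG,
    SiteClass.OUTGROUP_CONFLICT_BG,
)


@dataclass(frozen=True)
class CohortSpec:
    """All knobs of the synthetic study."""

    n_polar_modern: int = 119
    n_brown: int = 135
    n_ancient: int = 2
    n_outgroup: int = 2
    depth_mean_modern: float = 18.0
    depth_mean_ancient: float = 20.0
    ancient_missing_rate: float = 0.0
    damage_rate_per_ancient: tuple[float, ...] = (0.20, 0.05)
    seed: int = 0
    read_length: int = 60
    damage_decay: float = 0.5
    n_background_reads: int = 48_000
    sequencing_error_rate: float = 0.0
    #: zygosity of the non-fixed ancient at fixed_post sites
    ancient_post_state: str = "het"  # or "hom_ancestral"
    flank: int = 51_000
    #: gene whose first post-fixed sites carry the near-threshold
    #: heterozygote proportions (0.25 and 0.29) with damage-type alleles
    flagged_gene: str = "TTN"

    def __post_init__(self) -> None:
        for name in ("n_polar_modern", "n_brown", "n_ancient", "n_outgroup"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ancient_missing_rate", "damage_decay", "sequencing_error_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0,1]")
        rates = self.damage_rate_per_ancient
        if len(rates) != self.n_ancient:
            raise ValueError("damage_rate_per_ancient must have one rate per ancient")
        if any(not (0 <= r <= 1) for r in rates):
            raise ValueError("damage rates must be in [0,1]")
        if self.ancient_post_state not in ("het", "hom_ancestral"):
            raise ValueError("ancient_post_state must be 'het' or 'hom_ancestral'")
        if self.flank < 50_000:
            raise ValueError("flank must be at least 50 kb")
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")

    @property
    def min_spacing(self) -> int:
        return _MIN_SPACING_FACTOR * self.read_length


@dataclass(frozen=True)
class GenePlanEntry:
    name: str
    coding_length: int
    strand: str
    n_fixed_pre: int = 0
    n_fixed_post: int = 0

    def __post_init__(self) -> None:
        if self.coding_length % 3:
            raise ValueError(
                f"{self.name}: coding length {self.coding_length} not divisible by 3"
            )


# Default plan: the seven genes carrying fixed derived alleles with their
# coding lengths and pre/post split, plus four genes with none.
DEFAULT_GENE_PLAN: tuple[GenePlanEntry, ...] = (
    GenePlanEntry("ABCC6", 4551, "+", 1, 0),
    GenePlanEntry("AIM1", 5484, "-", 5, 0),
    GenePlanEntry("APOB", 13305, "+", 3, 7),
    GenePlanEntry("COL5A3", 5256, "-", 2, 0),
    GenePlanEntry("CUL7", 5106, "+", 0, 0),
    GenePlanEntry("FCGBP", 16128, "+", 0, 0),
    GenePlanEntry("LAMC3", 4902, "-", 0, 0),
    GenePlanEntry("LYST", 11403, "+", 5, 3),
    GenePlanEntry("POLR1A", 5172, "+", 1, 0),
    GenePlanEntry("TTN", 102861, "+", 17, 4),
    GenePlanEntry("XIRP1", 5403, "-", 0, 0),
)

ClassPlan = dict[str, dict[SiteClass, int]]


def default_class_plan(
    gene_plan: Sequence[GenePlanEntry] = DEFAULT_GENE_PLAN,
    n_flank_background: int = 8,
) -> ClassPlan:
    """Per-gene counts: planned fixed sites plus one of each background
    class and a handful of non-coding flank sites per gene."""
    plan: ClassPlan = {}
    for entry in gene_plan:
        plan[entry.name] = {
            SiteClass.FIXED_PRE: entry.n_fixed_pre,
            SiteClass.FIXED_POST: entry.n_fixed_post,
            SiteClass.FIXED_DENOVO: 0,
            SiteClass.SEGREGATING_POLAR: 1,
            SiteClass.SYNONYMOUS_BG: 1,
            SiteClass.LOW_DEPTH_BG: 1,
            SiteClass.TRIALLELIC_BG: 1,
            SiteClass.OUTGROUP_CONFLICT_BG: 1,
            SiteClass.NO_FIXED_SITE_BACKGROUND: n_flank_background,
        }
    return plan


@dataclass
class PlantedSiteClass:
    site_class: SiteClass
    gene: str
    contig: str
    position: int  # 0-based contig coordinate
    ancestral: str
    derived: str
    brown_derived_freq: float
    polar_derived_freq: float = 1.0
    second_alt: Optional[str] = None  # triallelic_bg only

    def __post_init__(self) -> None:
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived must differ")
        if self.site_class == SiteClass.FIXED_DENOVO and self.brown_derived_freq != 0:
            raise ValueError("fixed_denovo requires brown_derived_freq == 0")


@dataclass(frozen=True)
class HetPlan:
    """A planted ancient heterozygote with its target minor-base counts."""

    contig: str
    pos: int
    gene: str
    ancient_index: int
    coverage: int
    n_minor: int
    minor_allele: str
    major_allele: str

    @property
    def proportion(self) -> float:
        return self.n_minor / self.coverage


@dataclass
class TruthTable:
    sites: list[PlantedSiteClass]
    #: per-site tuple of planted ancient genotypes (None = missing)
    ancient_genotypes: dict[tuple[str, int], tuple[Genotype, ...]]
    #: per-site per-ancient read coverage used for targeted reads
    ancient_coverage: dict[tuple[str, int], tuple[int, ...]]
    het_plans: list[HetPlan]

    def by_key(self) -> dict[tuple[str, int], PlantedSiteClass]:
        return {(s.contig, s.position): s for s in self.sites}

    def class_counts(self) -> dict[str, dict[SiteClass, int]]:
        out: dict[str, dict[SiteClass, int]] = {}
        for s in self.sites:
            out.setdefault(s.gene, {}).setdefault(s.site_class, 0)
            out[s.gene][s.site_class] += 1
        return out


# ---------------------------------------------------------------------------
# reference + gene models
# ---------------------------------------------------------------------------

def generate_reference_and_genes(
    spec: CohortSpec,
    gene_plan: Sequence[GenePlanEntry] = DEFAULT_GENE_PLAN,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, str], list[GeneModel]]:
    """One contig per gene with >= 50 kb flanks; CDS split into up to
    three exons and guaranteed free of internal stop codons."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    reference: dict[str, str] = {}
    genes: list[GeneModel] = []
    for entry in gene_plan:
        coding = _random_coding_sequence(entry.coding_length, rng)
        exon_lengths = _split_exons(entry.coding_length, rng)
        intron_lengths = [int(rng.integers(300, 800)) for _ in exon_lengths[1:]]
        intervals = []
        cursor = spec.flank
        for i, exlen in enumerate(exon_lengths):
            intervals.append((cursor, cursor + exlen))
            cursor += exlen
            if i < len(intron_lengths):
                cursor += intron_lengths[i]
        contig_len = cursor + spec.flank
        contig = f"ctg_{entry.name}"
        seq = rng.integers(0, 4, contig_len)
        arr = np.array(
            [_U8["A"], _U8["C"], _U8["G"], _U8["T"]], dtype=np.uint8
        )[seq]
        model = GeneModel(
            name=entry.name,
            contig=contig,
            strand=entry.strand,
            cds_intervals=intervals,
        )
        positions = np.concatenate(
            [np.arange(s, e) for s, e in intervals]
        )
        coding_arr = np.frombuffer(coding.encode(), dtype=np.uint8)
        if entry.strand == "+":
            arr[positions] = coding_arr
        else:
            comp = np.frombuffer(
                complement(coding).encode(), dtype=np.uint8
            )
            arr[positions] = comp[::-1]
        reference[contig] = arr.tobytes().decode()
        genes.append(model)
    # dedicated damage-calibration contig: carries only background reads
    ctrl_len = max(120_000, spec.read_length * 3)
    seq = rng.integers(0, 4, ctrl_len)
    reference[DAMAGE_CONTIG] = (
        np.array([_U8["A"], _U8["C"], _U8["G"], _U8["T"]], dtype=np.uint8)[seq]
        .tobytes()
        .decode()
    )
    return reference, genes


def _random_coding_sequence(length: int, rng: np.random.Generator) -> str:
    n_codons = length // 3
    codons = [
        _NON_STOP_CODONS[i]
        for i in rng.integers(0, len(_NON_STOP_CODONS), n_codons)
    ]
    codons[0] = "ATG"
    return "".join(codons)


def _split_exons(length: int, rng: np.random.Generator) -> list[int]:
    if length < 600:
        return [length]
    cuts = sorted(rng.integers(100, length - 100, 2).tolist())
    if cuts[1] - cuts[0] < 50:  # keep exons non-trivial
        return [length]
    return [cuts[0], cuts[1] - cuts[0], length - cuts[1]]


# ---------------------------------------------------------------------------
# truth planting
# ---------------------------------------------------------------------------

class PlantingError(RuntimeError):
    pass


def plant_site_truth(
    genes: Sequence[GeneModel],
    reference: dict[str, str],
    class_plan: ClassPlan,
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
    max_tries: int = 20_000,
) -> TruthTable:
    """Place every planned site, re-annotating each coding site against
    the emitted reference so planted fixed sites are guaranteed
    non-synonymous. Raises PlantingError after bounded retries."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    genes_by_name = {g.name: g for g in genes}
    used: dict[str, list[int]] = {}
    sites: list[PlantedSiteClass] = []
    for gene_name, counts in class_plan.items():
        if gene_name not in genes_by_name:
            raise PlantingError(f"plan names unknown gene {gene_name}")
        gene = genes_by_name[gene_name]
        flagged_remaining = 0
        if gene_name == spec.flagged_gene:
            flagged_remaining = min(2, counts.get(SiteClass.FIXED_POST, 0))
        for cls in SiteClass:
            for _ in range(counts.get(cls, 0)):
                require_pair = None
                if cls == SiteClass.FIXED_POST and flagged_remaining > 0:
                    require_pair = True
                    flagged_remaining -= 1
                sites.append(
                    _plant_one(
                        cls, gene, reference, spec, rng, used, require_pair, max_tries
                    )
                )
    ancient_gts, coverage, het_plans = _plan_ancient_states(sites, spec, rng)
    return TruthTable(
        sites=sites,
        ancient_genotypes=ancient_gts,
        ancient_coverage=coverage,
        het_plans=het_plans,
    )


def _plant_one(
    cls: SiteClass,
    gene: GeneModel,
    reference: dict[str, str],
    spec: CohortSpec,
    rng: np.random.Generator,
    used: dict[str, list[int]],
    damage_pair: Optional[bool],
    max_tries: int,
) -> PlantedSiteClass:
    contig = gene.contig
    ref_seq = reference[contig]
    taken = used.setdefault(contig, [])
    want_nonsyn = cls != SiteClass.SYNONYMOUS_BG
    for _ in range(max_tries):
        if cls == SiteClass.NO_FIXED_SITE_BACKGROUND:
            pos = _draw_flank_position(gene, len(ref_seq), spec, rng)
            if pos is None or _too_close(pos, taken, spec.min_spacing):
                continue
            ref_base = ref_seq[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            planted = PlantedSiteClass(
                site_class=cls,
                gene=gene.name,
                contig=contig,
                position=pos,
                ancestral=ref_base,
                derived=alt,
                brown_derived_freq=0.05,
                polar_derived_freq=0.95,
            )
            taken.append(pos)
            return planted
        cds_idx = int(rng.integers(0, gene.coding_length))
        pos = gene.genomic_position(cds_idx)
        if _too_close(pos, taken, spec.min_spacing):
            continue
        # keep targeted reads inside the contig
        if pos < spec.read_length or pos > len(ref_seq) - spec.read_length:
            continue
        ref_base = ref_seq[pos]
        if damage_pair:
            if ref_base == "C":
                candidates = ["T"]
            elif ref_base == "G":
                candidates = ["A"]
            else:
                continue
        else:
            candidates = list(rng.permutation([b for b in "ACGT" if b != ref_base]))
        probe = SiteCall(contig, pos, ref_base, ["A" if ref_base != "A" else "C"], [], [])
        alt_found = None
        for alt in candidates:
            ann = annotate_coding_effect(probe, [gene], reference, alt_allele=alt)
            assert ann is not None
            if ann.is_nonsynonymous == want_nonsyn:
                alt_found = alt
                break
        if alt_found is None:
            continue
        second_alt = None
        if cls == SiteClass.TRIALLELIC_BG:
            others = [b for b in "ACGT" if b not in (ref_base, alt_found)]
            second_alt = str(rng.choice(others))
        planted = PlantedSiteClass(
            site_class=cls,
            gene=gene.name,
            contig=contig,
            position=pos,
            ancestral=ref_base,
            derived=alt_found,
            brown_derived_freq=_draw_brown_freq(cls, rng),
            polar_derived_freq=_polar_freq(cls),
            second_alt=second_alt,
        )
        taken.append(pos)
        return planted
    raise PlantingError(
        f"could not place a {cls.value} site in {gene.name} after {max_tries} tries"
    )


def _too_close(pos: int, taken: list[int], spacing: int) -> bool:
    return any(abs(pos - t) < spacing for t in taken)


def _draw_flank_position(
    gene: GeneModel, contig_len: int, spec: CohortSpec, rng: np.random.Generator
) -> Optional[int]:
    lo_l = max(gene.start - 50_000, spec.read_length)
    hi_r = min(gene.end + 50_000, contig_len - spec.read_length)
    left = (lo_l, gene.start)
    right = (gene.end, hi_r)
    spans = [s for s in (left, right) if s[1] > s[0]]
    if not spans:
        return None
    lo, hi = spans[int(rng.integers(0, len(spans)))]
    return int(rng.integers(lo, hi))


def _draw_brown_freq(cls: SiteClass, rng: np.random.Generator) -> float:
    if cls == SiteClass.FIXED_DENOVO:
        return 0.0
    if cls in (SiteClass.FIXED_PRE, SiteClass.FIXED_POST, SiteClass.OUTGROUP_CONFLICT_BG,
               SiteClass.LOW_DEPTH_BG):
        return float(np.round(rng.uniform(0.05, 0.95), 3))
    if cls == SiteClass.SEGREGATING_POLAR:
        return float(np.round(rng.uniform(0.2, 0.8), 3))
    if cls == SiteClass.TRIALLELIC_BG:
        return 0.3
    return 0.5  # synonymous_bg


def _polar_freq(cls: SiteClass) -> float:
    if cls == SiteClass.SEGREGATING_POLAR:
        return 0.5
    return 1.0


_FLAGGED_HET = ((5, 20), (29, 100))  # (n_minor, coverage): proportions 0.25, 0.29


def _plan_ancient_states(
    sites: Sequence[PlantedSiteClass],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[
    dict[tuple[str, int], tuple[Genotype, ...]],
    dict[tuple[str, int], tuple[int, ...]],
    list[HetPlan],
]:
    base_cov = int(round(spec.depth_mean_ancient))
    genotypes: dict[tuple[str, int], tuple[Genotype, ...]] = {}
    coverage: dict[tuple[str, int], tuple[int, ...]] = {}
    het_plans: list[HetPlan] = []
    flagged_used = 0
    for s in sites:
        key = (s.contig, s.position)
        a, d = s.ancestral, s.derived
        gts: list[Genotype] = []
        covs: list[int] = []
        if s.site_class == SiteClass.FIXED_POST and spec.n_ancient > 0:
            het_idx = int(rng.integers(0, spec.n_ancient))
            is_flagged = (
                s.gene == spec.flagged_gene
                and flagged_used < len(_FLAGGED_HET)
                and set((a, d)) in ({"C", "T"}, {"G", "A"})
            )
            for i in range(spec.n_ancient):
                if i == het_idx:
                    if spec.ancient_post_state == "hom_ancestral":
                        gts.append((a, a))
                        covs.append(base_cov)
                    else:
                        if is_flagged:
                            n_minor, cov = _FLAGGED_HET[flagged_used]
                        else:
                            cov = base_cov
                            n_minor = int(rng.integers(
                                int(np.ceil(0.40 * cov)), cov // 2 + 1
                            ))
                        gts.append(tuple(sorted((a, d))))
                        covs.append(cov)
                        het_plans.append(
                            HetPlan(
                                contig=s.contig,
                                pos=s.position,
                                gene=s.gene,
                                ancient_index=i,
                                coverage=cov,
                                n_minor=n_minor,
                                minor_allele=a,
                                major_allele=d,
                            )
                        )
                else:
                    gts.append((d, d))
                    covs.append(base_cov)
            if is_flagged and spec.ancient_post_state == "het":
                flagged_used += 1
        elif s.site_class in (SiteClass.FIXED_PRE, SiteClass.FIXED_DENOVO):
            gts = [(d, d)] * spec.n_ancient
            covs = [base_cov] * spec.n_ancient
        else:
            # background sites: ancient polar bears are forced homozygous
            # so planted heterozygosity stays confined to fixed_post sites
            for _ in range(spec.n_ancient):
                gts.append((d, d) if rng.random() < s.polar_derived_freq else (a, a))
                covs.append(base_cov)
        # missingness applies uniformly
        for i in range(spec.n_ancient):
            if rng.random() < spec.ancient_missing_rate:
                gts[i] = None
                covs[i] = 0
        genotypes[key] = tuple(gts)
        coverage[key] = tuple(covs)
    return genotypes, coverage, het_plans


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def make_sample_metadata(spec: CohortSpec) -> list[SampleMeta]:
    samples: list[SampleMeta] = []
    for i in range(spec.n_polar_modern):
        samples.append(SampleMeta(f"polar_{i + 1:03d}", Species.POLAR, Era.MODERN))
    for i in range(spec.n_brown):
        samples.append(SampleMeta(f"brown_{i + 1:03d}", Species.BROWN, Era.MODERN))
    for i in range(spec.n_ancient):
        samples.append(SampleMeta(f"ancient_{i + 1}", Species.POLAR, Era.ANCIENT))
    taxa = ["spectacled_bear", "giant_panda"]
    for i in range(spec.n_outgroup):
        taxon = taxa[i] if i < len(taxa) else f"outgroup_taxon_{i + 1}"
        samples.append(
            SampleMeta(f"outgroup_{i + 1}", Species.OUTGROUP, Era.MODERN, taxon)
        )
    return samples


def simulate_genotypes(
    truth: TruthTable,
    spec: CohortSpec,
    contig_order: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SiteCall], list[SampleMeta], dict[tuple[str, int], np.ndarray]]:
    """Genotype table + per-sample depths + per-site AD matrices.

    Modern polar bears are homozygous derived at every fixed-class site;
    brown bears draw binomially at the planted frequency (with at least
    one derived allele enforced for standing-variation sites); outgroups
    are homozygous ancestral except at outgroup-conflict sites.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)
    samples = make_sample_metadata(spec)
    n = len(samples)
    np_, nb, na, no = (
        spec.n_polar_modern,
        spec.n_brown,
        spec.n_ancient,
        spec.n_outgroup,
    )
    polar_sl = slice(0, np_)
    brown_sl = slice(np_, np_ + nb)
    ancient_sl = slice(np_ + nb, np_ + nb + na)
    out_sl = slice(np_ + nb + na, n)

    order = {c: i for i, c in enumerate(contig_order)}
    planted = sorted(truth.sites, key=lambda s: (order[s.contig], s.position))
    sites: list[SiteCall] = []
    allele_depths: dict[tuple[str, int], np.ndarray] = {}
    n_low = int(np.floor(np_ * 0.1)) + 3  # enough to break a 0.9 callable guard
    for s in planted:
        key = (s.contig, s.position)
        a, d = s.ancestral, s.derived
        genotypes: list[Genotype] = [None] * n
        depths = np.zeros(n, dtype=int)
        depths[polar_sl] = np.maximum(rng.poisson(spec.depth_mean_modern, np_), 4)
        depths[brown_sl] = np.maximum(rng.poisson(spec.depth_mean_modern, nb), 4)
        depths[out_sl] = np.maximum(rng.poisson(spec.depth_mean_modern, no), 4)

        # modern polar
        if s.site_class == SiteClass.SEGREGATING_POLAR:
            draws = rng.binomial(2, s.polar_derived_freq, np_)
            if (draws == 2).all() or (draws == 0).all():
                draws[0] = 1
            polar = [_gt_from_dosage(k, a, d) for k in draws]
        elif s.site_class == SiteClass.NO_FIXED_SITE_BACKGROUND:
            draws = rng.binomial(2, s.polar_derived_freq, np_)
            if (draws == 2).all():
                draws[0] = 1
            polar = [_gt_from_dosage(k, a, d) for k in draws]
        else:
            polar = [(d, d)] * np_
        genotypes[polar_sl] = polar
        if s.site_class == SiteClass.LOW_DEPTH_BG:
            low_idx = rng.choice(np_, size=min(n_low, np_), replace=False)
            depths[low_idx] = rng.integers(0, 4, len(low_idx))

        # brown
        draws = rng.binomial(2, s.brown_derived_freq, nb)
        if s.site_class == SiteClass.FIXED_DENOVO:
            draws[:] = 0
        elif s.site_class in (
            SiteClass.FIXED_PRE,
            SiteClass.FIXED_POST,
            SiteClass.OUTGROUP_CONFLICT_BG,
            SiteClass.LOW_DEPTH_BG,
        ):
            if draws.sum() == 0 and nb > 0:
                draws[0] = 1
        brown = [_gt_from_dosage(k, a, d) for k in draws]
        if s.site_class == SiteClass.TRIALLELIC_BG and nb >= 3:
            for j in range(3):
                brown[j] = tuple(sorted((a, s.second_alt)))  # type: ignore[arg-type]
        genotypes[brown_sl] = brown

        # ancients
        anc_gts = truth.ancient_genotypes[key]
        anc_cov = truth.ancient_coverage[key]
        genotypes[ancient_sl] = list(anc_gts)
        depths[ancient_sl] = list(anc_cov)

        # outgroups
        outg: list[Genotype] = [(a, a)] * no
        if s.site_class == SiteClass.OUTGROUP_CONFLICT_BG and no > 0:
            outg[0] = tuple(sorted((a, d)))  # type: ignore[assignment]
        genotypes[out_sl] = outg

        alts = [d] + ([s.second_alt] if s.second_alt else [])
        site = SiteCall(
            contig=s.contig,
            pos=s.position,
            ref_allele=a,
            alt_alleles=alts,
            genotypes=genotypes,
            depths=depths,
        )
        sites.append(site)
        allele_depths[key] = _allele_depth_matrix(site)
    return sites, samples, allele_depths


def _gt_from_dosage(k: int, ancestral: str, derived: str) -> tuple[str, str]:
    if k == 0:
        return (ancestral, ancestral)
    if k == 1:
        return tuple(sorted((ancestral, derived)))  # type: ignore[return-value]
    return (derived, derived)


def _allele_depth_matrix(site: SiteCall) -> np.ndarray:
    # even split for heterozygotes; ancient rows are patched afterwards
    # from the realised read pileups
    idx = {al: i for i, al in enumerate(site.alleles)}
    ad = np.zeros((len(site.genotypes), len(site.alleles)), dtype=int)
    for j, (gt, dp) in enumerate(zip(site.genotypes, site.depths)):
        if gt is None or dp <= 0:
            continue
        if gt[0] == gt[1]:
            ad[j, idx[gt[0]]] = dp
        else:
            ad[j, idx[gt[0]]] = dp // 2
            ad[j, idx[gt[1]]] = dp - dp // 2
    return ad


# ---------------------------------------------------------------------------
# ancient reads + damage
# ---------------------------------------------------------------------------

def simulate_ancient_reads(
    truth: TruthTable,
    spec: CohortSpec,
    reference: dict[str, str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[AncientRead], list[BaseCountRecord]]:
    """Targeted reads over every planted site plus background reads on a
    dedicated calibration contig, with terminal deamination applied.

    C->T flips are applied from the 5' end and G->A from the 3' end with
    probability rate * decay**position. The focal planted base of each
    targeted read is exempt from damage and sequencing error so planted
    genotype proportions are realised exactly; minor-allele bases are
    always placed mid-read (>= 10 bp from either end).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 3)
    L = spec.read_length
    margin = 10
    reads: list[AncientRead] = []
    het_lookup = {(hp.contig, hp.pos, hp.ancient_index): hp for hp in truth.het_plans}
    sample_ids = [f"ancient_{i + 1}" for i in range(spec.n_ancient)]
    for i in range(spec.n_ancient):
        rate = spec.damage_rate_per_ancient[i]
        seqs: list[np.ndarray] = []
        starts: list[int] = []
        contigs: list[str] = []
        exempts: list[int] = []
        for s in sorted(truth.sites, key=lambda x: (x.contig, x.position)):
            key = (s.contig, s.position)
            gt = truth.ancient_genotypes[key][i]
            cov = truth.ancient_coverage[key][i]
            if gt is None or cov <= 0:
                continue
            hp = het_lookup.get((s.contig, s.position, i))
            if hp is not None:
                bases = [hp.minor_allele] * hp.n_minor + [hp.major_allele] * (
                    hp.coverage - hp.n_minor
                )
            else:
                bases = [gt[0]] * cov  # homozygous
            offsets = rng.integers(margin, L - margin, len(bases))
            ref = reference[s.contig]
            for base, off in zip(bases, offsets):
                start = s.position - int(off)
                chunk = np.frombuffer(
                    ref[start : start + L].encode(), dtype=np.uint8
                ).copy()
                chunk[int(off)] = _U8[base]
                seqs.append(chunk)
                starts.append(start)
                contigs.append(s.contig)
                exempts.append(int(off))
        n_targeted = len(seqs)
        # background reads for damage calibration
        ctrl = reference[DAMAGE_CONTIG]
        bg_starts = rng.integers(0, len(ctrl) - L, spec.n_background_reads)
        ctrl_arr = np.frombuffer(ctrl.encode(), dtype=np.uint8)
        for st in bg_starts:
            seqs.append(ctrl_arr[st : st + L].copy())
            starts.append(int(st))
            contigs.append(DAMAGE_CONTIG)
            exempts.append(-1)
        mat = np.vstack(seqs) if seqs else np.zeros((0, L), dtype=np.uint8)
        exempt_arr = np.array(exempts, dtype=int)
        _apply_damage(mat, rate, spec.damage_decay, rng, exempt_arr)
        if spec.sequencing_error_rate > 0:
            _apply_sequencing_error(mat, spec.sequencing_error_rate, rng, exempt_arr)
        for row, st, ctg in zip(mat, starts, contigs):
            reads.append(
                AncientRead(
                    sample_id=sample_ids[i],
                    contig=ctg,
                    start=st,
                    sequence=bytes(row).decode(),
                )
            )
        del mat
    positions = {(s.contig, s.position) for s in truth.sites}
    counts = recount_base_counts(reads, positions)
    return reads, counts


def _apply_damage(
    mat: np.ndarray,
    rate: float,
    decay: float,
    rng: np.random.Generator,
    exempt_offsets: np.ndarray,
) -> None:
    if mat.size == 0 or rate <= 0:
        return
    n, L = mat.shape
    rows = np.arange(n)
    exempt = np.zeros((n, L), dtype=bool)
    has = exempt_offsets >= 0
    exempt[rows[has], exempt_offsets[has]] = True
    for p in range(L):
        prob = rate * decay**p
        if prob < 1e-12:
            break
        hit = (
            (mat[:, p] == _U8["C"]) & ~exempt[:, p] & (rng.random(n) < prob)
        )
        mat[hit, p] = _U8["T"]
        col = L - 1 - p
        hit = (
            (mat[:, col] == _U8["G"]) & ~exempt[:, col] & (rng.random(n) < prob)
        )
        mat[hit, col] = _U8["A"]


def _apply_sequencing_error(
    mat: np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
    exempt_offsets: np.ndarray,
) -> None:
    n, L = mat.shape
    rows = np.arange(n)
    err = rng.random((n, L)) < error_rate
    has = exempt_offsets >= 0
    err[rows[has], exempt_offsets[has]] = False
    if not err.any():
        return
    shift = rng.integers(1, 4, err.sum())
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    inv = {int(_U8[b]): k for k, b in enumerate("ACGT")}
    vals = mat[err]
    codes = np.array([inv[int(v)] for v in vals])
    mat[err] = lut[(codes + shift) % 4]


def recount_base_counts(
    reads: Sequence[AncientRead], positions: set[tuple[str, int]]
) -> list[BaseCountRecord]:
    """Pileup of the emitted reads at the planted positions — the base
    count table is derived from the reads, never stated independently."""
    by_contig: dict[str, np.ndarray] = {}
    for contig in {c for c, _ in positions}:
        by_contig[contig] = np.array(sorted(p for c, p in positions if c == contig))
    acc: dict[tuple[str, int, str], dict[str, int]] = {}
    for r in reads:
        pos_arr = by_contig.get(r.contig)
        if pos_arr is None or pos_arr.size == 0:
            continue
        lo = np.searchsorted(pos_arr, r.start, side="left")
        hi = np.searchsorted(pos_arr, r.end - 1, side="right")
        for p in pos_arr[lo:hi]:
            base = r.sequence[p - r.start]
            if base not in "ACGT":
                continue
            key = (r.contig, int(p), r.sample_id)
            acc.setdefault(key, {"A": 0, "C": 0, "G": 0, "T": 0})[base] += 1
    out = []
    for (contig, pos, sample), c in sorted(acc.items()):
        out.append(
            BaseCountRecord(
                contig=contig,
                pos=pos,
                sample_id=sample,
                n_a=c["A"],
                n_c=c["C"],
                n_g=c["G"],
                n_t=c["T"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# full cohort + fixture writing
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    spec: CohortSpec
    reference: dict[str, str]
    genes: list[GeneModel]
    truth: TruthTable
    samples: list[SampleMeta]
    sites: list[SiteCall]
    allele_depths: dict[tuple[str, int], np.ndarray]
    reads: list[AncientRead]
    base_counts: list[BaseCountRecord]


def generate_cohort(
    spec: CohortSpec,
    gene_plan: Sequence[GenePlanEntry] = DEFAULT_GENE_PLAN,
    class_plan: Optional[ClassPlan] = None,
) -> SyntheticCohort:
    """Run every generation stage off a single seed."""
    rng = np.random.default_rng(spec.seed)
    reference, genes = generate_reference_and_genes(spec, gene_plan, rng)
    if class_plan is None:
        class_plan = default_class_plan(gene_plan)
    truth = plant_site_truth(genes, reference, class_plan, spec, rng)
    contig_order = [g.contig for g in genes] + [DAMAGE_CONTIG]
    sites, samples, allele_depths = simulate_genotypes(truth, spec, contig_order, rng)
    reads, base_counts = simulate_ancient_reads(truth, spec, reference, rng)
    # patch ancient AD to match the realised read pileups
    counts_by_key = {(c.contig, c.pos, c.sample_id): c for c in base_counts}
    ancient_ids = [s.sample_id for s in samples if s.era == Era.ANCIENT]
    sample_index = {s.sample_id: j for j, s in enumerate(samples)}
    for site in sites:
        ad = allele_depths[(site.contig, site.pos)]
        for sid in ancient_ids:
            rec = counts_by_key.get((site.contig, site.pos, sid))
            if rec is None:
                continue
            j = sample_index[sid]
            ad[j] = [rec.count(a) for a in site.alleles]
    return SyntheticCohort(
        spec=spec,
        reference=reference,
        genes=genes,
        truth=truth,
        samples=samples,
        sites=sites,
        allele_depths=allele_depths,
        reads=reads,
        base_counts=base_counts,
    )


TRUTH_COLUMNS = [
    "gene",
    "contig",
    "pos",
    "class",
    "ancestral",
    "derived",
    "brown_freq",
    "second_alt",
    "ancient_genotypes",
    "het_ancient",
    "het_coverage",
    "het_n_minor",
]


def write_fixture(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact; returns the path of each file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "gff": outdir / "genes.gff3",
        "vcf": outdir / "genotypes.vcf",
        "metadata": outdir / "samples.tsv",
        "base_counts": outdir / "base_counts.tsv",
        "reads": outdir / "reads.tsv",
        "truth": outdir / "truth.tsv",
    }
    io_formats.write_fasta(cohort.reference, paths["reference"])
    io_formats.write_gff3(cohort.genes, paths["gff"])
    contig_lengths = {name: len(seq) for name, seq in cohort.reference.items()}
    io_formats.write_vcf(
        cohort.sites,
        cohort.samples,
        contig_lengths,
        paths["vcf"],
        allele_depths=cohort.allele_depths,
    )
    io_formats.write_sample_metadata(cohort.samples, paths["metadata"])
    io_formats.write_base_counts(cohort.base_counts, paths["base_counts"])
    io_formats.write_reads(cohort.reads, paths["reads"])
    write_truth_table(cohort.truth, paths["truth"])
    return paths


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    het_by_key = {(hp.contig, hp.pos): hp for hp in truth.het_plans}
    rows = []
    for s in sorted(truth.sites, key=lambda x: (x.contig, x.position)):
        key = (s.contig, s.position)
        gts = truth.ancient_genotypes.get(key, ())
        gt_str = ",".join("./." if g is None else f"{g[0]}/{g[1]}" for g in gts)
        hp = het_by_key.get(key)
        rows.append(
            {
                "gene": s.gene,
                "contig": s.contig,
                "pos": s.position + 1,
                "class": s.site_class.value,
                "ancestral": s.ancestral,
                "derived": s.derived,
                "brown_freq": s.brown_derived_freq,
                "second_alt": s.second_alt or "",
                "ancient_genotypes": gt_str,
                "het_ancient": hp.ancient_index + 1 if hp else "",
                "het_coverage": hp.coverage if hp else "",
                "het_n_minor": hp.n_minor if hp else "",
            }
        )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"].astype(int) - 1
    return df
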