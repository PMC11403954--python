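"""End-to-end orchestration: io -> filter -> polarity -> timing ->
damage QC -> PCA, with every stage writing an auditable TSV and the run
ending in a consolidated per-site report plus a plain-text summary.

All thresholds are echoed into the summary header; reruns with the same
config are byte-identical.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .annotation import (
    FilterFate,
    FilterThresholds,
    SiteFate,
    apply_depth_mask,
    select_candidate_sites,
)
from .damage import (
    HetValidation,
    estimate_damage_profile,
    flag_damage_candidates,
    minor_allele_position_check,
    validate_heterozygote,
)
from .models import Era, GeneModel, SampleMeta, SiteCall, Species
from .pca import build_dosage_matrix, extract_gene_region, pca, species_separation
from .polarity import Origin, classify_sites, summarize_by_gene
from .timing import TimingClass, classify_timing, timing_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    reference: str
    gff: str
    vcf: str
    metadata: str
    outdir: str
    base_counts: Optional[str] = None
    reads: Optional[str] = None
    exclude_genes: list[str] = field(default_factory=lambda: ["EDH3"])
    min_depth: int = 4
    min_callable_fraction: float = 0.9
    allow_single_outgroup: bool = False
    timing_strict: bool = False
    het_threshold: float = 0.30
    terminal_window: int = 5
    rescue_cutoff: float = 0.5
    pca_flank: int = 50_000
    pca_completeness: float = 0.95
    pca_min_maf: float = 0.0
    pca_separation_threshold: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.het_threshold <= 0.5):
            raise ValueError("het_threshold must be in [0, 0.5]")
        if not (0 <= self.rescue_cutoff <= 1):
            raise ValueError("rescue_cutoff must be in [0, 1]")
        if self.terminal_window < 1:
            raise ValueError("terminal_window must be >= 1")
        if self.pca_flank < 0:
            raise ValueError("pca_flank must be >= 0")

    @property
    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            min_depth=self.min_depth,
            min_callable_fraction=self.min_callable_fraction,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def echo_lines(self) -> list[str]:
        return [
            f"{k} = {self.__dict__[k]}" for k in sorted(self.__dict__)
        ]


@dataclass
class PipelineInputs:
    reference: dict[str, str]
    genes: list[GeneModel]
    metadata: list[SampleMeta]
    sites: list[SiteCall]          # depth-masked
    raw_sites: list[SiteCall]
    base_counts: list
    reads: list


def load_inputs(config: PipelineConfig) -> PipelineInputs:
    for name in ("reference", "gff", "vcf", "metadata"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} file not found: {p}")
    reference = io_formats.read_fasta(config.reference)
    genes = [
        g
        for g in io_formats.read_gene_models(config.gff)
        if g.name not in set(config.exclude_genes)
    ]
    metadata = io_formats.read_sample_metadata(config.metadata)
    raw_sites = io_formats.read_vcf_genotypes(config.vcf, metadata)
    excluded_contigs = {
        g.contig
        for g in io_formats.read_gene_models(config.gff)
        if g.name in set(config.exclude_genes)
    }
    raw_sites = [s for s in raw_sites if s.contig not in excluded_contigs]
    masked = apply_depth_mask(raw_sites, config.thresholds)
    base_counts = (
        io_formats.read_base_counts(config.base_counts)
        if config.base_counts and Path(config.base_counts).exists()
        else []
    )
    reads = (
        io_formats.read_reads(config.reads)
        if config.reads and Path(config.reads).exists()
        else []
    )
    logger.info(
        "loaded %d sites, %d samples, %d genes",
        len(raw_sites),
        len(metadata),
        len(genes),
    )
    return PipelineInputs(
        reference=reference,
        genes=genes,
        metadata=metadata,
        sites=masked,
        raw_sites=raw_sites,
        base_counts=base_counts,
        reads=reads,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_filter_stage(
    inputs: PipelineInputs, config: PipelineConfig
) -> tuple[list[SiteFate], pd.DataFrame]:
    fates = select_candidate_sites(
        inputs.sites,
        inputs.metadata,
        inputs.genes,
        inputs.reference,
        config.thresholds,
    )
    rows = []
    for f in fates:
        ann = f.annotation
        rows.append(
            {
                "contig": f.site.contig,
                "pos": f.site.pos,
                "gene": ann.gene if ann else "",
                "fate": f.fate.value,
                "allelic_state": f.allelic_state.value,
                "is_nonsynonymous": ann.is_nonsynonymous if ann else "",
                "ref_aa": ann.ref_aa if ann else "",
                "alt_aa": ann.alt_aa if ann else "",
                "callable_fraction_polar": round(f.callable_fraction_polar, 6),
                "callable_fraction_brown": round(f.callable_fraction_brown, 6),
            }
        )
    df = pd.DataFrame(rows)
    counts = df["fate"].value_counts().to_dict() if not df.empty else {}
    logger.info("filter fates: %s", counts)
    return fates, df


def run_classify_stage(
    fates: Sequence[SiteFate], inputs: PipelineInputs, config: PipelineConfig
) -> pd.DataFrame:
    retained = [f for f in fates if f.fate == FilterFate.RETAINED]
    sites = [f.site for f in retained]
    gene_of = {
        (f.site.contig, f.site.pos): f.annotation.gene
        for f in retained
        if f.annotation
    }
    df = classify_sites(
        sites,
        inputs.metadata,
        allow_single_outgroup=config.allow_single_outgroup,
    )
    if not df.empty:
        df["gene"] = [
            gene_of.get((c, p), "") for c, p in zip(df["contig"], df["pos"])
        ]
    logger.info(
        "origin classes: %s",
        df["origin_class"].value_counts().to_dict() if not df.empty else {},
    )
    return df


def run_timing_stage(
    classifications: pd.DataFrame,
    inputs: PipelineInputs,
    config: PipelineConfig,
) -> pd.DataFrame:
    ancient_idx = [
        i for i, s in enumerate(inputs.metadata) if s.era == Era.ANCIENT
    ]
    site_by_key = {(s.contig, s.pos): s for s in inputs.sites}
    rows = []
    fixed = classifications[
        classifications["origin_class"].isin(
            [Origin.STANDING_VARIATION.value, Origin.DE_NOVO.value]
        )
    ]
    for _, row in fixed.iterrows():
        site = site_by_key[(row["contig"], row["pos"])]
        call = classify_timing(
            [site.genotypes[i] for i in ancient_idx],
            derived=row["derived"],
            strict=config.timing_strict,
        )
        rows.append(
            {
                "gene": row["gene"],
                "contig": row["contig"],
                "pos": row["pos"],
                "timing_class": call.timing.value,
                "ancient_states": ",".join(s.value for s in call.ancient_states),
                "low_confidence": call.low_confidence,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "contig",
            "pos",
            "timing_class",
            "ancient_states",
            "low_confidence",
        ],
    )
    logger.info(
        "timing classes: %s",
        df["timing_class"].value_counts().to_dict() if not df.empty else {},
    )
    return df


def run_damage_stage(
    fates: Sequence[SiteFate],
    inputs: PipelineInputs,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Damage profiles per ancient sample + heterozygote validation over
    ancient het calls at retained candidate sites."""
    ancient = [
        (i, s) for i, s in enumerate(inputs.metadata) if s.era == Era.ANCIENT
    ]
    profile_rows = []
    for _, meta in ancient:
        sample_reads = [r for r in inputs.reads if r.sample_id == meta.sample_id]
        profile = estimate_damage_profile(sample_reads, inputs.reference)
        pf = profile.to_frame()
        pf.insert(0, "sample", meta.sample_id)
        profile_rows.append(pf)
    profiles = (
        pd.concat(profile_rows, ignore_index=True)
        if profile_rows
        else pd.DataFrame(
            columns=["sample", "end", "position", "rate", "mismatches", "opportunities"]
        )
    )

    counts_by_key = {
        (c.contig, c.pos, c.sample_id): c for c in inputs.base_counts
    }
    validations: list[HetValidation] = []
    for f in fates:
        if f.fate != FilterFate.RETAINED:
            continue
        site = f.site
        gene = f.annotation.gene if f.annotation else ""
        for i, meta in ancient:
            gt = site.genotypes[i]
            if gt is None or gt[0] == gt[1]:
                continue
            rec = counts_by_key.get((site.contig, site.pos, meta.sample_id))
            if rec is None:
                logger.warning(
                    "no base counts for het call %s:%d %s",
                    site.contig,
                    site.pos + 1,
                    meta.sample_id,
                )
                continue
            v = validate_heterozygote(
                rec, (gt[0], gt[1]), threshold=config.het_threshold, gene=gene
            )
            v = minor_allele_position_check(
                inputs.reads,
                v,
                k=config.terminal_window,
                rescue_cutoff=config.rescue_cutoff,
            )
            validations.append(v)
    damage_df, counts = flag_damage_candidates(validations)
    het_df = pd.DataFrame(
        {
            "gene": [v.gene for v in validations],
            "contig": [v.contig for v in validations],
            "pos": [v.pos + 1 for v in validations],
            "sample": [v.sample_id for v in validations],
            "allele_pair": ["/".join(v.allele_pair) for v in validations],
            "is_damage_type": [v.is_damage_type for v in validations],
            "minor_base_proportion": [
                round(v.minor_base_proportion, 6) for v in validations
            ],
            "proportion_flagged": [v.proportion_flagged for v in validations],
            "terminal_minor_fraction": [
                "" if v.terminal_minor_fraction is None else round(v.terminal_minor_fraction, 6)
                for v in validations
            ],
            "verdict": [v.verdict.value for v in validations],
        }
    )
    logger.info("het validation: %s", counts)
    return profiles, het_df, counts


def run_pca_stage(
    inputs: PipelineInputs, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    coord_rows, eig_rows, sep_rows = [], [], []
    for gene in inputs.genes:
        contig_len = len(inputs.reference.get(gene.contig, ""))
        region = extract_gene_region(
            inputs.sites, gene, flank=config.pca_flank, contig_length=contig_len or None
        )
        dosage = build_dosage_matrix(
            region,
            inputs.metadata,
            completeness=config.pca_completeness,
            min_maf=config.pca_min_maf,
        )
        if dosage is None:
            sep_rows.append(
                {
                    "gene": gene.name,
                    "n_sites": 0,
                    "separation": np.nan,
                    "passes": False,
                }
            )
            continue
        result = pca(dosage)
        sep = species_separation(result, inputs.metadata)
        n_pc = min(2, result.coordinates.shape[1])
        for sid, coords in zip(result.sample_ids, result.coordinates):
            coord_rows.append(
                {
                    "gene": gene.name,
                    "sample": sid,
                    "PC1": round(float(coords[0]), 6),
                    "PC2": round(float(coords[1]), 6) if n_pc > 1 else 0.0,
                }
            )
        for k, ev in enumerate(result.eigenvalues, 1):
            eig_rows.append(
                {"gene": gene.name, "component": k, "eigenvalue": round(float(ev), 8)}
            )
        sep_rows.append(
            {
                "gene": gene.name,
                "n_sites": dosage.matrix.shape[1],
                "separation": round(float(sep), 6),
                "passes": bool(sep >= config.pca_separation_threshold),
            }
        )
    return (
        pd.DataFrame(coord_rows, columns=["gene", "sample", "PC1", "PC2"]),
        pd.DataFrame(eig_rows, columns=["gene", "component", "eigenvalue"]),
        pd.DataFrame(sep_rows, columns=["gene", "n_sites", "separation", "passes"]),
    )


# ---------------------------------------------------------------------------
# consolidated run
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    n_sites: int
    fate_counts: dict
    origin_counts: dict
    timing_totals: dict
    gene_summary: pd.DataFrame
    het_counts: dict
    site_report: pd.DataFrame
    pca_separation: pd.DataFrame


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(config)

    fates, fates_df = run_filter_stage(inputs, config)
    _write_stage_tsv(fates_df, outdir / "filter_fates.tsv")

    classifications = run_classify_stage(fates, inputs, config)
    _write_stage_tsv(classifications, outdir / "classification.tsv")

    timed = run_timing_stage(classifications, inputs, config)
    _write_stage_tsv(timed, outdir / "timing.tsv")
    timing_totals, _ = timing_summary(timed)

    joined = classifications.merge(
        timed[["contig", "pos", "timing_class", "ancient_states", "low_confidence"]],
        on=["contig", "pos"],
        how="left",
    )
    gene_summary = summarize_by_gene(joined)
    _write_stage_tsv(gene_summary, outdir / "gene_summary.tsv")

    profiles, het_df, het_counts = run_damage_stage(fates, inputs, config)
    _write_stage_tsv(profiles, outdir / "damage_profile.tsv")
    _write_stage_tsv(het_df, outdir / "het_validation.tsv")

    coords, eigs, seps = run_pca_stage(inputs, config)
    _write_stage_tsv(coords, outdir / "pca_coordinates.tsv")
    _write_stage_tsv(eigs, outdir / "pca_eigenvalues.tsv")
    _write_stage_tsv(seps, outdir / "pca_separation.tsv")

    report = _build_site_report(fates_df, joined)
    io_formats.write_site_report(report, outdir / "site_report.tsv")

    fate_counts = (
        fates_df["fate"].value_counts().to_dict() if not fates_df.empty else {}
    )
    origin_counts = (
        classifications["origin_class"].value_counts().to_dict()
        if not classifications.empty
        else {}
    )
    result = PipelineResult(
        n_sites=len(inputs.sites),
        fate_counts=fate_counts,
        origin_counts=origin_counts,
        timing_totals=timing_totals,
        gene_summary=gene_summary,
        het_counts=het_counts,
        site_report=report,
        pca_separation=seps,
    )
    _write_summary(result, config, outdir / "summary.txt")
    return result


def _build_site_report(fates_df: pd.DataFrame, joined: pd.DataFrame) -> pd.DataFrame:
    """One row per candidate site entering classification; asterisk-style
    flag for sites where at least one ancient individual is not
    homozygous derived."""
    if joined.empty:
        return pd.DataFrame(columns=io_formats.SITE_REPORT_COLUMNS)
    df = joined.copy()
    df["filter_fate"] = FilterFate.RETAINED.value
    df["timing_class"] = df["timing_class"].fillna("")
    df["ancient_states"] = df["ancient_states"].fillna("")
    df["low_confidence"] = df["low_confidence"].map(
        lambda x: bool(x) if pd.notna(x) else False
    )
    df["ancient_not_fixed"] = df["ancient_states"].str.contains(
        "carries_ancestral", na=False
    )
    return df[io_formats.SITE_REPORT_COLUMNS]


def _write_stage_tsv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    if "pos" in out.columns and path.name in (
        "filter_fates.tsv",
        "classification.tsv",
        "timing.tsv",
    ):
        out["pos"] = out["pos"].astype(int) + 1  # 1-based on disk
    out.to_csv(path, sep="\t", index=False)


def _write_summary(
    result: PipelineResult, config: PipelineConfig, path: Path
) -> None:
    lines = ["# pipeline summary", "", "## configuration"]
    lines += [f"  {line}" for line in config.echo_lines()]
    lines += ["", "## counts"]
    lines.append(f"  input sites: {result.n_sites}")
    for fate in sorted(result.fate_counts):
        lines.append(f"  fate {fate}: {result.fate_counts[fate]}")
    for origin in sorted(result.origin_counts):
        lines.append(f"  origin {origin}: {result.origin_counts[origin]}")
    n_fixed = result.origin_counts.get(
        Origin.STANDING_VARIATION.value, 0
    ) + result.origin_counts.get(Origin.DE_NOVO.value, 0)
    lines.append(f"  fixed derived sites: {n_fixed}")
    for k in ("pre_fixed", "post_fixed", "unresolved"):
        lines.append(f"  timing {k}: {result.timing_totals.get(k, 0)}")
    lines.append(
        "  genes with post-fixed sites: "
        + ",".join(result.timing_totals.get("genes_with_post_fixed", []))
    )
    lines += ["", "## per-gene summary"]
    for _, row in result.gene_summary.iterrows():
        lines.append(
            f"  {row['gene']}: fixed={row['n_fixed']} pre={row['n_pre_fixed']} "
            f"post={row['n_post_fixed']} unresolved={row['n_unresolved']}"
        )
    lines += ["", "## heterozygote validation"]
    for k in sorted(result.het_counts):
        lines.append(f"  {k}: {result.het_counts[k]}")
    lines += ["", "## pca separation"]
    for _, row in result.pca_separation.iterrows():
        lines.append(
            f"  {row['gene']}: n_sites={row['n_sites']} "
            f"separation={row['separation']} passes={row['passes']}"
        )
    path.write_text("\n".join(lines) + "\n")
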