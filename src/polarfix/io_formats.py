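"""Readers and writers for every external format the pipeline touches.

All readers validate their schema strictly and never drop rows silently:
a malformed record raises with the offending line or column named.
Writers are deterministic (stable row order, fixed float formatting) so
that reruns are byte-identical.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .models import (
    BaseCountRecord,
    Era,
    GeneModel,
    Genotype,
    SampleMeta,
    SiteCall,
    Species,
)

logger = logging.getLogger(__name__)

VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
]

#: Column order of the consolidated per-site report (stable contract).
SITE_REPORT_COLUMNS = [
    "gene",
    "contig",
    "pos",
    "ancestral",
    "derived",
    "filter_fate",
    "origin_class",
    "removal_reason",
    "brown_derived_count",
    "brown_called_alleles",
    "brown_derived_freq",
    "timing_class",
    "ancient_states",
    "ancient_not_fixed",
    "low_confidence",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "species", "era"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("metadata file contains no samples")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    out = []
    for _, row in df.iterrows():
        taxon = row.get("outgroup_taxon")
        if isinstance(taxon, float) and np.isnan(taxon):
            taxon = None
        out.append(
            SampleMeta(
                sample_id=row["sample_id"],
                species=Species(row["species"]),
                era=Era(row["era"]),
                outgroup_taxon=taxon or None,
            )
        )
    return out


def write_sample_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "species": [s.species.value for s in samples],
            "era": [s.era.value for s in samples],
            "outgroup_taxon": [s.outgroup_taxon or "" for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_genotypes(
    path: str | Path, metadata: Sequence[SampleMeta]
) -> list[SiteCall]:
    """Read GT/DP/AD from a VCF into SiteCall records.

    VCF 1-based positions become 0-based. Depth precedence is DP, then
    sum(AD), then missing (-1). Sample columns must be exactly the
    metadata ids, in order.
    """
    vcf = VCF(str(path))
    meta_ids = [s.sample_id for s in metadata]
    if list(vcf.samples) != meta_ids:
        raise ValueError(
            "VCF samples do not match metadata: "
            f"vcf={list(vcf.samples)[:5]}... meta={meta_ids[:5]}..."
        )
    sites: list[SiteCall] = []
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        genotypes: list[Genotype] = []
        for g in var.genotypes:
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                genotypes.append(None)
            else:
                pair = tuple(sorted((alleles[a], alleles[b])))
                genotypes.append(pair)  # type: ignore[arg-type]
        dp = var.format("DP")
        ad = var.format("AD")
        n = len(meta_ids)
        depths = np.full(n, -1, dtype=int)
        if dp is not None:
            d = dp.reshape(n).astype(int)
            depths = np.where(d >= 0, d, -1)
        if ad is not None:
            ad_arr = ad.reshape(n, -1)
            ad_sum = np.where(ad_arr < 0, 0, ad_arr).sum(axis=1)
            has_ad = (ad_arr >= 0).any(axis=1)
            depths = np.where((depths < 0) & has_ad, ad_sum, depths)
        sites.append(
            SiteCall(
                contig=var.CHROM,
                pos=var.POS - 1,
                ref_allele=var.REF,
                alt_alleles=list(var.ALT),
                genotypes=genotypes,
                depths=depths,
            )
        )
    return sites


def write_vcf(
    sites: Sequence[SiteCall],
    samples: Sequence[SampleMeta],
    contig_lengths: dict[str, int],
    path: str | Path,
    allele_depths: dict[tuple[str, int], np.ndarray] | None = None,
) -> None:
    """Write a plain-text VCF 4.2 with GT, DP and AD per sample.

    ``allele_depths`` optionally maps (contig, pos) to an (n_samples,
    n_alleles) array; when absent AD puts all depth on the called
    alleles (even split for heterozygotes).
    """
    lines = list(VCF_HEADER_LINES)
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    sample_ids = [s.sample_id for s in samples]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    order = {name: i for i, name in enumerate(contig_lengths)}
    for site in sorted(sites, key=lambda s: (order[s.contig], s.pos)):
        alleles = site.alleles
        idx = {a: i for i, a in enumerate(alleles)}
        n_alleles = len(alleles)
        ad_matrix = None
        if allele_depths is not None:
            ad_matrix = allele_depths.get((site.contig, site.pos))
        cols = []
        for j, (gt, dp) in enumerate(zip(site.genotypes, site.depths)):
            dp_str = str(dp) if dp >= 0 else "."
            if gt is None:
                gt_str = "./."
                ad = [0] * n_alleles
            else:
                i0, i1 = sorted((idx[gt[0]], idx[gt[1]]))
                gt_str = f"{i0}/{i1}"
                ad = [0] * n_alleles
                d = max(dp, 0)
                if i0 == i1:
                    ad[i0] = d
                else:
                    ad[i0] = d // 2
                    ad[i1] = d - d // 2
            if ad_matrix is not None:
                ad = [int(x) for x in ad_matrix[j]]
            cols.append(f"{gt_str}:{dp_str}:{','.join(map(str, ad))}")
        lines.append(
            "\t".join(
                [
                    site.contig,
                    str(site.pos + 1),
                    ".",
                    site.ref_allele,
                    ",".join(site.alt_alleles),
                    ".",
                    "PASS",
                    ".",
                    "GT:DP:AD",
                    *cols,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse CDS features from GFF3 into GeneModel records.

    Intervals become 0-based half-open, sorted ascending per gene. A
    gene whose total CDS length is not divisible by 3 is kept but
    logged as a warning.
    """
    by_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line {lineno}: expected 9 columns")
            contig, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "CDS":
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene = attr_map.get("gene_id") or attr_map.get("Parent") or attr_map.get("ID")
            if gene is None:
                raise ValueError(f"CDS without identifier at line {lineno}")
            gene = gene.removesuffix(".t1").removeprefix("cds-")
            rec = by_gene.setdefault(
                gene, {"contig": contig, "strand": strand, "intervals": []}
            )
            if rec["contig"] != contig or rec["strand"] != strand:
                raise ValueError(f"gene {gene}: inconsistent contig/strand (line {lineno})")
            rec["intervals"].append((int(start) - 1, int(end)))
    genes = []
    for name, rec in by_gene.items():
        model = GeneModel(
            name=name,
            contig=rec["contig"],
            strand=rec["strand"],
            cds_intervals=_merge_intervals(rec["intervals"]),
        )
        if model.coding_length % 3:
            logger.warning(
                "gene %s: CDS length %d not divisible by 3", name, model.coding_length
            )
        genes.append(model)
    genes.sort(key=lambda g: g.name)
    return genes


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene + mRNA + CDS features with correct phase."""
    lines = ["##gff-version 3"]
    for gene in genes:
        start1, end1 = gene.start + 1, gene.end
        lines.append(
            f"{gene.contig}\tpolarfix\tgene\t{start1}\t{end1}\t.\t{gene.strand}\t.\t"
            f"ID={gene.name}"
        )
        lines.append(
            f"{gene.contig}\tpolarfix\tmRNA\t{start1}\t{end1}\t.\t{gene.strand}\t.\t"
            f"ID={gene.name}.t1;Parent={gene.name}"
        )
        ivals = gene.cds_intervals
        # transcription order: ascending on '+', descending on '-'
        tx = ivals if gene.strand == "+" else list(reversed(ivals))
        cum = 0
        phases = {}
        for s, e in tx:
            phases[(s, e)] = (3 - cum % 3) % 3
            cum += e - s
        for s, e in ivals:
            lines.append(
                f"{gene.contig}\tpolarfix\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t"
                f"{phases[(s, e)]}\tID=cds-{gene.name};Parent={gene.name}.t1;"
                f"gene_id={gene.name}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Base counts
# ---------------------------------------------------------------------------

BASE_COUNT_COLUMNS = ["contig", "pos", "sample", "nA", "nC", "nG", "nT"]


def read_base_counts(path: str | Path) -> list[BaseCountRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(BASE_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"base-count file missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            BaseCountRecord(
                contig=str(row["contig"]),
                pos=int(row["pos"]) - 1,
                sample_id=str(row["sample"]),
                n_a=int(row["nA"]),
                n_c=int(row["nC"]),
                n_g=int(row["nG"]),
                n_t=int(row["nT"]),
            )
        )
    return out


def write_base_counts(records: Iterable[BaseCountRecord], path: str | Path) -> None:
    rows = sorted(records, key=lambda r: (r.contig, r.pos, r.sample_id))
    df = pd.DataFrame(
        {
            "contig": [r.contig for r in rows],
            "pos": [r.pos + 1 for r in rows],
            "sample": [r.sample_id for r in rows],
            "nA": [r.n_a for r in rows],
            "nC": [r.n_c for r in rows],
            "nG": [r.n_g for r in rows],
            "nT": [r.n_t for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Simulated reads (plain-text exchange format)
# ---------------------------------------------------------------------------

def read_reads(path: str | Path) -> list["AncientRead"]:
    from .models import AncientRead

    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "contig": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            AncientRead(
                sample_id=row["sample"],
                contig=row["contig"],
                start=int(row["start"]),
                sequence=row["sequence"],
            )
        )
    return out


def write_reads(reads: Sequence["AncientRead"], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample": [r.sample_id for r in reads],
            "contig": [r.contig for r in reads],
            "start": [r.start for r in reads],
            "sequence": [r.sequence for r in reads],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Consolidated site report
# ---------------------------------------------------------------------------

def write_site_report(classifications: pd.DataFrame, path: str | Path) -> None:
    """Write the per-candidate-site report with a stable column order.

    One row per candidate site entering classification; ``ancient_not_fixed``
    marks sites where at least one ancient individual is not homozygous
    for the derived allele.
    """
    missing = set(SITE_REPORT_COLUMNS) - set(classifications.columns)
    if missing:
        raise ValueError(f"report missing columns: {sorted(missing)}")
    df = classifications[SITE_REPORT_COLUMNS].copy()
    df = df.sort_values(["contig", "pos"], kind="mergesort")
    df["pos"] = df["pos"].astype(int) + 1  # report in 1-based coordinates
    df["brown_derived_freq"] = df["brown_derived_freq"].map(
        lambda x: "" if pd.isna(x) else f"{x:.6g}"
    )
    df.to_csv(path, sep="\t", index=False)


def read_site_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ancient_states": str})
    df["pos"] = df["pos"].astype(int) - 1
    return df
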