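"""Timing of fixation relative to the ancient individuals.

A site already called fixed for the derived allele in modern polar
bears is pre-fixed if the ancient genomes are also homozygous derived,
post-fixed if at least one ancient carries the ancestral allele, and
unresolved when no ancient genotype is callable.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .models import Genotype


class TimingClass(str, Enum):
    PRE_FIXED = "pre_fixed"
    POST_FIXED = "post_fixed"
    UNRESOLVED = "unresolved"


class AncientState(str, Enum):
    HOM_DERIVED = "hom_derived"
    CARRIES_ANCESTRAL = "carries_ancestral"
    MISSING = "missing"


@dataclass(frozen=True)
class TimingCall:
    timing: TimingClass
    ancient_states: tuple[AncientState, ...]
    low_confidence: bool  # pre_fixed decided from a single ancient


def ancient_state(genotype: Genotype, derived: str) -> AncientState:
    if genotype is None:
        return AncientState.MISSING
    if genotype[0] == derived and genotype[1] == derived:
        return AncientState.HOM_DERIVED
    return AncientState.CARRIES_ANCESTRAL


def classify_timing(
    ancient_genotypes: Sequence[Genotype],
    derived: str,
    strict: bool = False,
) -> TimingCall:
    """Classify one fixed site from (depth-masked) ancient genotypes.

    With ``strict`` a pre_fixed call requires every ancient to be
    homozygous derived; otherwise a single homozygous-derived ancient
    with the rest missing yields pre_fixed flagged low-confidence.
    """
    states = tuple(ancient_state(g, derived) for g in ancient_genotypes)
    n_derived = sum(s == AncientState.HOM_DERIVED for s in states)
    n_ancestral = sum(s == AncientState.CARRIES_ANCESTRAL for s in states)
    n_missing = sum(s == AncientState.MISSING for s in states)
    if n_ancestral > 0:
        return TimingCall(TimingClass.POST_FIXED, states, low_confidence=False)
    if n_derived == 0:
        return TimingCall(TimingClass.UNRESOLVED, states, low_confidence=False)
    if n_missing == 0:
        return TimingCall(TimingClass.PRE_FIXED, states, low_confidence=False)
    if strict:
        return TimingCall(TimingClass.UNRESOLVED, states, low_confidence=False)
    return TimingCall(TimingClass.PRE_FIXED, states, low_confidence=True)


def timing_summary(timed: pd.DataFrame) -> tuple[dict, pd.DataFrame]:
    """Totals plus a per-gene breakdown.

    ``timed`` must hold one row per fixed site with columns ``gene`` and
    ``timing_class``. Returns (totals dict, per-gene DataFrame); the
    totals include the list of genes containing post-fixed sites.
    """
    totals = {
        "pre_fixed": int((timed["timing_class"] == TimingClass.PRE_FIXED.value).sum()),
        "post_fixed": int(
            (timed["timing_class"] == TimingClass.POST_FIXED.value).sum()
        ),
        "unresolved": int(
            (timed["timing_class"] == TimingClass.UNRESOLVED.value).sum()
        ),
    }
    if timed.empty:
        per_gene = pd.DataFrame(
            columns=["gene", "n_fixed", "n_pre_fixed", "n_post_fixed", "n_unresolved"]
        )
        totals["genes_with_post_fixed"] = []
        return totals, per_gene
    rows = []
    for gene, grp in timed.groupby("gene", sort=True):
        rows.append(
            {
                "gene": gene,
                "n_fixed": len(grp),
                "n_pre_fixed": int(
                    (grp["timing_class"] == TimingClass.PRE_FIXED.value).sum()
                ),
                "n_post_fixed": int(
                    (grp["timing_class"] == TimingClass.POST_FIXED.value).sum()
                ),
                "n_unresolved": int(
                    (grp["timing_class"] == TimingClass.UNRESOLVED.value).sum()
                ),
            }
        )
    per_gene = pd.DataFrame(rows)
    totals["genes_with_post_fixed"] = sorted(
        per_gene.loc[per_gene["n_post_fixed"] > 0, "gene"].tolist()
    )
    return totals, per_gene
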