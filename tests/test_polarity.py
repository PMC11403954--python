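import numpy as np
import pandas as pd
import pytest

from polarfix import synthetic_cohort as sc
from polarfix.annotation import FilterFate, FilterThresholds, apply_depth_mask, select_candidate_sites
from polarfix.models import SiteCall
from polarfix.polarity import (
    FixationCall,
    Origin,
    PolarityCall,
    RemovalReason,
    assess_polar_fixation,
    brown_derived_frequency,
    classify_origin,
    classify_sites,
    determine_ancestral,
    summarize_by_gene,
)


def _site(genotypes, ref="A", alts=("G",)):
    return SiteCall(
        "c", 0, ref, list(alts), genotypes, np.full(len(genotypes), 10)
    )


class TestDetermineAncestral:
    def test_both_outgroups_hom_ancestral(self):
        site = _site([("G", "G"), ("A", "A"), ("A", "A")])
        call = determine_ancestral(
            site, [("A", "A"), ("A", "A")], polar_fixed_allele="G"
        )
        assert call.ancestral == "A"
        assert call.derived == "G"
        assert call.removal_reason is None

    def test_outgroup_carrying_polar_allele_removes_site(self):
        site = _site([("G", "G"), ("A", "A")])
        call = determine_ancestral(
            site, [("A", "G"), ("A", "A")], polar_fixed_allele="G"
        )
        assert call.removal_reason == RemovalReason.OUTGROUP_CARRIES_POLAR_ALLELE

    def test_outgroup_hom_polar_allele_removes_site(self):
        site = _site([("G", "G"), ("A", "A")])
        call = determine_ancestral(
            site, [("G", "G"), ("A", "A")], polar_fixed_allele="G"
        )
        assert call.removal_reason == RemovalReason.OUTGROUP_CARRIES_POLAR_ALLELE

    def test_both_outgroups_missing_unpolarizable(self):
        site = _site([("G", "G"), ("A", "A")])
        call = determine_ancestral(site, [None, None], polar_fixed_allele="G")
        assert call.ancestral is None
        assert call.removal_reason == RemovalReason.OUTGROUP_MISSING

    def test_one_outgroup_missing_requires_both_by_default(self):
        site = _site([("G", "G"), ("A", "A")])
        call = determine_ancestral(site, [("A", "A"), None])
        assert call.removal_reason == RemovalReason.OUTGROUP_MISSING

    def test_single_outgroup_mode(self):
        site = _site([("G", "G"), ("A", "A")])
        call = determine_ancestral(
            site, [("A", "A"), None], allow_single_outgroup=True
        )
        assert call.ancestral == "A"
        assert call.derived == "G"

    def test_discordant_homozygous_outgroups(self):
        site = _site([("G", "G"), ("A", "A")])
        call = determine_ancestral(site, [("A", "A"), ("G", "G")])
        assert call.removal_reason == RemovalReason.OUTGROUP_DISCORDANT

    def test_het_outgroup_without_fixation_is_discordant(self):
        site = _site([("A", "G"), ("A", "A")])
        call = determine_ancestral(site, [("A", "G"), ("A", "A")])
        assert call.removal_reason == RemovalReason.OUTGROUP_DISCORDANT

    def test_ancestral_equal_derived_rejected(self):
        with pytest.raises(ValueError):
            PolarityCall(ancestral="A", derived="A", outgroup_states=())


class TestFixation:
    def test_all_hom_same_allele_is_fixed(self):
        site = _site([("G", "G")] * 5)
        call = assess_polar_fixation(site, range(5))
        assert call.is_fixed and call.fixed_allele == "G"
        assert call.callable_count == 5

    def test_single_heterozygote_breaks_fixation(self):
        site = _site([("G", "G")] * 4 + [("A", "G")])
        call = assess_polar_fixation(site, range(5))
        assert not call.is_fixed

    def test_zero_callable_not_fixed(self):
        site = _site([None, None])
        call = assess_polar_fixation(site, range(2))
        assert not call.is_fixed and call.callable_count == 0

    def test_masked_individuals_ignored(self):
        site = _site([("G", "G"), None, ("G", "G")])
        call = assess_polar_fixation(site, range(3))
        assert call.is_fixed and call.callable_count == 2


class TestBrownFrequency:
    def test_all_ancestral_is_zero(self):
        site = _site([("A", "A")] * 10)
        count, called = brown_derived_frequency(site, range(10), "G")
        assert (count, called) == (0, 20)

    def test_direct_count(self):
        # 27 derived alleles among 270 called alleles -> 0.10
        gts = [("G", "G")] * 13 + [("A", "G")] * 1 + [("A", "A")] * 121
        site = _site(gts)
        count, called = brown_derived_frequency(site, range(135), "G")
        assert (count, called) == (27, 270)
        assert count / called == pytest.approx(0.10)

    def test_missing_excluded_from_denominator(self):
        site = _site([("A", "G"), None, ("A", "A")])
        count, called = brown_derived_frequency(site, range(3), "G")
        assert (count, called) == (1, 4)


class TestClassifyOrigin:
    def _fixed(self, allele="G"):
        return FixationCall(is_fixed=True, fixed_allele=allele, callable_count=5)

    def _polarized(self):
        return PolarityCall(
            ancestral="A", derived="G", outgroup_states=(("A", "A"), ("A", "A"))
        )

    def test_standing_variation(self):
        origin = classify_origin(self._fixed(), self._polarized(), 10, 270)
        assert origin.origin == Origin.STANDING_VARIATION
        assert origin.brown_derived_freq == pytest.approx(10 / 270)

    def test_de_novo(self):
        origin = classify_origin(self._fixed(), self._polarized(), 0, 270)
        assert origin.origin == Origin.DE_NOVO

    def test_not_fixed(self):
        unfixed = FixationCall(is_fixed=False, fixed_allele=None, callable_count=5)
        origin = classify_origin(unfixed, self._polarized(), 10, 270)
        assert origin.origin == Origin.NOT_FIXED

    def test_removed(self):
        removed = PolarityCall(
            ancestral=None,
            derived=None,
            outgroup_states=(("A", "G"), ("A", "A")),
            removal_reason=RemovalReason.OUTGROUP_CARRIES_POLAR_ALLELE,
        )
        origin = classify_origin(self._fixed(), removed, 10, 270)
        assert origin.origin == Origin.REMOVED

    def test_fixed_for_ancestral_allele_is_not_fixed_derived(self):
        origin = classify_origin(self._fixed("A"), self._polarized(), 0, 270)
        assert origin.origin == Origin.NOT_FIXED


@pytest.fixture(scope="module")
def classified(default_cohort):
    thresholds = FilterThresholds()
    masked = apply_depth_mask(default_cohort.sites, thresholds)
    fates = select_candidate_sites(
        masked,
        default_cohort.samples,
        default_cohort.genes,
        default_cohort.reference,
        thresholds,
    )
    retained = [f for f in fates if f.fate == FilterFate.RETAINED]
    df = classify_sites([f.site for f in retained], default_cohort.samples)
    df["gene"] = [f.annotation.gene for f in retained]
    return df


class TestFixtureClassification:
    def test_48_fixed_sites(self, classified):
        fixed = classified[
            classified["origin_class"].isin(["standing_variation", "de_novo"])
        ]
        assert len(fixed) == 48

    def test_zero_de_novo_on_default_fixture(self, classified):
        assert (classified["origin_class"] == "de_novo").sum() == 0

    def test_planted_denovo_is_recovered(self):
        from conftest import MINI_GENES, make_mini_cohort

        plan = sc.default_class_plan(MINI_GENES, n_flank_background=1)
        plan["G2"][sc.SiteClass.FIXED_DENOVO] = 1
        cohort = make_mini_cohort(seed=21, class_plan=plan)
        thresholds = FilterThresholds()
        masked = apply_depth_mask(cohort.sites, thresholds)
        fates = select_candidate_sites(
            masked, cohort.samples, cohort.genes, cohort.reference, thresholds
        )
        retained = [f for f in fates if f.fate == FilterFate.RETAINED]
        df = classify_sites([f.site for f in retained], cohort.samples)
        assert (df["origin_class"] == "de_novo").sum() == 1

    def test_conflict_sites_removed(self, classified, default_cohort):
        truth = default_cohort.truth.by_key()
        for _, row in classified.iterrows():
            planted = truth[(row["contig"], row["pos"])]
            if planted.site_class == sc.SiteClass.OUTGROUP_CONFLICT_BG:
                assert row["origin_class"] == "removed"
                assert row["removal_reason"] == "outgroup_carries_polar_allele"

    def test_origin_partition(self, classified):
        counts = classified["origin_class"].value_counts()
        assert counts.sum() == len(classified)
        assert set(counts.index) <= {
            "standing_variation",
            "de_novo",
            "not_fixed",
            "removed",
        }

    def test_brown_frequencies_match_site_counts(self, classified, default_cohort):
        truth = default_cohort.truth.by_key()
        for _, row in classified.iterrows():
            planted = truth[(row["contig"], row["pos"])]
            if planted.site_class in (sc.SiteClass.FIXED_PRE, sc.SiteClass.FIXED_POST):
                assert row["brown_derived_count"] > 0

    def test_label_symmetry_ref_alt_swap(self, default_cohort):
        """Swapping REF/ALT labels everywhere leaves origin classes invariant."""
        thresholds = FilterThresholds()
        masked = apply_depth_mask(default_cohort.sites, thresholds)
        fates = select_candidate_sites(
            masked,
            default_cohort.samples,
            default_cohort.genes,
            default_cohort.reference,
            thresholds,
        )
        retained = [
            f.site
            for f in fates
            if f.fate == FilterFate.RETAINED and len(f.site.alt_alleles) == 1
        ]
        swapped = [
            SiteCall(
                s.contig,
                s.pos,
                s.alt_alleles[0],
                [s.ref_allele],
                s.genotypes,
                s.depths,
            )
            for s in retained
        ]
        a = classify_sites(retained, default_cohort.samples)
        b = classify_sites(swapped, default_cohort.samples)
        assert list(a["origin_class"]) == list(b["origin_class"])
        assert list(a["ancestral"]) == list(b["ancestral"])


class TestGeneSummary:
    def test_empty_input(self):
        out = summarize_by_gene(pd.DataFrame())
        assert out.empty

    def test_fixture_summary_matches_plan(self, default_result):
        summary = default_result.gene_summary.set_index("gene")
        zero_fixed = sorted(summary.index[summary["n_fixed"] == 0])
        assert zero_fixed == ["CUL7", "FCGBP", "LAMC3", "XIRP1"]
        assert (summary["n_fixed"] >= 1).sum() == 7
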