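import numpy as np
import pytest
from scipy import stats

from polarfix import synthetic_cohort as sc
from polarfix.annotation import annotate_coding_effect
from polarfix.models import Era, SiteCall, Species

from conftest import MINI_GENES, make_mini_cohort, make_mini_spec
import oracles


class TestCohortSpec:
    def test_defaults(self):
        spec = sc.CohortSpec()
        assert (spec.n_polar_modern, spec.n_brown) == (119, 135)
        assert (spec.n_ancient, spec.n_outgroup) == (2, 2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_polar_modern": -1},
            {"ancient_missing_rate": 1.5},
            {"damage_rate_per_ancient": (0.2,)},  # length != n_ancient
            {"damage_rate_per_ancient": (0.2, 1.2)},
            {"ancient_post_state": "nonsense"},
            {"flank": 10_000},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            sc.CohortSpec(**kwargs)

    def test_gene_plan_rejects_length_not_divisible_by_3(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            sc.GenePlanEntry("BAD", 100, "+")


class TestReferenceAndGenes:
    def test_default_plan_gene_lengths(self, default_cohort):
        lengths = {g.name: g.coding_length for g in default_cohort.genes}
        assert lengths["TTN"] == 102_861
        assert lengths["APOB"] == 13_305
        assert lengths["LYST"] == 11_403
        assert len(lengths) == 11

    def test_flanks_at_least_50kb(self, default_cohort):
        for gene in default_cohort.genes:
            contig_len = len(default_cohort.reference[gene.contig])
            assert gene.start >= 50_000
            assert contig_len - gene.end >= 50_000

    def test_cds_translates_without_internal_stops(self, default_cohort):
        # independent codon-table oracle, spliced by hand
        for gene in default_cohort.genes:
            protein = oracles.translate(
                oracles.extract_cds(default_cohort.reference, gene)
            )
            assert "*" not in protein
            assert len(protein) == gene.coding_length // 3

    def test_same_seed_byte_identical(self, tmp_path):
        a = make_mini_cohort(seed=5)
        b = make_mini_cohort(seed=5)
        pa = sc.write_fixture(a, tmp_path / "a")
        pb = sc.write_fixture(b, tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes(), key

    def test_different_seeds_differ(self):
        a = make_mini_cohort(seed=5)
        b = make_mini_cohort(seed=6)
        assert a.reference != b.reference


class TestPlantSiteTruth:
    def test_default_plan_totals(self, default_cohort):
        counts = default_cohort.truth.class_counts()
        pre = sum(c.get(sc.SiteClass.FIXED_PRE, 0) for c in counts.values())
        post = sum(c.get(sc.SiteClass.FIXED_POST, 0) for c in counts.values())
        assert pre == 34
        assert post == 14

    def test_default_per_gene_plan(self, default_cohort):
        expected = {
            "ABCC6": (1, 0), "AIM1": (5, 0), "APOB": (3, 7), "COL5A3": (2, 0),
            "CUL7": (0, 0), "FCGBP": (0, 0), "LAMC3": (0, 0), "LYST": (5, 3),
            "POLR1A": (1, 0), "TTN": (17, 4), "XIRP1": (0, 0),
        }
        counts = default_cohort.truth.class_counts()
        for gene, (pre, post) in expected.items():
            got = counts.get(gene, {})
            assert got.get(sc.SiteClass.FIXED_PRE, 0) == pre, gene
            assert got.get(sc.SiteClass.FIXED_POST, 0) == post, gene

    def test_empty_plan_gives_empty_truth(self):
        spec = make_mini_spec(seed=2)
        rng = np.random.default_rng(2)
        reference, genes = sc.generate_reference_and_genes(spec, MINI_GENES, rng)
        plan = {g.name: {} for g in MINI_GENES}
        truth = sc.plant_site_truth(genes, reference, plan, spec, rng)
        assert truth.sites == []

    def test_planted_fixed_sites_reannotate_nonsynonymous(self, default_cohort):
        genes = {g.name: g for g in default_cohort.genes}
        for s in default_cohort.truth.sites:
            if s.site_class not in sc.FIXED_CLASSES:
                continue
            probe = SiteCall(s.contig, s.position, s.ancestral, [s.derived], [], [])
            ann = annotate_coding_effect(
                probe, [genes[s.gene]], default_cohort.reference
            )
            assert ann is not None and ann.is_nonsynonymous, s

    def test_positions_unique_and_spaced(self, default_cohort):
        by_contig = {}
        for s in default_cohort.truth.sites:
            by_contig.setdefault(s.contig, []).append(s.position)
        spacing = default_cohort.spec.min_spacing
        for positions in by_contig.values():
            positions.sort()
            assert len(set(positions)) == len(positions)
            assert all(b - a >= spacing for a, b in zip(positions, positions[1:]))

    def test_denovo_requires_zero_brown_freq(self):
        with pytest.raises(ValueError):
            sc.PlantedSiteClass(
                site_class=sc.SiteClass.FIXED_DENOVO,
                gene="G1", contig="ctg_G1", position=100,
                ancestral="A", derived="G", brown_derived_freq=0.2,
            )


class TestSimulateGenotypes:
    def test_sample_columns(self, default_cohort):
        assert len(default_cohort.samples) == 119 + 135 + 2 + 2
        for site in default_cohort.sites:
            assert len(site.genotypes) == 258

    def test_modern_polar_hom_derived_at_fixed_sites(self, default_cohort):
        truth = default_cohort.truth.by_key()
        polar_idx = [
            i for i, s in enumerate(default_cohort.samples)
            if s.species == Species.POLAR and s.era == Era.MODERN
        ]
        for site in default_cohort.sites:
            planted = truth[(site.contig, site.pos)]
            if planted.site_class not in sc.FIXED_CLASSES:
                continue
            d = planted.derived
            assert all(site.genotypes[i] == (d, d) for i in polar_idx)

    def test_denovo_site_absent_from_brown_and_outgroups(self):
        plan = sc.default_class_plan(MINI_GENES, n_flank_background=1)
        plan["G3"][sc.SiteClass.FIXED_DENOVO] = 1
        cohort = make_mini_cohort(seed=3, class_plan=plan)
        truth = cohort.truth.by_key()
        non_polar = [
            i for i, s in enumerate(cohort.samples)
            if s.species != Species.POLAR
        ]
        found = 0
        for site in cohort.sites:
            planted = truth[(site.contig, site.pos)]
            if planted.site_class != sc.SiteClass.FIXED_DENOVO:
                continue
            found += 1
            for i in non_polar:
                gt = site.genotypes[i]
                assert gt is not None and planted.derived not in gt
        assert found == 1

    def test_brown_frequencies_within_binomial_ci(self, default_cohort):
        # planted parameter recovery at alpha=0.01 per site
        truth = default_cohort.truth.by_key()
        brown_idx = [
            i for i, s in enumerate(default_cohort.samples)
            if s.species == Species.BROWN
        ]
        for site in default_cohort.sites:
            planted = truth[(site.contig, site.pos)]
            if planted.site_class not in (
                sc.SiteClass.FIXED_PRE, sc.SiteClass.FIXED_POST
            ):
                continue
            n = 2 * len(brown_idx)
            k = sum(
                sum(1 for a in site.genotypes[i] if a == planted.derived)
                for i in brown_idx
            )
            lo, hi = stats.binom.interval(0.99, n, planted.brown_derived_freq)
            # the generator tops up one derived allele when the draw is 0
            assert max(lo, 1) - 1 <= k <= hi + 1, (site.contig, site.pos)

    def test_all_ancient_missing_when_rate_one(self):
        cohort = make_mini_cohort(seed=4, ancient_missing_rate=1.0)
        ancient_idx = [
            i for i, s in enumerate(cohort.samples) if s.era == Era.ANCIENT
        ]
        for site in cohort.sites:
            assert all(site.genotypes[i] is None for i in ancient_idx)

    def test_ancient_het_only_at_post_sites(self, default_cohort):
        truth = default_cohort.truth.by_key()
        ancient_idx = [
            i for i, s in enumerate(default_cohort.samples) if s.era == Era.ANCIENT
        ]
        n_het = 0
        for site in default_cohort.sites:
            planted = truth[(site.contig, site.pos)]
            for i in ancient_idx:
                gt = site.genotypes[i]
                if gt is not None and gt[0] != gt[1]:
                    n_het += 1
                    assert planted.site_class == sc.SiteClass.FIXED_POST
        assert n_het == 14

    def test_hom_ancestral_post_state_option(self):
        cohort = make_mini_cohort(seed=8, ancient_post_state="hom_ancestral")
        ancient_idx = [
            i for i, s in enumerate(cohort.samples) if s.era == Era.ANCIENT
        ]
        truth = cohort.truth.by_key()
        n_post = 0
        for site in cohort.sites:
            planted = truth[(site.contig, site.pos)]
            gts = [site.genotypes[i] for i in ancient_idx]
            assert all(g is None or g[0] == g[1] for g in gts)
            if planted.site_class == sc.SiteClass.FIXED_POST:
                n_post += 1
                a = planted.ancestral
                assert any(g == (a, a) for g in gts)
        assert n_post == 2


class TestSimulateAncientReads:
    def test_no_damage_means_no_terminal_mismatches(self):
        cohort = make_mini_cohort(seed=9, damage_rate_per_ancient=(0.0, 0.0))
        ct, ga = oracles.brute_force_damage_counts(
            [r for r in cohort.reads if r.contig == sc.DAMAGE_CONTIG],
            cohort.reference,
        )
        assert ct[0][0] == 0 and ga[0][0] == 0

    def test_base_counts_equal_brute_force_recount(self, mini_cohort):
        positions = [
            (s.contig, s.position) for s in mini_cohort.truth.sites
        ]
        expected = oracles.brute_force_base_counts(mini_cohort.reads, positions)
        got = {
            (c.contig, c.pos, c.sample_id): {
                "A": c.n_a, "C": c.n_c, "G": c.n_g, "T": c.n_t
            }
            for c in mini_cohort.base_counts
        }
        assert got == expected

    def test_het_sites_realise_planted_minor_counts(self, default_cohort):
        counts = {
            (c.contig, c.pos, c.sample_id): c for c in default_cohort.base_counts
        }
        assert default_cohort.truth.het_plans
        for hp in default_cohort.truth.het_plans:
            sid = f"ancient_{hp.ancient_index + 1}"
            rec = counts[(hp.contig, hp.pos, sid)]
            assert rec.count(hp.minor_allele) == hp.n_minor
            assert rec.count(hp.major_allele) == hp.coverage - hp.n_minor

    def test_flagged_proportions_present(self, default_cohort):
        props = sorted(hp.proportion for hp in default_cohort.truth.het_plans)
        assert props[0] == pytest.approx(0.25)
        assert props[1] == pytest.approx(0.29)
        flagged = [hp for hp in default_cohort.truth.het_plans if hp.proportion <= 0.30]
        assert len(flagged) == 2
        assert all(hp.gene == "TTN" for hp in flagged)

    def test_terminal_damage_rate_near_planted(self, default_cohort):
        reads = [
            r for r in default_cohort.reads
            if r.sample_id == "ancient_1" and r.contig == sc.DAMAGE_CONTIG
        ]
        ct, _ = oracles.brute_force_damage_counts(reads, default_cohort.reference)
        mm, opp = ct[0]
        assert opp >= 10_000
        lo, hi = stats.binom.interval(0.99, opp, 0.20)
        assert lo <= mm <= hi
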