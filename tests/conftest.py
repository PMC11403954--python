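import pytest

from polarfix import pipeline
from polarfix import synthetic_cohort as sc
from polarfix.annotation import apply_depth_mask

# small gene plan for fast randomized runs
MINI_GENES = (
    sc.GenePlanEntry("G1", 1500, "+", 2, 1),
    sc.GenePlanEntry("G2", 2400, "-", 1, 1),
    sc.GenePlanEntry("G3", 3000, "+", 0, 0),
)


def make_mini_spec(seed: int, **overrides) -> sc.CohortSpec:
    kwargs = dict(
        n_polar_modern=10,
        n_brown=12,
        n_ancient=2,
        n_outgroup=2,
        n_background_reads=400,
        flagged_gene="G1",
        seed=seed,
    )
    kwargs.update(overrides)
    return sc.CohortSpec(**kwargs)


def make_mini_cohort(seed: int, class_plan=None, **overrides) -> sc.SyntheticCohort:
    spec = make_mini_spec(seed, **overrides)
    if class_plan is None:
        class_plan = sc.default_class_plan(MINI_GENES, n_flank_background=2)
    return sc.generate_cohort(spec, gene_plan=MINI_GENES, class_plan=class_plan)


def dummy_config(**overrides) -> pipeline.PipelineConfig:
    kwargs = dict(reference="", gff="", vcf="", metadata="", outdir="")
    kwargs.update(overrides)
    return pipeline.PipelineConfig(**kwargs)


def in_memory_inputs(
    cohort: sc.SyntheticCohort, config: pipeline.PipelineConfig
) -> pipeline.PipelineInputs:
    """PipelineInputs built straight from a cohort, no disk round-trip."""
    masked = apply_depth_mask(cohort.sites, config.thresholds)
    return pipeline.PipelineInputs(
        reference=cohort.reference,
        genes=cohort.genes,
        metadata=cohort.samples,
        sites=masked,
        raw_sites=cohort.sites,
        base_counts=cohort.base_counts,
        reads=cohort.reads,
    )


@pytest.fixture(scope="session")
def default_cohort() -> sc.SyntheticCohort:
    return sc.generate_cohort(sc.CohortSpec(seed=1))


@pytest.fixture(scope="session")
def fixture_paths(default_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return sc.write_fixture(default_cohort, outdir)


@pytest.fixture(scope="session")
def default_config(fixture_paths, tmp_path_factory) -> pipeline.PipelineConfig:
    outdir = tmp_path_factory.mktemp("results")
    return pipeline.PipelineConfig(
        reference=str(fixture_paths["reference"]),
        gff=str(fixture_paths["gff"]),
        vcf=str(fixture_paths["vcf"]),
        metadata=str(fixture_paths["metadata"]),
        base_counts=str(fixture_paths["base_counts"]),
        reads=str(fixture_paths["reads"]),
        outdir=str(outdir),
        seed=1,
    )


@pytest.fixture(scope="session")
def default_result(default_config) -> pipeline.PipelineResult:
    return pipeline.run_pipeline(default_config)


@pytest.fixture(scope="session")
def mini_cohort() -> sc.SyntheticCohort:
    return make_mini_cohort(seed=11)
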