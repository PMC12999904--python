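import pytest
from hypothesis import settings

from asterfam.pipeline import PipelineConfig, run
from asterfam.synth import SyntheticConfig, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A four-species dataset with every planted feature enabled."""
    cfg = SyntheticConfig(
        n_species=4,
        n_oggs=36,
        genes_per_chromosome=160,
        block_length=10,
        dup_events={"WGD": 1, "TD": 2, "PD": 2, "TRD": 1, "DSD": 2},
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("dataset")
    _paths, truth = generate_dataset(cfg, outdir)
    return cfg, outdir, truth


@pytest.fixture(scope="session")
def small_pipeline(small_dataset, tmp_path_factory):
    """Full pipeline results on the four-species dataset."""
    cfg, indir, truth = small_dataset
    out = tmp_path_factory.mktemp("pipeline_out")
    pcfg = PipelineConfig(input_dir=indir, output_dir=out, species=cfg.species)
    results = run(pcfg)
    return pcfg, results, truth


@pytest.fixture(scope="session")
def rbh_dataset(tmp_path_factory):
    """Ten species, fifty orthogroups, no duplications: copy number one
    everywhere, so reciprocal-best-hit grouping should be exact."""
    cfg = SyntheticConfig(
        n_species=10,
        n_oggs=50,
        genes_per_chromosome=80,
        block_length=10,
        dup_events={},
        motif_plan={},
        promoter_window=120,
        seed=7,
    )
    outdir = tmp_path_factory.mktemp("rbh_dataset")
    _paths, truth = generate_dataset(cfg, outdir)
    return cfg, outdir, truth
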