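import pytest

from allokit.cli import run_full_analysis
from allokit.simulate import (GroundTruth, SimulationConfig, score_recovery,
                              simulate_all)


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """Default-condition synthetic dataset (500 genes/subgenome, 30 losses,
    5 HE events, 50x depth, 195 cp SNPs / 100 indels)."""
    outdir = tmp_path_factory.mktemp("simdata")
    truth = simulate_all(SimulationConfig(seed=1), outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def pipeline_results(sim_dataset):
    datadir, truth = sim_dataset
    return run_full_analysis(datadir), truth


@pytest.fixture(scope="session")
def recovery_scores(pipeline_results):
    results, truth = pipeline_results
    return score_recovery(results, truth)


def clean_config(seed=0, genes_per_chrom=60, **overrides):
    """A small event-free configuration for targeted tests."""
    defaults = dict(
        seed=seed, n_chrom_c=1, n_chrom_h=1, genes_per_chrom=genes_per_chrom,
        loss_counts_c={}, loss_counts_h={}, n_restored_c=0, n_restored_h=0,
        n_misannotated=0, n_partial=0, n_pseudo=0, n_genotype_diff=0,
        he_events=(), noise_paralogs=0, n_sv=0,
        n_cp_snp=4, cp_snp_f1=4, n_cp_indel=0, cp_indel_f1=0)
    defaults.update(overrides)
    return SimulationConfig(**defaults)
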