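import numpy as np
import pytest

from editnas import (ArchitectureTokens, ModelConfig, PlantedRule, build_model,
                     make_fixture_genome_and_vcf, planted_dataset,
                     split_dataset, train)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted-rule dataset shared across tests: (sites, X, Y)."""
    sites, X, Y = planted_dataset(600, PlantedRule(), seed=101)
    return sites, X, np.asarray(Y)


@pytest.fixture(scope="session")
def tiny_trained_model(small_planted):
    """A quickly trained small CNN on the planted rule (not high accuracy)."""
    sites, X, Y = small_planted
    idx_tr, idx_va, _ = split_dataset(range(len(X)), seed=5)
    tokens = ArchitectureTokens(ops=(4, 7, 7), residuals=((), (0,), (0, 0)))
    cfg = ModelConfig(max_epochs=12, early_stop_patience=100, dropout=0.0,
                      learning_rate=5e-3, batch_size=64, seed=7)
    net = build_model(tokens, cfg)
    return train(net, (X[idx_tr], Y[idx_tr]), (X[idx_va], Y[idx_va]), cfg)


@pytest.fixture(scope="session")
def genome_fixture(tmp_path_factory):
    """Toy genome + BED + VCF with the generator's ground-truth counts."""
    out = tmp_path_factory.mktemp("fixture")
    return make_fixture_genome_and_vcf(seed=42, out_dir=out)
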