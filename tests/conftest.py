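import pytest
from hypothesis import settings

from slscreen import build_custom_library

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from slscreen.simulate import GeneEffectSpec, ScreenSimConfig, simulate_screen_counts

N_GENES = 1000
N_SL = 20
N_ESSENTIAL = 50
N_WT_ADVANTAGE = 30


@pytest.fixture(scope="session")
def screen_library():
    """1000 genes x 4 sgRNAs plus 100 non-targeting controls."""
    genes = [f"G{i:04d}" for i in range(N_GENES)]
    return build_custom_library(genes, [], sgrnas_per_gene=4, n_nontargeting=100, seed=7)


@pytest.fixture(scope="session")
def planted_effects(screen_library):
    """20 SL-in-mutant genes, 50 essentials, 30 WT-advantage genes."""
    genes = screen_library.genes
    effects = {}
    for g in genes[:N_SL]:
        effects[g] = GeneEffectSpec(g, "sl_mutant_only", 0.0, -0.2)
    for g in genes[N_SL : N_SL + N_ESSENTIAL]:
        effects[g] = GeneEffectSpec(g, "essential", -0.25, -0.25)
    for g in genes[N_SL + N_ESSENTIAL : N_SL + N_ESSENTIAL + N_WT_ADVANTAGE]:
        effects[g] = GeneEffectSpec(g, "wt_advantage", 0.1, 0.0)
    return effects


@pytest.fixture(scope="session")
def sl_screen(screen_library, planted_effects):
    """Simulated paired-background screen at 500 reads/sgRNA depth."""
    config = ScreenSimConfig(
        screen_library,
        planted_effects,
        depth=500 * len(screen_library),
        dispersion=10.0,
        seed=11,
    )
    return simulate_screen_counts(config)


@pytest.fixture
def small_library():
    return build_custom_library(
        ["ALPHA", "BETA", "GAMMA"], ["CTRL1"], sgrnas_per_gene=2, n_nontargeting=2, seed=3
    )
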