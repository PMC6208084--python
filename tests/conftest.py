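import pytest

from somalu.pipeline import ScenarioConfig, run_pipeline
from somalu.synthetic_data import ReferenceConfig, build_reference


def tiny_scenario(**overrides) -> ScenarioConfig:
    """A fast scenario: 100-kb genome, 40 fixed / 3 somatic loci, 20k pairs."""
    base = dict(
        chrom_lengths={"chr1": 100_000},
        n_fixed=40,
        n_other=5,
        total_cells=200,
        somatic_cell_counts=[1, 2, 3],
        depth=20_000,
        error_rate=0.001,
        kct_scale=0.02,
        leak_rate=0.05,
        amplification_sigma=0.8,
        seed=7,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def tiny_run():
    return run_pipeline(tiny_scenario())


@pytest.fixture(scope="session")
def small_ref():
    return build_reference(
        ReferenceConfig(chrom_lengths={"chrA": 50_000}, n_fixed=10, seed=3)
    )
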