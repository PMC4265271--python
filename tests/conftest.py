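import pytest

import polyclust as pc
from polyclust import scenarios

#: seed fixing the canonical study conditions across the suite
BENCHMARK_SEED = 101


@pytest.fixture(scope="session")
def benchmark_run():
    """Full default benchmark (1000 samples x 200 assays), clustered and
    called once per session; shared by the end-to-end accuracy checks."""
    panel, truth = scenarios.benchmark_panel(seed=BENCHMARK_SEED)
    model, genotypes, report = pc.run_protocol(panel, mode="diversity")
    return {
        "panel": panel,
        "truth": truth,
        "model": model,
        "genotypes": genotypes,
        "report": report,
    }


@pytest.fixture()
def small_benchmark():
    """A fast 200-sample x 20-assay slice of the benchmark conditions."""
    panel, truth = scenarios.benchmark_panel(seed=7, n_samples=200, n_assays=20)
    return panel, truth
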