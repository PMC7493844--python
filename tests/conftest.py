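import pytest

from cerna import GeneratorSpec, RunConfig, generate_dataset, run_pipeline


@pytest.fixture(scope="session")
def benchmark_data():
    """Standard benchmark tissue: 5 planted triplets, 20 decoys, n=200."""
    return generate_dataset(GeneratorSpec(seed=7))


@pytest.fixture(scope="session")
def benchmark_run(benchmark_data, tmp_path_factory):
    """One full pipeline run on the benchmark tissue, artifacts on disk."""
    dataset, truth = benchmark_data
    out = tmp_path_factory.mktemp("run")
    config = RunConfig(seed=11, null_draws=1000, tissue_label="synthetic")
    interactions, report = run_pipeline(dataset, config, out_dir=out)
    return {
        "dataset": dataset,
        "truth": truth,
        "config": config,
        "interactions": interactions,
        "report": report,
        "out": out,
    }
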