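import pytest

from histone_profiler.histone_code import load_panels, load_references
from histone_profiler.reporting import run_pipeline
from histone_profiler.synthetic_data import generate_transcriptome

DATASET_SEED = 11


@pytest.fixture(scope="session")
def references():
    return load_references()


@pytest.fixture(scope="session")
def panels(references):
    return load_panels(references=references)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default synthetic dataset plus its on-disk paths."""
    ds = generate_transcriptome(seed=DATASET_SEED)
    paths = ds.write(tmp_path_factory.mktemp("sim"))
    return ds, paths


@pytest.fixture(scope="session")
def pipeline_result(dataset, tmp_path_factory):
    ds, paths = dataset
    outdir = tmp_path_factory.mktemp("bundle")
    config = {
        "proteins": str(paths["proteins"]),
        "blast": str(paths["blast"]),
        "domtbl": str(paths["domtbl"]),
        "tpm": str(paths["tpm"]),
    }
    return run_pipeline(config, outdir)
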