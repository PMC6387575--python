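import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_genomes():
    """The three study-shaped synthetic genomes with truth annotations."""
    from virsift import synthdata

    return [
        synthdata.make_viral_genome(a, seed=101) for a in synthdata.study_architectures()
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """A small full synthetic study: 7 libraries, diverged protein db."""
    from virsift import synthdata

    return synthdata.make_dataset(
        seed=11,
        n_host_contigs=15,
        total_read_pairs=500,
        replicates=1,
        aa_divergence=0.25,
    )


@pytest.fixture(scope="session")
def pipeline_result(small_dataset, tmp_path_factory):
    """The full pipeline run once on the small dataset."""
    from virsift import pipeline

    out = tmp_path_factory.mktemp("pipeline_out")
    libs = {spec.library_id: reads for spec, reads, _t in small_dataset.libraries}
    result = pipeline.run_pipeline(
        small_dataset.contigs,
        libs,
        small_dataset.protein_db,
        small_dataset.metadata,
        out_dir=out,
    )
    return result, out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
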