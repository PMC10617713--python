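import numpy as np
import pytest

from mitocr import crres, mitosim, pipeline, readqc, repeats


@pytest.fixture(scope="session")
def default_spec():
    return mitosim.default_genome_spec(seed=1)


@pytest.fixture(scope="session")
def default_genome(default_spec):
    return mitosim.build_genome(default_spec)


@pytest.fixture(scope="session")
def true_motifs(default_spec):
    (ma, _), (mb, _) = default_spec.cr_spec.arrays
    return [repeats.Motif("A", ma), repeats.Motif("B", mb)]


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """The documented synthetic study: 200 CR-spanning reads at 8% error
    (4% del / 2% ins / 2% sub) with copy-number jitter dispersion 1, run end
    to end once and shared across tests."""
    outdir = tmp_path_factory.mktemp("study")
    cfg = pipeline.RunConfig(seed=1, outdir=str(outdir))
    state = pipeline.RunState()
    report = pipeline.run_pipeline(cfg, state)
    return cfg, state, report


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
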