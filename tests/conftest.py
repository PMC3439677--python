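import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from copeak.pipeline import RunConfig, run_pipeline
from copeak.synthetic_data import CALLER_NAMES, SynthConfig, generate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


SMALL_CONFIG = dict(n_chroms=1, genome_length=200_000, n_true_sites=15,
                    n_decoy_sites=30, n_labeled_pos=6, n_negative_pool=60)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact synthetic bundle for fast unit tests."""
    outdir = tmp_path_factory.mktemp("synth_small")
    return generate(SynthConfig(seed=7, **SMALL_CONFIG), outdir)


def make_run_config(ds, outdir, seed, **overrides) -> RunConfig:
    cfg = RunConfig(
        caller_files=[str(ds.paths[c]) for c in CALLER_NAMES],
        caller_names=list(CALLER_NAMES),
        genome=str(ds.paths["genome"]),
        occupancy=str(ds.paths["occupancy"]),
        er_peaks=str(ds.paths["er_peaks"]),
        genes=str(ds.paths["genes"]),
        labeled_positives=str(ds.paths["labeled_positives"]),
        negative_pool=str(ds.paths["negative_pool"]),
        outdir=str(outdir), seed=seed)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default study conditions, seed 1.

    Session-scoped: the dataset, pipeline outputs and results dict are
    shared by the acceptance tests and the directional pipeline checks.
    """
    root = tmp_path_factory.mktemp("synth_default")
    ds = generate(SynthConfig(seed=1), root / "data")
    results = run_pipeline(make_run_config(ds, root / "out", seed=1))
    return ds, results


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
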