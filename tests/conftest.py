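"""Shared fixtures: synthetic bundles at two scales, screened once per session."""

import pytest

from subscreen import pipeline, synthetic


def small_config(**overrides):
    """A compact screen (300+300 clones, 8 blocks) for fast tests."""
    base = dict(
        n_forward=300,
        n_reverse=300,
        blocks=8,
        rows=12,
        cols=14,
        control_row=6,
        control_blocks_per_half=3,
        n_sequenced=40,
        seed=101,
    )
    base.update(overrides)
    return synthetic.SimConfig(**base)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_bundle")
    return synthetic.generate_experiment(small_config(), out)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    return pipeline.screen(small_bundle.out_dir)


@pytest.fixture(scope="session")
def full_bundle(tmp_path_factory):
    """Default study conditions: 2000+2000 clones, 12 arrays, 10% DE."""
    out = tmp_path_factory.mktemp("full_bundle")
    return synthetic.generate_experiment(synthetic.SimConfig(seed=202), out)


@pytest.fixture(scope="session")
def full_result(full_bundle):
    return pipeline.screen(full_bundle.out_dir)
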