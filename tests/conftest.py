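"""Shared fixtures: the synthetic starvation system and its ground truth."""

import pytest

from dynabof.synthetic_data import (ToySpec, make_timecourse_composition,
                                    make_toy_model)


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec()


@pytest.fixture(scope="session")
def toy(toy_spec):
    """(model, ground_truth) for the default synthetic system."""
    return make_toy_model(toy_spec)


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def ground_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def composition(toy_spec):
    """Six-stage starvation composition table for the default system."""
    return make_timecourse_composition(toy_spec)


@pytest.fixture(scope="session")
def narrow_spec(toy_spec):
    """Trend shrunk to ±10% of its default span around the midpoints,
    where regression slopes approximate derivatives."""
    return toy_spec.narrowed(0.1)


@pytest.fixture(scope="session")
def narrow_system(narrow_spec):
    model, gt = make_toy_model(narrow_spec)
    return model, gt, make_timecourse_composition(narrow_spec)


@pytest.fixture()
def fresh_toy(toy_spec):
    """A mutable copy of the toy for tests that modify the model."""
    model, gt = make_toy_model(toy_spec)
    return model, gt
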