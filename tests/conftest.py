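"""Shared fixtures: one small synthetic study built once per session.

All inputs are generated programmatically by the package's own fixture
module; no test reads external data.
"""

from __future__ import annotations

import pytest

from lcdc import (
    StudyConfig, UriScheme, build_all, generate_study,
    generate_terminologies, parse_odm, register_variables,
)
from lcdc.synth_fixtures import DEFAULT_SUBJECT_PROPS, DEFAULT_THEME_MAP


SMALL = StudyConfig(n_subjects=24, timepoints=("baseline", "month18",
                                               "month36"), seed=11)


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    return SMALL


@pytest.fixture(scope="session")
def study(small_config):
    """(xml, manifest) for the session's small study."""
    return generate_study(small_config)


@pytest.fixture(scope="session")
def doc(study):
    return parse_odm(study[0])


@pytest.fixture(scope="session")
def manifest(study):
    return study[1]


@pytest.fixture(scope="session")
def dictionary(doc):
    """(variables, universes) for the session study."""
    return register_variables(doc.meta, DEFAULT_THEME_MAP)


@pytest.fixture(scope="session")
def cubeset(doc, dictionary):
    variables, universes = dictionary
    return build_all(doc, variables, universes, UriScheme(),
                     DEFAULT_THEME_MAP, DEFAULT_SUBJECT_PROPS)


@pytest.fixture(scope="session")
def terms():
    return generate_terminologies()
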