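import warnings

import pytest

from kapentagyrus.key import build_printed_key
from kapentagyrus.reference import builtin_profiles, builtin_surveys


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def profiles_by_epithet(profiles):
    return {p.species_name.split()[-1]: p for p in profiles}


@pytest.fixture(scope="session")
def surveys():
    return builtin_surveys()


@pytest.fixture(scope="session")
def printed_key():
    return build_printed_key()


@pytest.fixture(autouse=True)
def _quiet_generator_warnings():
    # profiles with sparse columns legitimately warn about unsampleable
    # parameters; tests assert on them explicitly where relevant
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*parameters without published summaries.*"
        )
        yield
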