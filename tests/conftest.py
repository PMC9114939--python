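"""Shared fixtures: the default synthetic bundle and its fitted pipeline.

The heavy stages (mixture fitting over all click-count families, the clan
delineation) run once per session and are shared by the unit and acceptance
tests.
"""

import pytest

from codaclan.clan_delineation import build_repertoires, delineate_clans
from codaclan.coda_typing import classify_codas
from codaclan.synthetic_data import gen_codas

SEED = 42


@pytest.fixture(scope="session")
def coda_bundle():
    return gen_codas(seed=SEED)


@pytest.fixture(scope="session")
def typing_result(coda_bundle):
    return classify_codas(coda_bundle.codas, k_max=15, seed=SEED)


@pytest.fixture(scope="session")
def repertoires(coda_bundle, typing_result):
    reps, report = build_repertoires(coda_bundle.codas, typing_result.assignment)
    return reps, report


@pytest.fixture(scope="session")
def clan_result(repertoires):
    reps, _ = repertoires
    return delineate_clans(reps)
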