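"""Shared fixtures: noise-free default subjects and their fitted analyses.

The fitted analyses are session-scoped because each full pipeline run
(subcutaneous insulin fit + staged glucose-model fit) takes tens of
seconds; every test that needs a fitted subject reuses these.
"""

from __future__ import annotations

import pytest

import hepaflux as hf


@pytest.fixture(scope="session")
def config():
    return hf.AnalysisConfig()


@pytest.fixture(scope="session")
def healthy_noisefree():
    return hf.generate_subject(hf.healthy_profile(), seed=0, noise=False)


@pytest.fixture(scope="session")
def sub1_noisefree():
    return hf.generate_subject(hf.t1d_sub1_profile(), seed=0, noise=False)


@pytest.fixture(scope="session")
def sub2_noisefree():
    return hf.generate_subject(hf.t1d_sub2_profile(), seed=0, noise=False)


@pytest.fixture(scope="session")
def healthy_analysis(healthy_noisefree):
    ds, _ = healthy_noisefree
    return hf.analyse_subject(ds)


@pytest.fixture(scope="session")
def sub1_analysis(sub1_noisefree):
    ds, _ = sub1_noisefree
    return hf.analyse_subject(ds)


@pytest.fixture(scope="session")
def sub2_analysis(sub2_noisefree):
    ds, _ = sub2_noisefree
    return hf.analyse_subject(ds)
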