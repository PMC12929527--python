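"""Shared fixtures: the shipped parameter set and the (expensive)
lifespan simulations, computed once per session."""

import pytest

import amyprog as ap


@pytest.fixture(scope="session")
def params():
    return ap.ParameterSet.defaults()


@pytest.fixture(scope="session")
def ad_result(params):
    """Default amyloid-positive lifespan run (male, e3/e3, ages 20-100)."""
    return ap.LifespanModel(
        ap.SubjectProfile(disease_status="ad_prone"), params).run()


@pytest.fixture(scope="session")
def healthy_result(params):
    return ap.LifespanModel(
        ap.SubjectProfile(disease_status="healthy"), params).run()


@pytest.fixture(scope="session")
def carrier_result(params):
    """Maximally impaired APOE carrier (alpha = 1)."""
    return ap.LifespanModel(
        ap.SubjectProfile(disease_status="ad_prone", apoe_genotype="e4/e4"),
        params).run()


@pytest.fixture(scope="session")
def female_result(params):
    return ap.LifespanModel(
        ap.SubjectProfile(disease_status="ad_prone", sex="female"), params).run()


@pytest.fixture(scope="session")
def healthy_audit_default(params):
    return ap.healthy_audit(params)
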