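"""Shared fixtures: the worked controlled-access example and small ecosystems."""

from __future__ import annotations

import pytest

from ga4gh_passport import (
    AssertedBy,
    AssertionStore,
    Identity,
    IssuerConfig,
    TrustConfig,
    VisaAssertion,
    VisaTokenHeader,
    VisaType,
)
from ga4gh_passport.fixtures import test_keypair
from ga4gh_passport.jws import jwks_document

# The printed controlled-access visa: a DAC at the sensitive-data application
# portal grants access to an example beacon dataset for one year.
GOLDEN_ISS = "https://sd-apply.csc.fi/"
GOLDEN_JKU = "https://sd-apply.csc.fi/api/jwk"
GOLDEN_SUB = "12345678@elixir-europe.org"
GOLDEN_VALUE = "https://beaconpy-elixirbeacon.rahtiapp.fi/urn:hg:example-controlled"
GOLDEN_ASSERTED = 1_625_055_001
GOLDEN_IAT = 1_625_144_975
GOLDEN_EXP = 1_656_680_975
GOLDEN_TTL = GOLDEN_EXP - GOLDEN_IAT  # 31,536,000 s = 365 d


@pytest.fixture(scope="session")
def keypair():
    return test_keypair(0)


@pytest.fixture(scope="session")
def other_keypair():
    return test_keypair(1)


@pytest.fixture()
def golden_assertion() -> VisaAssertion:
    return VisaAssertion(
        visa_type=VisaType.CONTROLLED_ACCESS_GRANTS,
        value=GOLDEN_VALUE,
        source=GOLDEN_ISS,
        by=AssertedBy.DAC,
        asserted=GOLDEN_ASSERTED,
    )


@pytest.fixture()
def golden_header() -> VisaTokenHeader:
    return VisaTokenHeader(alg="RS256", jku=GOLDEN_JKU, typ="JWT", kid="key-1")


@pytest.fixture()
def golden_issuer(keypair) -> IssuerConfig:
    return IssuerConfig(
        iss=GOLDEN_ISS,
        signing_key=keypair,
        kid="key-1",
        jku=GOLDEN_JKU,
        store=AssertionStore(),
        default_ttl=GOLDEN_TTL,
    )


def trust_for(*issuers: IssuerConfig, clock_skew: int = 0) -> TrustConfig:
    """A TrustConfig trusting exactly the given issuers (in-memory JWKS)."""
    return TrustConfig(
        trusted_issuers={
            iss.jku: jwks_document([(iss.kid, iss.signing_key.public_key)])
            for iss in issuers
        },
        clock_skew=clock_skew,
    )


@pytest.fixture()
def golden_trust(golden_issuer) -> TrustConfig:
    return trust_for(golden_issuer)


@pytest.fixture()
def home_org_issuer(other_keypair) -> IssuerConfig:
    return IssuerConfig(
        iss="https://cam.ac.uk/",
        signing_key=other_keypair,
        kid="cam-key-1",
        jku="https://cam.ac.uk/api/jwk",
        store=AssertionStore(),
        default_ttl=GOLDEN_TTL,
    )


def make_identity(issuer: IssuerConfig, subject: str) -> Identity:
    return Identity(issuer.iss, subject)
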