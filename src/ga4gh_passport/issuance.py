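"""Visa Issuer and Passport Broker: sign assertions into visas, package passports.

A *Visa Issuer* queries an assertion repository for a subject's active records
and signs each into a visa token.  A *Passport Broker* authenticates a user
(simulated here by the caller handing over the identities it has proven),
pulls visas from every configured issuer for every identity, and packages the
result as a passport document:

    {"sub": ..., "ga4gh_passport_v1": [<visa token>, ...]}

The envelope itself is unsigned — every visa inside is independently signed
and independently verifiable, so the envelope adds no authority of its own.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import quote, unquote

from .jws import RSAPrivateKey
from .store import AssertionStore, Identity
from .visa import (
    AssertedBy,
    EncodedVisa,
    VisaAssertion,
    VisaClaims,
    VisaTokenHeader,
    VisaType,
    build_visa,
    encode_visa,
)

__all__ = [
    "DEFAULT_TTL",
    "IssuerConfig",
    "Passport",
    "ProvenIdentity",
    "issue_visas",
    "assemble_passport",
    "mint_linked_identities",
    "encode_linked_identity_list",
    "decode_linked_identity_list",
]

logger = logging.getLogger(__name__)

PASSPORT_CLAIM_NAME = "ga4gh_passport_v1"

#: Default visa lifetime: 365 days, the window of the worked example.
DEFAULT_TTL = 31_536_000


@dataclass
class IssuerConfig:
    """A visa issuer: signing identity plus the repository it speaks for."""

    iss: str
    signing_key: RSAPrivateKey
    kid: str
    jku: str
    store: AssertionStore = field(default_factory=AssertionStore)
    default_ttl: int = DEFAULT_TTL

    def header(self) -> VisaTokenHeader:
        return VisaTokenHeader(alg="RS256", jku=self.jku, typ="JWT", kid=self.kid)


@dataclass(frozen=True)
class Passport:
    """A subject's packaged collection of visas."""

    subject: Identity
    visas: tuple[EncodedVisa, ...]
    assembled_at: int

    def to_json_dict(self) -> dict:
        return {
            "iss": self.subject.issuer,
            "sub": self.subject.subject,
            "assembled_at": self.assembled_at,
            PASSPORT_CLAIM_NAME: list(self.visas),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json_dict(cls, doc: dict) -> "Passport":
        return cls(
            subject=Identity(doc.get("iss", ""), doc["sub"]),
            visas=tuple(doc[PASSPORT_CLAIM_NAME]),
            assembled_at=doc.get("assembled_at", 0),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "Passport":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass(frozen=True)
class ProvenIdentity:
    """An identity plus the broker's word that it authenticated its holder."""

    identity: Identity
    authenticated: bool = True


def issue_visas(issuer: IssuerConfig, subject: Identity, now: int) -> list[EncodedVisa]:
    """Sign one visa per active assertion about ``subject`` in the issuer's store.

    Revoked records are never issued.  Tokens carry ``iss=issuer.iss``,
    ``sub=subject.subject``, ``iat=now`` and ``exp=now+default_ttl``.  A
    signing failure aborts the whole batch.
    """
    subject = Identity(*subject)
    tokens: list[EncodedVisa] = []
    header = issuer.header()
    for record in issuer.store.query_active(subject, now):
        claims = build_visa(
            record.assertion, iss=issuer.iss, sub=subject.subject,
            now=now, ttl=issuer.default_ttl,
        )
        tokens.append(encode_visa(claims, header, issuer.signing_key))
    return tokens


def assemble_passport(
    broker_iss: str,
    user_identities: list[Identity],
    issuers: list[IssuerConfig],
    now: int,
) -> Passport:
    """Pull visas from every (issuer, identity) pair and package a passport.

    Visa order is issuer order, then record-creation order; there is no
    deduplication across issuers.  An issuer that raises is skipped with a
    logged warning (best-effort assembly).  The passport subject is the
    broker's identity for the user: the first identity's subject at the
    broker.
    """
    if not user_identities:
        raise ValueError("the broker must have authenticated at least one identity")
    identities = [Identity(*i) for i in user_identities]
    visas: list[EncodedVisa] = []
    for issuer in issuers:
        for identity in identities:
            try:
                visas.extend(issue_visas(issuer, identity, now))
            except Exception as exc:  # pragma: no cover - exercised via stub issuer
                logger.warning(
                    "issuer %s unreachable while assembling passport: %s", issuer.iss, exc
                )
                break
    return Passport(
        subject=Identity(broker_iss, identities[0].subject),
        visas=tuple(visas),
        assembled_at=now,
    )


# --- LinkedIdentities -----------------------------------------------------


def encode_linked_identity_list(identities: list[Identity]) -> str:
    """Encode identities as ``subject,issuer`` pairs, percent-encoded, ';'-joined."""
    return ";".join(
        quote(i.subject, safe="") + "," + quote(i.issuer, safe="") for i in identities
    )


def decode_linked_identity_list(value: str) -> list[Identity]:
    identities = []
    for pair in value.split(";"):
        parts = pair.split(",")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(f"malformed linked-identity pair: {pair!r}")
        identities.append(Identity(unquote(parts[1]), unquote(parts[0])))
    return identities


def mint_linked_identities(
    issuer: IssuerConfig,
    proven: list[ProvenIdentity],
    now: int,
    ttl: int | None = None,
) -> EncodedVisa:
    """Sign a LinkedIdentities visa joining every proven identity.

    The caller (the broker) vouches that the user demonstrated holding each
    identity; an entry with ``authenticated=False`` is refused.  The token's
    ``sub`` is the first proven identity's subject, and its value lists every
    identity pair.
    """
    if len(proven) < 2:
        raise ValueError("linking requires at least two proven identities")
    for entry in proven:
        if not entry.authenticated:
            raise PermissionError(
                f"identity {entry.identity} was not authenticated; refusing to link"
            )
    identities = [Identity(*p.identity) for p in proven]
    assertion = VisaAssertion(
        visa_type=VisaType.LINKED_IDENTITIES,
        value=encode_linked_identity_list(identities),
        source=issuer.iss,
        by=AssertedBy.SYSTEM,
        asserted=now,
    )
    claims = build_visa(
        assertion, iss=issuer.iss, sub=identities[0].subject,
        now=now, ttl=ttl if ttl is not None else issuer.default_ttl,
    )
    return encode_visa(claims, issuer.header(), issuer.signing_key)


def linked_identities_from_claims(claims: VisaClaims) -> list[Identity]:
    """Parse the identity list out of a decoded LinkedIdentities visa."""
    if claims.visa.visa_type is not VisaType.LINKED_IDENTITIES:
        raise ValueError("not a LinkedIdentities visa")
    return decode_linked_identity_list(claims.visa.value)
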