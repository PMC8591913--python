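"""Visa data model: assertions, claims, signing, and trust-anchored verification.

A *visa* is one digitally signed token carrying a single assertion about a data
user — a controlled-access grant from a DAC, an affiliation from a home
organization, a researcher-status or terms attestation, or an identity link.
The token is a compact RS256 JWS whose payload carries the assertion under the
claim name ``ga4gh_visa_v1``:

    {"iss": ..., "sub": ..., "iat": ..., "exp": ...,
     "ga4gh_visa_v1": {"type": ..., "value": ..., "source": ..., "by": ...,
                       "asserted": ..., "conditions": ...}}

Verification is offline and trust-anchored: a :class:`TrustConfig` maps the
``jku`` key-set URIs a clearinghouse trusts to local JWKS documents, and a
token can only ever verify against a key reached through that map.
"""

from __future__ import annotations

import enum
import json
import re
from pathlib import Path
from typing import Any, Callable, Optional

from pydantic import BaseModel, ConfigDict, StrictInt, StrictStr, field_validator, model_validator

from . import jws
from .jws import JWSError, RSAPrivateKey, RSAPublicKey

__all__ = [
    "VisaType",
    "AssertedBy",
    "VisaAssertion",
    "VisaTokenHeader",
    "VisaClaims",
    "EncodedVisa",
    "TrustConfig",
    "RejectionReason",
    "VisaRejection",
    "SigningError",
    "VISA_CLAIM_NAME",
    "build_visa",
    "encode_visa",
    "verify_and_decode",
]

VISA_CLAIM_NAME = "ga4gh_visa_v1"

#: A compact serialized signed visa token (``header.payload.signature``).
EncodedVisa = str

_ROLE_AT_DOMAIN = re.compile(r"^[^@\s]+@[^@\s]+$")


class VisaType(str, enum.Enum):
    """The five visa types of the Passport standard."""

    CONTROLLED_ACCESS_GRANTS = "ControlledAccessGrants"
    ACCEPTED_TERMS_AND_POLICIES = "AcceptedTermsAndPolicies"
    RESEARCHER_STATUS = "ResearcherStatus"
    AFFILIATION_AND_ROLE = "AffiliationAndRole"
    LINKED_IDENTITIES = "LinkedIdentities"


class AssertedBy(str, enum.Enum):
    """Who made the assertion relative to the source organization.

    Only ``dac`` appears in the worked controlled-access example; the remaining
    members follow the v1 visa format registry.
    """

    SELF = "self"
    PEER = "peer"
    SYSTEM = "system"
    SO = "so"
    DAC = "dac"


class VisaAssertion(BaseModel):
    """The atomic claim an assertion source makes about a user."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    visa_type: VisaType
    value: StrictStr
    source: StrictStr
    by: AssertedBy
    asserted: StrictInt
    conditions: Optional[Any] = None  # preserved verbatim, never evaluated

    @field_validator("value", "source")
    @classmethod
    def _non_empty(cls, v: str, info) -> str:
        if not v:
            raise ValueError(f"{info.field_name} must be non-empty")
        return v

    @field_validator("asserted")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("asserted must be a positive epoch timestamp")
        return v

    @model_validator(mode="after")
    def _role_shape(self) -> "VisaAssertion":
        if self.visa_type is VisaType.AFFILIATION_AND_ROLE and not _ROLE_AT_DOMAIN.match(self.value):
            raise ValueError("AffiliationAndRole value must have the shape role@domain")
        return self

    def to_claim(self) -> dict:
        """Render in token field order: type, value, source, by, asserted[, conditions]."""
        claim = {
            "type": self.visa_type.value,
            "value": self.value,
            "source": self.source,
            "by": self.by.value,
            "asserted": self.asserted,
        }
        if self.conditions is not None:
            claim["conditions"] = self.conditions
        return claim

    @classmethod
    def from_claim(cls, claim: dict) -> "VisaAssertion":
        if not isinstance(claim, dict):
            raise ValueError("visa claim must be a JSON object")
        known = {"type", "value", "source", "by", "asserted", "conditions"}
        extra = set(claim) - known
        if extra:
            raise ValueError(f"unknown visa claim fields: {sorted(extra)}")
        return cls(
            visa_type=claim.get("type"),
            value=claim.get("value"),
            source=claim.get("source"),
            by=claim.get("by"),
            asserted=claim.get("asserted"),
            conditions=claim.get("conditions"),
        )


class VisaTokenHeader(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    alg: StrictStr = "RS256"
    jku: StrictStr
    typ: StrictStr = "JWT"
    kid: StrictStr

    def to_dict(self) -> dict:
        # printed order: alg, jku, typ, kid
        return {"alg": self.alg, "jku": self.jku, "typ": self.typ, "kid": self.kid}


class VisaClaims(BaseModel):
    """Payload of a visa token: standard JWT fields plus one assertion."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    iss: StrictStr
    sub: StrictStr
    iat: StrictInt
    exp: StrictInt
    visa: VisaAssertion

    @field_validator("iss", "sub")
    @classmethod
    def _non_empty(cls, v: str, info) -> str:
        if not v:
            raise ValueError(f"{info.field_name} must be non-empty")
        return v

    @model_validator(mode="after")
    def _exp_after_iat(self) -> "VisaClaims":
        if self.exp <= self.iat:
            raise ValueError("exp must be strictly after iat")
        return self

    @property
    def identity(self) -> tuple[str, str]:
        """The (issuer, subject) identity pair this token speaks for."""
        return (self.iss, self.sub)

    def to_payload(self) -> dict:
        return {
            "iss": self.iss,
            "sub": self.sub,
            "iat": self.iat,
            "exp": self.exp,
            VISA_CLAIM_NAME: self.visa.to_claim(),
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "VisaClaims":
        known = {"iss", "sub", "iat", "exp", VISA_CLAIM_NAME}
        extra = set(payload) - known
        if extra:
            raise ValueError(f"unknown claims: {sorted(extra)}")
        if VISA_CLAIM_NAME not in payload:
            raise ValueError(f"payload carries no {VISA_CLAIM_NAME} claim")
        return cls(
            iss=payload.get("iss"),
            sub=payload.get("sub"),
            iat=payload.get("iat"),
            exp=payload.get("exp"),
            visa=VisaAssertion.from_claim(payload[VISA_CLAIM_NAME]),
        )


class RejectionReason(str, enum.Enum):
    MALFORMED = "malformed"
    UNTRUSTED_ISSUER = "untrusted_issuer"
    UNKNOWN_KEY = "unknown_key"
    BAD_SIGNATURE = "bad_signature"
    EXPIRED = "expired"
    NOT_YET_VALID = "not_yet_valid"
    BAD_CLAIMS = "bad_claims"
    # clearinghouse-side code, shares the audit vocabulary
    REVOKED = "revoked"


class VisaRejection(Exception):
    """A verification failure with a machine-readable reason code."""

    def __init__(self, reason: RejectionReason, detail: str = ""):
        self.reason = reason
        self.detail = detail
        super().__init__(f"{reason.value}: {detail}" if detail else reason.value)


class SigningError(Exception):
    """Raised when a token cannot be produced (bad alg, key mismatch)."""


class TrustConfig:
    """Trust anchors for verification: jku URI -> local JWKS document.

    Verification consults only keys reachable through ``trusted_issuers``; a
    key-set URI absent from the map can never verify.  Values are either paths
    to JWKS JSON files (resolved lazily, cached) or in-memory JWKS dicts.
    """

    def __init__(
        self,
        trusted_issuers: dict[str, str | Path | dict],
        allowed_algs: set[str] | None = None,
        clock_skew: int = 0,
    ):
        if clock_skew < 0:
            raise ValueError("clock_skew must be non-negative")
        self.trusted_issuers = dict(trusted_issuers)
        self.allowed_algs = frozenset(allowed_algs) if allowed_algs is not None else frozenset({"RS256"})
        if "none" in {a.lower() for a in self.allowed_algs}:
            raise ValueError('the "none" algorithm is never allowed')
        self.clock_skew = int(clock_skew)
        self._jwks_cache: dict[str, dict] = {}

    def _load_jwks(self, jku: str) -> dict:
        if jku in self._jwks_cache:
            return self._jwks_cache[jku]
        entry = self.trusted_issuers[jku]
        if isinstance(entry, (str, Path)):
            with open(entry, "r", encoding="utf-8") as fh:
                jwks = json.load(fh)
        else:
            jwks = entry
        self._jwks_cache[jku] = jwks
        return jwks

    def resolve_key(self, jku: str, kid: str) -> RSAPublicKey | None:
        """Return the public key for (jku, kid), or None if kid is unknown.

        Raises KeyError if jku is not a trusted key-set URI (the caller maps
        this to an ``untrusted_issuer`` rejection before touching any key).
        """
        if jku not in self.trusted_issuers:
            raise KeyError(jku)
        return jws.find_key_in_jwks(self._load_jwks(jku), kid)

    @classmethod
    def from_file(cls, path: str | Path) -> "TrustConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        base = Path(path).parent
        issuers = {
            jku: (str(base / p) if not Path(p).is_absolute() else p)
            for jku, p in doc["trusted_issuers"].items()
        }
        return cls(
            trusted_issuers=issuers,
            allowed_algs=set(doc.get("allowed_algs", ["RS256"])),
            clock_skew=doc.get("clock_skew", 0),
        )

    def to_file(self, path: str | Path) -> None:
        doc = {
            "trusted_issuers": {
                jku: str(v) for jku, v in self.trusted_issuers.items() if isinstance(v, (str, Path))
            },
            "allowed_algs": sorted(self.allowed_algs),
            "clock_skew": self.clock_skew,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def build_visa(
    assertion: VisaAssertion,
    iss: str,
    sub: str,
    now: int,
    ttl: int,
) -> VisaClaims:
    """Wrap an assertion into token claims: iat=now, exp=now+ttl."""
    if not isinstance(ttl, int) or isinstance(ttl, bool) or ttl <= 0:
        raise ValueError("ttl must be a positive integer number of seconds")
    if not isinstance(now, int) or isinstance(now, bool):
        raise ValueError("now must be an integer epoch timestamp")
    return VisaClaims(iss=iss, sub=sub, iat=now, exp=now + ttl, visa=assertion)


def encode_visa(
    claims: VisaClaims,
    header: VisaTokenHeader,
    signing_key: RSAPrivateKey,
) -> EncodedVisa:
    """Serialize and sign claims into a compact visa token."""
    if header.alg != "RS256":
        raise SigningError(f"algorithm {header.alg!r} is not allowed for signing")
    if header.typ != "JWT":
        raise SigningError(f'typ must be "JWT", got {header.typ!r}')
    try:
        return jws.sign_compact(header.to_dict(), claims.to_payload(), signing_key)
    except JWSError as exc:
        raise SigningError(str(exc)) from exc


def _parse_header(raw: dict, trust: TrustConfig) -> VisaTokenHeader:
    try:
        header = VisaTokenHeader(**raw)
    except Exception as exc:
        raise VisaRejection(RejectionReason.MALFORMED, f"bad header: {exc}") from exc
    if header.alg not in trust.allowed_algs:
        raise VisaRejection(RejectionReason.MALFORMED, f"algorithm {header.alg!r} not allowed")
    if header.typ != "JWT":
        raise VisaRejection(RejectionReason.MALFORMED, f"typ must be JWT, got {header.typ!r}")
    return header


def verify_and_decode(
    token: EncodedVisa,
    trust: TrustConfig,
    now: int,
    key_resolver: Callable[[str, str], RSAPublicKey | None] | None = None,
) -> VisaClaims:
    """Verify a visa token against local trust anchors and return its claims.

    Checks, in order: structural parse and header policy (``malformed``), jku
    membership in the trust map (``untrusted_issuer``), kid presence in the
    mapped key set (``unknown_key``), RS256 signature over the signing input
    (``bad_signature``), claims well-formedness (``bad_claims``), and the time
    window ``iat - skew <= now <= exp + skew`` (``not_yet_valid`` /
    ``expired``).  Any failure raises :class:`VisaRejection`; partial claims
    are never returned.

    ``key_resolver`` overrides ``trust.resolve_key`` (used to instrument key
    lookups in tests); it must honor the same contract.
    """
    try:
        raw_header, payload_segment, signature, signing_input = (
            jws.split_compact_unverified_payload(token)
        )
    except JWSError as exc:
        raise VisaRejection(RejectionReason.MALFORMED, str(exc)) from exc

    header = _parse_header(raw_header, trust)

    resolver = key_resolver if key_resolver is not None else trust.resolve_key
    try:
        key = resolver(header.jku, header.kid)
    except KeyError:
        raise VisaRejection(
            RejectionReason.UNTRUSTED_ISSUER, f"key set {header.jku!r} is not trusted"
        ) from None
    if key is None:
        raise VisaRejection(
            RejectionReason.UNKNOWN_KEY, f"kid {header.kid!r} not in key set {header.jku!r}"
        )

    if not jws.verify_signature(key, signing_input, signature):
        raise VisaRejection(RejectionReason.BAD_SIGNATURE, "signature does not verify")

    # the signature is checked over the raw segment; only now interpret it
    try:
        claims = VisaClaims.from_payload(jws.decode_payload_segment(payload_segment))
    except (JWSError, ValueError, TypeError) as exc:
        raise VisaRejection(RejectionReason.BAD_CLAIMS, str(exc)) from exc

    if now > claims.exp + trust.clock_skew:
        raise VisaRejection(
            RejectionReason.EXPIRED, f"expired at {claims.exp} (now={now}, skew={trust.clock_skew})"
        )
    if claims.iat > now + trust.clock_skew:
        raise VisaRejection(
            RejectionReason.NOT_YET_VALID,
            f"issued at {claims.iat} in the future (now={now}, skew={trust.clock_skew})",
        )
    return claims
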