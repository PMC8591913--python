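"""Passport Clearinghouse: visa validation, identity resolution, policy decisions.

The clearinghouse is the decision core a data-serving API calls before
releasing a dataset.  It validates every visa in a presented passport against
local trust anchors, resolves which token identities belong to the same
person (via LinkedIdentities visas), and evaluates conjunctive access
policies for the three data-sharing tiers — open, registered, controlled.
If any requirement is unmet, or authenticity cannot be verified, access is
denied by default.

Policies are purely conjunctive (``require_all``); disjunction is expressed
as multiple policies per dataset, any one sufficing.  This keeps decisions
total and monotone: adding a visa to a passport can never turn a grant into
a denial.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, StrictInt, StrictStr, model_validator

from .issuance import Passport, linked_identities_from_claims
from .store import Identity
from .visa import (
    AssertedBy,
    EncodedVisa,
    RejectionReason,
    TrustConfig,
    VisaClaims,
    VisaRejection,
    VisaType,
    verify_and_decode,
)

__all__ = [
    "Tier",
    "DenialReason",
    "VisaPattern",
    "AccessPolicy",
    "AccessDecision",
    "AuditEntry",
    "IdentityGraph",
    "token_digest",
    "validate_passport",
    "resolve_linked_identities",
    "evaluate_access",
    "registered_access_check",
]


class Tier(str, enum.Enum):
    """The three data-sharing tiers."""

    OPEN = "open"
    REGISTERED = "registered"
    CONTROLLED = "controlled"


class SubjectBinding(str, enum.Enum):
    SINGLE_IDENTITY = "single_identity"
    LINKED_IDENTITIES = "linked_identities"


class DenialReason(str, enum.Enum):
    MISSING_REQUIRED_VISA = "missing_required_visa"
    SUBJECT_BINDING_UNSATISFIED = "subject_binding_unsatisfied"


class VisaPattern(BaseModel):
    """One required visa shape: type, value match, and optional constraints."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    visa_type: VisaType
    exact: Optional[StrictStr] = None
    prefix: Optional[StrictStr] = None
    required_source: Optional[StrictStr] = None
    required_by: Optional[AssertedBy] = None
    max_age: Optional[StrictInt] = None  # limit on now - asserted, seconds

    @model_validator(mode="after")
    def _exactly_one_matcher(self) -> "VisaPattern":
        if (self.exact is None) == (self.prefix is None):
            raise ValueError("exactly one of exact/prefix must be given")
        if self.max_age is not None and self.max_age < 0:
            raise ValueError("max_age must be non-negative")
        return self

    def matches(self, claims: VisaClaims, now: int) -> bool:
        visa = claims.visa
        if visa.visa_type is not self.visa_type:
            return False
        if self.exact is not None and visa.value != self.exact:
            return False
        if self.prefix is not None and not visa.value.startswith(self.prefix):
            return False
        if self.required_source is not None and visa.source != self.required_source:
            return False
        if self.required_by is not None and visa.by is not self.required_by:
            return False
        if self.max_age is not None and now - visa.asserted > self.max_age:
            return False
        return True


class AccessPolicy(BaseModel):
    """A conjunctive set of required visa patterns for one dataset tier."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    policy_id: StrictStr
    tier: Tier
    require_all: tuple[VisaPattern, ...] = ()
    subject_binding: SubjectBinding = SubjectBinding.LINKED_IDENTITIES

    @model_validator(mode="after")
    def _tier_shape(self) -> "AccessPolicy":
        types = [p.visa_type for p in self.require_all]
        if self.tier is Tier.OPEN and self.require_all:
            raise ValueError("open-tier policies must not require visas")
        if self.tier is Tier.REGISTERED:
            if VisaType.RESEARCHER_STATUS not in types or VisaType.ACCEPTED_TERMS_AND_POLICIES not in types:
                raise ValueError(
                    "registered-tier policies require at least one ResearcherStatus "
                    "and one AcceptedTermsAndPolicies pattern"
                )
        if self.tier is Tier.CONTROLLED and VisaType.CONTROLLED_ACCESS_GRANTS not in types:
            raise ValueError("controlled-tier policies require a ControlledAccessGrants pattern")
        return self


@dataclass(frozen=True)
class AuditEntry:
    """Per-visa verification outcome, suitable for audit logs."""

    index: int
    digest: str
    outcome: str  # "accepted" or a RejectionReason value
    detail: str = ""

    def to_json_dict(self) -> dict:
        return {
            "index": self.index,
            "digest": self.digest,
            "outcome": self.outcome,
            "detail": self.detail,
        }


@dataclass(frozen=True)
class AccessDecision:
    granted: bool
    matched: dict[int, VisaClaims] = field(default_factory=dict)  # pattern index -> visa
    reasons: tuple[str, ...] = ()
    audit: tuple[AuditEntry, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "granted": self.granted,
            "matched": {
                str(i): claims.to_payload() for i, claims in sorted(self.matched.items())
            },
            "reasons": list(self.reasons),
            "audit": [a.to_json_dict() for a in self.audit],
        }


def token_digest(token: EncodedVisa) -> str:
    """SHA-256 hex digest of a compact token; the revocation-list key."""
    return hashlib.sha256(token.encode("ascii")).hexdigest()


def validate_passport(
    passport: Passport,
    trust: TrustConfig,
    now: int,
    revocation_list: set[str] | None = None,
) -> tuple[list[VisaClaims], list[AuditEntry]]:
    """Verify every visa independently; return the valid claims and an audit log.

    A visa is excluded (with an audit entry carrying its reason) if it fails
    :func:`verify_and_decode` or if its digest is on the revocation list.
    Validation of one visa never affects another.
    """
    valid: list[VisaClaims] = []
    audit: list[AuditEntry] = []
    for index, token in enumerate(passport.visas):
        digest = token_digest(token) if isinstance(token, str) else ""
        if revocation_list and digest in revocation_list:
            audit.append(AuditEntry(index, digest, RejectionReason.REVOKED.value, "token digest on revocation list"))
            continue
        try:
            claims = verify_and_decode(token, trust, now)
        except VisaRejection as rej:
            audit.append(AuditEntry(index, digest, rej.reason.value, rej.detail))
            continue
        valid.append(claims)
        audit.append(AuditEntry(index, digest, "accepted"))
    return valid, audit


class IdentityGraph:
    """Equivalence classes over (issuer, subject) identity pairs (union-find)."""

    def __init__(self) -> None:
        self._parent: dict[Identity, Identity] = {}

    def add(self, identity: Identity) -> None:
        identity = Identity(*identity)
        if identity not in self._parent:
            self._parent[identity] = identity

    def _find(self, identity: Identity) -> Identity:
        root = identity
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[identity] != root:  # path compression
            self._parent[identity], identity = root, self._parent[identity]
        return root

    def union(self, a: Identity, b: Identity) -> None:
        a, b = Identity(*a), Identity(*b)
        self.add(a)
        self.add(b)
        ra, rb = self._find(a), self._find(b)
        if ra != rb:
            self._parent[rb] = ra

    def same_person(self, a: Identity, b: Identity) -> bool:
        a, b = Identity(*a), Identity(*b)
        if a == b:
            return True
        if a not in self._parent or b not in self._parent:
            return False
        return self._find(a) == self._find(b)

    def class_of(self, identity: Identity) -> frozenset[Identity]:
        identity = Identity(*identity)
        if identity not in self._parent:
            return frozenset({identity})
        root = self._find(identity)
        return frozenset(i for i in self._parent if self._find(i) == root)

    def classes(self) -> list[frozenset[Identity]]:
        by_root: dict[Identity, set[Identity]] = {}
        for identity in self._parent:
            by_root.setdefault(self._find(identity), set()).add(identity)
        return [frozenset(members) for members in by_root.values()]


def resolve_linked_identities(
    valid: Iterable[VisaClaims],
    audit: list[AuditEntry] | None = None,
) -> IdentityGraph:
    """Partition the identities of validated visas into same-person classes.

    Every visa contributes its own token (iss, sub) as a node; every
    LinkedIdentities visa unions the identity pairs co-listed in its value.
    A malformed LinkedIdentities value contributes nothing (audit-logged when
    an audit list is supplied).
    """
    graph = IdentityGraph()
    for claims in valid:
        graph.add(claims.identity)
        if claims.visa.visa_type is VisaType.LINKED_IDENTITIES:
            try:
                identities = linked_identities_from_claims(claims)
            except ValueError as exc:
                if audit is not None:
                    audit.append(
                        AuditEntry(-1, "", "malformed_link_ignored", f"{claims.identity}: {exc}")
                    )
                continue
            for other in identities[1:]:
                graph.union(identities[0], other)
    return graph


def _satisfying_class(
    candidates: list[list[VisaClaims]],
    graph: IdentityGraph,
    binding: SubjectBinding,
) -> dict[int, VisaClaims] | None:
    """Pick one candidate per pattern with all identities bound to one person."""
    if binding is SubjectBinding.SINGLE_IDENTITY:
        anchors = {c.identity for c in candidates[0]}
        for anchor in sorted(anchors):
            chosen: dict[int, VisaClaims] = {}
            for i, pool in enumerate(candidates):
                match = next((c for c in pool if c.identity == anchor), None)
                if match is None:
                    break
                chosen[i] = match
            else:
                return chosen
        return None
    # linked_identities: every pattern must be satisfiable within one class
    for cls in sorted(graph.classes(), key=lambda c: sorted(c)):
        chosen = {}
        for i, pool in enumerate(candidates):
            match = next((c for c in pool if c.identity in cls), None)
            if match is None:
                break
            chosen[i] = match
        else:
            return chosen
    return None


def evaluate_access(
    passport: Passport,
    policy: AccessPolicy,
    trust: TrustConfig,
    now: int,
    revocation_list: set[str] | None = None,
) -> AccessDecision:
    """Decide access for a passport under one policy; deny by default.

    Grants iff every pattern in ``require_all`` is satisfied by some valid
    visa and, under the policy's subject binding, all matching visas speak for
    the same person.  Open-tier policies always grant.
    """
    valid, audit = validate_passport(passport, trust, now, revocation_list)

    if policy.tier is Tier.OPEN:
        return AccessDecision(granted=True, audit=tuple(audit))

    candidates = [[c for c in valid if pattern.matches(c, now)] for pattern in policy.require_all]
    unmatched = [i for i, pool in enumerate(candidates) if not pool]
    if unmatched:
        return AccessDecision(
            granted=False,
            reasons=(DenialReason.MISSING_REQUIRED_VISA.value,),
            audit=tuple(audit),
        )

    graph = resolve_linked_identities(valid, audit)
    chosen = _satisfying_class(candidates, graph, policy.subject_binding)
    if chosen is None:
        return AccessDecision(
            granted=False,
            reasons=(DenialReason.SUBJECT_BINDING_UNSATISFIED.value,),
            audit=tuple(audit),
        )
    return AccessDecision(granted=True, matched=chosen, audit=tuple(audit))


def registered_access_check(
    passport: Passport,
    terms_uri: str,
    status_uri: str,
    trust: TrustConfig,
    now: int,
    revocation_list: set[str] | None = None,
) -> AccessDecision:
    """Registered-tier convenience check: bona fide status plus attestation."""
    policy = AccessPolicy(
        policy_id="registered-access",
        tier=Tier.REGISTERED,
        require_all=(
            VisaPattern(visa_type=VisaType.RESEARCHER_STATUS, exact=status_uri),
            VisaPattern(visa_type=VisaType.ACCEPTED_TERMS_AND_POLICIES, exact=terms_uri),
        ),
    )
    return evaluate_access(passport, policy, trust, now, revocation_list)


# --- policy files ---------------------------------------------------------


def load_policy_file(path: str | Path) -> dict[str, list[AccessPolicy]]:
    """Read ``{"datasets": [{"dataset_id", "policies": [...]}]}`` into a map."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    out: dict[str, list[AccessPolicy]] = {}
    for entry in doc["datasets"]:
        out[entry["dataset_id"]] = [AccessPolicy.model_validate(p) for p in entry["policies"]]
    return out


def dump_policy_file(datasets: dict[str, list[AccessPolicy]], path: str | Path) -> None:
    doc = {
        "datasets": [
            {
                "dataset_id": dataset_id,
                "policies": [
                    json.loads(p.model_dump_json(exclude_none=True)) for p in policies
                ],
            }
            for dataset_id, policies in sorted(datasets.items())
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
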