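"""Seeded synthetic ecosystems and a brute-force decision oracle.

:func:`generate_scenario` builds a complete miniature data-sharing ecosystem —
DACs with assertion repositories, home organizations asserting affiliations
and researcher status, a broker that links identities, per-dataset policies
for all three access tiers, and a roster of users — deterministically from a
seed.  Every signed visa it produces verifies under the scenario's own trust
configuration, and revoked/expired cases are injected at configurable rates.

:func:`oracle_decide` is an independent re-statement of the clearinghouse's
deny-by-default semantics: it works on raw token payload dictionaries,
computes identity linkage by brute-force pairwise closure, and enumerates
every assignment of visas to policy patterns.  It deliberately shares no code
with :mod:`ga4gh_passport.clearinghouse`, so agreement between the two is a
meaningful check.
"""

from __future__ import annotations

import csv
import itertools
import json
import random
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from urllib.parse import unquote

from pydantic import BaseModel, ConfigDict, Field

from . import jws
from .clearinghouse import AccessPolicy, SubjectBinding, Tier, VisaPattern
from .issuance import (
    DEFAULT_TTL,
    IssuerConfig,
    Passport,
    encode_linked_identity_list,
)
from .jws import RSAPrivateKey
from .store import AssertionStore, Identity
from .visa import (
    AssertedBy,
    EncodedVisa,
    TrustConfig,
    VisaAssertion,
    VisaClaims,
    VisaType,
    build_visa,
    encode_visa,
)

__all__ = [
    "ScenarioSpec",
    "Scenario",
    "UserProfile",
    "generate_scenario",
    "oracle_decide",
    "test_keypair",
    "BONA_FIDE_URI",
    "TERMS_URI",
]

#: Shared registered-access reference URIs used throughout the fixtures.
BONA_FIDE_URI = "https://doi.org/10.1038/s41431-018-0219-y"
TERMS_URI = "https://example.org/policies/registered-access-terms/v1"

_KEY_POOL_SIZE = 8


@lru_cache(maxsize=None)
def test_keypair(index: int, bits: int = 2048) -> RSAPrivateKey:
    """Deterministic test keypair #``index`` from a fixed PRNG stream.

    Scenarios draw issuer keys from this small pool (assignment is driven by
    the scenario seed) so that generating hundreds of scenarios does not pay
    for fresh 2048-bit key searches each time.  These are fixture keys, never
    production material.
    """
    rng = random.Random(f"ga4gh-passport-test-key/{bits}/{index}")
    return jws.generate_rsa_keypair(bits=bits, rng=rng)


class ScenarioSpec(BaseModel):
    """Knobs for one synthetic ecosystem; identical spec → identical scenario."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    seed: int
    n_users: int = 6
    n_dacs: int = 2
    n_home_orgs: int = 2
    n_datasets: int = 3
    p_grant: float = 0.5
    p_affiliation: float = 0.7
    p_link: float = 0.9
    p_revoked: float = 0.1
    p_expired: float = 0.1
    clock: int = 1_625_144_975
    ttl: int = DEFAULT_TTL

    @property
    def probabilities(self) -> dict[str, float]:
        return {
            "p_grant": self.p_grant,
            "p_affiliation": self.p_affiliation,
            "p_link": self.p_link,
            "p_revoked": self.p_revoked,
            "p_expired": self.p_expired,
        }

    def validate_probabilities(self) -> None:
        for name, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass
class UserProfile:
    user_id: str
    identities: list[Identity]
    link_components: list[list[Identity]]  # ground-truth same-person classes


@dataclass
class Scenario:
    """A generated ecosystem plus its oracle-computed expected decisions."""

    spec: ScenarioSpec
    issuers: list[IssuerConfig]
    broker: IssuerConfig
    trust: TrustConfig
    users: list[UserProfile]
    dataset_policies: dict[str, dict[Tier, AccessPolicy]]
    expected: dict[tuple[str, str, str], bool]
    expired_marks: set[tuple[str, str]] = field(default_factory=set)  # (iss, record_id)
    revoked_record_ids: set[tuple[str, str]] = field(default_factory=set)
    _passports: dict[str, Passport] = field(default_factory=dict, repr=False)

    @property
    def all_issuers(self) -> list[IssuerConfig]:
        return self.issuers + [self.broker]

    def user(self, user_id: str) -> UserProfile:
        for u in self.users:
            if u.user_id == user_id:
                return u
        raise KeyError(user_id)

    def _issued_claims(self, user: UserProfile) -> list[tuple[IssuerConfig, VisaClaims, bool]]:
        """Replay assembly order: (issuer, claims, ground-truth validity)."""
        out: list[tuple[IssuerConfig, VisaClaims, bool]] = []
        clock, ttl = self.spec.clock, self.spec.ttl
        for issuer in self.issuers:
            for identity in user.identities:
                for record in issuer.store.query_active(identity, clock):
                    expired = (issuer.iss, record.record_id) in self.expired_marks
                    iat = clock - 2 * ttl if expired else clock
                    claims = build_visa(
                        record.assertion, iss=issuer.iss, sub=identity.subject,
                        now=iat, ttl=ttl,
                    )
                    out.append((issuer, claims, not expired))
        for component in user.link_components:
            if len(component) < 2:
                continue
            assertion = VisaAssertion(
                visa_type=VisaType.LINKED_IDENTITIES,
                value=encode_linked_identity_list(component),
                source=self.broker.iss,
                by=AssertedBy.SYSTEM,
                asserted=clock,
            )
            claims = build_visa(
                assertion, iss=self.broker.iss, sub=component[0].subject,
                now=clock, ttl=ttl,
            )
            out.append((self.broker, claims, True))
        return out

    def decision_inputs(self, user_id: str) -> list[tuple[VisaClaims, bool]]:
        """The user's would-be visas with ground-truth validity verdicts."""
        return [(claims, ok) for _, claims, ok in self._issued_claims(self.user(user_id))]

    def build_passport(self, user_id: str) -> Passport:
        """Assemble (and sign) the user's passport at the scenario clock."""
        if user_id in self._passports:
            return self._passports[user_id]
        user = self.user(user_id)
        visas: list[EncodedVisa] = [
            encode_visa(claims, issuer.header(), issuer.signing_key)
            for issuer, claims, _ in self._issued_claims(user)
        ]
        passport = Passport(
            subject=Identity(self.broker.iss, user.identities[0].subject),
            visas=tuple(visas),
            assembled_at=self.spec.clock,
        )
        self._passports[user_id] = passport
        return passport

    def expected_decision(self, user_id: str, dataset_id: str, tier: Tier) -> bool:
        return self.expected[(user_id, dataset_id, tier.value)]

    # --- serialization ----------------------------------------------------

    def to_canonical_json(self) -> str:
        """Stable full serialization; equal specs must produce equal strings."""
        doc = {
            "spec": json.loads(self.spec.model_dump_json()),
            "issuers": [
                {
                    "iss": iss.iss,
                    "jku": iss.jku,
                    "kid": iss.kid,
                    "n": iss.signing_key.n,
                    "store": [r.to_json_dict() for r in iss.store],
                }
                for iss in self.all_issuers
            ],
            "users": [
                {
                    "user_id": u.user_id,
                    "identities": [list(i) for i in u.identities],
                    "links": [[list(i) for i in comp] for comp in u.link_components],
                }
                for u in self.users
            ],
            "policies": {
                ds: {
                    tier.value: json.loads(p.model_dump_json(exclude_none=True))
                    for tier, p in tiers.items()
                }
                for ds, tiers in self.dataset_policies.items()
            },
            "expected": {"|".join(k): v for k, v in self.expected.items()},
            "expired_marks": sorted(self.expired_marks),
            "revoked": sorted(self.revoked_record_ids),
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))

    def export(self, directory: str | Path) -> None:
        """Write stores, JWKS files, trust config, policies, and decisions."""
        directory = Path(directory)
        (directory / "keys").mkdir(parents=True, exist_ok=True)
        (directory / "stores").mkdir(exist_ok=True)
        trusted: dict[str, str] = {}
        for i, issuer in enumerate(self.all_issuers):
            jwks_path = directory / "keys" / f"issuer{i}.jwks.json"
            with open(jwks_path, "w", encoding="utf-8") as fh:
                json.dump(
                    jws.jwks_document([(issuer.kid, issuer.signing_key.public_key)]),
                    fh, indent=2,
                )
            trusted[issuer.jku] = str(Path("keys") / jwks_path.name)
            issuer.store.save(directory / "stores" / f"issuer{i}.jsonl")
        with open(directory / "trust.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "trusted_issuers": trusted,
                    "allowed_algs": sorted(self.trust.allowed_algs),
                    "clock_skew": self.trust.clock_skew,
                },
                fh, indent=2, sort_keys=True,
            )
        from .clearinghouse import dump_policy_file

        dump_policy_file(
            {ds: list(tiers.values()) for ds, tiers in self.dataset_policies.items()},
            directory / "policies.json",
        )
        with open(directory / "roster.json", "w", encoding="utf-8") as fh:
            json.dump(
                [
                    {
                        "user_id": u.user_id,
                        "identities": [list(i) for i in u.identities],
                        "links": [[list(i) for i in c] for c in u.link_components],
                    }
                    for u in self.users
                ],
                fh, indent=2,
            )
        with open(directory / "expected_decisions.csv", "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["user_id", "dataset_id", "tier", "expected_granted"])
            for (user_id, dataset_id, tier), granted in sorted(self.expected.items()):
                writer.writerow([user_id, dataset_id, tier, int(granted)])


def _spanning_components(
    identities: list[Identity], rng: random.Random, p_link: float
) -> list[list[Identity]]:
    """Random spanning-tree edges kept with p_link; components are ground truth."""
    parent = list(range(len(identities)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = list(range(1, len(identities)))
    rng.shuffle(order)
    for i in order:
        attach = rng.randrange(i)  # spanning-tree edge i -> earlier node
        if rng.random() < p_link:
            parent[find(i)] = find(attach)
    groups: dict[int, list[Identity]] = {}
    for i, identity in enumerate(identities):
        groups.setdefault(find(i), []).append(identity)
    return [sorted(g) for g in sorted(groups.values())]


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Deterministically build the ecosystem described by ``spec``."""
    spec.validate_probabilities()
    rng = random.Random(spec.seed)
    clock = spec.clock

    # organizations and their signing keys (drawn from the fixture key pool)
    def make_issuer(uri: str, label: str) -> IssuerConfig:
        key = test_keypair(rng.randrange(_KEY_POOL_SIZE))
        return IssuerConfig(
            iss=uri,
            signing_key=key,
            kid=f"{label}-key-1",
            jku=uri + "api/jwk",
            store=AssertionStore(),
            default_ttl=spec.ttl,
        )

    dacs = [make_issuer(f"https://dac{i}.example.org/", f"dac{i}") for i in range(spec.n_dacs)]
    orgs = [
        make_issuer(f"https://org{i}.example.edu/", f"org{i}") for i in range(spec.n_home_orgs)
    ]
    broker = make_issuer("https://broker.example.net/", "broker")
    issuers = dacs + orgs

    trust = TrustConfig(
        trusted_issuers={
            iss.jku: jws.jwks_document([(iss.kid, iss.signing_key.public_key)])
            for iss in issuers + [broker]
        }
    )

    # datasets and their three-tier policies; odd datasets also demand an
    # affiliation alongside the DAC grant (the multi-source conjunction case)
    dataset_policies: dict[str, dict[Tier, AccessPolicy]] = {}
    dataset_owner: dict[str, IssuerConfig] = {}
    for d in range(spec.n_datasets):
        dataset_id = f"urn:example:dataset{d}"
        value = f"https://data.example.org/datasets/{d}"
        owner = dacs[d % spec.n_dacs] if dacs else broker
        dataset_owner[dataset_id] = owner
        controlled_patterns = [
            VisaPattern(
                visa_type=VisaType.CONTROLLED_ACCESS_GRANTS,
                exact=value,
                required_source=owner.iss,
                required_by=AssertedBy.DAC,
            )
        ]
        if d % 2 == 1:
            controlled_patterns.append(
                VisaPattern(visa_type=VisaType.AFFILIATION_AND_ROLE, prefix="faculty@")
            )
        dataset_policies[dataset_id] = {
            Tier.OPEN: AccessPolicy(policy_id=f"{dataset_id}/open", tier=Tier.OPEN),
            Tier.REGISTERED: AccessPolicy(
                policy_id=f"{dataset_id}/registered",
                tier=Tier.REGISTERED,
                require_all=(
                    VisaPattern(visa_type=VisaType.RESEARCHER_STATUS, exact=BONA_FIDE_URI),
                    VisaPattern(
                        visa_type=VisaType.ACCEPTED_TERMS_AND_POLICIES, exact=TERMS_URI
                    ),
                ),
                subject_binding=SubjectBinding.LINKED_IDENTITIES,
            ),
            Tier.CONTROLLED: AccessPolicy(
                policy_id=f"{dataset_id}/controlled",
                tier=Tier.CONTROLLED,
                require_all=tuple(controlled_patterns),
                subject_binding=SubjectBinding.LINKED_IDENTITIES,
            ),
        }

    expired_marks: set[tuple[str, str]] = set()
    revoked_record_ids: set[tuple[str, str]] = set()

    def place_record(issuer: IssuerConfig, identity: Identity, assertion: VisaAssertion) -> None:
        record_id = issuer.store.record_assertion(identity, assertion, clock)
        if rng.random() < spec.p_revoked:
            issuer.store.revoke(record_id, clock)
            revoked_record_ids.add((issuer.iss, record_id))
        elif rng.random() < spec.p_expired:
            expired_marks.add((issuer.iss, record_id))

    users: list[UserProfile] = []
    for u in range(spec.n_users):
        user_id = f"user{u:03d}"
        home = orgs[u % spec.n_home_orgs] if orgs else None
        identities = [Identity(iss.iss, f"{user_id}@{iss.iss}") for iss in dacs]
        if home is not None:
            identities.append(Identity(home.iss, f"{user_id}@{home.iss}"))

        # DAC grants per dataset
        for dataset_id, tiers in dataset_policies.items():
            owner = dataset_owner[dataset_id]
            if owner not in dacs:
                continue
            if rng.random() < spec.p_grant:
                dac_identity = identities[dacs.index(owner)]
                place_record(
                    owner,
                    dac_identity,
                    VisaAssertion(
                        visa_type=VisaType.CONTROLLED_ACCESS_GRANTS,
                        value=f"https://data.example.org/datasets/{dataset_id.rsplit('dataset', 1)[1]}",
                        source=owner.iss,
                        by=AssertedBy.DAC,
                        asserted=clock - rng.randrange(1, 90 * 86_400),
                    ),
                )

        # home-organization assertions: affiliation, status, attestation
        if home is not None:
            home_identity = identities[-1]
            domain = home.iss.removeprefix("https://").rstrip("/")
            if rng.random() < spec.p_affiliation:
                place_record(
                    home,
                    home_identity,
                    VisaAssertion(
                        visa_type=VisaType.AFFILIATION_AND_ROLE,
                        value=f"faculty@{domain}",
                        source=home.iss,
                        by=AssertedBy.SYSTEM,
                        asserted=clock - rng.randrange(1, 365 * 86_400),
                    ),
                )
            if rng.random() < spec.p_affiliation:
                place_record(
                    home,
                    home_identity,
                    VisaAssertion(
                        visa_type=VisaType.RESEARCHER_STATUS,
                        value=BONA_FIDE_URI,
                        source=home.iss,
                        by=AssertedBy.SO,
                        asserted=clock - rng.randrange(1, 365 * 86_400),
                    ),
                )
            if rng.random() < spec.p_affiliation:
                place_record(
                    home,
                    home_identity,
                    VisaAssertion(
                        visa_type=VisaType.ACCEPTED_TERMS_AND_POLICIES,
                        value=TERMS_URI,
                        source=home.iss,
                        by=AssertedBy.SELF,
                        asserted=clock - rng.randrange(1, 365 * 86_400),
                    ),
                )

        components = (
            _spanning_components(identities, rng, spec.p_link)
            if len(identities) > 1
            else [identities]
        )
        users.append(UserProfile(user_id=user_id, identities=identities, link_components=components))

    scenario = Scenario(
        spec=spec,
        issuers=issuers,
        broker=broker,
        trust=trust,
        users=users,
        dataset_policies=dataset_policies,
        expected={},
        expired_marks=expired_marks,
        revoked_record_ids=revoked_record_ids,
    )

    # expected decision table straight from the oracle (no signing needed)
    for user in users:
        inputs = scenario.decision_inputs(user.user_id)
        for dataset_id, tiers in dataset_policies.items():
            for tier, policy in tiers.items():
                scenario.expected[(user.user_id, dataset_id, tier.value)] = oracle_decide(
                    inputs, policy, now=clock
                )
    return scenario


# --- brute-force oracle ---------------------------------------------------


def _oracle_pattern_ok(pattern: VisaPattern, payload: dict, now: int | None) -> bool:
    visa = payload.get("ga4gh_visa_v1", {})
    if visa.get("type") != pattern.visa_type.value:
        return False
    value = visa.get("value", "")
    if pattern.exact is not None and value != pattern.exact:
        return False
    if pattern.prefix is not None and not value.startswith(pattern.prefix):
        return False
    if pattern.required_source is not None and visa.get("source") != pattern.required_source:
        return False
    if pattern.required_by is not None and visa.get("by") != pattern.required_by.value:
        return False
    if pattern.max_age is not None:
        if now is None:
            raise ValueError("max_age pattern needs the evaluation clock")
        if now - visa.get("asserted", 0) > pattern.max_age:
            return False
    return True


def _oracle_closure(payloads: list[dict]) -> list[set[tuple[str, str]]]:
    """Same-person classes by naive repeated merging (no union-find)."""
    groups: list[set[tuple[str, str]]] = [{(p["iss"], p["sub"])} for p in payloads]
    for p in payloads:
        visa = p.get("ga4gh_visa_v1", {})
        if visa.get("type") != VisaType.LINKED_IDENTITIES.value:
            continue
        linked = set()
        try:
            for pair in visa.get("value", "").split(";"):
                sub_enc, iss_enc = pair.split(",")
                if not sub_enc or not iss_enc:
                    raise ValueError(pair)
                linked.add((unquote(iss_enc), unquote(sub_enc)))
        except ValueError:
            continue  # malformed link contributes nothing
        groups.append(linked)
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] and groups[j] and groups[i] & groups[j]:
                    groups[i] |= groups[j]
                    groups[j] = set()
                    changed = True
    return [g for g in groups if g]


def oracle_decide(
    user_visas: list[tuple[VisaClaims, bool]],
    policy: AccessPolicy,
    now: int | None = None,
) -> bool:
    """Exhaustive independent decision: deny unless some assignment satisfies.

    ``user_visas`` pairs decoded claims with an externally supplied validity
    verdict; invalid visas are discarded up front.  Every assignment of valid
    visas to ``require_all`` patterns is tried, and under linked-identity
    binding the assignment must sit inside one brute-force closure class.
    """
    if policy.tier is Tier.OPEN:
        return True
    if len(policy.require_all) > 8:
        raise ValueError("oracle pattern lists are capped at 8")
    payloads = [claims.to_payload() for claims, ok in user_visas if ok]
    candidates = [
        [p for p in payloads if _oracle_pattern_ok(pattern, p, now)]
        for pattern in policy.require_all
    ]
    if any(not pool for pool in candidates):
        return False
    classes = _oracle_closure(payloads)

    def same_person(a: tuple[str, str], b: tuple[str, str]) -> bool:
        if a == b:
            return True
        return any(a in cls and b in cls for cls in classes)

    for assignment in itertools.product(*candidates):
        ids = [(p["iss"], p["sub"]) for p in assignment]
        if policy.subject_binding is SubjectBinding.SINGLE_IDENTITY:
            if all(i == ids[0] for i in ids):
                return True
        else:
            if all(same_person(ids[0], i) for i in ids[1:]):
                return True
    return False
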