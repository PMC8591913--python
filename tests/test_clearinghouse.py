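"""Clearinghouse tests: validation, identity resolution, policy decisions."""

import itertools
import random

import networkx as nx
import pytest
from pydantic import ValidationError

from ga4gh_passport import (
    AccessPolicy,
    AssertedBy,
    Identity,
    IssuerConfig,
    Passport,
    ProvenIdentity,
    SubjectBinding,
    Tier,
    VisaAssertion,
    VisaPattern,
    VisaType,
    build_visa,
    encode_visa,
    evaluate_access,
    mint_linked_identities,
    registered_access_check,
    resolve_linked_identities,
    token_digest,
    validate_passport,
    verify_and_decode,
)
from ga4gh_passport.clearinghouse import IdentityGraph
from ga4gh_passport.fixtures import BONA_FIDE_URI, TERMS_URI

from .conftest import GOLDEN_IAT, GOLDEN_ISS, GOLDEN_TTL, GOLDEN_VALUE, trust_for


def make_token(issuer, visa_type, value, sub, by=AssertedBy.DAC, iat=GOLDEN_IAT,
               ttl=GOLDEN_TTL, asserted=1_625_055_001, source=None):
    assertion = VisaAssertion(
        visa_type=visa_type, value=value, source=source or issuer.iss, by=by, asserted=asserted
    )
    claims = build_visa(assertion, issuer.iss, sub, iat, ttl)
    return encode_visa(claims, issuer.header(), issuer.signing_key)


def passport_of(*tokens, subject=("https://broker/", "u1")):
    return Passport(subject=Identity(*subject), visas=tuple(tokens), assembled_at=GOLDEN_IAT)


@pytest.fixture()
def grant_token(golden_issuer):
    return make_token(
        golden_issuer, VisaType.CONTROLLED_ACCESS_GRANTS, GOLDEN_VALUE,
        "u1@elixir-europe.org", by=AssertedBy.DAC,
    )


@pytest.fixture()
def golden_policy():
    return AccessPolicy(
        policy_id="golden/controlled",
        tier=Tier.CONTROLLED,
        require_all=(
            VisaPattern(
                visa_type=VisaType.CONTROLLED_ACCESS_GRANTS,
                exact=GOLDEN_VALUE,
                required_source=GOLDEN_ISS,
                required_by=AssertedBy.DAC,
            ),
        ),
    )


class TestValidatePassport:
    def test_all_valid(self, golden_issuer, golden_trust, grant_token):
        other = make_token(
            golden_issuer, VisaType.RESEARCHER_STATUS, BONA_FIDE_URI,
            "u1@elixir-europe.org", by=AssertedBy.SO,
        )
        valid, audit = validate_passport(passport_of(grant_token, other), golden_trust, GOLDEN_IAT)
        assert len(valid) == 2
        assert [a.outcome for a in audit] == ["accepted", "accepted"]

    def test_expired_visa_is_excluded_with_audit_entry(
        self, golden_issuer, golden_trust, grant_token
    ):
        stale = make_token(
            golden_issuer, VisaType.RESEARCHER_STATUS, BONA_FIDE_URI,
            "u1@elixir-europe.org", by=AssertedBy.SO, iat=GOLDEN_IAT - 2 * GOLDEN_TTL,
        )
        valid, audit = validate_passport(passport_of(grant_token, stale), golden_trust, GOLDEN_IAT)
        assert len(valid) == 1
        assert [a.outcome for a in audit] == ["accepted", "expired"]

    def test_revocation_list_excludes_by_digest(self, golden_trust, grant_token):
        valid, audit = validate_passport(
            passport_of(grant_token), golden_trust, GOLDEN_IAT,
            revocation_list={token_digest(grant_token)},
        )
        assert valid == []
        assert audit[0].outcome == "revoked"

    def test_visas_validated_independently(self, golden_trust, grant_token):
        valid, _ = validate_passport(
            passport_of("garbage", grant_token), golden_trust, GOLDEN_IAT
        )
        assert len(valid) == 1


def brute_force_components(n_nodes, link_groups):
    """Independent closure oracle via networkx connected components."""
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for group in link_groups:
        for a, b in itertools.combinations(group, 2):
            g.add_edge(a, b)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestIdentityGraph:
    def test_no_links_gives_singletons(self, golden_issuer, golden_trust):
        a = make_token(golden_issuer, VisaType.RESEARCHER_STATUS, BONA_FIDE_URI, "a",
                       by=AssertedBy.SO)
        b = make_token(golden_issuer, VisaType.RESEARCHER_STATUS, BONA_FIDE_URI, "b",
                       by=AssertedBy.SO)
        valid, _ = validate_passport(passport_of(a, b), golden_trust, GOLDEN_IAT)
        graph = resolve_linked_identities(valid)
        assert len(graph.classes()) == 2

    def test_chain_links_close_transitively(self, golden_issuer, golden_trust):
        ids = [Identity(f"https://i{k}/", f"s{k}") for k in range(3)]
        link_ab = mint_linked_identities(
            golden_issuer, [ProvenIdentity(ids[0]), ProvenIdentity(ids[1])], GOLDEN_IAT
        )
        link_bc = mint_linked_identities(
            golden_issuer, [ProvenIdentity(ids[1]), ProvenIdentity(ids[2])], GOLDEN_IAT
        )
        valid, _ = validate_passport(passport_of(link_ab, link_bc), golden_trust, GOLDEN_IAT)
        graph = resolve_linked_identities(valid)
        assert graph.same_person(ids[0], ids[2])

    def test_two_institutional_identities_form_one_class(self, golden_issuer, golden_trust):
        """The canonical pair: one person's accounts at two organizations."""
        lisa_a = Identity("https://elixir-europe.org/", "lisa.z@elixir-europe.org")
        lisa_b = Identity("https://csc.fi/", "lisaz@csc.fi")
        link = mint_linked_identities(
            golden_issuer, [ProvenIdentity(lisa_a), ProvenIdentity(lisa_b)], GOLDEN_IAT
        )
        valid, _ = validate_passport(passport_of(link), golden_trust, GOLDEN_IAT)
        graph = resolve_linked_identities(valid)
        assert graph.class_of(lisa_a) >= {lisa_a, lisa_b}

    def test_union_find_matches_brute_force_closure(self):
        """Randomized link structures on 12 identities vs networkx components."""
        rng = random.Random(2024)
        identities = [Identity(f"https://org{k}/", f"user{k}") for k in range(12)]
        for _ in range(300):
            n_groups = rng.randrange(0, 6)
            link_groups = [
                rng.sample(range(12), rng.randrange(2, 5)) for _ in range(n_groups)
            ]
            graph = IdentityGraph()
            for identity in identities:
                graph.add(identity)
            for group in link_groups:
                for a, b in zip(group, group[1:]):
                    graph.union(identities[a], identities[b])
            got = {
                frozenset(identities.index(i) for i in cls) for cls in graph.classes()
            }
            assert got == brute_force_components(12, link_groups)

    def test_exhaustive_small_graphs(self):
        """Every link graph on 4 identities, exhaustively."""
        identities = [Identity(f"https://org{k}/", f"user{k}") for k in range(4)]
        edges = list(itertools.combinations(range(4), 2))
        for mask in range(2 ** len(edges)):
            chosen = [e for i, e in enumerate(edges) if mask >> i & 1]
            graph = IdentityGraph()
            for identity in identities:
                graph.add(identity)
            for a, b in chosen:
                graph.union(identities[a], identities[b])
            got = {frozenset(identities.index(i) for i in cls) for cls in graph.classes()}
            assert got == brute_force_components(4, [list(e) for e in chosen])

    def test_partition_property(self):
        graph = IdentityGraph()
        ids = [Identity("https://x/", f"s{k}") for k in range(6)]
        for i in ids:
            graph.add(i)
        graph.union(ids[0], ids[1])
        graph.union(ids[2], ids[3])
        classes = graph.classes()
        seen = [i for cls in classes for i in cls]
        assert sorted(seen) == sorted(ids)  # each identity in exactly one class


class TestEvaluateAccess:
    def test_worked_example_grants(self, golden_trust, grant_token, golden_policy):
        decision = evaluate_access(
            passport_of(grant_token), golden_policy, golden_trust, GOLDEN_IAT
        )
        assert decision.granted
        assert decision.matched[0].visa.value == GOLDEN_VALUE

    def test_empty_passport_denied_by_default(self, golden_trust, golden_policy):
        decision = evaluate_access(passport_of(), golden_policy, golden_trust, GOLDEN_IAT)
        assert not decision.granted
        assert "missing_required_visa" in decision.reasons

    def test_open_tier_always_grants(self, golden_trust):
        policy = AccessPolicy(policy_id="p/open", tier=Tier.OPEN)
        assert evaluate_access(passport_of(), policy, golden_trust, GOLDEN_IAT).granted

    def test_conjunction_requires_both_visas(self, golden_trust, grant_token):
        """Grant alone does not satisfy a policy also demanding an affiliation."""
        policy = AccessPolicy(
            policy_id="both/controlled",
            tier=Tier.CONTROLLED,
            require_all=(
                VisaPattern(visa_type=VisaType.CONTROLLED_ACCESS_GRANTS, exact=GOLDEN_VALUE),
                VisaPattern(visa_type=VisaType.AFFILIATION_AND_ROLE, prefix="faculty@"),
            ),
        )
        decision = evaluate_access(passport_of(grant_token), policy, golden_trust, GOLDEN_IAT)
        assert not decision.granted
        assert "missing_required_visa" in decision.reasons

    def test_linked_identities_bridge_two_sources(
        self, golden_issuer, home_org_issuer, grant_token
    ):
        """Grant to identity A, affiliation to identity B, plus an A-B link: granted."""
        a = Identity(golden_issuer.iss, "u1@elixir-europe.org")
        b = Identity(home_org_issuer.iss, "u1@cam.ac.uk")
        affiliation = make_token(
            home_org_issuer, VisaType.AFFILIATION_AND_ROLE, "faculty@cam.ac.uk",
            b.subject, by=AssertedBy.SYSTEM,
        )
        link = mint_linked_identities(
            golden_issuer, [ProvenIdentity(a), ProvenIdentity(b)], GOLDEN_IAT
        )
        trust = trust_for(golden_issuer, home_org_issuer)
        policy = AccessPolicy(
            policy_id="both/controlled",
            tier=Tier.CONTROLLED,
            require_all=(
                VisaPattern(visa_type=VisaType.CONTROLLED_ACCESS_GRANTS, exact=GOLDEN_VALUE),
                VisaPattern(visa_type=VisaType.AFFILIATION_AND_ROLE, prefix="faculty@"),
            ),
            subject_binding=SubjectBinding.LINKED_IDENTITIES,
        )
        without_link = evaluate_access(
            passport_of(grant_token, affiliation), policy, trust, GOLDEN_IAT
        )
        assert not without_link.granted
        assert "subject_binding_unsatisfied" in without_link.reasons
        with_link = evaluate_access(
            passport_of(grant_token, affiliation, link), policy, trust, GOLDEN_IAT
        )
        assert with_link.granted

    def test_single_identity_binding_ignores_links(
        self, golden_issuer, home_org_issuer, grant_token
    ):
        a = Identity(golden_issuer.iss, "u1@elixir-europe.org")
        b = Identity(home_org_issuer.iss, "u1@cam.ac.uk")
        affiliation = make_token(
            home_org_issuer, VisaType.AFFILIATION_AND_ROLE, "faculty@cam.ac.uk",
            b.subject, by=AssertedBy.SYSTEM,
        )
        link = mint_linked_identities(
            golden_issuer, [ProvenIdentity(a), ProvenIdentity(b)], GOLDEN_IAT
        )
        trust = trust_for(golden_issuer, home_org_issuer)
        policy = AccessPolicy(
            policy_id="strict/controlled",
            tier=Tier.CONTROLLED,
            require_all=(
                VisaPattern(visa_type=VisaType.CONTROLLED_ACCESS_GRANTS, exact=GOLDEN_VALUE),
                VisaPattern(visa_type=VisaType.AFFILIATION_AND_ROLE, prefix="faculty@"),
            ),
            subject_binding=SubjectBinding.SINGLE_IDENTITY,
        )
        decision = evaluate_access(
            passport_of(grant_token, affiliation, link), policy, trust, GOLDEN_IAT
        )
        assert not decision.granted

    def test_max_age_limits_assertion_staleness(self, golden_issuer, golden_trust):
        token = make_token(
            golden_issuer, VisaType.CONTROLLED_ACCESS_GRANTS, GOLDEN_VALUE, "u1",
            asserted=GOLDEN_IAT - 10_000,
        )
        fresh_only = AccessPolicy(
            policy_id="fresh/controlled", tier=Tier.CONTROLLED,
            require_all=(
                VisaPattern(
                    visa_type=VisaType.CONTROLLED_ACCESS_GRANTS, exact=GOLDEN_VALUE,
                    max_age=5_000,
                ),
            ),
        )
        assert not evaluate_access(passport_of(token), fresh_only, golden_trust, GOLDEN_IAT).granted
        lenient = AccessPolicy(
            policy_id="ok/controlled", tier=Tier.CONTROLLED,
            require_all=(
                VisaPattern(
                    visa_type=VisaType.CONTROLLED_ACCESS_GRANTS, exact=GOLDEN_VALUE,
                    max_age=20_000,
                ),
            ),
        )
        assert evaluate_access(passport_of(token), lenient, golden_trust, GOLDEN_IAT).granted

    def test_monotonicity_adding_a_visa_never_revokes_a_grant(
        self, golden_issuer, golden_trust, grant_token, golden_policy
    ):
        base = passport_of(grant_token)
        assert evaluate_access(base, golden_policy, golden_trust, GOLDEN_IAT).granted
        extras = [
            make_token(golden_issuer, VisaType.RESEARCHER_STATUS, BONA_FIDE_URI, "someone-else",
                       by=AssertedBy.SO),
            "not-even-a-token",
            make_token(golden_issuer, VisaType.CONTROLLED_ACCESS_GRANTS, "https://other/", "u9"),
        ]
        for extra in extras:
            grown = passport_of(grant_token, extra)
            assert evaluate_access(grown, golden_policy, golden_trust, GOLDEN_IAT).granted

    def test_expiry_dominance(self, golden_trust, grant_token, golden_policy):
        granted_at = evaluate_access(
            passport_of(grant_token), golden_policy, golden_trust, GOLDEN_IAT
        )
        assert granted_at.granted
        matched_exp = min(c.exp for c in granted_at.matched.values())
        later = evaluate_access(
            passport_of(grant_token), golden_policy, golden_trust, matched_exp + 1
        )
        assert not later.granted

    def test_untrusted_issuer_visa_cannot_grant(self, golden_issuer, grant_token, golden_policy):
        from ga4gh_passport import TrustConfig

        decision = evaluate_access(
            passport_of(grant_token), golden_policy, TrustConfig({}), GOLDEN_IAT
        )
        assert not decision.granted
        assert decision.audit[0].outcome == "untrusted_issuer"


class TestRegisteredAccess:
    def make_pair(self, issuer, sub="u1@cam.ac.uk", status_iat=GOLDEN_IAT):
        status = make_token(
            issuer, VisaType.RESEARCHER_STATUS, BONA_FIDE_URI, sub,
            by=AssertedBy.SO, iat=status_iat,
        )
        terms = make_token(
            issuer, VisaType.ACCEPTED_TERMS_AND_POLICIES, TERMS_URI, sub, by=AssertedBy.SELF
        )
        return status, terms

    def test_both_visas_grant(self, home_org_issuer):
        status, terms = self.make_pair(home_org_issuer)
        decision = registered_access_check(
            passport_of(status, terms), TERMS_URI, BONA_FIDE_URI,
            trust_for(home_org_issuer), GOLDEN_IAT,
        )
        assert decision.granted

    def test_status_alone_denied(self, home_org_issuer):
        status, _ = self.make_pair(home_org_issuer)
        decision = registered_access_check(
            passport_of(status), TERMS_URI, BONA_FIDE_URI,
            trust_for(home_org_issuer), GOLDEN_IAT,
        )
        assert not decision.granted

    def test_expired_status_denied(self, home_org_issuer):
        status, terms = self.make_pair(home_org_issuer, status_iat=GOLDEN_IAT - 2 * GOLDEN_TTL)
        decision = registered_access_check(
            passport_of(status, terms), TERMS_URI, BONA_FIDE_URI,
            trust_for(home_org_issuer), GOLDEN_IAT,
        )
        assert not decision.granted


class TestPolicyInvariants:
    def test_open_tier_must_be_requirement_free(self):
        with pytest.raises(ValidationError):
            AccessPolicy(
                policy_id="bad", tier=Tier.OPEN,
                require_all=(
                    VisaPattern(visa_type=VisaType.RESEARCHER_STATUS, exact="x"),
                ),
            )

    def test_registered_tier_needs_status_and_terms(self):
        with pytest.raises(ValidationError):
            AccessPolicy(
                policy_id="bad", tier=Tier.REGISTERED,
                require_all=(
                    VisaPattern(visa_type=VisaType.RESEARCHER_STATUS, exact="x"),
                ),
            )

    def test_controlled_tier_needs_a_grant_pattern(self):
        with pytest.raises(ValidationError):
            AccessPolicy(
                policy_id="bad", tier=Tier.CONTROLLED,
                require_all=(
                    VisaPattern(visa_type=VisaType.AFFILIATION_AND_ROLE, prefix="faculty@"),
                ),
            )

    def test_pattern_needs_exactly_one_matcher(self):
        with pytest.raises(ValidationError):
            VisaPattern(visa_type=VisaType.RESEARCHER_STATUS)
        with pytest.raises(ValidationError):
            VisaPattern(visa_type=VisaType.RESEARCHER_STATUS, exact="x", prefix="y")

    def test_tier_enumeration_has_three_members(self):
        assert {t.value for t in Tier} == {"open", "registered", "controlled"}
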