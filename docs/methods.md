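# Methods

This note documents the model, the numerical and design choices, and the
limits of what the test suite shows.

## The authorization model

A visa is one signed statement by an *assertion source* (a DAC, a home
organization, or the system itself) about one user identity.  Five assertion
types exist: `ControlledAccessGrants` (a DAC's dataset grant),
`ResearcherStatus` and `AcceptedTermsAndPolicies` (the two registered-tier
credentials: vetted bona fide status and a terms attestation),
`AffiliationAndRole` (a `role@domain` statement such as `faculty@cam.ac.uk`),
and `LinkedIdentities` (a list of `(issuer, subject)` pairs confirmed to
belong to one person).  The registry is closed: any other type string is
rejected at parse time.

Authority flows in one direction.  An assertion is recorded in a repository;
an issuer signs it into a token bound to an `(iss, sub)` identity with an
`iat`/`exp` validity window; a broker concatenates tokens from many issuers
into a passport; a clearinghouse verifies each token independently against
its own trust anchors and evaluates policy.  The envelope is deliberately
unsigned: every visa carries its own signature, so the passport adds no
authority and needs none.

The clearinghouse is deny-by-default and its policies are purely
conjunctive-positive (`require_all` of visa patterns; disjunction is
expressed as multiple policies per dataset).  Two structural consequences are
load-bearing and tested as invariants:

- **monotonicity** — adding a visa can only add candidates and merge
  identity classes, so a granted decision can never flip to denied;
- **expiry dominance** — every grant rests on concrete matched visas, so the
  decision lapses once the earliest matched `exp` passes.

### Subject binding and identity linkage

Visas from different issuers name different identities for the same person.
The default policy binding (`linked_identities`) counts visas together only
when their token identities are equal or joined by a `LinkedIdentities` visa;
`single_identity` requires exact `(iss, sub)` equality.  Linkage is the
transitive closure of co-listing: each valid visa contributes its own
`(iss, sub)` as a node, each valid `LinkedIdentities` visa unions the pairs
co-listed in its value.  The engine uses union-find with path compression;
the test suite compares it against two independent oracles (networkx
connected components, and a naive repeated-merge closure inside the decision
oracle).  A grant is made under binding B iff some equivalence class contains
a satisfying visa for every pattern — because classes are disjoint, this is
equivalent to, and cheaper than, enumerating assignments.

The identity list in a `LinkedIdentities` value is encoded as
percent-encoded `subject,issuer` pairs joined by `;` — the standard leaves
the encoding to profiles, and this one is unambiguous and reversible (the
codec is round-trip-tested against an independent string-level parser).

## The token layer

Tokens are compact JWS (`base64url(header).base64url(payload).signature`)
signed with RSASSA-PKCS1-v1_5 over SHA-256 (RS256) — the only algorithm the
allow-list admits by default, and `"none"` is unconditionally rejected.  The
RSA arithmetic (Miller–Rabin keygen with 40 rounds, CRT signing, PKCS#1 v1.5
encoding) is implemented directly on Python integers, and key material
round-trips through standard JWK/JWKS JSON.  Keys generated here are test
fixtures; nothing in the package manages production key material.

Verification order matters and is fixed: structural parse and header policy
(`malformed`) → `jku` membership in the trust map (`untrusted_issuer`,
raised before any key is consulted — instrumented tests confirm no key
outside the map is ever touched) → `kid` lookup (`unknown_key`) → signature
over the raw signing input (`bad_signature`) → claims interpretation
(`bad_claims`) → time window (`expired` / `not_yet_valid`).  The payload is
parsed only *after* the signature verifies, so any tamper in the payload
segment surfaces as `bad_signature` rather than a parse error.  All
timestamps are integer epoch seconds; fractional values are rejected.  The
`conditions` field of an assertion is preserved verbatim and never
evaluated — the standard does not define its matching semantics, and
silently evaluating an under-specified restriction field would be worse than
ignoring it openly.

Key defaults: `clock_skew` 0 s (strict, testable semantics; deployments can
widen it), visa TTL 31,536,000 s (365 days, the window of the worked
example), `iat` is only required to satisfy `iat ≤ now + skew` (whether
issuers may backdate is unspecified, so it is not forbidden).

## Revocation

Revoking an assertion record stops future issuance immediately; it does not
reach into tokens already issued, which remain valid until `exp`.  A
clearinghouse may additionally be given a local revocation list of token
SHA-256 digests, which excludes tokens before verification.  This two-layer
model (short TTLs plus optional digest lists) reproduces the observable
behavior without prescribing a revocation transport, which the standard
leaves open.

## The synthetic ecosystems

`generate_scenario(ScenarioSpec)` emulates a miniature federation: `n_dacs`
DACs owning `n_datasets` datasets round-robin, `n_home_orgs` home
organizations, one broker, and `n_users` users, each with one identity per
DAC and one at their home organization.  Per user: each dataset's owning DAC
issues a grant with probability `p_grant`; the home organization asserts
affiliation, researcher status, and a terms attestation each with
probability `p_affiliation`; every recorded assertion is revoked with
probability `p_revoked`, else marked to be issued already-expired with
probability `p_expired`; and a random spanning structure over the user's
identities keeps each edge with probability `p_link`, so the ground-truth
same-person classes are known by construction and minted as
`LinkedIdentities` visas.  Each dataset carries three policies (open /
registered / controlled); odd-numbered datasets additionally require a
`faculty@` affiliation next to the grant, exercising the multi-source
conjunction and the linked-identity binding.

Defaults (`n_users=6, n_dacs=2, n_home_orgs=2, n_datasets=3, p_grant=0.5,
p_affiliation=0.7, p_link=0.9, p_revoked=0.1, p_expired=0.1,
clock=1625144975`) are chosen to make every decision path — grant, missing
visa, unlinked identities, expiry, revocation — well represented in a
scenario of a few dozen visas; the clock matches the worked example's epoch.
The expected decision table is computed by the independent oracle, not by
the engine under test.

Issuer keys are drawn from a fixed pool of eight deterministic 2048-bit test
keypairs (lazily generated once per process from a constant PRNG stream) with
pool assignment driven by the scenario seed.  Pure-Python 2048-bit key
generation costs roughly a second per pair, and the property suites generate
hundreds of ecosystems; a shared pool keeps them fast while preserving the
contract that identical specs yield byte-identical scenarios.  Distinct
seeds may share key material — irrelevant here, since trust is anchored per
`jku`/`kid`, not per key uniqueness.

### What the fixtures do not model

Scenarios exercise the message contracts, not the wire: there is no OIDC
flow, no network `jku` fetch, no real authentication (the broker's
authentication is an injected flag).  Grant rates and ecosystem shapes are
chosen for decision-path coverage, not statistical realism.  Passing tests
therefore show the token format, trust model, and decision semantics are
correct and self-consistent — not that a deployment's federation, consent
semantics (e.g. DUO codes), or trust framework are sound.

## The brute-force oracle

`oracle_decide` re-states the decision semantics with none of the engine's
machinery: it works on raw payload dictionaries, filters by externally
supplied validity verdicts, computes linkage by naive repeated set-merging,
and enumerates every assignment of visas to patterns (`require_all` capped
at 8, so ≤ 8-fold products).  Engine/oracle agreement is checked on 1,000+
generated decisions per run with zero tolerated disagreements.

## Problem sizes

The default test run uses: 500 visas for the round-trip/tamper sweep, ~25
ecosystems (≥1,000 pairs) for the decision invariants, ~28 ecosystems
(≥1,000 decisions) for oracle equivalence, 200 small ecosystems for
revocation soundness, 300 randomized 12-identity link structures plus an
exhaustive sweep of all 4-identity graphs for the identity partition.  The
acceptance script uses the same shapes with 300 visas for the signing sweep.
These sizes saturate the decision paths; scaling them up changes runtime,
not coverage.

## Known limitations

- Only RS256 is implemented; the allow-list is a config hook, not a
  multi-algorithm suite.
- The trust map is flat: any trusted issuer may mint any visa type,
  including `LinkedIdentities` — defining which issuers may link identities
  is a trust-framework question the standard itself leaves open.
- The assertion store is single-writer and in-memory with JSON-lines
  persistence; it is a reference repository, not a database.
- Policy-side patterns must name dataset identifiers exactly (or by prefix);
  there is no mapping table between clearinghouse dataset ids and grant
  value URIs.
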