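# ga4gh-passport

A self-contained reference implementation of the GA4GH Passport v1 standard:
the machine-readable digital identity used in genomics to convey a data
user's roles and data-access permissions across organizational boundaries.

Sharing human genomic data is governed by data access committees (DACs) and a
three-tier access model — **open** (public), **registered** (vetted, bona fide
researchers who have attested to terms of use), and **controlled**
(DAC-approved per dataset).  The Passport standard encodes each governance
outcome as a **visa**: a single digitally signed assertion such as "this DAC
granted this person access to this dataset" or "this person is faculty at
this university".  A **passport** is the collection of a user's visas,
assembled by a broker and presented to a **clearinghouse** — the decision
point in front of a data-serving API — which validates every visa against its
trust anchors and evaluates its access policies, denying by default.

This package implements the whole pipeline, offline and deterministic:

| layer | module | what it does |
|---|---|---|
| token format | `ga4gh_passport.jws` | RS256 compact JWS, JWK/JWKS key material |
| visa model | `ga4gh_passport.visa` | the five visa types, claims building, signing, trust-anchored verification with machine-readable rejection reasons |
| repository | `ga4gh_passport.store` | DAC-side assertion records: record / query / revoke, JSON-lines persistence |
| issuance | `ga4gh_passport.issuance` | visa issuer, passport broker, LinkedIdentities minting |
| clearinghouse | `ga4gh_passport.clearinghouse` | per-visa validation + audit log, identity-equivalence resolution (union-find), conjunctive tiered policy evaluation |
| fixtures | `ga4gh_passport.fixtures` | seeded synthetic ecosystems and an independent brute-force decision oracle |
| CLI | `ga4gh_passport.cli` | `ga4gh-passport` command: keygen, store, issue, assemble, inspect, evaluate, scenario, demo |

## The core objects

A visa is a JWT whose payload carries one assertion under `ga4gh_visa_v1`:

```
{"iss", "sub", "iat", "exp",
 "ga4gh_visa_v1": {"type", "value", "source", "by", "asserted"[, "conditions"]}}
```

with header `{"alg": "RS256", "jku", "typ": "JWT", "kid"}`.  Verification is
trust-anchored: a `TrustConfig` maps trusted `jku` key-set URIs to local JWKS
documents, and a token can only verify through that map.  An `AccessPolicy`
is a conjunctive list of visa patterns (type, exact/prefix value, source,
asserting party, maximum assertion age) plus a subject binding: under
`linked_identities`, visas issued to different `(iss, sub)` identities only
count together when a LinkedIdentities visa proves they are the same person.

## Worked example

```
$ ga4gh-passport demo --seed 7
[1] user registers identity 00000007@elixir-europe.org via the broker
[2] DAC approves the data access request; assertion recorded as rec-000001
[3] broker assembles passport with 1 visa(s) at t=1625144975
[4] decoded visa (header then payload):
{
  "alg": "RS256",
  "jku": "https://sd-apply.csc.fi/api/jwk",
  "typ": "JWT",
  "kid": "demo-key-7"
}
{
  "iss": "https://sd-apply.csc.fi/",
  "sub": "00000007@elixir-europe.org",
  "iat": 1625144975,
  "exp": 1656680975,
  "ga4gh_visa_v1": {
    "type": "ControlledAccessGrants",
    "value": "https://beaconpy-elixirbeacon.rahtiapp.fi/urn:hg:example-controlled",
    "source": "https://sd-apply.csc.fi/",
    "by": "dac",
    "asserted": 1625055001
  }
}
[5] golden-fixture field check: all match
[6] clearinghouse decision at t=1625144975: GRANTED
[7] clearinghouse decision at t=1656680976 (past exp): DENIED (audit: ['expired'])
```

The walk-through records a DAC approval (`asserted` is when the DAC decided),
signs it into a one-year visa (`exp − iat` = 31,536,000 s), and shows the
clearinghouse granting while the visa is live and denying — with an `expired`
audit entry — once the virtual clock passes `exp`.

Library use mirrors the CLI:

```python
from ga4gh_passport import *

store = AssertionStore()
identity = Identity("https://dac.example.org/", "alice@dac.example.org")
store.record_assertion(identity, VisaAssertion(
    visa_type=VisaType.CONTROLLED_ACCESS_GRANTS,
    value="https://data.example.org/datasets/0",
    source="https://dac.example.org/", by="dac", asserted=1_625_055_001,
), now=1_625_055_001)
# ... wrap the store in an IssuerConfig, assemble_passport(), evaluate_access()
```

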