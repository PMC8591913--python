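"""Minimal RS256 JSON Web Signature layer: integer RSA, PKCS#1 v1.5, JWK/JWKS.

Visas are compact JWS tokens (``base64url(header).base64url(payload).base64url(sig)``)
signed with RSASSA-PKCS1-v1_5 over SHA-256 — the only algorithm the visa format
prints and the only one this package accepts.  The RSA arithmetic is implemented
directly on Python integers; key material round-trips through standard JWK/JWKS
JSON documents (``kty=RSA`` with base64url big-endian ``n``/``e``, private keys
adding ``d``/``p``/``q``/``dp``/``dq``/``qi``).

Keys produced here are test/fixture keys: probable primes from a seeded
Miller-Rabin search, e=65537, CRT-accelerated signing.
"""

from __future__ import annotations

import base64
import hashlib
import json
import random
from dataclasses import dataclass
from typing import Any, Iterator

__all__ = [
    "RSAPublicKey",
    "RSAPrivateKey",
    "JWSError",
    "b64url_encode",
    "b64url_decode",
    "generate_rsa_keypair",
    "sign_compact",
    "split_compact",
    "verify_signature",
    "jwk_from_public_key",
    "jwk_from_private_key",
    "public_key_from_jwk",
    "private_key_from_jwk",
    "jwks_document",
    "find_key_in_jwks",
]

# DER DigestInfo prefix for SHA-256 (EMSA-PKCS1-v1_5, RFC 8017 section 9.2)
_SHA256_DIGESTINFO = bytes.fromhex("3031300d060960864801650304020105000420")

_SMALL_PRIMES = (
    2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61,
    67, 71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113, 127, 131, 137,
)


class JWSError(Exception):
    """Raised on malformed token material or signing misuse."""


def b64url_encode(data: bytes) -> str:
    return base64.urlsafe_b64encode(data).rstrip(b"=").decode("ascii")


def b64url_decode(segment: str) -> bytes:
    """Strict unpadded base64url decode; raises JWSError on bad input."""
    if not isinstance(segment, str) or any(c in segment for c in "=+/ \n"):
        raise JWSError("invalid base64url segment")
    pad = -len(segment) % 4
    if pad == 3:
        raise JWSError("invalid base64url length")
    try:
        return base64.urlsafe_b64decode(segment + "=" * pad)
    except (ValueError, base64.binascii.Error) as exc:  # type: ignore[attr-defined]
        raise JWSError(f"invalid base64url segment: {exc}") from exc


def _int_to_bytes(value: int, length: int | None = None) -> bytes:
    if length is None:
        length = max(1, (value.bit_length() + 7) // 8)
    return value.to_bytes(length, "big")


def _int_from_bytes(data: bytes) -> int:
    return int.from_bytes(data, "big")


def _b64url_uint(value: int) -> str:
    return b64url_encode(_int_to_bytes(value))


def _uint_from_b64url(segment: str) -> int:
    return _int_from_bytes(b64url_decode(segment))


@dataclass(frozen=True)
class RSAPublicKey:
    n: int
    e: int

    @property
    def byte_length(self) -> int:
        return (self.n.bit_length() + 7) // 8


@dataclass(frozen=True)
class RSAPrivateKey:
    n: int
    e: int
    d: int
    p: int
    q: int
    dp: int
    dq: int
    qinv: int

    @property
    def public_key(self) -> RSAPublicKey:
        return RSAPublicKey(self.n, self.e)

    @property
    def byte_length(self) -> int:
        return (self.n.bit_length() + 7) // 8


def _is_probable_prime(n: int, rng: random.Random, rounds: int = 40) -> bool:
    if n < 2:
        return False
    for p in _SMALL_PRIMES:
        if n % p == 0:
            return n == p
    d, r = n - 1, 0
    while d % 2 == 0:
        d //= 2
        r += 1
    for _ in range(rounds):
        a = rng.randrange(2, n - 1)
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(r - 1):
            x = x * x % n
            if x == n - 1:
                break
        else:
            return False
    return True


def _generate_prime(bits: int, rng: random.Random) -> int:
    while True:
        # force top two bits so p*q has exactly 2*bits bits, and oddness
        candidate = rng.getrandbits(bits) | (1 << bits - 1) | (1 << bits - 2) | 1
        if _is_probable_prime(candidate, rng):
            return candidate


def generate_rsa_keypair(bits: int = 2048, rng: random.Random | None = None) -> RSAPrivateKey:
    """Generate an RSA keypair with e=65537 from a (seedable) PRNG stream."""
    if rng is None:
        rng = random.Random()
    e = 65537
    half = bits // 2
    while True:
        p = _generate_prime(half, rng)
        q = _generate_prime(half, rng)
        if p == q:
            continue
        phi = (p - 1) * (q - 1)
        if phi % e == 0:
            continue
        d = pow(e, -1, phi)
        if p < q:
            p, q = q, p
        return RSAPrivateKey(
            n=p * q, e=e, d=d, p=p, q=q,
            dp=d % (p - 1), dq=d % (q - 1), qinv=pow(q, -1, p),
        )


def _emsa_pkcs1_v15_sha256(message: bytes, em_len: int) -> bytes:
    t = _SHA256_DIGESTINFO + hashlib.sha256(message).digest()
    if em_len < len(t) + 11:
        raise JWSError("RSA modulus too small for SHA-256 signature")
    return b"\x00\x01" + b"\xff" * (em_len - len(t) - 3) + b"\x00" + t


def _rsa_private_op(key: RSAPrivateKey, m: int) -> int:
    # CRT: two half-size exponentiations instead of one full-size
    m1 = pow(m % key.p, key.dp, key.p)
    m2 = pow(m % key.q, key.dq, key.q)
    h = (key.qinv * (m1 - m2)) % key.p
    return m2 + h * key.q


def sign_bytes(key: RSAPrivateKey, message: bytes) -> bytes:
    em = _emsa_pkcs1_v15_sha256(message, key.byte_length)
    return _int_to_bytes(_rsa_private_op(key, _int_from_bytes(em)), key.byte_length)


def verify_signature(key: RSAPublicKey, message: bytes, signature: bytes) -> bool:
    if len(signature) != key.byte_length:
        return False
    s = _int_from_bytes(signature)
    if s >= key.n:
        return False
    em = _int_to_bytes(pow(s, key.e, key.n), key.byte_length)
    try:
        expected = _emsa_pkcs1_v15_sha256(message, key.byte_length)
    except JWSError:
        return False
    return em == expected


def _canonical_json(obj: Any) -> bytes:
    # insertion order preserved: the printed visa layout survives a round trip
    return json.dumps(obj, separators=(",", ":"), ensure_ascii=False).encode("utf-8")


def sign_compact(header: dict, payload: dict, key: RSAPrivateKey) -> str:
    """Serialize header/payload and sign: compact JWS ``h.p.s``."""
    signing_input = (
        b64url_encode(_canonical_json(header))
        + "."
        + b64url_encode(_canonical_json(payload))
    )
    signature = sign_bytes(key, signing_input.encode("ascii"))
    return signing_input + "." + b64url_encode(signature)


def split_compact_unverified_payload(token: str) -> tuple[dict, str, bytes, bytes]:
    """Parse a compact JWS into (header, raw payload segment, signature, signing_input).

    Only the header is JSON-decoded; the payload segment is returned verbatim
    so a verifier can check the signature over the exact bytes before
    interpreting the payload.  Raises JWSError on structural defects.
    """
    if not isinstance(token, str):
        raise JWSError("token is not a string")
    parts = token.split(".")
    if len(parts) != 3:
        raise JWSError("token must have exactly three dot-separated segments")
    try:
        header = json.loads(b64url_decode(parts[0]))
    except (JWSError, json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise JWSError(f"undecodable header segment: {exc}") from exc
    if not isinstance(header, dict):
        raise JWSError("header must be a JSON object")
    signature = b64url_decode(parts[2])
    signing_input = (parts[0] + "." + parts[1]).encode("ascii")
    return header, parts[1], signature, signing_input


def decode_payload_segment(segment: str) -> dict:
    try:
        payload = json.loads(b64url_decode(segment))
    except (JWSError, json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise JWSError(f"undecodable payload segment: {exc}") from exc
    if not isinstance(payload, dict):
        raise JWSError("payload must be a JSON object")
    return payload


def split_compact(token: str) -> tuple[dict, dict, bytes, bytes]:
    """Parse a compact JWS into (header, payload, signature, signing_input).

    Raises JWSError on any structural defect; performs no verification.
    """
    header, payload_segment, signature, signing_input = split_compact_unverified_payload(token)
    return header, decode_payload_segment(payload_segment), signature, signing_input


# --- JWK / JWKS -----------------------------------------------------------


def jwk_from_public_key(key: RSAPublicKey, kid: str) -> dict:
    return {
        "kty": "RSA",
        "use": "sig",
        "alg": "RS256",
        "kid": kid,
        "n": _b64url_uint(key.n),
        "e": _b64url_uint(key.e),
    }


def jwk_from_private_key(key: RSAPrivateKey, kid: str) -> dict:
    jwk = jwk_from_public_key(key.public_key, kid)
    jwk.update(
        d=_b64url_uint(key.d),
        p=_b64url_uint(key.p),
        q=_b64url_uint(key.q),
        dp=_b64url_uint(key.dp),
        dq=_b64url_uint(key.dq),
        qi=_b64url_uint(key.qinv),
    )
    return jwk


def public_key_from_jwk(jwk: dict) -> RSAPublicKey:
    if jwk.get("kty") != "RSA":
        raise JWSError(f"unsupported key type: {jwk.get('kty')!r}")
    try:
        return RSAPublicKey(n=_uint_from_b64url(jwk["n"]), e=_uint_from_b64url(jwk["e"]))
    except KeyError as exc:
        raise JWSError(f"JWK missing field {exc}") from exc


def private_key_from_jwk(jwk: dict) -> RSAPrivateKey:
    pub = public_key_from_jwk(jwk)
    try:
        return RSAPrivateKey(
            n=pub.n, e=pub.e,
            d=_uint_from_b64url(jwk["d"]),
            p=_uint_from_b64url(jwk["p"]),
            q=_uint_from_b64url(jwk["q"]),
            dp=_uint_from_b64url(jwk["dp"]),
            dq=_uint_from_b64url(jwk["dq"]),
            qinv=_uint_from_b64url(jwk["qi"]),
        )
    except KeyError as exc:
        raise JWSError(f"private JWK missing field {exc}") from exc


def jwks_document(entries: list[tuple[str, RSAPublicKey]]) -> dict:
    """Build a JWKS document from (kid, public key) pairs."""
    return {"keys": [jwk_from_public_key(k, kid) for kid, k in entries]}


def iter_jwks(jwks: dict) -> Iterator[dict]:
    keys = jwks.get("keys")
    if not isinstance(keys, list):
        raise JWSError("JWKS document has no 'keys' array")
    yield from (k for k in keys if isinstance(k, dict))


def find_key_in_jwks(jwks: dict, kid: str) -> RSAPublicKey | None:
    for jwk in iter_jwks(jwks):
        if jwk.get("kid") == kid:
            return public_key_from_jwk(jwk)
    return None
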