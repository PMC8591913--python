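"""Passport Visa Assertion Repository: record, query, and revoke assertions.

This is the DAC-side (or home-organization-side) datastore: when a data access
request is approved, the grant is recorded here; a visa issuer later queries
the active records and signs them into visas.  Revoking a record stops future
issuance — tokens already in the wild remain valid until their ``exp`` unless
a clearinghouse also applies a revocation list.

Records persist as JSON-lines, one record per line, append-friendly.
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import NamedTuple, Optional

from pydantic import BaseModel, ConfigDict, StrictInt, StrictStr, model_validator

from .visa import VisaAssertion

__all__ = ["Identity", "RecordStatus", "AssertionRecord", "AssertionStore", "RecordNotFound"]


class Identity(NamedTuple):
    """An (issuer URI, subject identifier) pair naming one user identity."""

    issuer: str
    subject: str


class RecordStatus(str, enum.Enum):
    ACTIVE = "active"
    REVOKED = "revoked"


class RecordNotFound(KeyError):
    pass


class AssertionRecord(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    record_id: StrictStr
    subject: Identity
    assertion: VisaAssertion
    status: RecordStatus = RecordStatus.ACTIVE
    created: StrictInt
    revoked_at: Optional[StrictInt] = None

    @model_validator(mode="after")
    def _revocation_consistent(self) -> "AssertionRecord":
        if (self.status is RecordStatus.REVOKED) != (self.revoked_at is not None):
            raise ValueError("status=revoked iff revoked_at is set")
        if self.revoked_at is not None and self.revoked_at < self.created:
            raise ValueError("revoked_at must be >= created")
        return self

    def to_json_dict(self) -> dict:
        d = {
            "record_id": self.record_id,
            "subject": {"issuer": self.subject.issuer, "subject": self.subject.subject},
            "assertion": self.assertion.to_claim(),
            "status": self.status.value,
            "created": self.created,
        }
        if self.revoked_at is not None:
            d["revoked_at"] = self.revoked_at
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "AssertionRecord":
        return cls(
            record_id=d["record_id"],
            subject=Identity(d["subject"]["issuer"], d["subject"]["subject"]),
            assertion=VisaAssertion.from_claim(d["assertion"]),
            status=RecordStatus(d["status"]),
            created=d["created"],
            revoked_at=d.get("revoked_at"),
        )


class AssertionStore:
    """In-memory assertion repository with JSON-lines persistence.

    Subject matching is exact byte equality on (issuer URI, subject
    identifier).  Record ids are a monotone counter, stable across save/load.
    Queries are time-independent: validity windows live on issued tokens, not
    on the records themselves.
    """

    def __init__(self) -> None:
        self._records: dict[str, AssertionRecord] = {}
        self._counter = 0

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def record_assertion(self, subject: Identity, assertion: VisaAssertion, now: int) -> str:
        """Record an active assertion about ``subject``; returns the record id."""
        if not isinstance(assertion, VisaAssertion):
            assertion = VisaAssertion.model_validate(assertion)
        self._counter += 1
        record_id = f"rec-{self._counter:06d}"
        self._records[record_id] = AssertionRecord(
            record_id=record_id,
            subject=Identity(*subject),
            assertion=assertion,
            status=RecordStatus.ACTIVE,
            created=now,
        )
        return record_id

    def get(self, record_id: str) -> AssertionRecord:
        try:
            return self._records[record_id]
        except KeyError:
            raise RecordNotFound(record_id) from None

    def query_active(self, subject: Identity, now: int | None = None) -> list[AssertionRecord]:
        """All active records for ``subject``, in creation order.

        ``now`` is accepted for interface symmetry but never consulted.
        """
        subject = Identity(*subject)
        return [
            r
            for r in self._records.values()
            if r.subject == subject and r.status is RecordStatus.ACTIVE
        ]

    def revoke(self, record_id: str, now: int) -> AssertionRecord:
        """Mark a record revoked; idempotent on already-revoked records."""
        record = self.get(record_id)
        if record.status is RecordStatus.REVOKED:
            return record
        revoked = record.model_copy(
            update={"status": RecordStatus.REVOKED, "revoked_at": now}
        )
        self._records[record_id] = revoked
        return revoked

    # --- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for record in self._records.values():
                fh.write(json.dumps(record.to_json_dict(), separators=(",", ":")))
                fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "AssertionStore":
        store = cls()
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                record = AssertionRecord.from_json_dict(json.loads(line))
                store._records[record.record_id] = record
                # keep the counter past any loaded id of our own format
                try:
                    store._counter = max(store._counter, int(record.record_id.rsplit("-", 1)[1]))
                except (IndexError, ValueError):
                    pass
        return store
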