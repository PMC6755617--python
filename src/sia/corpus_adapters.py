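"""Pluggable document fetchers with retry and mark-unavailable semantics.

A corpus adapter turns ``(document_id, source)`` references into
section-structured text (title / abstract / full text).  Remote providers
are unreliable, so fetching is wrapped in capped exponential-backoff retry;
after the attempt budget is exhausted the documents are marked unavailable
and the pipeline proceeds treating them as empty text — an unavailable
document never blocks or fails the enclosing request, it is only logged.

Adapters included here:

* :class:`LocalCorpusAdapter` — reads the local JSON-lines corpus format
  (also what the fixture generator writes); the default for offline runs.
* :class:`IdentityAdapter` — returns text carried inline in the request
  message itself, bypassing any external provider.
* :class:`ScriptedAdapter` — deterministic failure injection for tests.

Live PubMed/PMC/patent-server clients would implement the same two-method
interface; they are intentionally not part of this package.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Optional, Protocol, Sequence

from .clock import Clock, SystemClock

log = logging.getLogger(__name__)

SECTION_CODES = ("T", "A", "F")  # title, abstract, full text

DEFAULT_BATCH_SIZE = 25


class RecoverableFetchError(RuntimeError):
    """Transient transport/parse failure: the fetch may be retried."""


@dataclass(frozen=True)
class Document:
    """One fetched document: section code -> text, plus availability.

    Section codes are restricted to ``T`` (title), ``A`` (abstract) and
    ``F`` (full text).  ``available = False`` implies empty sections.
    """

    document_id: str
    source: str
    sections: dict[str, str] = field(default_factory=dict)
    available: bool = True

    def __post_init__(self) -> None:
        bad = set(self.sections) - set(SECTION_CODES)
        if bad:
            raise ValueError(f"invalid section codes {sorted(bad)}; allowed: T, A, F")
        if not self.available and self.sections:
            raise ValueError("unavailable document must have empty sections")

    @classmethod
    def unavailable(cls, document_id: str, source: str) -> "Document":
        return cls(document_id=document_id, source=source, sections={}, available=False)

    def to_dict(self) -> dict[str, Any]:
        return {
            "document_id": self.document_id,
            "source": self.source,
            "sections": dict(self.sections),
            "available": self.available,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Document":
        return cls(
            document_id=d["document_id"],
            source=d["source"],
            sections=dict(d.get("sections", {})),
            available=d.get("available", True),
        )


@dataclass(frozen=True)
class RetryPolicy:
    """Capped exponential backoff: wait ``initial_wait * multiplier**(k-1)``
    seconds before retry ``k``, never more than ``max_wait``.

    Defaults (1 s initial, doubling, 60 s cap) reflect that the dominant
    failure mode of remote document providers is a temporarily unavailable
    endpoint: early retries are cheap, and the cap keeps a long outage from
    inflating delays unboundedly.  ``max_attempts = 7`` puts the cumulative
    wait (63 s) in the same regime as the cap before giving up.
    """

    initial_wait: float = 1.0
    multiplier: float = 2.0
    max_wait: float = 60.0
    max_attempts: int = 7

    def __post_init__(self) -> None:
        if self.initial_wait <= 0:
            raise ValueError("initial_wait must be > 0")
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if self.max_wait < self.initial_wait:
            raise ValueError("max_wait must be >= initial_wait")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


def backoff_delay(attempt: int, policy: RetryPolicy = RetryPolicy()) -> float:
    """Delay in seconds before retry number ``attempt`` (1-based).

    ``min(initial_wait * multiplier**(attempt - 1), max_wait)`` — a
    non-decreasing sequence saturating at ``max_wait``.
    """
    if attempt < 1:
        raise ValueError(f"attempt must be >= 1, got {attempt}")
    return min(policy.initial_wait * policy.multiplier ** (attempt - 1), policy.max_wait)


class CorpusAdapter(Protocol):
    """Adapter interface: bulk-resolve ids into documents, order-aligned."""

    name: str

    def fetch(self, ids: Sequence[str]) -> list[Document]:
        """One Document per id, ``output[i].document_id == ids[i]``.

        Unknown ids come back ``available = False``.  Transient transport
        failures raise :class:`RecoverableFetchError`; anything else is a
        programming error and propagates.
        """
        ...


def fetch_with_retry(
    ids: Sequence[str],
    adapter: CorpusAdapter,
    policy: RetryPolicy = RetryPolicy(),
    clock: Optional[Clock] = None,
) -> list[Document]:
    """Fetch a batch, retrying recoverable failures with capped backoff.

    After ``policy.max_attempts`` consecutive recoverable failures every id
    in the batch is marked unavailable (logged, not raised) and processing
    proceeds.  Non-recoverable exceptions propagate untouched.
    """
    if not ids:
        return []
    clock = clock if clock is not None else SystemClock()
    for attempt in range(1, policy.max_attempts + 1):
        try:
            docs = adapter.fetch(ids)
        except RecoverableFetchError as exc:
            if attempt == policy.max_attempts:
                log.warning(
                    "adapter %s exhausted %d attempts for %d ids; marking "
                    "unavailable: %s",
                    getattr(adapter, "name", "?"),
                    policy.max_attempts,
                    len(ids),
                    exc,
                )
                return [Document.unavailable(i, getattr(adapter, "name", "?")) for i in ids]
            delay = backoff_delay(attempt, policy)
            log.info(
                "adapter %s attempt %d failed (%s); retrying in %.0f s",
                getattr(adapter, "name", "?"),
                attempt,
                exc,
                delay,
            )
            clock.sleep(delay)
            continue
        if len(docs) != len(ids) or any(
            d.document_id != i for d, i in zip(docs, ids)
        ):
            raise RuntimeError(
                f"adapter {getattr(adapter, 'name', '?')} broke batch alignment"
            )
        for d in docs:
            if not d.available:
                log.info("document %s unavailable from %s", d.document_id, d.source)
        return docs
    raise AssertionError("unreachable")


class LocalCorpusAdapter:
    """Reads the local corpus format: JSON-lines (or one JSON per file),
    each record ``{"document_id", "source", "title", "abstract", "fulltext"}``.

    The entire corpus is indexed at construction; ids not present fetch as
    unavailable.
    """

    def __init__(self, path: str, name: str = "local"):
        self.name = name
        self._index: dict[str, Document] = {}
        if os.path.isdir(path):
            files = sorted(
                os.path.join(path, f)
                for f in os.listdir(path)
                if f.endswith((".json", ".jsonl"))
            )
        else:
            files = [path]
        for fp in files:
            with open(fp, encoding="utf-8") as fh:
                text = fh.read().strip()
            if not text:
                continue
            records = (
                [json.loads(line) for line in text.splitlines() if line.strip()]
                if fp.endswith(".jsonl") or "\n" in text
                else [json.loads(text)]
            )
            for rec in records:
                self._index[rec["document_id"]] = _record_to_document(rec, self.name)

    def __len__(self) -> int:
        return len(self._index)

    def document_ids(self) -> list[str]:
        return sorted(self._index)

    def fetch(self, ids: Sequence[str]) -> list[Document]:
        return [
            self._index.get(i, Document.unavailable(i, self.name)) for i in ids
        ]


def _record_to_document(rec: dict[str, Any], source: str) -> Document:
    sections: dict[str, str] = {}
    if rec.get("title"):
        sections["T"] = rec["title"]
    if rec.get("abstract"):
        sections["A"] = rec["abstract"]
    if rec.get("fulltext"):
        sections["F"] = rec["fulltext"]
    return Document(
        document_id=rec["document_id"],
        source=rec.get("source", source),
        sections=sections,
        available=True,
    )


class IdentityAdapter:
    """Returns document text carried inline in the request message itself.

    Used by the offline bulk mode: the pipeline is fed from a local
    collection without any external document provider.  ``fetch`` is only
    meaningful through :meth:`fetch_inline`, since identity documents never
    leave the message.
    """

    name = "identity"

    def fetch(self, ids: Sequence[str]) -> list[Document]:
        # No external store: ids alone carry no text.
        return [Document.unavailable(i, self.name) for i in ids]

    @staticmethod
    def fetch_inline(document_id: str, inline_sections: Optional[dict[str, str]]) -> Document:
        """Document whose sections equal the inline text verbatim."""
        if not inline_sections:
            return Document.unavailable(document_id, IdentityAdapter.name)
        return Document(
            document_id=document_id,
            source=IdentityAdapter.name,
            sections={k: v for k, v in inline_sections.items() if v},
            available=True,
        )


class ScriptedAdapter:
    """Test double: fails recoverably ``fail_times`` times, then delegates.

    ``fail_forever=True`` never succeeds (exercises retry exhaustion).
    """

    def __init__(
        self,
        inner: CorpusAdapter,
        fail_times: int = 0,
        fail_forever: bool = False,
        name: str = "mock-remote",
    ):
        self.name = name
        self._inner = inner
        self._fail_times = fail_times
        self._fail_forever = fail_forever
        self.calls = 0

    def fetch(self, ids: Sequence[str]) -> list[Document]:
        self.calls += 1
        if self._fail_forever or self.calls <= self._fail_times:
            raise RecoverableFetchError(
                f"scripted transient failure #{self.calls}"
            )
        docs = self._inner.fetch(ids)
        return [
            Document(
                document_id=d.document_id,
                source=self.name,
                sections=dict(d.sections),
                available=d.available,
            )
            if d.available
            else Document.unavailable(d.document_id, self.name)
            for d in docs
        ]
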