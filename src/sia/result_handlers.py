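"""Deliver aggregated annotation responses: HTTP post-back or local file.

Delivery sits behind the output queue with the same ack discipline as
every other stage: a response message is acknowledged only after the
handler succeeded (or exhausted its retries into a dead-letter log), so a
crash redelivers it.  Because the bus is at-least-once, handlers are
idempotent per communication id — redelivery has exactly-once *effect*.
"""

from __future__ import annotations

import json
import logging
import os
import threading
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Optional

from .annotators import Annotation
from .clock import Clock, SystemClock
from .corpus_adapters import RetryPolicy, backoff_delay

log = logging.getLogger(__name__)

#: logical field -> wire name for one annotation record; "init"/"end"
#: follow the task's response style and are remappable via configuration.
DEFAULT_RESULT_ALIASES = {
    "communication_id": "communication_id",
    "document_id": "document_id",
    "section": "section",
    "init": "init",
    "end": "end",
    "score": "score",
    "annotated_text": "annotated_text",
    "type": "type",
}


@dataclass(frozen=True)
class AnnotationResponse:
    """The aggregated result of one request: all annotations across all of
    its documents, sorted by (document_id, section, start, end), plus which
    requested types had no active annotator and which documents could not
    be fetched."""

    communication_id: str
    annotations: tuple[Annotation, ...]
    unserved_types: frozenset[str] = frozenset()
    unavailable_documents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(
                self.annotations,
                key=lambda a: (a.document_id, a.section, a.start, a.end),
            )
        )
        object.__setattr__(self, "annotations", ordered)

    def to_payload(self) -> dict[str, Any]:
        return {
            "kind": "response",
            "communication_id": self.communication_id,
            "annotations": [a.to_dict() for a in self.annotations],
            "unserved_types": sorted(self.unserved_types),
            "unavailable_documents": list(self.unavailable_documents),
        }

    @classmethod
    def from_payload(cls, payload: dict[str, Any]) -> "AnnotationResponse":
        return cls(
            communication_id=payload["communication_id"],
            annotations=tuple(
                Annotation.from_dict(a) for a in payload["annotations"]
            ),
            unserved_types=frozenset(payload.get("unserved_types", ())),
            unavailable_documents=tuple(payload.get("unavailable_documents", ())),
        )


def response_records(
    response: AnnotationResponse, aliases: Optional[dict[str, str]] = None
) -> list[dict[str, Any]]:
    """One JSON-ready record per annotation, in the task's response style."""
    a = dict(DEFAULT_RESULT_ALIASES)
    if aliases:
        a.update(aliases)
    return [
        {
            a["communication_id"]: response.communication_id,
            a["document_id"]: ann.document_id,
            a["section"]: ann.section,
            a["init"]: ann.start,
            a["end"]: ann.end,
            a["score"]: ann.score,
            a["annotated_text"]: ann.text,
            a["type"]: ann.type,
        }
        for ann in response.annotations
    ]


# ---------------------------------------------------------------------------
# HTTP post-back

class PermanentDeliveryError(RuntimeError):
    """4xx response: retrying cannot help; dead-letter the response."""


class TransientDeliveryError(RuntimeError):
    """5xx/timeout/connection failure: retry with backoff."""


Transport = Callable[[str, bytes], int]
"""POST ``body`` to ``url``; return the HTTP status code.  Connection-level
failures raise :class:`TransientDeliveryError`."""


def _urllib_transport(url: str, body: bytes) -> int:
    req = urllib.request.Request(
        url, data=body, headers={"Content-Type": "application/json"}, method="POST"
    )
    try:
        with urllib.request.urlopen(req, timeout=30) as resp:
            return resp.status
    except urllib.error.HTTPError as exc:
        return exc.code
    except (urllib.error.URLError, TimeoutError) as exc:
        raise TransientDeliveryError(str(exc)) from exc


@dataclass
class DeliveryStatus:
    status: str  # "delivered" | "dead_letter"
    attempts: int
    http_status: Optional[int] = None


def post_results(
    response: AnnotationResponse,
    endpoint: str,
    policy: RetryPolicy = RetryPolicy(),
    transport: Optional[Transport] = None,
    clock: Optional[Clock] = None,
    aliases: Optional[dict[str, str]] = None,
) -> DeliveryStatus:
    """POST the response to the callback endpoint with capped backoff.

    2xx → delivered.  4xx is permanent: one attempt, dead-lettered.
    5xx/timeouts are transient and retried under the same backoff contract
    as corpus fetching; exhaustion dead-letters with a log entry.
    """
    transport = transport if transport is not None else _urllib_transport
    clock = clock if clock is not None else SystemClock()
    body = json.dumps(
        {
            "communication_id": response.communication_id,
            "annotations": response_records(response, aliases),
        }
    ).encode()
    for attempt in range(1, policy.max_attempts + 1):
        try:
            status = transport(endpoint, body)
        except TransientDeliveryError as exc:
            status = None
            reason = str(exc)
        else:
            if 200 <= status < 300:
                return DeliveryStatus("delivered", attempts=attempt, http_status=status)
            if 400 <= status < 500:
                log.error(
                    "permanent delivery failure (%d) for %s; dead-lettered",
                    status,
                    response.communication_id,
                )
                return DeliveryStatus("dead_letter", attempts=attempt, http_status=status)
            reason = f"HTTP {status}"
        if attempt == policy.max_attempts:
            log.error(
                "delivery of %s exhausted %d attempts (%s); dead-lettered",
                response.communication_id,
                policy.max_attempts,
                reason,
            )
            return DeliveryStatus("dead_letter", attempts=attempt, http_status=status)
        clock.sleep(backoff_delay(attempt, policy))
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# file writer (offline mode)

class FileResultHandler:
    """Appends one JSON line per annotation to a local results file.

    Idempotent per communication id: a redelivered response whose id was
    already written changes nothing.  The already-written set is rebuilt
    from the file on construction, so idempotence survives a restart.
    """

    def __init__(self, path: str, aliases: Optional[dict[str, str]] = None):
        self.path = path
        self.aliases = dict(DEFAULT_RESULT_ALIASES)
        if aliases:
            self.aliases.update(aliases)
        self._lock = threading.Lock()
        self._written: set[str] = set()
        if os.path.exists(path):
            comm_field = self.aliases["communication_id"]
            with open(path, encoding="utf-8") as fh:
                for line in fh:
                    if line.strip():
                        self._written.add(json.loads(line)[comm_field])

    def write(self, response: AnnotationResponse) -> int:
        """Append the response's annotation records; return lines written."""
        with self._lock:
            if response.communication_id in self._written:
                return 0
            records = response_records(response, self.aliases)
            with open(self.path, "a", encoding="utf-8") as fh:
                for rec in records:
                    fh.write(json.dumps(rec, sort_keys=True) + "\n")
            self._written.add(response.communication_id)
            return len(records)


def write_results_file(
    response: AnnotationResponse, path: str, aliases: Optional[dict[str, str]] = None
) -> int:
    """One-shot convenience over :class:`FileResultHandler`."""
    return FileResultHandler(path, aliases).write(response)
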