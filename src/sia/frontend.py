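"""REST entry point: validation, deadline-derived priority, monitoring.

The frontend never touches the back end synchronously.  A valid request is
turned into one message on the input queue (a priority queue) and
acknowledged immediately; the back end may be offline, requests are simply
buffered as long as the bus has storage, otherwise new requests are denied
(backpressure).  Earlier deadlines get higher priority — already-running
work is never preempted, priority is only a fast path to the front of the
queue.

Wire field names are config-remappable through an alias table so the
server can match any dialect of the asynchronous annotation-task JSON
schema bit-exactly.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import math
import threading
from collections import Counter, deque
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Any, Optional

from .annotators import ENTITY_TYPES
from .clock import Clock, SystemClock
from .messaging import Message, MessageHeader, MessageBus, QueueFullError

log = logging.getLogger(__name__)

DEFAULT_INPUT_QUEUE = "q.request.in"

#: logical field -> wire name; override via configuration to match any
#: dialect of the task protocol.
DEFAULT_ALIASES = {
    "communication_id": "communication_id",
    "expiry": "expiry",
    "types": "types",
    "documents": "documents",
    "document_id": "document_id",
    "source": "source",
    "callback_url": "callback_url",
    "sections": "sections",
}


class ValidationFailure(ValueError):
    """Carries field-level error descriptions; nothing was enqueued."""

    def __init__(self, errors: list[dict[str, str]]):
        super().__init__("; ".join(e["message"] for e in errors))
        self.errors = errors


class BackpressureError(RuntimeError):
    """Input queue refused the request (storage exhausted)."""


@dataclass(frozen=True)
class DocumentRef:
    document_id: str
    source: str
    inline_sections: Optional[dict[str, str]] = None  # offline/identity mode


@dataclass(frozen=True)
class AnnotationRequest:
    """A validated client request, field-normalized.

    ``requested_types`` are upper-cased with duplicates removed; the
    document list is kept exactly as the caller sent it (duplicates
    preserved — the caller's list is authoritative).
    """

    communication_id: str
    documents: tuple[DocumentRef, ...]
    requested_types: frozenset[str]
    expiry_time: float
    callback_url: Optional[str] = None

    def to_payload(self) -> dict[str, Any]:
        return {
            "kind": "request",
            "communication_id": self.communication_id,
            "documents": [
                {
                    "document_id": d.document_id,
                    "source": d.source,
                    "sections": d.inline_sections,
                }
                for d in self.documents
            ],
            "requested_types": sorted(self.requested_types),
            "expiry_time": self.expiry_time,
            "callback_url": self.callback_url,
        }

    @classmethod
    def from_payload(cls, payload: dict[str, Any]) -> "AnnotationRequest":
        return cls(
            communication_id=payload["communication_id"],
            documents=tuple(
                DocumentRef(
                    document_id=d["document_id"],
                    source=d["source"],
                    inline_sections=d.get("sections"),
                )
                for d in payload["documents"]
            ),
            requested_types=frozenset(payload["requested_types"]),
            expiry_time=payload["expiry_time"],
            callback_url=payload.get("callback_url"),
        )


def _parse_expiry(value: Any) -> float:
    """Accept ISO-8601 strings (naive = UTC) or POSIX seconds."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        dt = _dt.datetime.fromisoformat(value.replace("Z", "+00:00"))
        if dt.tzinfo is None:
            dt = dt.replace(tzinfo=_dt.timezone.utc)
        return dt.timestamp()
    raise ValueError(f"unparseable expiry {value!r}")


def validate_request(
    raw: dict[str, Any],
    now: float,
    aliases: Optional[dict[str, str]] = None,
) -> AnnotationRequest:
    """Validate and normalize a raw JSON request document.

    Each defect yields a distinct error code echoed to the caller:
    ``missing_field``, ``invalid_field``, ``unknown_type``,
    ``empty_documents``, ``empty_types``, ``past_expiry``.  On failure a
    :class:`ValidationFailure` with the full error list is raised and
    nothing is enqueued.
    """
    a = dict(DEFAULT_ALIASES)
    if aliases:
        a.update(aliases)
    errors: list[dict[str, str]] = []

    def err(code: str, fieldname: str, message: str) -> None:
        errors.append({"code": code, "field": fieldname, "message": message})

    comm_id = raw.get(a["communication_id"])
    if not isinstance(comm_id, str) or not comm_id:
        err("missing_field", a["communication_id"], "communication id is required")

    expiry_raw = raw.get(a["expiry"])
    expiry_time: Optional[float] = None
    if expiry_raw is None:
        err("missing_field", a["expiry"], "expiry is required")
    else:
        try:
            expiry_time = _parse_expiry(expiry_raw)
        except ValueError:
            err("invalid_field", a["expiry"], f"unparseable expiry {expiry_raw!r}")
    if expiry_time is not None and expiry_time <= now:
        err("past_expiry", a["expiry"], "expiry must be strictly in the future")

    types_raw = raw.get(a["types"])
    requested: frozenset[str] = frozenset()
    if types_raw is None:
        err("missing_field", a["types"], "entity types are required")
    elif not isinstance(types_raw, (list, tuple)) or not types_raw:
        err("empty_types", a["types"], "entity type list must be non-empty")
    else:
        normalized = {str(t).upper() for t in types_raw}
        unknown = sorted(normalized - ENTITY_TYPES)
        for t in unknown:
            err("unknown_type", a["types"], f"unknown entity type {t!r}")
        requested = frozenset(normalized & ENTITY_TYPES)

    docs_raw = raw.get(a["documents"])
    documents: list[DocumentRef] = []
    if docs_raw is None:
        err("missing_field", a["documents"], "document list is required")
    elif not isinstance(docs_raw, (list, tuple)) or not docs_raw:
        err("empty_documents", a["documents"], "document list must be non-empty")
    else:
        for i, d in enumerate(docs_raw):
            if not isinstance(d, dict) or not d.get(a["document_id"]):
                err("invalid_field", a["documents"], f"document #{i} lacks an id")
                continue
            documents.append(
                DocumentRef(
                    document_id=str(d[a["document_id"]]),
                    source=str(d.get(a["source"], "unknown")),
                    inline_sections=d.get(a["sections"]),
                )
            )

    if errors:
        raise ValidationFailure(errors)
    assert expiry_time is not None and comm_id is not None
    return AnnotationRequest(
        communication_id=comm_id,
        documents=tuple(documents),
        requested_types=requested,
        expiry_time=expiry_time,
        callback_url=raw.get(a["callback_url"]),
    )


# ---------------------------------------------------------------------------
# statistics

@dataclass
class ProcessingStats:
    """Monitoring counters plus an EMA of completed request durations.

    The EMA (smoothing 0.2, initialized at 1 s before any completion) is
    the system's running estimate of how long one request takes; the
    priority computation quantizes deadline slack in units of it.
    """

    accepted_count: int = 0
    rejected_count: int = 0
    completed_count: int = 0
    ema_processing_seconds: float = 1.0
    ema_alpha: float = 0.2
    _accept_times: deque = field(default_factory=deque, repr=False)
    _recent_sources: deque = field(default_factory=lambda: deque(maxlen=100), repr=False)
    _has_completion: bool = False

    def record_accepted(self, sources: list[str], now: float) -> None:
        self.accepted_count += 1
        self._accept_times.append(now)
        self._recent_sources.extend(sources)

    def record_rejected(self) -> None:
        self.rejected_count += 1

    def record_completed(self, duration_seconds: float) -> None:
        self.completed_count += 1
        self.ema_processing_seconds += self.ema_alpha * (
            duration_seconds - self.ema_processing_seconds
        )
        self._has_completion = True

    def request_rate(self, now: float) -> float:
        """Accepted requests in the rolling last minute."""
        while self._accept_times and self._accept_times[0] < now - 60.0:
            self._accept_times.popleft()
        return float(len(self._accept_times))

    def snapshot(self, now: float) -> dict[str, Any]:
        return {
            "accepted_count": self.accepted_count,
            "rejected_count": self.rejected_count,
            "completed_count": self.completed_count,
            "request_rate_per_minute": self.request_rate(now),
            "recent_sources": dict(Counter(self._recent_sources)),
            "ema_processing_seconds": self.ema_processing_seconds,
        }


def compute_priority(
    expiry_time: float, now: float, stats: Optional[ProcessingStats] = None
) -> int:
    """Map deadline slack to a 0-9 queue priority (9 = most urgent).

    ``clamp(9 - floor(slack / ema), 0, 9)`` where ``slack`` is seconds
    until expiry and ``ema`` the running mean processing time: a request
    whose slack is worth fewer completed-request-units is more urgent.
    Monotone — smaller slack never yields lower priority.  Non-positive
    slack should have been rejected upstream; defensively returns 9.
    """
    ema = stats.ema_processing_seconds if stats is not None else 1.0
    slack = expiry_time - now
    if slack <= 0:
        return 9
    return max(0, min(9, 9 - math.floor(slack / max(ema, 1e-9))))


# ---------------------------------------------------------------------------
# frontend service

class Frontend:
    """Validates, prioritizes and enqueues requests; serves monitoring."""

    def __init__(
        self,
        bus: MessageBus,
        clock: Optional[Clock] = None,
        input_queue: str = DEFAULT_INPUT_QUEUE,
        aliases: Optional[dict[str, str]] = None,
        bearer_token: Optional[str] = None,
    ):
        self.bus = bus
        self.clock = clock if clock is not None else SystemClock()
        self.input_queue = input_queue
        self.aliases = aliases
        self.bearer_token = bearer_token
        self.stats = ProcessingStats()
        self._lock = threading.Lock()
        self._accept_time_by_id: dict[str, float] = {}
        bus.declare_queue(input_queue)

    def accept(self, request: AnnotationRequest) -> dict[str, str]:
        """Enqueue one validated request; acknowledge immediately.

        Raises :class:`BackpressureError` when the bus refuses the publish.
        """
        now = self.clock.now()
        with self._lock:
            priority = compute_priority(request.expiry_time, now, self.stats)
            header = MessageHeader(
                communication_id=request.communication_id,
                expiry_time=request.expiry_time,
                requested_types=request.requested_types,
                priority=priority,
            )
            try:
                self.bus.publish(self.input_queue, Message(header, request.to_payload()))
            except QueueFullError as exc:
                self.stats.record_rejected()
                raise BackpressureError(str(exc)) from exc
            self.stats.record_accepted([d.source for d in request.documents], now)
            self._accept_time_by_id[request.communication_id] = now
        return {"communication_id": request.communication_id, "status": "accepted"}

    def handle_annotate(self, raw: dict[str, Any]) -> dict[str, str]:
        """Validate + accept in one step (the POST /annotate body)."""
        try:
            request = validate_request(raw, now=self.clock.now(), aliases=self.aliases)
        except ValidationFailure:
            with self._lock:
                self.stats.record_rejected()
            raise
        return self.accept(request)

    def record_completion(self, communication_id: str) -> None:
        """Called by the result stage when a request's response is delivered."""
        now = self.clock.now()
        with self._lock:
            accepted_at = self._accept_time_by_id.pop(communication_id, None)
            duration = (now - accepted_at) if accepted_at is not None else 0.0
            self.stats.record_completed(max(duration, 1e-9))

    def monitoring_snapshot(self) -> dict[str, Any]:
        with self._lock:
            return self.stats.snapshot(self.clock.now())


# ---------------------------------------------------------------------------
# thin stdlib HTTP layer

class _Handler(BaseHTTPRequestHandler):
    frontend: Frontend  # set by build_http_server

    def _send(self, status: int, body: dict[str, Any]) -> None:
        data = json.dumps(body).encode()
        self.send_response(status)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(data)))
        self.end_headers()
        self.wfile.write(data)

    def _authorized(self) -> bool:
        token = self.frontend.bearer_token
        if token is None:
            return True
        return self.headers.get("Authorization") == f"Bearer {token}"

    def do_GET(self) -> None:  # noqa: N802 (stdlib naming)
        if self.path.rstrip("/") == "/status":
            self._send(200, self.frontend.monitoring_snapshot())
        else:
            self._send(404, {"error": "not found"})

    def do_POST(self) -> None:  # noqa: N802
        if self.path.rstrip("/") != "/annotate":
            self._send(404, {"error": "not found"})
            return
        if not self._authorized():
            self._send(401, {"error": "unauthorized"})
            return
        length = int(self.headers.get("Content-Length", "0"))
        try:
            raw = json.loads(self.rfile.read(length) or b"{}")
        except json.JSONDecodeError:
            self._send(400, {"errors": [{"code": "invalid_json", "field": "",
                                         "message": "body is not valid JSON"}]})
            return
        try:
            ack = self.frontend.handle_annotate(raw)
        except ValidationFailure as exc:
            self._send(400, {"errors": exc.errors})
            return
        except BackpressureError:
            self._send(503, {"error": "retry-later", "reason": "storage exhausted"})
            return
        self._send(202, ack)

    def log_message(self, fmt: str, *args: Any) -> None:
        log.debug("http: " + fmt, *args)


def build_http_server(
    frontend: Frontend, host: str = "127.0.0.1", port: int = 8080
) -> ThreadingHTTPServer:
    """HTTP server exposing POST /annotate and GET /status."""
    handler = type("BoundHandler", (_Handler,), {"frontend": frontend})
    return ThreadingHTTPServer((host, port), handler)
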