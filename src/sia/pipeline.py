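"""The back-end message flow: split → fetch → scatter → gather → aggregate.

Every arrow is a queue hop with acknowledge-on-success semantics:

1. A request message is split into one message per document id, each
   stamped with ``total_documents``.
2. Each document's text is fetched through a corpus adapter (with retry),
   then *scattered*: duplicated onto the input queue of every active
   annotator serving a requested type, stamped with ``total_annotators``.
3. Annotator workers consume, tag, and emit per-annotator annotation
   parts.
4. The gather/aggregate stage collects parts until a document is complete
   (``total_annotators`` parts) and a request is complete
   (``total_documents`` documents) — the inverse of the split — then emits
   one response message.  Overlapping annotations from different
   annotators are all retained, unmodified.

Completeness is tracked by the counts stamped at split/scatter time, so no
shared database is needed.  The aggregate stage acknowledges part messages
only after the response is published: a crash leaves them unacknowledged
in the bus journal, and replay rebuilds the partial aggregation (part
deduplication by annotator identity makes the rebuild idempotent).
Partial aggregations whose deadline passes are dropped and logged,
mirroring message TTL on the bus.
"""

from __future__ import annotations

import logging
import threading
import time as _time
from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

from .annotators import Annotation, AnnotatorRegistry, Annotator, safe_annotate
from .clock import Clock, SystemClock
from .corpus_adapters import (
    CorpusAdapter,
    Document,
    IdentityAdapter,
    RetryPolicy,
    fetch_with_retry,
)
from .frontend import AnnotationRequest, Frontend
from .messaging import Delivery, Message, MessageBus, MessageHeader
from .result_handlers import AnnotationResponse

log = logging.getLogger(__name__)

PASSTHROUGH_ANNOTATOR = "__passthrough__"


@dataclass(frozen=True)
class QueueConfig:
    """Names of the pipeline's internal queues (prefix-configurable)."""

    request_in: str = "q.request.in"
    document_fetch: str = "q.document.fetch"
    document_gathered: str = "q.document.gathered"
    response_out: str = "q.response.out"
    annotator_prefix: str = "q.annotator."

    @classmethod
    def with_prefix(cls, prefix: str) -> "QueueConfig":
        return cls(
            request_in=f"{prefix}request.in",
            document_fetch=f"{prefix}document.fetch",
            document_gathered=f"{prefix}document.gathered",
            response_out=f"{prefix}response.out",
            annotator_prefix=f"{prefix}annotator.",
        )


# ---------------------------------------------------------------------------
# pure message transformations

def split_request(msg: Message) -> list[Message]:
    """One message per document reference, ``total_documents`` stamped.

    Duplicated ids are preserved — the request's list is authoritative.
    """
    request = AnnotationRequest.from_payload(msg.payload)
    total = len(request.documents)
    out = []
    for ref in request.documents:
        header = MessageHeader(
            communication_id=msg.header.communication_id,
            expiry_time=msg.header.expiry_time,
            requested_types=msg.header.requested_types,
            priority=msg.header.priority,
            total_documents=total,
        )
        payload = {
            "kind": "docref",
            "document_id": ref.document_id,
            "source": ref.source,
            "sections": ref.inline_sections,
        }
        out.append(Message(header, payload))
    return out


def scatter(
    msg: Message,
    document: Document,
    registry: AnnotatorRegistry,
    gathered_queue: str,
) -> list[tuple[str, Message]]:
    """Duplicate a fetched document to every qualified annotator queue.

    One duplicate per distinct *active* queue serving any requested type
    (per-queue, not per-type); the header is stamped with
    ``total_annotators`` and any unserved types.  With zero active
    annotators a single pass-through part with an empty annotation set is
    routed straight to the gather queue so aggregation still completes.
    """
    queues, unserved = registry.resolve_queues(msg.header.requested_types)
    targets = sorted(queues)
    total = max(len(targets), 1)
    header = MessageHeader(
        communication_id=msg.header.communication_id,
        expiry_time=msg.header.expiry_time,
        requested_types=msg.header.requested_types,
        priority=msg.header.priority,
        total_documents=msg.header.total_documents,
        total_annotators=total,
        unserved_types=frozenset(unserved),
    )
    if not targets:
        part = {
            "kind": "part",
            "document_id": document.document_id,
            "annotator": PASSTHROUGH_ANNOTATOR,
            "annotations": [],
            "available": document.available,
        }
        return [(gathered_queue, Message(header, part))]
    payload = {"kind": "doc_task", "document": document.to_dict()}
    return [(queue, Message(header, payload)) for queue in targets]


def annotate_document(
    annotator: Annotator, document: Document
) -> list[Annotation]:
    """Run one annotator over every section of a document (crash-isolated)."""
    annotations: list[Annotation] = []
    for section in sorted(document.sections):
        text = document.sections[section]
        annotations.extend(
            safe_annotate(annotator, text, section, document.document_id)
        )
    return annotations


# ---------------------------------------------------------------------------
# gather/aggregate state

@dataclass
class _DocState:
    total_annotators: int
    parts: dict[str, list[Annotation]] = field(default_factory=dict)
    available: bool = True

    @property
    def complete(self) -> bool:
        return len(self.parts) >= self.total_annotators


@dataclass
class _RequestState:
    expiry_time: float
    priority: int
    requested_types: frozenset[str]
    total_documents: int
    docs: dict[str, _DocState] = field(default_factory=dict)
    completed_docs: set = field(default_factory=set)
    unserved_types: set = field(default_factory=set)
    held_tags: list[int] = field(default_factory=list)


class Aggregator:
    """Collects annotation parts into per-document gathers and per-request
    aggregates, emitting exactly one response per complete request.

    Thread-safe; duplicate parts (redelivery) are idempotent, keyed on
    (communication id, document id, annotator identity).
    """

    def __init__(self) -> None:
        self._lock = threading.RLock()
        self._pending: dict[str, _RequestState] = {}
        self._emitted: set[str] = set()

    def pending_count(self) -> int:
        with self._lock:
            return len(self._pending)

    def offer(
        self, delivery: Delivery
    ) -> tuple[Optional[Message], list[int]]:
        """Feed one part message; returns (response message or None, tags
        safe to acknowledge now).

        Tags of parts belonging to incomplete requests are *held* — they
        are only released for acknowledgement together with the response,
        so unacknowledged parts persist in the journal until the request's
        result is on the output queue.
        """
        msg = delivery.message
        payload = msg.payload
        comm_id = msg.header.communication_id
        with self._lock:
            if comm_id in self._emitted:
                # redelivered remnant of an already-emitted response
                return None, [delivery.tag]
            state = self._pending.get(comm_id)
            if state is None:
                state = _RequestState(
                    expiry_time=msg.header.expiry_time,
                    priority=msg.header.priority,
                    requested_types=msg.header.requested_types,
                    total_documents=msg.header.total_documents or 1,
                )
                self._pending[comm_id] = state
            state.unserved_types.update(msg.header.unserved_types)

            doc_id = payload["document_id"]
            doc = state.docs.get(doc_id)
            if doc is None:
                doc = _DocState(total_annotators=msg.header.total_annotators or 1)
                state.docs[doc_id] = doc
            annotator = payload["annotator"]
            if annotator in doc.parts:
                log.debug(
                    "duplicate part (%s, %s, %s) ignored", comm_id, doc_id, annotator
                )
                return None, [delivery.tag]
            doc.parts[annotator] = [
                Annotation.from_dict(a) for a in payload["annotations"]
            ]
            doc.available = doc.available and payload.get("available", True)
            state.held_tags.append(delivery.tag)

            if doc.complete:
                state.completed_docs.add(doc_id)
            if len(state.completed_docs) < state.total_documents:
                return None, []

            # request complete: aggregate (the inverse of the split)
            annotations: list[Annotation] = []
            unavailable: list[str] = []
            for d_id in sorted(state.docs):
                d = state.docs[d_id]
                for part in d.parts.values():
                    annotations.extend(part)
                if not d.available:
                    unavailable.append(d_id)
            response = AnnotationResponse(
                communication_id=comm_id,
                annotations=tuple(annotations),
                unserved_types=frozenset(state.unserved_types),
                unavailable_documents=tuple(unavailable),
            )
            header = MessageHeader(
                communication_id=comm_id,
                expiry_time=state.expiry_time,
                requested_types=state.requested_types,
                priority=state.priority,
                total_documents=state.total_documents,
                unserved_types=frozenset(state.unserved_types),
            )
            tags = list(state.held_tags)
            del self._pending[comm_id]
            self._emitted.add(comm_id)
            return Message(header, response.to_payload()), tags

    def drop_expired(self, now: float) -> list[int]:
        """Discard partial aggregations past their deadline; returns the
        held tags to acknowledge away.  Consistent with bus-level TTL: an
        expired request yields no (partial) response, only a log entry."""
        with self._lock:
            tags: list[int] = []
            for comm_id in [
                c for c, s in self._pending.items() if s.expiry_time <= now
            ]:
                state = self._pending.pop(comm_id)
                tags.extend(state.held_tags)
                log.warning(
                    "request %s expired with %d/%d documents aggregated; "
                    "partial state dropped",
                    comm_id,
                    len(state.completed_docs),
                    state.total_documents,
                )
            return tags


# ---------------------------------------------------------------------------
# stages

class Stage:
    """One pipeline worker step: consume at most one message, process, ack."""

    name = "stage"

    def step(self) -> bool:
        """Process one message if available; True iff something was done."""
        raise NotImplementedError


class SplitStage(Stage):
    name = "split"

    def __init__(self, bus: MessageBus, queues: QueueConfig, clock: Clock):
        self.bus, self.queues, self.clock = bus, queues, clock

    def step(self) -> bool:
        delivery = self.bus.consume(self.queues.request_in, now=self.clock.now())
        if delivery is None:
            return False
        for part in split_request(delivery.message):
            self.bus.publish(self.queues.document_fetch, part)
        self.bus.ack(delivery.tag)
        return True


class FetchScatterStage(Stage):
    """Fetch one document's text, then scatter it to annotator queues."""

    name = "fetch"

    def __init__(
        self,
        bus: MessageBus,
        queues: QueueConfig,
        registry: AnnotatorRegistry,
        adapters: dict[str, CorpusAdapter],
        policy: RetryPolicy,
        clock: Clock,
    ):
        self.bus, self.queues, self.clock = bus, queues, clock
        self.registry = registry
        self.adapters = adapters
        self.policy = policy

    def _fetch(self, payload: dict[str, Any]) -> Document:
        doc_id = payload["document_id"]
        source = payload["source"]
        if payload.get("sections"):
            return IdentityAdapter.fetch_inline(doc_id, payload["sections"])
        adapter = self.adapters.get(source)
        if adapter is None:
            log.warning("no corpus adapter for source %r; %s unavailable", source, doc_id)
            return Document.unavailable(doc_id, source)
        return fetch_with_retry([doc_id], adapter, self.policy, self.clock)[0]

    def step(self) -> bool:
        delivery = self.bus.consume(self.queues.document_fetch, now=self.clock.now())
        if delivery is None:
            return False
        document = self._fetch(delivery.message.payload)
        for queue, message in scatter(
            delivery.message, document, self.registry, self.queues.document_gathered
        ):
            self.bus.publish(queue, message)
        self.bus.ack(delivery.tag)
        return True


class AnnotateStage(Stage):
    """Consume from one annotator's input queue, tag, emit a part message."""

    def __init__(
        self,
        bus: MessageBus,
        queue: str,
        annotator: Annotator,
        queues: QueueConfig,
        clock: Clock,
    ):
        self.bus, self.queue, self.annotator = bus, queue, annotator
        self.queues, self.clock = queues, clock
        self.name = f"annotate:{annotator.name}"

    def step(self) -> bool:
        delivery = self.bus.consume(self.queue, now=self.clock.now())
        if delivery is None:
            return False
        document = Document.from_dict(delivery.message.payload["document"])
        annotations = annotate_document(self.annotator, document)
        part = {
            "kind": "part",
            "document_id": document.document_id,
            "annotator": self.annotator.name,
            "annotations": [a.to_dict() for a in annotations],
            "available": document.available,
        }
        self.bus.publish(
            self.queues.document_gathered, Message(delivery.message.header, part)
        )
        self.bus.ack(delivery.tag)
        return True


class GatherAggregateStage(Stage):
    name = "aggregate"

    def __init__(
        self, bus: MessageBus, queues: QueueConfig, aggregator: Aggregator, clock: Clock
    ):
        self.bus, self.queues, self.clock = bus, queues, clock
        self.aggregator = aggregator

    def step(self) -> bool:
        delivery = self.bus.consume(self.queues.document_gathered, now=self.clock.now())
        if delivery is None:
            return False
        response_msg, tags = self.aggregator.offer(delivery)
        if response_msg is not None:
            self.bus.publish(self.queues.response_out, response_msg)
        for tag in tags:
            self.bus.ack(tag)
        return True


ResponseHandler = Callable[[AnnotationResponse], None]


class ResultStage(Stage):
    """Hand completed responses to the configured result handlers.

    A handler exception leaves the message unacknowledged (it will be
    redelivered); handlers are idempotent per communication id.
    """

    name = "result"

    def __init__(
        self,
        bus: MessageBus,
        queues: QueueConfig,
        handlers: Sequence[ResponseHandler],
        clock: Clock,
        completion_listener: Optional[Callable[[str], None]] = None,
    ):
        self.bus, self.queues, self.clock = bus, queues, clock
        self.handlers = list(handlers)
        self.completion_listener = completion_listener
        self.completed_order: list[str] = []
        self._lock = threading.Lock()

    def step(self) -> bool:
        delivery = self.bus.consume(self.queues.response_out, now=self.clock.now())
        if delivery is None:
            return False
        response = AnnotationResponse.from_payload(delivery.message.payload)
        for handler in self.handlers:
            handler(response)  # raise → no ack → redelivery
        self.bus.ack(delivery.tag)
        with self._lock:
            self.completed_order.append(response.communication_id)
        if self.completion_listener is not None:
            self.completion_listener(response.communication_id)
        return True


# ---------------------------------------------------------------------------
# engine

class PipelineEngine:
    """Runs stages downstream-first: each step services the furthest-along
    message available, so an urgent request admitted by the priority queue
    drains through the whole pipeline before the next buffered request is
    even split."""

    def __init__(self, stages: Sequence[Stage], aggregator: Aggregator, bus: MessageBus, clock: Clock):
        self.stages = list(stages)
        self.aggregator = aggregator
        self.bus = bus
        self.clock = clock

    def step(self) -> bool:
        for stage in self.stages:
            if stage.step():
                return True
        return False

    def run_until_idle(self, max_steps: Optional[int] = None) -> int:
        """Single-threaded drain; returns the number of steps taken."""
        steps = 0
        while max_steps is None or steps < max_steps:
            if not self.step():
                for tag in self.aggregator.drop_expired(self.clock.now()):
                    self.bus.ack(tag)
                if not self.step():
                    break
            steps += 1
        return steps


class Backend:
    """Wires bus, registry, annotators, adapters and handlers into a
    runnable back end; supports 1..k parallel workers over one bus."""

    def __init__(
        self,
        bus: MessageBus,
        registry: AnnotatorRegistry,
        annotators: dict[str, Annotator],
        adapters: Optional[dict[str, CorpusAdapter]] = None,
        result_handlers: Sequence[ResponseHandler] = (),
        queues: Optional[QueueConfig] = None,
        retry_policy: Optional[RetryPolicy] = None,
        clock: Optional[Clock] = None,
        frontend: Optional[Frontend] = None,
    ):
        self.bus = bus
        self.registry = registry
        self.annotators = annotators
        self.adapters = adapters or {}
        self.result_handlers = list(result_handlers)
        self.queues = queues or QueueConfig()
        self.retry_policy = retry_policy or RetryPolicy()
        self.clock = clock if clock is not None else SystemClock()
        self.frontend = frontend
        self.aggregator = Aggregator()
        self.result_stage: Optional[ResultStage] = None
        for q in (
            self.queues.request_in,
            self.queues.document_fetch,
            self.queues.document_gathered,
            self.queues.response_out,
        ):
            bus.declare_queue(q)
        for entry_type in registry.types():
            entry = registry.entry(entry_type)
            assert entry is not None
            bus.declare_queue(entry.queue)

    def make_engine(self) -> PipelineEngine:
        """A fresh stage chain (downstream-first order) over the shared bus."""
        completion = (
            self.frontend.record_completion if self.frontend is not None else None
        )
        result_stage = ResultStage(
            self.bus, self.queues, self.result_handlers, self.clock, completion
        )
        if self.result_stage is None:
            self.result_stage = result_stage
        annotate_stages: list[Stage] = []
        seen_queues: set[str] = set()
        for entity_type in self.registry.types():
            entry = self.registry.entry(entity_type)
            assert entry is not None
            if entry.queue in seen_queues:
                continue
            seen_queues.add(entry.queue)
            annotator = self.annotators.get(entry.annotator)
            if annotator is None:
                continue
            annotate_stages.append(
                AnnotateStage(self.bus, entry.queue, annotator, self.queues, self.clock)
            )
        stages: list[Stage] = [
            result_stage,
            GatherAggregateStage(self.bus, self.queues, self.aggregator, self.clock),
            *annotate_stages,
            FetchScatterStage(
                self.bus,
                self.queues,
                self.registry,
                self.adapters,
                self.retry_policy,
                self.clock,
            ),
            SplitStage(self.bus, self.queues, self.clock),
        ]
        return PipelineEngine(stages, self.aggregator, self.bus, self.clock)

    def run(self, parallelism: int = 1, timeout: Optional[float] = None) -> None:
        """Drain all queued work with ``parallelism`` concurrent workers.

        The parallelism controls how many messages are consumed from the
        queues simultaneously; the response annotation multiset is
        invariant to it.
        """
        if parallelism < 1:
            raise ValueError("parallelism must be >= 1")
        if parallelism == 1:
            self.make_engine().run_until_idle()
            return
        stop = threading.Event()
        errors: list[BaseException] = []
        deadline = None if timeout is None else _time.monotonic() + timeout

        def worker() -> None:
            engine = self.make_engine()
            try:
                while not stop.is_set():
                    if engine.step():
                        continue
                    for tag in self.aggregator.drop_expired(self.clock.now()):
                        self.bus.ack(tag)
                    if self.bus.is_idle():
                        stop.set()
                        break
                    if deadline is not None and _time.monotonic() > deadline:
                        stop.set()
                        break
                    _time.sleep(0.001)
            except BaseException as exc:  # surface worker failures to caller
                errors.append(exc)
                stop.set()

        threads = [threading.Thread(target=worker) for _ in range(parallelism)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        if errors:
            raise errors[0]
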