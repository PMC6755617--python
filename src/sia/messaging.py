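"""Broker-agnostic durable priority-queue message bus.

Every hop in the annotation pipeline is a named queue on this bus.  The
contract is deliberately small and matches what mainstream brokers offer:

* ``publish`` — durably enqueue; among ready messages, consumption order is
  priority-descending with FIFO tie-break.
* ``consume`` — deliver one message and mark it in-flight (invisible to
  other consumers) until it is acknowledged or the consumer disappears.
* ``ack`` — remove permanently; unacknowledged deliveries are replayed on
  recovery with an incremented delivery count (at-least-once semantics;
  downstream consumers must be idempotent).
* ``purge_expired`` — messages carry an absolute expiry timestamp (TTL);
  an expired message is never delivered.

The default backend is in-process and journaled: an append-only
newline-delimited-JSON file records ``pub``/``consume``/``ack``/``drop``
events, and :meth:`MessageBus.open_journal` replays it to reconstruct queue
state after a crash.  The contract above, not the storage, is normative; an
external broker could back the same interface.
"""

from __future__ import annotations

import heapq
import itertools
import json
import logging
import os
import threading
from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Optional

log = logging.getLogger(__name__)

__all__ = [
    "MessageHeader",
    "Message",
    "Delivery",
    "MessageBus",
    "SerializationError",
    "UnknownQueueError",
    "QueueFullError",
]


class SerializationError(ValueError):
    """Payload or header cannot be serialized to JSON."""


class UnknownQueueError(KeyError):
    """Consume from a queue that was never declared or published to.

    Distinct from an *empty* queue, which yields ``None`` — this error
    signals a misconfigured queue name.
    """


class QueueFullError(RuntimeError):
    """Bus storage exhausted; publish refused (backpressure signal)."""


@dataclass(frozen=True)
class MessageHeader:
    """Routing and correlation metadata carried by every message.

    ``communication_id`` correlates a request with its response across all
    pipeline stages.  ``expiry_time`` is an absolute POSIX timestamp (UTC);
    the bus drops messages past it.  ``priority`` is 0–9 with 9 most
    urgent.  ``total_documents`` / ``total_annotators`` are completeness
    counts stamped by the split and scatter steps so the gather and
    aggregate steps know when a request is complete without shared state.
    """

    communication_id: str
    expiry_time: float
    requested_types: frozenset[str] = frozenset()
    priority: int = 0
    delivery_count: int = 0
    total_documents: Optional[int] = None
    total_annotators: Optional[int] = None
    unserved_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 <= self.priority <= 9:
            raise ValueError(f"priority must be in [0, 9], got {self.priority}")
        if self.delivery_count < 0:
            raise ValueError("delivery_count must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        return {
            "communication_id": self.communication_id,
            "expiry_time": self.expiry_time,
            "requested_types": sorted(self.requested_types),
            "priority": self.priority,
            "delivery_count": self.delivery_count,
            "total_documents": self.total_documents,
            "total_annotators": self.total_annotators,
            "unserved_types": sorted(self.unserved_types),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MessageHeader":
        return cls(
            communication_id=d["communication_id"],
            expiry_time=d["expiry_time"],
            requested_types=frozenset(d.get("requested_types", ())),
            priority=d.get("priority", 0),
            delivery_count=d.get("delivery_count", 0),
            total_documents=d.get("total_documents"),
            total_annotators=d.get("total_annotators"),
            unserved_types=frozenset(d.get("unserved_types", ())),
        )


@dataclass(frozen=True)
class Message:
    """Unit of transport: header (routing/meta) + structured payload.

    The payload must be JSON-serializable; it round-trips losslessly
    through the journal (serialize∘deserialize = identity).
    """

    header: MessageHeader
    payload: Any

    def to_dict(self) -> dict[str, Any]:
        return {"header": self.header.to_dict(), "payload": self.payload}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Message":
        return cls(header=MessageHeader.from_dict(d["header"]), payload=d["payload"])


@dataclass(frozen=True)
class Delivery:
    """One in-flight delivery: the message plus the tag to ack it with."""

    message: Message
    tag: int
    queue: str


@dataclass
class _Entry:
    msg_id: int
    queue: str
    message: Message
    seq: int  # global FIFO sequence for equal-priority tie-break


class MessageBus:
    """In-process durable message bus with priority queues.

    Parameters
    ----------
    journal_path:
        If given, every state change is appended to this newline-delimited
        JSON file and fsync'd on publish/ack, so the bus survives a crash.
        ``None`` keeps state in memory only (tests, throwaway runs).
    max_depth:
        Total ready+in-flight message cap across all queues; publishing
        beyond it raises :class:`QueueFullError` so the frontend can deny
        new requests instead of overloading storage.
    """

    def __init__(self, journal_path: Optional[str] = None, max_depth: int = 1_000_000):
        self._lock = threading.RLock()
        self._journal_path = journal_path
        self._journal_file = None
        self._max_depth = max_depth
        self._queues: dict[str, list[tuple[int, int, int]]] = {}
        self._entries: dict[int, _Entry] = {}
        self._in_flight: dict[int, int] = {}  # tag -> msg_id
        self._acked_tags: set[int] = set()
        self._ids = itertools.count(1)
        self._seqs = itertools.count(1)
        self._tags = itertools.count(1)
        if journal_path is not None:
            self._journal_file = open(journal_path, "a", encoding="utf-8")

    # ------------------------------------------------------------------
    # journal

    def _journal(self, record: dict[str, Any]) -> None:
        if self._journal_file is None:
            return
        self._journal_file.write(json.dumps(record, separators=(",", ":")) + "\n")
        self._journal_file.flush()
        os.fsync(self._journal_file.fileno())

    @classmethod
    def open_journal(cls, journal_path: str, max_depth: int = 1_000_000) -> "MessageBus":
        """Rebuild bus state by replaying a journal (crash recovery).

        Messages published but not acked reappear as ready, with
        ``delivery_count`` equal to the number of journaled deliveries —
        each unacknowledged consume counts as one redelivery.
        """
        pending: dict[int, dict[str, Any]] = {}
        order: list[int] = []
        consume_counts: dict[int, int] = {}
        known_queues: set[str] = set()
        if os.path.exists(journal_path):
            with open(journal_path, encoding="utf-8") as fh:
                for line in fh:
                    line = line.strip()
                    if not line:
                        continue
                    rec = json.loads(line)
                    op = rec["op"]
                    if op == "pub":
                        pending[rec["id"]] = rec
                        order.append(rec["id"])
                        known_queues.add(rec["queue"])
                    elif op == "declare":
                        known_queues.add(rec["queue"])
                    elif op == "consume":
                        consume_counts[rec["id"]] = consume_counts.get(rec["id"], 0) + 1
                    elif op in ("ack", "drop"):
                        pending.pop(rec["id"], None)
        # Start a fresh journal generation: truncate and re-journal survivors
        # so the file does not grow without bound across restarts.
        with open(journal_path, "w", encoding="utf-8"):
            pass
        bus = cls(journal_path=journal_path, max_depth=max_depth)
        for queue in sorted(known_queues):
            bus.declare_queue(queue)
        for msg_id in order:
            rec = pending.get(msg_id)
            if rec is None:
                continue
            message = Message.from_dict(rec["message"])
            redeliveries = consume_counts.get(msg_id, 0)
            if redeliveries:
                message = Message(
                    header=replace(
                        message.header,
                        delivery_count=message.header.delivery_count + redeliveries,
                    ),
                    payload=message.payload,
                )
            bus.publish(rec["queue"], message)
        return bus

    def close(self) -> None:
        with self._lock:
            if self._journal_file is not None:
                self._journal_file.close()
                self._journal_file = None

    # ------------------------------------------------------------------
    # contract operations

    def declare_queue(self, queue_name: str) -> None:
        with self._lock:
            if queue_name not in self._queues:
                self._queues[queue_name] = []
                self._journal({"op": "declare", "queue": queue_name})

    def queues(self) -> list[str]:
        with self._lock:
            return sorted(self._queues)

    def publish(self, queue_name: str, message: Message) -> int:
        """Durably enqueue ``message``; returns an opaque delivery receipt.

        Raises :class:`SerializationError` for unserializable payloads and
        :class:`QueueFullError` when the depth cap is reached.
        """
        try:
            serialized = message.to_dict()
            json.dumps(serialized)
        except (TypeError, ValueError) as exc:
            raise SerializationError(
                f"message for queue {queue_name!r} is not JSON-serializable: {exc}"
            ) from exc
        with self._lock:
            if len(self._entries) >= self._max_depth:
                raise QueueFullError(
                    f"bus depth cap {self._max_depth} reached; publish refused"
                )
            msg_id = next(self._ids)
            seq = next(self._seqs)
            entry = _Entry(msg_id=msg_id, queue=queue_name, message=message, seq=seq)
            self._entries[msg_id] = entry
            self._queues.setdefault(queue_name, [])
            heapq.heappush(
                self._queues[queue_name], (-message.header.priority, seq, msg_id)
            )
            self._journal(
                {"op": "pub", "id": msg_id, "queue": queue_name, "message": serialized}
            )
            return msg_id

    def consume(self, queue_name: str, now: Optional[float] = None) -> Optional[Delivery]:
        """Deliver the highest-priority ready, non-expired message, or None.

        The delivered message is in-flight until :meth:`ack`.  Expired
        messages encountered on the way are dropped (TTL), never delivered.
        """
        with self._lock:
            if queue_name not in self._queues:
                raise UnknownQueueError(
                    f"queue {queue_name!r} does not exist (misconfiguration, "
                    "not emptiness)"
                )
            heap = self._queues[queue_name]
            while heap:
                _, _, msg_id = heapq.heappop(heap)
                entry = self._entries.get(msg_id)
                if entry is None:  # stale heap slot (acked or dropped)
                    continue
                if now is not None and entry.message.header.expiry_time <= now:
                    del self._entries[msg_id]
                    self._journal({"op": "drop", "id": msg_id})
                    log.info(
                        "dropped expired message %s (communication_id=%s) from %s",
                        msg_id,
                        entry.message.header.communication_id,
                        queue_name,
                    )
                    continue
                tag = next(self._tags)
                self._in_flight[tag] = msg_id
                self._journal({"op": "consume", "id": msg_id})
                return Delivery(message=entry.message, tag=tag, queue=queue_name)
            return None

    def ack(self, tag: int) -> bool:
        """Permanently remove the delivery; idempotent on duplicate tags."""
        with self._lock:
            msg_id = self._in_flight.pop(tag, None)
            if msg_id is None:
                if tag in self._acked_tags:
                    log.warning("duplicate ack for tag %s ignored", tag)
                else:
                    log.warning("ack for unknown tag %s ignored", tag)
                return False
            self._acked_tags.add(tag)
            self._entries.pop(msg_id, None)
            self._journal({"op": "ack", "id": msg_id})
            return True

    def purge_expired(self, queue_name: str, now: float) -> int:
        """Drop every ready message with ``expiry_time <= now``; return count."""
        with self._lock:
            if queue_name not in self._queues:
                return 0
            dropped = 0
            survivors: list[tuple[int, int, int]] = []
            for key in self._queues[queue_name]:
                entry = self._entries.get(key[2])
                if entry is None:
                    continue
                if entry.message.header.expiry_time <= now:
                    del self._entries[key[2]]
                    self._journal({"op": "drop", "id": key[2]})
                    dropped += 1
                else:
                    survivors.append(key)
            heapq.heapify(survivors)
            self._queues[queue_name] = survivors
            return dropped

    # ------------------------------------------------------------------
    # recovery helpers

    def requeue_unacked(self) -> int:
        """Return all in-flight deliveries to their queues (consumer died).

        Each message is re-enqueued at its original priority with
        ``delivery_count`` incremented by one.  Returns the number requeued.
        """
        with self._lock:
            requeued = 0
            for tag, msg_id in list(self._in_flight.items()):
                del self._in_flight[tag]
                entry = self._entries.get(msg_id)
                if entry is None:
                    continue
                bumped = Message(
                    header=replace(
                        entry.message.header,
                        delivery_count=entry.message.header.delivery_count + 1,
                    ),
                    payload=entry.message.payload,
                )
                entry.message = bumped
                heapq.heappush(
                    self._queues[entry.queue],
                    (-bumped.header.priority, entry.seq, msg_id),
                )
                requeued += 1
            return requeued

    # ------------------------------------------------------------------
    # introspection

    def depth(self, queue_name: Optional[str] = None) -> int:
        """Number of ready (not in-flight) messages, per queue or total."""
        with self._lock:
            in_flight_ids = set(self._in_flight.values())
            if queue_name is None:
                return sum(
                    1 for e in self._entries.values() if e.msg_id not in in_flight_ids
                )
            return sum(
                1
                for e in self._entries.values()
                if e.queue == queue_name and e.msg_id not in in_flight_ids
            )

    def in_flight_count(self) -> int:
        with self._lock:
            return len(self._in_flight)

    def is_idle(self) -> bool:
        """True when no ready and no in-flight messages remain anywhere."""
        with self._lock:
            return not self._entries

    def iter_ready(self, queue_name: str) -> Iterator[Message]:
        """Snapshot of ready messages in consumption order (diagnostics)."""
        with self._lock:
            in_flight_ids = set(self._in_flight.values())
            keys = sorted(self._queues.get(queue_name, []))
            return iter(
                [
                    self._entries[k[2]].message
                    for k in keys
                    if k[2] in self._entries and k[2] not in in_flight_ids
                ]
            )
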