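"""Bus contract: priority ordering, ack/redelivery, TTL, durability."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from sia.messaging import (
    Message,
    MessageBus,
    MessageHeader,
    QueueFullError,
    SerializationError,
    UnknownQueueError,
)

from conftest import make_message

Q = "q.test"


class TestPriorityOrdering:
    def test_priority_descending(self, bus):
        for p in (1, 9, 5):
            bus.publish(Q, make_message(f"m{p}", priority=p))
        order = [bus.consume(Q).message.header.priority for _ in range(3)]
        assert order == [9, 5, 1]

    def test_fifo_within_equal_priority(self, bus):
        bus.publish(Q, make_message("first", priority=5))
        bus.publish(Q, make_message("second", priority=5))
        assert bus.consume(Q).message.header.communication_id == "first"
        assert bus.consume(Q).message.header.communication_id == "second"

    @given(priorities=st.lists(st.integers(0, 9), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_delivery_is_priority_sorted_fifo_stable(self, priorities):
        bus = MessageBus()
        for i, p in enumerate(priorities):
            bus.publish(Q, make_message(f"m{i}", priority=p))
        seen = []
        while (d := bus.consume(Q)) is not None:
            seen.append((d.message.header.priority, d.message.header.communication_id))
            bus.ack(d.tag)
        expected = sorted(
            ((p, f"m{i}") for i, p in enumerate(priorities)),
            key=lambda t: (-t[0], int(t[1][1:])),
        )
        assert seen == expected


class TestExpiry:
    def test_already_expired_never_delivered(self, bus, clock):
        clock.advance(100.0)
        bus.publish(Q, make_message("dead", expiry=50.0))
        assert bus.consume(Q, now=clock.now()) is None

    def test_purge_expired_counts_and_preserves(self, bus):
        bus.publish(Q, make_message("a", expiry=10.0))
        bus.publish(Q, make_message("b", expiry=20.0))
        bus.publish(Q, make_message("c", expiry=500.0))
        assert bus.purge_expired(Q, now=30.0) == 2
        assert bus.depth(Q) == 1
        assert bus.consume(Q, now=30.0).message.header.communication_id == "c"

    def test_purge_nothing_expired_is_identity(self, bus):
        bus.publish(Q, make_message("a", expiry=100.0))
        assert bus.purge_expired(Q, now=5.0) == 0
        assert bus.depth(Q) == 1

    def test_expiry_boundary_is_inclusive(self, bus):
        bus.publish(Q, make_message("edge", expiry=42.0))
        assert bus.purge_expired(Q, now=42.0) == 1

    @given(offset=st.floats(-100.0, 100.0, allow_nan=False))
    @settings(derandomize=True, max_examples=60)
    def test_expired_message_never_delivered_property(self, offset):
        now = 1000.0
        expiry = now + offset
        bus = MessageBus()
        bus.publish(Q, make_message("m", expiry=expiry))
        delivery = bus.consume(Q, now=now)
        if expiry <= now:
            assert delivery is None
        else:
            assert delivery is not None


class TestConsumeAck:
    def test_empty_queue_returns_none(self, bus):
        bus.declare_queue(Q)
        assert bus.consume(Q) is None

    def test_unknown_queue_is_an_error_not_emptiness(self, bus):
        with pytest.raises(UnknownQueueError):
            bus.consume("q.never.declared")

    def test_each_message_delivered_to_exactly_one_consumer(self, bus):
        for i in range(10):
            bus.publish(Q, make_message(f"m{i}"))
        seen_a, seen_b = [], []
        # two consumers alternating on one queue
        for i in range(10):
            d = bus.consume(Q)
            (seen_a if i % 2 == 0 else seen_b).append(
                d.message.header.communication_id
            )
            bus.ack(d.tag)
        assert not set(seen_a) & set(seen_b)
        assert sorted(seen_a + seen_b) == sorted(f"m{i}" for i in range(10))

    def test_in_flight_message_invisible_until_acked(self, bus):
        bus.publish(Q, make_message("only"))
        d = bus.consume(Q)
        assert bus.consume(Q) is None  # in-flight, not visible
        bus.ack(d.tag)
        assert bus.consume(Q) is None  # gone permanently

    def test_happy_path_ack_empties_queue(self, bus):
        bus.publish(Q, make_message("m"))
        d = bus.consume(Q)
        assert bus.ack(d.tag)
        assert bus.is_idle()
        assert bus.requeue_unacked() == 0

    def test_duplicate_ack_is_noop(self, bus):
        bus.publish(Q, make_message("m"))
        d = bus.consume(Q)
        assert bus.ack(d.tag) is True
        assert bus.ack(d.tag) is False

    def test_unacked_redelivered_with_incremented_count(self, bus):
        bus.publish(Q, make_message("m"))
        d = bus.consume(Q)
        assert d.message.header.delivery_count == 0
        assert bus.requeue_unacked() == 1
        d2 = bus.consume(Q)
        assert d2.message.header.delivery_count == 1
        assert d2.message.header.expiry_time == d.message.header.expiry_time


class TestDurability:
    def test_unacked_message_survives_restart(self, tmp_path):
        journal = str(tmp_path / "bus.journal")
        bus = MessageBus(journal_path=journal)
        bus.publish(Q, make_message("survivor", payload={"x": [1, 2, 3]}))
        bus.consume(Q)  # never acked
        bus.close()
        bus2 = MessageBus.open_journal(journal)
        d = bus2.consume(Q)
        assert d is not None
        assert d.message.payload == {"x": [1, 2, 3]}
        assert d.message.header.delivery_count == 1

    def test_acked_message_absent_after_restart(self, tmp_path):
        journal = str(tmp_path / "bus.journal")
        bus = MessageBus(journal_path=journal)
        bus.publish(Q, make_message("m"))
        bus.ack(bus.consume(Q).tag)
        bus.close()
        bus2 = MessageBus.open_journal(journal)
        assert bus2.consume(Q) is None
        assert bus2.is_idle()

    def test_payload_roundtrips_losslessly(self, tmp_path):
        journal = str(tmp_path / "bus.journal")
        payload = {"nested": {"a": [1, 2.5, "x", None, True]}, "s": "üñïçødé"}
        bus = MessageBus(journal_path=journal)
        bus.publish(Q, make_message("m", payload=payload))
        bus.close()
        d = MessageBus.open_journal(journal).consume(Q)
        assert d.message.payload == payload

    def test_no_loss_under_random_crash_restart(self, tmp_path):
        """Multiset of acked payloads equals multiset of published payloads
        over a random interleaving of consume/ack/crash/restart."""
        journal = str(tmp_path / "bus.journal")
        rng = random.Random(0)
        published = [f"payload-{i}" for i in range(40)]
        bus = MessageBus(journal_path=journal)
        for i, p in enumerate(published):
            bus.publish(Q, make_message(f"m{i}", priority=rng.randint(0, 9), payload=p))
        acked = []
        pending = {}
        for _ in range(400):
            action = rng.random()
            if action < 0.5:
                d = bus.consume(Q)
                if d is not None:
                    pending[d.tag] = d.message.payload
            elif action < 0.8 and pending:
                tag = rng.choice(list(pending))
                bus.ack(tag)
                acked.append(pending.pop(tag))
            elif action < 0.9:
                bus.requeue_unacked()  # consumer crash: in-flight lost
                pending.clear()
            else:
                bus.close()  # full process crash + journal recovery
                bus = MessageBus.open_journal(journal)
                pending.clear()
        while (d := bus.consume(Q)) is not None:
            bus.ack(d.tag)
            acked.append(d.message.payload)
        assert sorted(acked) == sorted(published)
        assert bus.is_idle()


class TestPublishErrors:
    def test_unserializable_payload_rejected(self, bus):
        with pytest.raises(SerializationError):
            bus.publish(Q, make_message("m", payload={"bad": object()}))

    def test_backpressure_when_storage_exhausted(self):
        bus = MessageBus(max_depth=2)
        bus.publish(Q, make_message("a"))
        bus.publish(Q, make_message("b"))
        with pytest.raises(QueueFullError):
            bus.publish(Q, make_message("c"))

    def test_header_priority_range_enforced(self):
        with pytest.raises(ValueError):
            MessageHeader(communication_id="c", expiry_time=1.0, priority=10)
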