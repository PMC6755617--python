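"""Request validation, deadline-derived priority, monitoring statistics."""

import json
import threading
import urllib.error
import urllib.request

import pytest
from hypothesis import given, settings, strategies as st

from sia.frontend import (
    AnnotationRequest,
    BackpressureError,
    DocumentRef,
    Frontend,
    ProcessingStats,
    ValidationFailure,
    build_http_server,
    compute_priority,
    validate_request,
)
from sia.messaging import MessageBus

from conftest import FAR_FUTURE, inline_request


def raw_request(**overrides):
    raw = {
        "communication_id": "c1",
        "expiry": 5000.0,
        "types": ["MUTATION", "mirna"],
        "documents": [
            {"document_id": "d1", "source": "pubmed"},
            {"document_id": "d2", "source": "pmc"},
        ],
    }
    raw.update(overrides)
    return raw


class TestValidation:
    def test_valid_request_normalized(self):
        req = validate_request(raw_request(), now=0.0)
        assert req.requested_types == frozenset({"MUTATION", "MIRNA"})
        assert [d.document_id for d in req.documents] == ["d1", "d2"]

    def test_unknown_type_rejected_naming_offender(self):
        with pytest.raises(ValidationFailure) as exc:
            validate_request(raw_request(types=["PROTEIN_COMPLEX"]), now=0.0)
        (error,) = [e for e in exc.value.errors if e["code"] == "unknown_type"]
        assert "PROTEIN_COMPLEX" in error["message"]

    def test_past_expiry_rejected(self):
        with pytest.raises(ValidationFailure) as exc:
            validate_request(raw_request(expiry=10.0), now=100.0)
        assert any(e["code"] == "past_expiry" for e in exc.value.errors)

    def test_duplicate_document_ids_preserved(self):
        raw = raw_request(documents=[
            {"document_id": "d1", "source": "pubmed"},
            {"document_id": "d1", "source": "pubmed"},
        ])
        req = validate_request(raw, now=0.0)
        assert [d.document_id for d in req.documents] == ["d1", "d1"]

    @pytest.mark.parametrize(
        "overrides,expected_code",
        [
            ({"communication_id": None}, "missing_field"),
            ({"expiry": None}, "missing_field"),
            ({"expiry": "not-a-date"}, "invalid_field"),
            ({"types": []}, "empty_types"),
            ({"documents": []}, "empty_documents"),
        ],
    )
    def test_each_defect_gets_distinct_code(self, overrides, expected_code):
        with pytest.raises(ValidationFailure) as exc:
            validate_request(raw_request(**overrides), now=0.0)
        assert any(e["code"] == expected_code for e in exc.value.errors)

    def test_iso8601_expiry_parsed(self):
        req = validate_request(
            raw_request(expiry="2100-01-01T00:00:00Z"), now=0.0
        )
        assert req.expiry_time > 4e9

    def test_alias_table_remaps_wire_fields(self):
        raw = {
            "comm": "c9",
            "deadline": 5000.0,
            "entity_types": ["DISEASE"],
            "docs": [{"id": "d1", "src": "patents"}],
        }
        aliases = {
            "communication_id": "comm",
            "expiry": "deadline",
            "types": "entity_types",
            "documents": "docs",
            "document_id": "id",
            "source": "src",
        }
        req = validate_request(raw, now=0.0, aliases=aliases)
        assert req.communication_id == "c9"
        assert req.documents[0].source == "patents"


class TestPriority:
    @pytest.mark.parametrize(
        "slack_in_ema_units,expected",
        [(0.5, 9), (3.0, 6), (100.0, 0)],
    )
    def test_slack_quantized_in_ema_units(self, slack_in_ema_units, expected):
        stats = ProcessingStats(ema_processing_seconds=10.0)
        assert compute_priority(100.0 + slack_in_ema_units * 10.0, 100.0, stats) == expected

    def test_defensive_on_nonpositive_slack(self):
        assert compute_priority(5.0, 10.0, ProcessingStats()) == 9

    @given(
        slack_a=st.floats(0.01, 1e6),
        slack_b=st.floats(0.01, 1e6),
        ema=st.floats(0.1, 1e4),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_smaller_slack_never_lower_priority(self, slack_a, slack_b, ema):
        stats = ProcessingStats(ema_processing_seconds=ema)
        pa = compute_priority(slack_a, 0.0, stats)
        pb = compute_priority(slack_b, 0.0, stats)
        if slack_a <= slack_b:
            assert pa >= pb


class TestStats:
    def test_fresh_counters_zero(self, bus, clock):
        snap = Frontend(bus, clock=clock).monitoring_snapshot()
        assert snap["accepted_count"] == 0
        assert snap["rejected_count"] == 0
        assert snap["completed_count"] == 0

    def test_accept_and_completion_counters(self, bus, clock):
        fe = Frontend(bus, clock=clock)
        for i in range(5):
            fe.accept(inline_request(f"c{i}", [(f"d{i}", {"T": "x"})]))
        for i in range(3):
            fe.record_completion(f"c{i}")
        snap = fe.monitoring_snapshot()
        assert snap["accepted_count"] == 5
        assert snap["completed_count"] == 3
        assert snap["accepted_count"] >= snap["completed_count"]

    def test_ema_recurrence(self):
        stats = ProcessingStats()
        stats.record_completed(2.0)
        assert stats.ema_processing_seconds == pytest.approx(1.2)
        stats.record_completed(4.0)
        assert stats.ema_processing_seconds == pytest.approx(1.76)


class TestAccept:
    def test_accept_with_backend_stopped_buffers(self, bus, clock):
        fe = Frontend(bus, clock=clock)
        ack = fe.accept(inline_request("c1", [("d1", {"T": "x"})]))
        assert ack == {"communication_id": "c1", "status": "accepted"}
        assert bus.depth(fe.input_queue) == 1  # buffered, nothing processed

    def test_storage_exhausted_denied(self, clock):
        bus = MessageBus(max_depth=1)
        fe = Frontend(bus, clock=clock)
        fe.accept(inline_request("c1", [("d1", {"T": "x"})]))
        with pytest.raises(BackpressureError):
            fe.accept(inline_request("c2", [("d2", {"T": "x"})]))
        assert fe.monitoring_snapshot()["rejected_count"] == 1

    def test_rejected_request_leaves_no_trace_on_queue(self, bus, clock):
        fe = Frontend(bus, clock=clock)
        with pytest.raises(ValidationFailure):
            fe.handle_annotate(raw_request(types=["NOT_A_TYPE"]))
        assert bus.depth(fe.input_queue) == 0


class TestHttpApi:
    @pytest.fixture
    def server(self, bus, clock):
        fe = Frontend(bus, clock=clock)
        srv = build_http_server(fe, port=0)
        thread = threading.Thread(target=srv.serve_forever, daemon=True)
        thread.start()
        yield srv, fe
        srv.shutdown()

    def _post(self, port, body):
        req = urllib.request.Request(
            f"http://127.0.0.1:{port}/annotate",
            data=json.dumps(body).encode(),
            headers={"Content-Type": "application/json"},
            method="POST",
        )
        try:
            with urllib.request.urlopen(req) as resp:
                return resp.status, json.loads(resp.read())
        except urllib.error.HTTPError as exc:
            return exc.code, json.loads(exc.read())

    def test_annotate_then_status(self, server):
        srv, fe = server
        port = srv.server_address[1]
        status, body = self._post(port, raw_request(expiry=FAR_FUTURE))
        assert status == 202
        assert body["status"] == "accepted"
        with urllib.request.urlopen(f"http://127.0.0.1:{port}/status") as resp:
            snap = json.loads(resp.read())
        assert snap["accepted_count"] == 1

    def test_invalid_request_gets_400_with_errors(self, server):
        srv, _ = server
        status, body = self._post(
            srv.server_address[1], raw_request(types=["PROTEIN_COMPLEX"])
        )
        assert status == 400
        assert any(e["code"] == "unknown_type" for e in body["errors"])
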