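import json

import pytest

from sia.annotators import build_default_annotators, build_default_registry
from sia.clock import FakeClock
from sia.frontend import AnnotationRequest, DocumentRef, Frontend
from sia.messaging import Message, MessageBus, MessageHeader
from sia.pipeline import Backend

FAR_FUTURE = 1e12


@pytest.fixture
def clock():
    return FakeClock(0.0)


@pytest.fixture
def bus():
    return MessageBus()


def make_message(comm_id="c1", priority=0, expiry=FAR_FUTURE, payload=None, **kw):
    header = MessageHeader(
        communication_id=comm_id, expiry_time=expiry, priority=priority, **kw
    )
    return Message(header, payload if payload is not None else {"id": comm_id})


def inline_request(comm_id, texts, types=("MUTATION", "MIRNA"), expiry=FAR_FUTURE):
    """Request with inline-text documents (identity fetching).

    ``texts`` is a list of (document_id, sections-dict).
    """
    return AnnotationRequest(
        communication_id=comm_id,
        documents=tuple(
            DocumentRef(doc_id, "identity", dict(sections))
            for doc_id, sections in texts
        ),
        requested_types=frozenset(types),
        expiry_time=expiry,
    )


def build_backend(bus, clock, collected=None, registry=None, annotators=None,
                  frontend=None, adapters=None):
    handlers = [] if collected is None else [collected.append]
    return Backend(
        bus,
        registry=registry or build_default_registry(),
        annotators=annotators or build_default_annotators(),
        adapters=adapters,
        result_handlers=handlers,
        clock=clock,
        frontend=frontend,
    )


def response_key(responses):
    """Order-insensitive canonical form of a list of AnnotationResponse."""
    return sorted(
        (
            r.communication_id,
            json.dumps([a.to_dict() for a in r.annotations], sort_keys=True),
            sorted(r.unserved_types),
            list(r.unavailable_documents),
        )
        for r in responses
    )
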