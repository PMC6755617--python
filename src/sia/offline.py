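"""Offline bulk mode: annotate a local document collection end-to-end.

Turns the server into an offline annotation tool: documents are read from
the local corpus format, fed through the full pipeline (identity fetch →
scatter/gather → aggregate) with text carried inline in the request
messages, and all results are written to a local JSON-lines file.  No
external document provider is involved.  The ``parallelism`` knob controls
how many messages are consumed from the queues simultaneously; the
result multiset is invariant to it.
"""

from __future__ import annotations

import json
import os
import time
from typing import Any, Iterable, Optional

from .annotators import (
    AnnotatorRegistry,
    Annotator,
    build_default_annotators,
    build_default_registry,
)
from .clock import Clock, SystemClock
from .corpus_adapters import LocalCorpusAdapter
from .frontend import AnnotationRequest, DocumentRef, Frontend
from .messaging import MessageBus
from .pipeline import Backend, QueueConfig
from .result_handlers import FileResultHandler


def corpus_to_requests(
    adapter: LocalCorpusAdapter,
    types: Iterable[str],
    expiry_time: float,
) -> list[AnnotationRequest]:
    """One request per document, text carried inline (identity fetching)."""
    requested = frozenset(t.upper() for t in types)
    requests = []
    for doc_id in adapter.document_ids():
        doc = adapter.fetch([doc_id])[0]
        requests.append(
            AnnotationRequest(
                communication_id=doc_id,
                documents=(
                    DocumentRef(
                        document_id=doc_id,
                        source="identity",
                        inline_sections=dict(doc.sections),
                    ),
                ),
                requested_types=requested,
                expiry_time=expiry_time,
            )
        )
    return requests


def run_offline(
    corpus_path: str,
    types: Iterable[str],
    parallelism: int = 1,
    out_path: str = "results.jsonl",
    registry: Optional[AnnotatorRegistry] = None,
    annotators: Optional[dict[str, Annotator]] = None,
    clock: Optional[Clock] = None,
    expiry_horizon: float = 24 * 3600.0,
) -> dict[str, Any]:
    """Annotate every document in ``corpus_path``; returns a run summary
    ``{"documents", "annotations", "elapsed"}``.

    Raises immediately (before any pipeline start) if the corpus is
    missing.  The results file receives one JSON line per annotation.
    """
    if not os.path.exists(corpus_path):
        raise FileNotFoundError(f"corpus not found: {corpus_path}")
    if parallelism < 1:
        raise ValueError("parallelism must be >= 1")
    clock = clock if clock is not None else SystemClock()
    adapter = LocalCorpusAdapter(corpus_path)
    started = time.monotonic()

    bus = MessageBus()
    frontend = Frontend(bus, clock=clock)
    handler = FileResultHandler(out_path)
    registry = registry if registry is not None else build_default_registry()
    annotators = annotators if annotators is not None else build_default_annotators()
    backend = Backend(
        bus,
        registry=registry,
        annotators=annotators,
        result_handlers=[handler.write],
        clock=clock,
        frontend=frontend,
    )
    expiry = clock.now() + expiry_horizon
    for request in corpus_to_requests(adapter, types, expiry):
        frontend.accept(request)
    backend.run(parallelism=parallelism)

    n_annotations = 0
    if os.path.exists(out_path):
        with open(out_path, encoding="utf-8") as fh:
            n_annotations = sum(1 for line in fh if line.strip())
    return {
        "documents": len(adapter),
        "annotations": n_annotations,
        "elapsed": time.monotonic() - started,
    }


def read_results(path: str) -> list[dict[str, Any]]:
    """Load a results file, sorted into canonical order for comparison."""
    if not os.path.exists(path):
        return []
    with open(path, encoding="utf-8") as fh:
        records = [json.loads(line) for line in fh if line.strip()]
    records.sort(
        key=lambda r: (
            r["communication_id"],
            r["document_id"],
            r["section"],
            r["init"],
            r["end"],
            r["type"],
        )
    )
    return records
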