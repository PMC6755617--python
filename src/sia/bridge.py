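"""External annotator hosting: run a tagger in a separate process.

Annotators can be hosted embedded (same process) or externally — useful
when taggers have conflicting dependencies or exceed one machine's
memory.  The bridge speaks newline-delimited JSON over the child's
stdin/stdout: one ``{"text", "section", "document_id"}`` request per line,
one ``{"annotations": [...]}`` response per line.  Because both sides run
the same deterministic tagger code, an externally hosted annotator
produces byte-identical annotation sets to the embedded run.

Run the worker side as ``python -m sia.bridge <annotator-name>``.
"""

from __future__ import annotations

import json
import subprocess
import sys
from typing import IO, Optional

from .annotators import Annotation, Annotator, build_default_annotators


def serve_stdio(annotator: Annotator, stdin: IO[str], stdout: IO[str]) -> None:
    """Worker loop: answer annotation requests until EOF."""
    for line in stdin:
        line = line.strip()
        if not line:
            continue
        req = json.loads(line)
        annotations = annotator.annotate(
            req["text"], req["section"], req["document_id"]
        )
        stdout.write(
            json.dumps({"annotations": [a.to_dict() for a in annotations]},
                       sort_keys=True) + "\n"
        )
        stdout.flush()


class ExternalAnnotatorBridge(Annotator):
    """Annotator-interface adapter that proxies to a child process.

    The pipeline consumes from the annotator's queue as usual; only the
    tagging itself happens out-of-process.
    """

    def __init__(self, annotator_name: str):
        self.name = annotator_name
        self._proc: Optional[subprocess.Popen] = None
        self.entity_type = build_default_annotators()[annotator_name].entity_type

    def _ensure_proc(self) -> subprocess.Popen:
        if self._proc is None or self._proc.poll() is not None:
            self._proc = subprocess.Popen(
                [sys.executable, "-m", "sia.bridge", self.name],
                stdin=subprocess.PIPE,
                stdout=subprocess.PIPE,
                text=True,
            )
        return self._proc

    def annotate(self, text: str, section: str, document_id: str) -> list[Annotation]:
        proc = self._ensure_proc()
        assert proc.stdin is not None and proc.stdout is not None
        proc.stdin.write(
            json.dumps(
                {"text": text, "section": section, "document_id": document_id}
            )
            + "\n"
        )
        proc.stdin.flush()
        line = proc.stdout.readline()
        if not line:
            raise RuntimeError(f"bridge worker {self.name!r} died")
        return [Annotation.from_dict(a) for a in json.loads(line)["annotations"]]

    def close(self) -> None:
        if self._proc is not None and self._proc.poll() is None:
            self._proc.stdin.close()  # type: ignore[union-attr]
            self._proc.wait(timeout=10)
        self._proc = None

    def __enter__(self) -> "ExternalAnnotatorBridge":
        return self

    def __exit__(self, *exc: object) -> None:
        self.close()


def _main(argv: list[str]) -> int:
    if len(argv) != 1:
        print("usage: python -m sia.bridge <annotator-name>", file=sys.stderr)
        return 2
    annotators = build_default_annotators()
    name = argv[0]
    if name not in annotators:
        print(f"unknown annotator {name!r}; have {sorted(annotators)}", file=sys.stderr)
        return 2
    serve_stdio(annotators[name], sys.stdin, sys.stdout)
    return 0


if __name__ == "__main__":
    raise SystemExit(_main(sys.argv[1:]))
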