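"""Named-entity annotators: interface, built-in taggers, registry.

An annotator receives a section of text and returns standoff annotations —
``(section, start, end, type, score, surface)`` offsets into the exact
input string, never inline markup.  Three rule-based taggers are built in:

* miRNA mentions via a regular-expression grammar following community
  miRNA nomenclature (``hsa-miR-21-5p``, ``let-7b`` ...);
* sequence-variant (mutation) mentions via an HGVS-style grammar subset
  (``V600E``, ``p.Val600Glu``, ``c.1799T>A``);
* disease (and, with toy vocabularies, chemical/gene/organism) mentions
  via greedy leftmost-longest dictionary lookup.

Annotators not under the pipeline's control may crash; :func:`safe_annotate`
converts any exception into zero annotations plus a structured error log so
the enclosing request still completes.  The :class:`AnnotatorRegistry` maps
entity types to annotator input queues and supports runtime
(de-)activation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Optional, Sequence

log = logging.getLogger(__name__)

ENTITY_TYPES = frozenset(
    {"CHEMICAL", "DISEASE", "GENE", "MIRNA", "MUTATION", "ORGANISM"}
)


@dataclass(frozen=True, order=True)
class Annotation:
    """One entity mention as character offsets into a document section.

    ``start`` is 0-based inclusive, ``end`` exclusive, both counted in the
    section named by ``section`` (T/A/F).  ``text`` must equal the section
    substring ``[start:end)``; ``score`` is a confidence in [0, 1].
    """

    document_id: str
    section: str
    start: int
    end: int
    type: str
    score: float
    text: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if self.section not in ("T", "A", "F"):
            raise ValueError(f"invalid section code {self.section!r}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "document_id": self.document_id,
            "section": self.section,
            "start": self.start,
            "end": self.end,
            "type": self.type,
            "score": self.score,
            "text": self.text,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Annotation":
        return cls(**{k: d[k] for k in
                      ("document_id", "section", "start", "end", "type", "score", "text")})


def check_offsets(text: str, annotations: Iterable[Annotation]) -> None:
    """Assert the offset invariant: text[start:end] == annotation.text."""
    for a in annotations:
        if a.end > len(text) or text[a.start : a.end] != a.text:
            raise AssertionError(
                f"offset invariant violated: [{a.start}:{a.end}] of len-{len(text)} "
                f"text != {a.text!r}"
            )


class Annotator:
    """Interface contract: input text in, set of found annotations out.

    Implementations must be deterministic and side-effect free; output is
    sorted by (section, start, end).  Empty text yields an empty list.
    """

    name: str = "annotator"
    entity_type: str = ""

    def annotate(self, text: str, section: str, document_id: str) -> list[Annotation]:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# miRNA grammar
#
# optional species prefix (3-4 lowercase letters + hyphen), stem
# miR/MiR/mir/let/lin, hyphen, 1-4 digits, optional lowercase letter,
# optional "-digit" paralog, optional -3p/-5p arm; word-boundary delimited,
# longest match wins (regex greediness + leading boundary on the prefix).

_MIRNA_RE = re.compile(
    r"(?<![\w-])"
    r"(?:[a-z]{3,4}-)?"
    r"(?:miR|MiR|mir|let|lin)"
    r"-\d{1,4}"
    r"[a-z]?"
    r"(?:-\d)?"
    r"(?:-[35]p)?"
    r"(?![\w-])"
)


class MirnaAnnotator(Annotator):
    """Regex tagger for microRNA nomenclature mentions (type MIRNA)."""

    name = "mirna"
    entity_type = "MIRNA"

    def annotate(self, text: str, section: str, document_id: str) -> list[Annotation]:
        return [
            Annotation(
                document_id=document_id,
                section=section,
                start=m.start(),
                end=m.end(),
                type="MIRNA",
                score=1.0,
                text=m.group(),
            )
            for m in _MIRNA_RE.finditer(text)
        ]


# ---------------------------------------------------------------------------
# mutation grammar (HGVS-style subset)
#
# (a) protein one-letter substitution: AA digits AA, position >= 1 (V600E)
# (b) three-letter form, optional "p." prefix (p.Val600Glu, Val600Glu)
# (c) coding DNA substitution: c.<digits><base>><base> (c.1799T>A)

_AA1 = "[ACDEFGHIKLMNPQRSTVWY]"
_AA3 = (
    "(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr"
    "|Trp|Tyr|Val)"
)
_MUTATION_RE = re.compile(
    r"(?<![\w.>])"
    r"(?:"
    rf"c\.\d+[ACGT]>[ACGT]"
    r"|"
    rf"(?:p\.)?{_AA3}[1-9]\d*{_AA3}"
    r"|"
    rf"{_AA1}[1-9]\d*{_AA1}"
    r")"
    r"(?!\w)"
)


class MutationAnnotator(Annotator):
    """Regex tagger for sequence-variant mentions (type MUTATION)."""

    name = "mutation"
    entity_type = "MUTATION"

    def annotate(self, text: str, section: str, document_id: str) -> list[Annotation]:
        return [
            Annotation(
                document_id=document_id,
                section=section,
                start=m.start(),
                end=m.end(),
                type="MUTATION",
                score=1.0,
                text=m.group(),
            )
            for m in _MUTATION_RE.finditer(text)
        ]


# ---------------------------------------------------------------------------
# dictionary lookup

# Tokens are runs of word characters, with hyphenated spans kept intact.
_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)
_EDGE_PUNCT_RE = re.compile(r"^[^\w]+|[^\w]+$")


def normalize_term(term: str) -> str:
    """Lower-case, collapse whitespace, strip punctuation at token edges."""
    tokens = [_EDGE_PUNCT_RE.sub("", t) for t in term.lower().split()]
    return " ".join(t for t in tokens if t)


class DictionaryError(ValueError):
    """Malformed dictionary file (reported with line number)."""


@dataclass
class TermDictionary:
    """Normalized surface term -> concept identifier, for longest-match lookup.

    ``max_term_tokens`` bounds the token-window length the tagger scans, set
    to the longest term in the dictionary.
    """

    entries: dict[str, str] = field(default_factory=dict)
    max_term_tokens: int = 1

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_terms(cls, pairs: Iterable[tuple[str, str]]) -> "TermDictionary":
        entries: dict[str, str] = {}
        max_tokens = 1
        for term, concept in pairs:
            norm = normalize_term(term)
            if not norm:
                raise DictionaryError(f"empty term after normalization: {term!r}")
            if norm in entries:
                log.warning(
                    "duplicate normalized term %r; keeping first concept id %s",
                    norm,
                    entries[norm],
                )
                continue
            entries[norm] = concept
            max_tokens = max(max_tokens, len(norm.split()))
        return cls(entries=entries, max_term_tokens=max_tokens)


def load_dictionary(path: str) -> TermDictionary:
    """Load a two-column TSV (surface term \\t concept id) dictionary."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise DictionaryError(
                    f"{path}:{lineno}: expected 'term<TAB>concept_id', got {line!r}"
                )
            pairs.append((parts[0], parts[1].strip()))
    return TermDictionary.from_terms(pairs)


class DictionaryAnnotator(Annotator):
    """Greedy leftmost-longest dictionary tagger over token windows.

    Matching is case-insensitive and must align to token boundaries
    (``anticancer`` never matches ``cancer``); after a match, scanning
    resumes past its end, so output spans never overlap.  The annotation
    text preserves the original casing from the input.
    """

    def __init__(self, entity_type: str, dictionary: TermDictionary, name: Optional[str] = None):
        self.entity_type = entity_type
        self.name = name or entity_type.lower()
        self.dictionary = dictionary

    def annotate(self, text: str, section: str, document_id: str) -> list[Annotation]:
        tokens = [(m.start(), m.end(), m.group()) for m in _TOKEN_RE.finditer(text)]
        out: list[Annotation] = []
        i = 0
        n = len(tokens)
        while i < n:
            matched = False
            max_len = min(self.dictionary.max_term_tokens, n - i)
            for length in range(max_len, 0, -1):
                window = tokens[i : i + length]
                candidate = normalize_term(" ".join(t[2] for t in window))
                concept = self.dictionary.entries.get(candidate)
                if concept is not None:
                    start, end = window[0][0], window[-1][1]
                    out.append(
                        Annotation(
                            document_id=document_id,
                            section=section,
                            start=start,
                            end=end,
                            type=self.entity_type,
                            score=1.0,
                            text=text[start:end],
                        )
                    )
                    i += length
                    matched = True
                    break
            if not matched:
                i += 1
        return out


# ---------------------------------------------------------------------------
# crash isolation

def safe_annotate(
    annotator: Annotator, text: str, section: str, document_id: str
) -> list[Annotation]:
    """Run an annotator, converting any exception into zero annotations.

    Annotator components are not under the pipeline's control; a crash on
    one text must not take down the back end or the request.  Errors are
    logged (structured, one entry per crash) for later analysis.
    """
    try:
        annotations = annotator.annotate(text, section, document_id)
    except Exception:
        log.error(
            "annotator failed; returning zero annotations",
            exc_info=True,
            extra={
                "annotator": getattr(annotator, "name", "?"),
                "document_id": document_id,
                "section": section,
            },
        )
        return []
    return sorted(annotations, key=lambda a: (a.section, a.start, a.end))


# ---------------------------------------------------------------------------
# registry

@dataclass
class RegistryEntry:
    annotator: str
    queue: str
    active: bool = True
    mode: str = "embedded"  # or "external"


class AnnotatorRegistry:
    """Runtime mapping entity type -> (annotator, input queue, active flag).

    Deactivation never removes an entry, so reactivating restores routing.
    Several types may map to the same queue; scatter deduplicates per
    queue, not per type.
    """

    def __init__(self, entries: Optional[dict[str, RegistryEntry]] = None):
        self._entries: dict[str, RegistryEntry] = dict(entries or {})

    def register(self, entity_type: str, entry: RegistryEntry) -> None:
        self._entries[entity_type] = entry

    def deactivate(self, entity_type: str) -> None:
        if entity_type in self._entries:
            self._entries[entity_type].active = False

    def activate(self, entity_type: str) -> None:
        if entity_type in self._entries:
            self._entries[entity_type].active = True

    def entry(self, entity_type: str) -> Optional[RegistryEntry]:
        return self._entries.get(entity_type)

    def types(self) -> list[str]:
        return sorted(self._entries)

    def active_queues(self) -> list[str]:
        return sorted({e.queue for e in self._entries.values() if e.active})

    def resolve_queues(
        self, requested_types: Iterable[str]
    ) -> tuple[set[str], set[str]]:
        """Queues of active entries serving any requested type, plus the
        requested types with no active entry (unserved)."""
        queues: set[str] = set()
        unserved: set[str] = set()
        for t in requested_types:
            e = self._entries.get(t)
            if e is not None and e.active:
                queues.add(e.queue)
            else:
                unserved.add(t)
        return queues, unserved


def resolve_queues(
    requested_types: Iterable[str], registry: AnnotatorRegistry
) -> tuple[set[str], set[str]]:
    return registry.resolve_queues(requested_types)


# ---------------------------------------------------------------------------
# defaults: all six routable entity types

def _packaged_dictionary(filename: str) -> TermDictionary:
    text = resources.files("sia.data").joinpath(filename).read_text(encoding="utf-8")
    pairs = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        term, concept = line.split("\t")
        pairs.append((term, concept))
    return TermDictionary.from_terms(pairs)


def build_default_annotators() -> dict[str, Annotator]:
    """The six built-in annotators, keyed by annotator name.

    MUTATION and MIRNA are regex taggers; DISEASE uses the packaged disease
    vocabulary; CHEMICAL, GENE and ORGANISM are dictionary-tagger instances
    with small packaged vocabularies so all six types are routable.
    """
    return {
        "mutation": MutationAnnotator(),
        "mirna": MirnaAnnotator(),
        "disease": DictionaryAnnotator("DISEASE", _packaged_dictionary("diseases.tsv")),
        "chemical": DictionaryAnnotator("CHEMICAL", _packaged_dictionary("chemicals.tsv")),
        "gene": DictionaryAnnotator("GENE", _packaged_dictionary("genes.tsv")),
        "organism": DictionaryAnnotator("ORGANISM", _packaged_dictionary("organisms.tsv")),
    }


def build_default_registry(queue_prefix: str = "q.annotator.") -> AnnotatorRegistry:
    """Default routing: one dedicated input queue per built-in annotator."""
    reg = AnnotatorRegistry()
    for entity_type, annotator_name in (
        ("MUTATION", "mutation"),
        ("MIRNA", "mirna"),
        ("DISEASE", "disease"),
        ("CHEMICAL", "chemical"),
        ("GENE", "gene"),
        ("ORGANISM", "organism"),
    ):
        reg.register(
            entity_type,
            RegistryEntry(annotator=annotator_name, queue=f"{queue_prefix}{annotator_name}"),
        )
    return reg
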