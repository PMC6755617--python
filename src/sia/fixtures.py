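"""Synthetic corpus generator with planted entity mentions at known offsets.

Every other module is testable offline against this generator: it emits
documents whose title and abstract are filler text with entity mentions
planted at exactly recorded offsets, drawn from the built-in taggers' own
positive grammars (miRNA names composed from the nomenclature grammar,
HGVS-style mutation strings, dictionary terms).  Near-miss negatives —
strings that look entity-like but fall outside the grammars, such as
``smirnoff``, ``E2F4`` or ``anticancer`` — are planted at a configurable
rate; the grammars define the gold standard, so planted recall and
precision against it are both exact quantities.

The filler vocabulary is screened against all positive grammars (no
digits, no hyphens, no dictionary terms), so no accidental true positives
can occur.  Mention counts per section are Poisson(density); positions are
uniform over token gaps, at most one planted string per gap so plants
never touch.  ``(corpus, gold)`` is a pure function of
``(n_docs, densities, seed)``.
"""

from __future__ import annotations

import json
import math
import os
import random
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotators import (
    ENTITY_TYPES,
    _MIRNA_RE,
    _MUTATION_RE,
    build_default_annotators,
)

# Lorem-style filler, all lowercase alphabetic: cannot match the mutation
# grammar (no digits), the miRNA grammar (no hyphen-digit), or any default
# dictionary term (disjoint vocabularies).
FILLER_WORDS = (
    "lorem ipsum dolor amet consectetur adipiscing elit eiusmod tempor "
    "incididunt labore dolore magna aliqua enim minim veniam quis nostrud "
    "exercitation ullamco laboris nisi aliquip commodo consequat duis aute "
    "irure reprehenderit voluptate velit esse cillum fugiat nulla pariatur "
    "excepteur sint occaecat cupidatat proident sunt culpa officia deserunt "
    "mollit anim laborum vero eos accusamus iusto odio dignissimos ducimus "
    "blanditiis praesentium voluptatum deleniti atque corrupti quos dolores "
    "quas molestias excepturi obcaecati cupiditate provident similique"
).split()

#: entity-lookalike strings that every grammar must reject
NEAR_MISS_NEGATIVES = ("smirnoff", "E2F4", "anticancer", "mirage", "H2O2", "letters")

_AA1_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_AA3_CODES = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr "
    "Trp Tyr Val"
).split()
_MIRNA_PREFIXES = (None, "hsa", "mmu", "rno", "dme")
_MIRNA_STEMS = ("miR", "mir", "let", "lin")


@dataclass(frozen=True)
class GoldMention:
    document_id: str
    section: str
    start: int
    end: int
    type: str
    text: str

    def to_dict(self) -> dict:
        return {
            "document_id": self.document_id,
            "section": self.section,
            "start": self.start,
            "end": self.end,
            "type": self.type,
            "text": self.text,
        }


@dataclass
class CorpusBundle:
    """In-memory result of a generation run."""

    documents: list[dict] = field(default_factory=list)
    gold: list[GoldMention] = field(default_factory=list)
    negatives: list[GoldMention] = field(default_factory=list)


def _poisson(rng: random.Random, mean: float) -> int:
    """Knuth's Poisson sampler; means here are O(1)."""
    if mean <= 0:
        return 0
    limit = math.exp(-mean)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _mirna_mention(rng: random.Random) -> str:
    prefix = rng.choice(_MIRNA_PREFIXES)
    stem = rng.choice(_MIRNA_STEMS)
    number = rng.randint(1, 999)
    letter = rng.choice(("", "a", "b", "c"))
    paralog = rng.choice(("", f"-{rng.randint(1, 9)}"))
    arm = rng.choice(("", "-3p", "-5p"))
    mention = f"{prefix + '-' if prefix else ''}{stem}-{number}{letter}{paralog}{arm}"
    assert _MIRNA_RE.fullmatch(mention), mention
    return mention


def _mutation_mention(rng: random.Random) -> str:
    form = rng.choice(("one_letter", "three_letter", "cdna"))
    pos = rng.randint(1, 2999)
    if form == "one_letter":
        mention = (
            rng.choice(_AA1_LETTERS) + str(pos) + rng.choice(_AA1_LETTERS)
        )
    elif form == "three_letter":
        prefix = rng.choice(("", "p."))
        mention = prefix + rng.choice(_AA3_CODES) + str(pos) + rng.choice(_AA3_CODES)
    else:
        ref = rng.choice("ACGT")
        alt = rng.choice([b for b in "ACGT" if b != ref])
        mention = f"c.{pos}{ref}>{alt}"
    assert _MUTATION_RE.fullmatch(mention), mention
    return mention


def _dictionary_terms() -> dict[str, list[str]]:
    annos = build_default_annotators()
    out: dict[str, list[str]] = {}
    for name in ("disease", "chemical", "gene", "organism"):
        tagger = annos[name]
        out[tagger.entity_type] = sorted(tagger.dictionary.entries)
    return out


_TERMS_CACHE: Optional[dict[str, list[str]]] = None


def _mention_for(entity_type: str, rng: random.Random) -> str:
    global _TERMS_CACHE
    if entity_type == "MIRNA":
        return _mirna_mention(rng)
    if entity_type == "MUTATION":
        return _mutation_mention(rng)
    if _TERMS_CACHE is None:
        _TERMS_CACHE = _dictionary_terms()
    term = rng.choice(_TERMS_CACHE[entity_type])
    if rng.random() < 0.3:  # dictionary matching is case-insensitive
        term = term[0].upper() + term[1:]
    return term


def _build_section(
    rng: random.Random,
    document_id: str,
    section: str,
    n_filler: int,
    densities: dict[str, float],
    near_miss_rate: float,
) -> tuple[str, list[GoldMention], list[GoldMention]]:
    filler = [rng.choice(FILLER_WORDS) for _ in range(n_filler)]
    plants: list[tuple[str, str]] = []  # (type or "", surface)
    for entity_type in sorted(densities):
        for _ in range(_poisson(rng, densities[entity_type])):
            plants.append((entity_type, _mention_for(entity_type, rng)))
    for _ in range(_poisson(rng, near_miss_rate)):
        plants.append(("", rng.choice(NEAR_MISS_NEGATIVES)))
    # one plant per gap so planted strings never touch each other
    n_gaps = n_filler + 1
    plants = plants[:n_gaps]
    gaps = sorted(rng.sample(range(n_gaps), len(plants)))
    rng.shuffle(plants)

    tokens: list[str] = []
    spans: list[tuple[str, int, int, str]] = []  # type, start, end, surface
    offset = 0
    gap_iter = dict(zip(gaps, plants))

    def _emit(token: str) -> tuple[int, int]:
        nonlocal offset
        if tokens:
            offset += 1  # the joining space
        start = offset
        tokens.append(token)
        offset += len(token)
        return start, offset

    for i in range(n_filler + 1):
        if i in gap_iter:
            entity_type, surface = gap_iter[i]
            start, end = _emit(surface)
            spans.append((entity_type, start, end, surface))
        if i < n_filler:
            _emit(filler[i])
    text = " ".join(tokens)

    gold = [
        GoldMention(document_id, section, s, e, t, surface)
        for (t, s, e, surface) in spans
        if t
    ]
    negatives = [
        GoldMention(document_id, section, s, e, "", surface)
        for (t, s, e, surface) in spans
        if not t
    ]
    for m in gold + negatives:
        assert text[m.start : m.end] == m.text
    return text, gold, negatives


def generate_corpus(
    n_docs: int,
    densities: dict[str, float],
    seed: int,
    out_dir: Optional[str] = None,
    near_miss_rate: float = 0.5,
    source: str = "synthetic",
) -> CorpusBundle:
    """Generate ``n_docs`` documents with planted mentions and exact gold.

    ``densities`` maps entity types (a subset of the six supported) to the
    mean number of planted mentions per section.  When ``out_dir`` is
    given, writes ``corpus.jsonl`` (the local corpus format),
    ``gold.jsonl`` and ``negatives.jsonl``.
    """
    unknown = set(densities) - ENTITY_TYPES
    if unknown:
        raise ValueError(f"unknown entity types in densities: {sorted(unknown)}")
    if n_docs < 1:
        raise ValueError("n_docs must be positive")
    rng = random.Random(seed)
    bundle = CorpusBundle()
    for i in range(n_docs):
        doc_id = f"doc-{i:05d}"
        sections = {}
        for section, n_filler in (("T", rng.randint(8, 14)), ("A", rng.randint(40, 80))):
            text, gold, negatives = _build_section(
                rng, doc_id, section, n_filler, densities, near_miss_rate
            )
            sections[section] = text
            bundle.gold.extend(gold)
            bundle.negatives.extend(negatives)
        bundle.documents.append(
            {
                "document_id": doc_id,
                "source": source,
                "title": sections["T"],
                "abstract": sections["A"],
                "fulltext": None,
            }
        )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "corpus.jsonl"), "w", encoding="utf-8") as fh:
            for doc in bundle.documents:
                fh.write(json.dumps(doc, sort_keys=True) + "\n")
        with open(os.path.join(out_dir, "gold.jsonl"), "w", encoding="utf-8") as fh:
            for m in bundle.gold:
                fh.write(json.dumps(m.to_dict(), sort_keys=True) + "\n")
        with open(os.path.join(out_dir, "negatives.jsonl"), "w", encoding="utf-8") as fh:
            for m in bundle.negatives:
                fh.write(json.dumps(m.to_dict(), sort_keys=True) + "\n")
    return bundle


def load_gold(path: str) -> list[GoldMention]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                out.append(
                    GoldMention(
                        d["document_id"], d["section"], d["start"], d["end"],
                        d["type"], d["text"],
                    )
                )
    return out
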