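"""Service configuration: one YAML file wires the whole server.

Example::

    host: 127.0.0.1
    port: 8080
    bearer_token: null          # optional static auth
    journal: /var/lib/sia/bus.journal
    queue_prefix: "q."
    parallelism: 2
    retry:
      initial_wait: 1.0
      multiplier: 2.0
      max_wait: 60.0
      max_attempts: 7
    corpora:
      local: /data/corpus       # source name -> local corpus path
    aliases: {}                 # wire-field remapping (request schema)
    result_aliases: {}          # wire-field remapping (response records)
    registry:                   # per-type overrides of the default routing
      CHEMICAL: {active: false}
      MUTATION: {mode: external}
    dictionaries:               # replace a packaged vocabulary with a TSV
      DISEASE: /data/umls_diseases.tsv
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .annotators import (
    Annotator,
    AnnotatorRegistry,
    DictionaryAnnotator,
    build_default_annotators,
    build_default_registry,
    load_dictionary,
)
from .corpus_adapters import LocalCorpusAdapter, RetryPolicy
from .pipeline import QueueConfig


@dataclass
class ServiceConfig:
    host: str = "127.0.0.1"
    port: int = 8080
    bearer_token: Optional[str] = None
    journal: Optional[str] = None
    queue_prefix: str = "q."
    parallelism: int = 1
    retry: RetryPolicy = field(default_factory=RetryPolicy)
    corpora: dict[str, str] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)
    result_aliases: dict[str, str] = field(default_factory=dict)
    registry_overrides: dict[str, dict[str, Any]] = field(default_factory=dict)
    dictionaries: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "ServiceConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        retry = RetryPolicy(**raw.get("retry", {}))
        return cls(
            host=raw.get("host", "127.0.0.1"),
            port=raw.get("port", 8080),
            bearer_token=raw.get("bearer_token"),
            journal=raw.get("journal"),
            queue_prefix=raw.get("queue_prefix", "q."),
            parallelism=raw.get("parallelism", 1),
            retry=retry,
            corpora=raw.get("corpora", {}) or {},
            aliases=raw.get("aliases", {}) or {},
            result_aliases=raw.get("result_aliases", {}) or {},
            registry_overrides=raw.get("registry", {}) or {},
            dictionaries=raw.get("dictionaries", {}) or {},
        )

    def queue_config(self) -> QueueConfig:
        return QueueConfig.with_prefix(self.queue_prefix)

    def build_registry(self) -> AnnotatorRegistry:
        registry = build_default_registry(
            queue_prefix=f"{self.queue_prefix}annotator."
        )
        for entity_type, overrides in self.registry_overrides.items():
            entry = registry.entry(entity_type.upper())
            if entry is None:
                continue
            if "active" in overrides:
                entry.active = bool(overrides["active"])
            if "mode" in overrides:
                entry.mode = overrides["mode"]
            if "queue" in overrides:
                entry.queue = overrides["queue"]
        return registry

    def build_annotators(self) -> dict[str, Annotator]:
        annotators = build_default_annotators()
        for entity_type, path in self.dictionaries.items():
            name = entity_type.lower()
            annotators[name] = DictionaryAnnotator(
                entity_type.upper(), load_dictionary(path), name=name
            )
        return annotators

    def build_adapters(self) -> dict[str, LocalCorpusAdapter]:
        return {name: LocalCorpusAdapter(path, name=name)
                for name, path in self.corpora.items()}
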