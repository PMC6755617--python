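# Methods

This note documents the processing model behind `sia`, the parameters
that matter, the synthetic-data generator used for testing, and the design
choices made where the design was genuinely open.

## Processing model

A request names documents (by id and source), entity types, a deadline
and a callback.  The system is a pipeline of message transformations over
durable priority queues; each stage consumes from the previous stage's
output queue and acknowledges a message only after it has successfully
published its own output.  The stages:

1. **Split** — one request message becomes one message per document
   reference (duplicates preserved; the caller's list is authoritative),
   each stamped with `total_documents`.
2. **Fetch** — a corpus adapter resolves `(document_id, source)` into
   section-structured text (`T`/`A`/`F`).  Inline text in the message
   bypasses adapters entirely (identity fetching, used by offline mode).
3. **Scatter** — the fetched document is duplicated onto the input queue
   of every *active* annotator whose type is requested, deduplicated per
   target queue, stamped with `total_annotators`.  Requested types with
   no active annotator are recorded as *unserved* in the header; if no
   annotator at all is active the document passes straight to the gather
   queue with an empty annotation set so the request still completes.
4. **Annotate** — each annotator worker tags every section independently
   and emits one *part* message per document.
5. **Gather + aggregate** — parts are collected per `(communication_id,
   document_id)` until `total_annotators` have arrived, and documents per
   `communication_id` until `total_documents` have, at which point one
   response is emitted.  This count-based completeness tracking needs no
   shared database; the counts stamped at split/scatter time travel in the
   message headers.  Overlapping annotations are all retained unmodified —
   no silent merging.

Delivery is **at-least-once**: after a crash, unacknowledged messages are
redelivered, so every consumer is idempotent — the aggregator dedupes
parts by `(communication_id, document_id, annotator)`, and result handlers
dedupe by `communication_id` (exactly-once *effect*).  The aggregate stage
holds the delivery tags of all collected parts and acknowledges them only
together with the emitted response; a crash therefore leaves the partial
aggregation recoverable from the journal, and restart rebuilds it from the
redelivered parts.

## Message bus

The bus contract (publish / consume / ack / purge-expired, priority
ordering, redelivery) is normative; the default backend is in-process with
an append-only newline-JSON journal (`pub`/`declare`/`consume`/`ack`/
`drop` records).  Replay reconstructs ready messages, counts
unacknowledged consumes as redeliveries (`delivery_count` += 1 each), and
truncates the journal to the surviving state.

Numerical/semantic choices:

* **Priority** is an integer 0–9 (9 = most urgent) because that is the
  level range typical brokers support.  Ready messages are delivered
  priority-descending, FIFO within equal priority.  Redelivered messages
  re-enter at their original priority (their deadline has not changed).
* **Expiry is inclusive**: a message with `expiry_time ≤ now` is dropped,
  never delivered.  Expired *partial aggregations* are likewise dropped
  and logged — no partial response is ever delivered, which keeps the
  output contract simple (exactly one complete response or nothing).
* **Backpressure**: the bus has a total depth cap; when reached, the
  frontend denies new requests with a retry-later status rather than
  accepting work it cannot store.

## Deadline-derived priority

`priority = clamp(9 − ⌊slack / EMA⌋, 0, 9)`, with `slack` the seconds
until the request's expiry and `EMA` the exponential moving average of
completed request durations (smoothing α = 0.2, initialized at 1 s before
any completion).  The quantization is monotone (smaller slack never yields
lower priority) and stateless per request; the EMA adapts the unit of
"urgency" to the workload actually observed.  A request with non-positive
slack is rejected at validation; the priority function defensively returns
9 if it is ever reached with one.  Note the resolution consequence: while
the EMA is small, two deadlines that are both many EMA-units away quantize
to the same priority and fall back to FIFO order.

## Retry policy

Remote document providers fail mostly by being temporarily unavailable, so
fetches retry with capped exponential backoff: delay before retry *k* is
`min(1 s · 2^(k−1), 60 s)`.  After `max_attempts = 7` consecutive failures
the whole batch is marked unavailable — the cumulative wait (63 s) is then
in the same regime as the cap, which balances "never advancing" against
"giving up too early".  Unavailable documents are logged, never surfaced
as errors: downstream treats them as empty text and the request completes.
Result post-back uses the same policy, with the extra rule that HTTP 4xx
is permanent (one attempt, dead-letter) while 5xx/timeouts are transient.
The default bulk-fetch batch size is 25 ids per adapter invocation.
Sleeping goes through an injectable clock so tests assert the exact delay
sequence without waiting.

## Built-in annotators

All taggers emit standoff annotations satisfying
`text[start:end] == annotation.text` and a fixed confidence score of 1.0
(they are rule-based; no calibrated probability exists to report).
Output is sorted by (section, start, end); ties cannot occur within one
tagger because matching is leftmost-longest and non-overlapping.

* **miRNA** — regex grammar per community nomenclature: optional species
  prefix (3–4 lowercase letters + hyphen), stem `miR`/`MiR`/`mir`/`let`/
  `lin`, hyphen, 1–4 digits, optional lowercase letter, optional `-digit`
  paralog, optional `-3p`/`-5p` arm, word-boundary delimited.  Greedy
  matching makes the longest reading win (`miR-21-5p`, not `miR-21`).
* **Mutation** — an HGVS-style subset: one-letter protein substitutions
  (`V600E`; both letters must be valid amino-acid codes and the position
  ≥ 1, so gene-like tokens such as `E2F4` are rejected by the
  letter–digits–letter shape), three-letter forms with optional `p.`
  (`p.Val600Glu`), and coding-DNA substitutions (`c.1799T>A`).  Full
  variant-nomenclature parsing (indels, frameshifts, intronic offsets) is
  out of scope.
* **Dictionary lookup** (disease, and toy vocabularies for chemical /
  gene / organism so all six types are routable) — terms are normalized
  (lower-case, whitespace-collapsed, edge punctuation stripped) and
  matched greedily leftmost-longest over token windows up to the longest
  term's token count.  Matches must align to token boundaries
  (`anticancer` never matches `cancer`); hyphenated spans count as one
  token; the annotation text preserves the input's original casing.  The
  packaged vocabularies are small synthetic demonstration lists; a
  production deployment would load a full terminology (e.g. a UMLS-derived
  disease list) through the same TSV loader.

`safe_annotate` wraps every tagger call: any exception becomes zero
annotations plus one structured error log entry, so a faulty third-party
annotator degrades output but never stalls a request or the back end.
Annotators can also be hosted out-of-process via a newline-JSON
stdin/stdout bridge; because the tagging code is deterministic, the bridge
produces byte-identical annotation sets to the embedded run.

## Synthetic corpus generator

The generator emulates the *shape* of annotation-service input — documents
with title and abstract sections containing entity mentions — not
biomedical language.  Filler text is drawn from a fixed lorem-style
vocabulary screened against every positive grammar (all-lowercase
alphabetic words: no digits for the mutation grammar, no hyphen–digit for
the miRNA grammar, disjoint from all dictionary terms), so planted
mentions are the *complete* ground truth and both recall and precision
against the gold file are exact, not estimated.  Mentions are drawn from
the taggers' own positive grammars; near-miss negatives (`smirnoff`,
`E2F4`, `anticancer`, `mirage`, `H2O2`, `letters`) are planted at a
configurable rate (default mean 0.5 per section).

Counts per section and type are Poisson(density); positions are uniform
over token gaps with at most one planted string per gap, so plants never
touch (mention boundaries stay unambiguous).  Titles are 8–14 filler
tokens, abstracts 40–80.  `(corpus, gold)` is a pure function of
`(n_docs, densities, seed)` — byte-identical across runs.

What passing these tests does **not** show: recall on real biomedical
prose (real mentions exhibit nomenclature variation beyond the grammars),
robustness to markup/encoding noise, or the behaviour of the third-party
taggers a production deployment would register for chemicals, genes and
organisms.

## Test problem sizes

System-level tests use deliberately small workloads — a 100-document
corpus (densities 2/2/2 per section for mutation/miRNA/disease) for the
recall check, 40 requests × 5 documents (200 document messages, 50 of
them consumed-but-unacknowledged at the injected crash) for recovery, 20
buffered requests for priority ordering, and 60 documents for the
parallelism-invariance comparison.  The properties under test (multiset
equality, exact recall, ordering) are size-independent; these sizes keep
the suite fast while still exercising every queue hop.

## Known limitations

* The in-process journal backend serializes bus operations under one
  lock; it is built for correctness and testability, not broker-scale
  throughput.  An external broker can implement the same contract.
* Exactly-once delivery is not attempted; idempotent consumers are the
  mechanism of record.
* The priority formula's EMA is global, not per-source; heterogeneous
  corpora with very different fetch times blur the urgency estimate.
* Entity normalization beyond the dictionary's concept identifier (e.g.
  linking mutations to reference sequences) is out of scope.
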