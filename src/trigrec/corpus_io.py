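"""Corpus containers and I/O for trigger-annotated text.

Two on-disk dialects are supported:

* **BioNLP standoff** — raw text (``.txt``) with entity (``.a1``) and trigger
  (``.a2``) annotations referenced by character offsets (0-based, half-open),
  one ``T`` line per annotation::

      T1<TAB>Gene_expression 12 22<TAB>expression

* **CoNLL-style columns** — one token per row with whitespace-separated
  columns (default schema: token, POS, entity type, dependency-context word,
  trigger tag), blank lines between sentences and ``#doc`` lines between
  documents.

Tags are raw type-per-token (no BIO prefixes): a token inside a trigger span
carries that trigger's event type, every other token carries the negative
label.  Adjacent same-type tokens are merged into a single span only when
writing standoff.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .errors import AmbiguityError, IntegrityError, ParseError

NEGATIVE_LABEL = "O"
ABSENT = "-"

DEFAULT_SCHEMA = ("token", "pos", "entity", "dep", "tag")

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)
_STANDOFF_T_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class TriggerAnnotation:
    """A typed text span: ``id`` like "T1", 0-based half-open offsets."""

    id: str
    type: str
    start: int
    end: int
    surface: str

    def validate(self, text: str | None = None) -> None:
        if not (0 <= self.start < self.end):
            raise IntegrityError(f"{self.id}: invalid span [{self.start}, {self.end})")
        if text is not None:
            if self.end > len(text):
                raise IntegrityError(
                    f"{self.id}: end {self.end} beyond text length {len(text)}")
            if text[self.start:self.end] != self.surface:
                raise IntegrityError(
                    f"{self.id}: surface {self.surface!r} does not match text slice "
                    f"{text[self.start:self.end]!r}")


@dataclass
class Token:
    """One token with its feature columns and gold trigger tag."""

    surface: str
    pos: str = "NN"
    entity_type: str | None = None
    dep_word: str | None = None
    tag: str = NEGATIVE_LABEL
    start: int | None = None
    end: int | None = None


Sentence = list  # list[Token]
Document = list  # list[Sentence]


@dataclass
class Corpus:
    """A list of documents (each a list of sentences) from one domain."""

    domain: str
    documents: list = field(default_factory=list)

    def sentences(self):
        for doc in self.documents:
            yield from doc

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_sentences(self) -> int:
        return sum(len(d) for d in self.documents)


@dataclass(frozen=True)
class LabelSet:
    """Ordered trigger-type inventory plus the negative (no-event) tag."""

    labels: tuple
    negative_label: str = NEGATIVE_LABEL

    def __post_init__(self):
        if self.negative_label in self.labels:
            raise IntegrityError("negative label must not appear among trigger labels")
        if len(set(self.labels)) != len(self.labels):
            raise IntegrityError("duplicate trigger labels")

    @property
    def tags(self) -> tuple:
        """Full tag inventory, negative tag first."""
        return (self.negative_label,) + tuple(self.labels)

    @property
    def tag_count(self) -> int:
        return len(self.labels) + 1

    def tag_index(self) -> dict:
        return {t: i for i, t in enumerate(self.tags)}


@dataclass(frozen=True)
class OverlapPartition:
    """Shared / source-only / target-only split of two trigger inventories."""

    shared: tuple
    source_only: tuple
    target_only: tuple


def compute_label_overlap(source: LabelSet, target: LabelSet) -> OverlapPartition:
    """Partition two trigger inventories by label-name equality.

    Negative labels are never counted as shared trigger labels.  Order within
    each part follows the source (resp. target) inventory order.
    """
    tgt = set(target.labels)
    src = set(source.labels)
    shared = tuple(l for l in source.labels if l in tgt)
    source_only = tuple(l for l in source.labels if l not in tgt)
    target_only = tuple(l for l in target.labels if l not in src)
    return OverlapPartition(shared, source_only, target_only)


# ---------------------------------------------------------------------------
# tokenization

def tokenize(text: str):
    """Whitespace + punctuation tokenizer returning (surface, start, end)."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# standoff dialect

def _parse_standoff_lines(content: str, text: str | None):
    annotations = []
    for lineno, line in enumerate(content.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            # E/R/M lines (event structure etc.) are outside our scope.
            continue
        m = _STANDOFF_T_RE.match(line)
        if m is None:
            raise ParseError(f"malformed standoff T line: {line!r}", line=lineno)
        ann = TriggerAnnotation(m.group(1), m.group(2), int(m.group(3)),
                                int(m.group(4)), m.group(5))
        ann.validate(text)
        annotations.append(ann)
    return annotations


def read_standoff(text: str, a1: str = "", a2: str = ""):
    """Parse a standoff triple; returns (entity annotations, trigger annotations).

    Entities come from ``.a1`` content, triggers from ``.a2``; both are
    validated against the raw text (offset bounds and surface/slice match).
    """
    entities = _parse_standoff_lines(a1, text)
    triggers = _parse_standoff_lines(a2, text)
    return entities, triggers


@dataclass(frozen=True)
class StandoffDoc:
    text: str
    a1: str
    a2: str


def _spans_from_column(tokens, value_of, negative):
    """Group maximal runs of adjacent same-label tokens into spans."""
    spans = []
    run_label, run_start, run_end = None, None, None
    for tok in tokens + [None]:
        label = None if tok is None else value_of(tok)
        if label == run_label and label is not None and tok.start == run_end + 1:
            run_end = tok.end - 1
            continue
        if run_label is not None and run_label != negative:
            spans.append((run_label, run_start, run_end + 1))
        if tok is None:
            break
        run_label, run_start, run_end = label, tok.start, tok.end - 1
    return spans


def assign_offsets(document) -> str:
    """Reconstruct a document text (space-joined tokens, newline-joined
    sentences) and record character offsets on every token in place."""
    pieces = []
    pos = 0
    for sentence in document:
        for i, tok in enumerate(sentence):
            if i > 0:
                pieces.append(" ")
                pos += 1
            tok.start = pos
            tok.end = pos + len(tok.surface)
            pieces.append(tok.surface)
            pos = tok.end
        pieces.append("\n")
        pos += 1
    return "".join(pieces)


def write_standoff(document) -> StandoffDoc:
    """Serialize one document to a standoff triple.

    Token offsets are (re)assigned from the reconstructed text.  Adjacent
    same-type trigger tokens become one trigger span; likewise entity tokens.
    """
    text = assign_offsets(document)
    a1_lines, a2_lines = [], []
    tid = 0
    for sentence in document:
        for label, start, end in _spans_from_column(
                list(sentence), lambda t: t.entity_type, None):
            tid += 1
            a1_lines.append(f"T{tid}\t{label} {start} {end}\t{text[start:end]}")
    for sentence in document:
        for label, start, end in _spans_from_column(
                list(sentence), lambda t: t.tag, NEGATIVE_LABEL):
            tid += 1
            a2_lines.append(f"T{tid}\t{label} {start} {end}\t{text[start:end]}")
    return StandoffDoc(text, "\n".join(a1_lines) + ("\n" if a1_lines else ""),
                       "\n".join(a2_lines) + ("\n" if a2_lines else ""))


def annotations_to_tags(tokens, annotations, negative_label=NEGATIVE_LABEL,
                        lenient=False):
    """Project span annotations onto per-token tags.

    A token overlapping a trigger span receives that trigger's type; all other
    tokens receive the negative label.  A token overlapping two triggers of
    different types raises :class:`AmbiguityError` unless ``lenient`` is set,
    in which case the first annotation (by start offset) wins.
    """
    anns = sorted(annotations, key=lambda a: (a.start, a.end))
    tags = []
    for tok in tokens:
        if tok.start is None or tok.end is None:
            raise IntegrityError("tokens must carry character offsets")
        hit = None
        for ann in anns:
            if ann.start < tok.end and tok.start < ann.end:  # overlap
                if hit is None:
                    hit = ann
                elif ann.type != hit.type and not lenient:
                    raise AmbiguityError(
                        f"token {tok.surface!r} [{tok.start},{tok.end}) overlaps "
                        f"triggers of types {hit.type!r} and {ann.type!r}")
        tags.append(hit.type if hit is not None else negative_label)
    return tags


def standoff_to_document(text: str, a1: str = "", a2: str = "", lenient=False):
    """Tokenize raw text and project standoff annotations onto token tags."""
    entities, triggers = read_standoff(text, a1, a2)
    document = []
    offset = 0
    for line in text.split("\n"):
        line_offset, offset = offset, offset + len(line) + 1
        if not line.strip():
            continue
        toks = [Token(s, start=line_offset + a, end=line_offset + b)
                for s, a, b in tokenize(line)]
        if not toks:
            continue
        tags = annotations_to_tags(toks, triggers, lenient=lenient)
        etags = annotations_to_tags(toks, entities, negative_label="", lenient=lenient)
        for tok, tag, etag in zip(toks, tags, etags):
            tok.tag = tag
            tok.entity_type = etag or None
        document.append(toks)
    return document


# ---------------------------------------------------------------------------
# CoNLL-column dialect

def write_conll(corpus: Corpus, schema=DEFAULT_SCHEMA) -> str:
    out = []
    for d, document in enumerate(corpus.documents):
        out.append(f"#doc {d}")
        for sentence in document:
            for tok in sentence:
                row = []
                for col in schema:
                    if col == "token":
                        row.append(tok.surface)
                    elif col == "pos":
                        row.append(tok.pos or ABSENT)
                    elif col == "entity":
                        row.append(tok.entity_type or ABSENT)
                    elif col == "dep":
                        row.append(tok.dep_word or ABSENT)
                    elif col == "tag":
                        row.append(tok.tag)
                    else:
                        raise ParseError(f"unknown schema column {col!r}")
                out.append("\t".join(row))
            out.append("")
    return "\n".join(out) + ("\n" if out else "")


def read_conll(content: str, schema=DEFAULT_SCHEMA, domain="corpus") -> Corpus:
    """Parse CoNLL-column content into a :class:`Corpus`.

    Columns absent from ``schema`` default to ``None`` (entity/dep) or the
    negative tag.  A row whose column count disagrees with the schema raises
    :class:`ParseError` with the row index.
    """
    col_of = {c: i for i, c in enumerate(schema)}
    if "token" not in col_of:
        raise ParseError("schema must contain a 'token' column")
    documents, sentence = [], []
    current_doc = None

    def flush_sentence():
        nonlocal sentence
        if sentence:
            current_doc.append(sentence)
            sentence = []

    for lineno, line in enumerate(content.splitlines(), start=1):
        if line.startswith("#doc"):
            if current_doc is not None:
                flush_sentence()
                documents.append(current_doc)
            current_doc = []
            continue
        if current_doc is None:
            current_doc = []
        if not line.strip():
            flush_sentence()
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != len(schema):
            raise ParseError(
                f"expected {len(schema)} columns, got {len(parts)}", line=lineno)

        def get(col, default=None):
            if col not in col_of:
                return default
            v = parts[col_of[col]]
            return None if v == ABSENT and col in ("entity", "dep") else v

        sentence.append(Token(
            surface=parts[col_of["token"]],
            pos=get("pos", "NN") or "NN",
            entity_type=get("entity"),
            dep_word=get("dep"),
            tag=get("tag", NEGATIVE_LABEL) or NEGATIVE_LABEL,
        ))
    if current_doc is not None:
        flush_sentence()
        documents.append(current_doc)
    return Corpus(domain=domain, documents=documents)


# ---------------------------------------------------------------------------
# statistics

@dataclass(frozen=True)
class CorpusStats:
    n_documents: int
    n_words: int
    n_triggers: int
    triggers_per_type: dict

    def __post_init__(self):
        assert self.n_triggers == sum(self.triggers_per_type.values())


def corpus_stats(corpus: Corpus, negative_label=NEGATIVE_LABEL) -> CorpusStats:
    """Document/word/trigger-instance counts (one instance per maximal run
    of adjacent same-type trigger tokens, matching standoff span grouping)."""
    n_words = 0
    per_type: Counter = Counter()
    for doc in corpus.documents:
        for sentence in doc:
            n_words += len(sentence)
            prev = negative_label
            for tok in sentence:
                if tok.tag != negative_label and tok.tag != prev:
                    per_type[tok.tag] += 1
                prev = tok.tag
    return CorpusStats(corpus.n_documents, n_words, sum(per_type.values()),
                       dict(per_type))
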