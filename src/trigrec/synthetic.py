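"""Seeded synthetic domain pairs for end-to-end testing without downloads.

The generator emulates the *statistical structure* of paired trigger
corpora, not biomedical language: sentences are background tokens with
single-token triggers inserted at a configurable density; trigger lexicons
are label-stamped synthetic stems shared across domains for overlapping
labels; entity columns come from per-domain inventories (the
domain-dependent feature); and a configurable fraction of trigger insertions
use *ambiguous* words whose label is determined by a marker word within a
±2-token window, forcing context modeling rather than lexicon lookup.

The generator is invertible by design: :func:`oracle_tag` recovers the gold
tags exactly (a learnability ceiling), while :func:`lexicon_tag` is the
context-blind baseline that breaks down as ambiguity rises.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import (Corpus, NEGATIVE_LABEL, Token, corpus_stats,
                        write_conll, write_standoff)
from .datasets import MLEE_TRIGGER_TYPES, ST09_TRIGGER_TYPES
from .errors import ConfigError

_POS_INVENTORY = ("NN", "VB", "JJ", "RB", "IN")
_MARKER_WINDOW = 2


def _slug(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9]", "", label).lower()


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings for one source/target domain pair.

    Overlap is implied by shared label names; lexicons of overlapping labels
    are identical in both domains by construction.  ``ambiguity`` is the
    fraction of trigger insertions drawn from the ambiguous-word pool;
    ``trigger_density`` the per-token probability of a trigger slot.
    """

    source_labels: tuple = ST09_TRIGGER_TYPES
    target_labels: tuple = MLEE_TRIGGER_TYPES
    lexicon_size: int = 2
    vocab_size: int = 50
    ambiguity: float = 0.0
    ambiguous_pool_size: int = 4
    sentence_length: tuple = (6, 10)
    trigger_density: float = 0.3
    entity_rate: float = 0.15
    source_entities: tuple = ("SrcProtein",)
    target_entities: tuple = ("TgtGene", "TgtCell", "TgtOrgan")
    n_source_docs: int = 36
    n_target_docs: int = 10
    sentences_per_doc: int = 4
    seed: int = 0

    def __post_init__(self):
        if not self.source_labels or not self.target_labels:
            raise ConfigError("label lists must be non-empty")
        if not (0.0 <= self.ambiguity <= 1.0):
            raise ConfigError("ambiguity rate must lie in [0, 1]")
        if self.trigger_density > 0 and self.lexicon_size < 1:
            raise ConfigError(
                "trigger lexicon too small for the requested density")
        if self.sentence_length[0] < 1 or self.sentence_length[0] > self.sentence_length[1]:
            raise ConfigError("invalid sentence-length range")


@dataclass
class GeneratorLedger:
    """Ground truth of one generation run.

    ``span_counts`` equals :func:`trigrec.corpus_io.corpus_stats` of the
    emitted corpora exactly; ``token_counts`` tallies individual trigger
    insertions (adjacent same-label insertions merge into one span).
    """

    lexicon: dict = field(default_factory=dict)         # word -> label
    ambiguous: tuple = ()                               # ambiguous words
    markers: dict = field(default_factory=dict)         # marker word -> label
    background_words: tuple = ()
    token_counts: dict = field(default_factory=dict)    # domain -> Counter
    span_counts: dict = field(default_factory=dict)     # domain -> Counter
    realized_majority: dict = field(default_factory=dict)  # word -> label

    def finalize_majority(self, uses: dict) -> None:
        for word, counter in uses.items():
            # deterministic tie-break: count desc, then label name
            self.realized_majority[word] = min(
                counter.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def _pos_of(word: str) -> str:
    return _POS_INVENTORY[sum(map(ord, word)) % len(_POS_INVENTORY)]


def _make_token(surface: str, entity=None, tag=NEGATIVE_LABEL) -> Token:
    return Token(surface=surface, pos=_pos_of(surface), entity_type=entity,
                 dep_word=None, tag=tag)


def _generate_sentence(rng, cfg: SynthConfig, labels, entities, lexicons,
                       amb_pool, token_counts, amb_uses):
    T = int(rng.integers(cfg.sentence_length[0], cfg.sentence_length[1] + 1))
    trigger_slots = [i for i in range(T) if rng.random() < cfg.trigger_density]
    surfaces = [None] * T
    tags = [NEGATIVE_LABEL] * T
    marker_slots: set = set()

    for i in trigger_slots:
        label = labels[int(rng.integers(len(labels)))]
        placed_amb = False
        if amb_pool and rng.random() < cfg.ambiguity:
            # marker must land on a background slot in the ±2 window, away
            # from other markers/ambiguous triggers so the mapping stays
            # invertible
            offsets = [o for o in (-2, -1, 1, 2) if 0 <= i + o < T]
            rng.shuffle(offsets)
            for o in offsets:
                m = i + o
                if m in trigger_slots or m in marker_slots:
                    continue
                if any(abs(m - j) <= _MARKER_WINDOW and j != i
                       for j in trigger_slots
                       if surfaces[j] is not None and surfaces[j] in amb_pool):
                    continue
                if any(abs(i - ms) <= _MARKER_WINDOW for ms in marker_slots):
                    continue
                word = amb_pool[int(rng.integers(len(amb_pool)))]
                surfaces[i] = word
                surfaces[m] = f"mk{_slug(label)}"
                marker_slots.add(m)
                amb_uses.setdefault(word, Counter())[label] += 1
                placed_amb = True
                break
        if not placed_amb:
            lex = lexicons[label]
            surfaces[i] = lex[int(rng.integers(len(lex)))]
        tags[i] = label
        token_counts[label] += 1

    for i in range(T):
        if surfaces[i] is None:
            surfaces[i] = f"w{int(rng.integers(cfg.vocab_size))}"

    sentence = []
    for i, (surface, tag) in enumerate(zip(surfaces, tags)):
        entity = None
        if (tag == NEGATIVE_LABEL and i not in marker_slots and entities
                and rng.random() < cfg.entity_rate):
            entity = entities[int(rng.integers(len(entities)))]
        sentence.append(_make_token(surface, entity=entity, tag=tag))
    # dependency-context word: previous token's surface (next for the first)
    for i, tok in enumerate(sentence):
        tok.dep_word = sentence[i - 1].surface if i > 0 else (
            sentence[1].surface if T > 1 else tok.surface)
    return sentence


def generate_domain_pair(cfg: SynthConfig):
    """Generate (source corpus, target corpus, ledger); same seed, same output."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    all_labels = tuple(dict.fromkeys(cfg.source_labels + cfg.target_labels))
    lexicons = {label: tuple(f"t{_slug(label)}{k}" for k in range(cfg.lexicon_size))
                for label in all_labels}
    amb_pool = (tuple(f"amb{k}" for k in range(cfg.ambiguous_pool_size))
                if cfg.ambiguity > 0 else ())
    ledger = GeneratorLedger(
        lexicon={w: label for label, words in lexicons.items() for w in words},
        ambiguous=amb_pool,
        markers={f"mk{_slug(label)}": label for label in all_labels},
        background_words=tuple(f"w{k}" for k in range(cfg.vocab_size)),
    )
    amb_uses: dict = {}
    corpora = {}
    for domain, labels, entities, n_docs in (
            ("source", cfg.source_labels, cfg.source_entities, cfg.n_source_docs),
            ("target", cfg.target_labels, cfg.target_entities, cfg.n_target_docs)):
        token_counts: Counter = Counter()
        documents = []
        for _ in range(n_docs):
            documents.append([
                _generate_sentence(rng, cfg, labels, entities, lexicons,
                                   amb_pool, token_counts, amb_uses)
                for _ in range(cfg.sentences_per_doc)])
        corpora[domain] = Corpus(domain=domain, documents=documents)
        ledger.token_counts[domain] = dict(token_counts)
        ledger.span_counts[domain] = dict(
            corpus_stats(corpora[domain]).triggers_per_type)
    ledger.finalize_majority(amb_uses)
    return corpora["source"], corpora["target"], ledger


def oracle_tag(sentence, ledger: GeneratorLedger):
    """Recover the generating labels exactly (the generator's inverse).

    Unambiguous lexicon words map to their label; ambiguous words take the
    label of the marker within ±2 tokens; everything else is negative.
    Raises on a word the ledger does not know.
    """
    known = (set(ledger.lexicon) | set(ledger.ambiguous) | set(ledger.markers)
             | set(ledger.background_words))
    surfaces = [t.surface for t in sentence]
    tags = []
    for i, surface in enumerate(surfaces):
        if surface not in known:
            raise ConfigError(f"word {surface!r} not in the generator ledger")
        if surface in ledger.lexicon:
            tags.append(ledger.lexicon[surface])
        elif surface in ledger.ambiguous:
            label = NEGATIVE_LABEL
            for o in range(-_MARKER_WINDOW, _MARKER_WINDOW + 1):
                j = i + o
                if 0 <= j < len(surfaces) and surfaces[j] in ledger.markers:
                    label = ledger.markers[surfaces[j]]
                    break
            tags.append(label)
        else:
            tags.append(NEGATIVE_LABEL)
    return tags


def lexicon_tag(sentence, ledger: GeneratorLedger):
    """Context-blind baseline: tag each word by lexicon lookup alone
    (ambiguous words get their majority realized label)."""
    tags = []
    for tok in sentence:
        if tok.surface in ledger.lexicon:
            tags.append(ledger.lexicon[tok.surface])
        elif tok.surface in ledger.realized_majority:
            tags.append(ledger.realized_majority[tok.surface])
        else:
            tags.append(NEGATIVE_LABEL)
    return tags


@dataclass(frozen=True)
class FixtureSuite:
    source: Corpus
    target: Corpus
    ledger: GeneratorLedger
    paths: dict


def make_fixture_suite(seed: int, out_dir) -> FixtureSuite:
    """A mini domain pair mirroring the reference geometry: a 9-label source
    and a 19-label target sharing 9 labels, with the source about 3.6x the
    target's document count.  Regeneration with the same seed is
    byte-identical; both dialects are emitted."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = SynthConfig(n_source_docs=36, n_target_docs=10, seed=seed,
                      ambiguity=0.3)
    source, target, ledger = generate_domain_pair(cfg)
    paths = {}
    for name, corpus in (("source", source), ("target", target)):
        p = out_dir / f"{name}.conll"
        p.write_text(write_conll(corpus), encoding="utf-8")
        paths[name] = p
    standoff = write_standoff(target.documents[0])
    for ext, content in (("txt", standoff.text), ("a1", standoff.a1),
                         ("a2", standoff.a2)):
        p = out_dir / f"target_doc0.{ext}"
        p.write_text(content, encoding="utf-8")
        paths[f"target_doc0.{ext}"] = p
    return FixtureSuite(source, target, ledger, paths)
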