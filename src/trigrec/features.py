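"""Input features: vocabularies, embedding configuration and token encoding.

Each token is represented by the concatenation of five channels::

    x_i = [word ; char ; POS ; entity ; dep]

where the char channel is the final hidden state of a character-level LSTM
run over the token's characters, and the other four are lookup-table rows.
The word/char/POS/dep channels are domain-independent; the entity channel is
domain-dependent (its inventory and dimensionality differ between source and
target domains), which is what drives vertical parameter partitioning in
transfer plans.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus_io import Corpus
from .errors import ConfigError, ParseError

PAD = "<pad>"
UNK = "<unk>"
NONE_ENTITY = "<none>"

CHANNELS = ("word", "char", "pos", "entity", "dep")


@dataclass(frozen=True)
class FeatureConfig:
    """Dimensions and activation flags of the five input channels.

    Defaults follow the reference setting: 200-dim word, 100-dim char,
    50-dim POS, 300-dim dependency-context embeddings, and a 10-dim
    (source domain) or 50-dim (target domain) entity-type embedding.
    ``dim_char`` is the char-LSTM hidden size (= the channel width);
    ``dim_char_in`` the per-character input embedding size.
    """

    dim_word: int = 200
    dim_char: int = 100
    dim_char_in: int = 30
    dim_pos: int = 50
    dim_entity: int = 50
    dim_dep: int = 300
    use_word: bool = True
    use_char: bool = True
    use_pos: bool = True
    use_entity: bool = True
    use_dep: bool = True
    lowercase_fallback: bool = True

    def __post_init__(self):
        for name in ("dim_word", "dim_char", "dim_char_in", "dim_pos",
                     "dim_entity", "dim_dep"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def source_default(cls) -> "FeatureConfig":
        return cls(dim_entity=10)

    @classmethod
    def target_default(cls) -> "FeatureConfig":
        return cls(dim_entity=50)

    def channel_dims(self) -> dict:
        """Active channel -> width, in fixed concatenation order."""
        dims = {}
        if self.use_word:
            dims["word"] = self.dim_word
        if self.use_char:
            dims["char"] = self.dim_char
        if self.use_pos:
            dims["pos"] = self.dim_pos
        if self.use_entity:
            dims["entity"] = self.dim_entity
        if self.use_dep:
            dims["dep"] = self.dim_dep
        return dims

    @property
    def total_dim(self) -> int:
        return sum(self.channel_dims().values())

    def channel_ranges(self) -> dict:
        """Active channel -> (start, stop) slice of the concatenated vector."""
        ranges, pos = {}, 0
        for name, d in self.channel_dims().items():
            ranges[name] = (pos, pos + d)
            pos += d
        return ranges


@dataclass
class Vocab:
    """Symbol -> dense index maps with reserved PAD (0) and UNK (1) slots."""

    words: dict = field(default_factory=dict)
    chars: dict = field(default_factory=dict)
    pos: dict = field(default_factory=dict)
    entities: dict = field(default_factory=dict)
    deps: dict = field(default_factory=dict)

    def sizes(self) -> dict:
        return {"word": len(self.words), "char": len(self.chars),
                "pos": len(self.pos), "entity": len(self.entities),
                "dep": len(self.deps)}


def _index(counter: Counter, min_count: int, extra=()) -> dict:
    mapping = {PAD: 0, UNK: 1}
    for sym in extra:
        mapping.setdefault(sym, len(mapping))
    # deterministic: frequency-descending, then lexicographic
    for sym, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])):
        if n >= min_count:
            mapping.setdefault(sym, len(mapping))
    return mapping


def build_vocab(corpus, min_count: int = 1, extra_corpora=()) -> Vocab:
    """Index every symbol with frequency >= min_count; rarer symbols fold to
    UNK at encode time.  ``extra_corpora`` contribute to the shared channels
    (word/char/POS/dep) but not to the entity map, which stays domain-local.
    """
    words, chars, pos, ents, deps = (Counter() for _ in range(5))
    for c, own in [(corpus, True)] + [(c, False) for c in extra_corpora]:
        for sentence in c.sentences():
            for tok in sentence:
                words[tok.surface] += 1
                chars.update(tok.surface)
                pos[tok.pos] += 1
                if own and tok.entity_type is not None:
                    ents[tok.entity_type] += 1
                if tok.dep_word is not None:
                    deps[tok.dep_word] += 1
    return Vocab(
        words=_index(words, min_count),
        chars=_index(chars, min_count),
        pos=_index(pos, min_count),
        entities=_index(ents, min_count, extra=(NONE_ENTITY,)),
        deps=_index(deps, min_count),
    )


def build_transfer_vocabs(source: Corpus, target: Corpus, min_count: int = 1):
    """Vocabularies for a domain pair: word/char/POS/dep maps are built
    jointly (so shared embedding tables index identically in both networks);
    each domain keeps its own entity map."""
    src = build_vocab(source, min_count, extra_corpora=(target,))
    tgt = build_vocab(target, min_count, extra_corpora=(source,))
    tgt = replace_shared_maps(tgt, src)
    return src, tgt


def replace_shared_maps(vocab: Vocab, reference: Vocab) -> Vocab:
    return Vocab(words=reference.words, chars=reference.chars,
                 pos=reference.pos, entities=vocab.entities,
                 deps=reference.deps)


def _lookup(mapping: dict, symbol, lowercase_fallback=False) -> int:
    idx = mapping.get(symbol)
    if idx is None and lowercase_fallback and isinstance(symbol, str):
        idx = mapping.get(symbol.lower())
    return mapping[UNK] if idx is None else idx


@dataclass(frozen=True)
class EncodedSentence:
    """Index arrays for one sentence, ready for the network graph."""

    word: np.ndarray          # (T,)
    chars: tuple              # T arrays of char indices
    pos: np.ndarray           # (T,)
    entity: np.ndarray        # (T,)
    dep: np.ndarray           # (T,)
    tags: np.ndarray          # (T,) gold tag indices

    def __len__(self):
        return len(self.word)


def encode_sentence(sentence, vocab: Vocab, tag_index: dict,
                    config: FeatureConfig) -> EncodedSentence:
    word, pos, ent, dep, tags = [], [], [], [], []
    chars = []
    for tok in sentence:
        word.append(_lookup(vocab.words, tok.surface, config.lowercase_fallback))
        chars.append(np.array([_lookup(vocab.chars, c) for c in tok.surface],
                              dtype=np.intp))
        pos.append(_lookup(vocab.pos, tok.pos))
        ent.append(_lookup(vocab.entities,
                           NONE_ENTITY if tok.entity_type is None else tok.entity_type))
        dep.append(_lookup(vocab.deps, tok.dep_word) if tok.dep_word is not None
                   else vocab.deps[UNK])
        tags.append(tag_index.get(tok.tag, 0))
    return EncodedSentence(np.array(word, dtype=np.intp), tuple(chars),
                           np.array(pos, dtype=np.intp), np.array(ent, dtype=np.intp),
                           np.array(dep, dtype=np.intp), np.array(tags, dtype=np.intp))


def char_lstm_embed(char_indices, char_table: np.ndarray, char_lstm: dict,
                    peephole: bool = True) -> np.ndarray:
    """Character-channel embedding: final hidden state of a unidirectional
    LSTM over the word's character embeddings.  Deterministic given
    parameters; components bounded in (-1, 1)."""
    from .network import lstm_step_np

    char_indices = np.asarray(char_indices, dtype=np.intp)
    if char_indices.size == 0:
        raise ConfigError("cannot embed an empty word")
    hidden = char_lstm["W_h"].shape[0]
    h = np.zeros(hidden)
    c = np.zeros(hidden)
    for idx in char_indices:
        h, c = lstm_step_np(char_table[idx], h, c, char_lstm, peephole=peephole)
    return h


def embed_token(token, bundle, vocab: Vocab, config: FeatureConfig,
                peephole: bool = True) -> np.ndarray:
    """Concatenated input vector for one token (inference path).

    Channel order is fixed: [word, char, POS, entity, dep]; unknown symbols
    fold to UNK.  A pure function of (token, parameters, config).
    """
    blocks = bundle.blocks if hasattr(bundle, "blocks") else bundle
    parts = []
    if config.use_word:
        parts.append(blocks["emb.word"][
            _lookup(vocab.words, token.surface, config.lowercase_fallback)])
    if config.use_char:
        idx = np.array([_lookup(vocab.chars, c) for c in token.surface], dtype=np.intp)
        char_lstm = {k.split(".")[-1]: blocks[k] for k in blocks
                     if k.startswith("emb.char_lstm.")}
        parts.append(char_lstm_embed(idx, blocks["emb.char"], char_lstm,
                                     peephole=peephole))
    if config.use_pos:
        parts.append(blocks["emb.pos"][_lookup(vocab.pos, token.pos)])
    if config.use_entity:
        sym = NONE_ENTITY if token.entity_type is None else token.entity_type
        parts.append(blocks["emb.entity"][_lookup(vocab.entities, sym)])
    if config.use_dep:
        idx = (_lookup(vocab.deps, token.dep_word)
               if token.dep_word is not None else vocab.deps[UNK])
        parts.append(blocks["emb.dep"][idx])
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# word2vec text format

_W2V_HEADER_RE = re.compile(r"^(\d+)\s+(\d+)\s*$")


def load_word2vec_text(stream, expected_dim: int | None = None) -> dict:
    """Read a word2vec text table ("N D" header, then "word v1 .. vD" rows).

    Rows whose dimensionality disagrees with the header (or with
    ``expected_dim``) are rejected with :class:`ParseError`.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]
    if not lines:
        raise ParseError("empty word2vec file")
    m = _W2V_HEADER_RE.match(lines[0])
    if m is None:
        raise ParseError(f"malformed word2vec header: {lines[0]!r}", line=1)
    n, dim = int(m.group(1)), int(m.group(2))
    if expected_dim is not None and dim != expected_dim:
        raise ParseError(f"table dimension {dim} != expected {expected_dim}")
    table = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != dim + 1:
            raise ParseError(
                f"expected {dim + 1} fields, got {len(parts)}", line=lineno)
        table[parts[0]] = np.array([float(v) for v in parts[1:]])
    if len(table) != n:
        raise ParseError(f"header promised {n} rows, found {len(table)}")
    return table


def save_word2vec_text(table: dict, precision: int = 8) -> str:
    if not table:
        return "0 0\n"
    dim = len(next(iter(table.values())))
    lines = [f"{len(table)} {dim}"]
    for word, vec in table.items():
        lines.append(word + " " + " ".join(f"{v:.{precision}g}" for v in vec))
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CoverageReport:
    """Which vocabulary words a pre-trained table covered."""

    found: int
    missing: tuple

    @property
    def total(self) -> int:
        return self.found + len(self.missing)

    @property
    def fraction(self) -> float:
        return self.found / self.total if self.total else 0.0


def load_pretrained_into(bundle, vocab: Vocab, table: dict,
                         channel: str = "word",
                         freeze: bool = True) -> CoverageReport:
    """Install a pre-trained table into a bundle's word or dep channel.

    Vocabulary words missing from the table keep their random rows.  The
    block is frozen (excluded from training) by default, the convention for
    externally trained tables; pass ``freeze=False`` to fine-tune it.
    """
    if channel not in ("word", "dep"):
        raise ConfigError("pre-trained tables attach to 'word' or 'dep'")
    symbol_map = vocab.words if channel == "word" else vocab.deps
    report = apply_pretrained(bundle.blocks[f"emb.{channel}"], symbol_map, table)
    frozen = set(bundle.meta.get("frozen", ()))
    if freeze:
        frozen.add(f"emb.{channel}")
    else:
        frozen.discard(f"emb.{channel}")
    bundle.meta["frozen"] = sorted(frozen)
    return report


def apply_pretrained(matrix: np.ndarray, symbol_map: dict, table: dict,
                     lowercase_fallback: bool = True) -> CoverageReport:
    """Overwrite rows of an embedding matrix with pre-trained vectors.

    Vocabulary words absent from the table keep their random initialization
    and are flagged in the returned coverage report.  PAD/UNK are not counted.
    """
    found, missing = 0, []
    for sym, idx in symbol_map.items():
        if sym in (PAD, UNK):
            continue
        vec = table.get(sym)
        if vec is None and lowercase_fallback:
            vec = table.get(sym.lower())
        if vec is None:
            missing.append(sym)
            continue
        if len(vec) != matrix.shape[1]:
            raise ParseError(f"vector for {sym!r} has dim {len(vec)}, "
                             f"table dim {matrix.shape[1]}")
        matrix[idx] = vec
        found += 1
    return CoverageReport(found, tuple(missing))
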