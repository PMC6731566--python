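"""Cross-domain transfer learning with vertically partitioned parameters.

Classic layer-wise ("horizontal") transfer either shares a whole layer or
discards it: with disjoint label sets the output layer cannot be shared
(Model B), and with inconsistent input feature sets the recurrent layer
cannot be shared either (Model C, embedding tables only).  The generalized
scheme (variant D) instead splits every layer's parameters *vertically* into
a domain-shared and a domain-specific block, driven by the overlap of the
feature channels and of the label sets:

* embedding layer — lookup tables of domain-independent channels
  (word, char, POS, dependency-context) are shared; domain-dependent
  channels (entity type, whose inventory and width differ per domain) stay
  specific;
* BiLSTM layer — recurrent, peephole and bias blocks are shared, and the
  input-weight rows are shared for the shared channels only (the
  input-side vertical partition);
* fully-connected layer — the hidden block is shared, and the label
  projection is partitioned by output: rows (and biases) of labels present
  in both inventories are shared, the rest stay specific;
* CRF transitions are never transferred (an experimental config flag can
  share them between identical label sets).

With an empty label overlap the variant-D plan degenerates exactly to the
Model B plan (identical feature sets) or the Model C plan (inconsistent
feature sets).

Training runs in three phases: (1) fit the source network on the
(ratio-subsampled) source corpus; (2) copy every plan-shared block into a
freshly initialized target bundle; (3) fit the target network on the target
corpus, updating shared and specific parameters alike.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import network
from .config import TrainConfig
from .corpus_io import Corpus, LabelSet, compute_label_overlap
from .errors import ConfigError, PlanError
from .features import CHANNELS, FeatureConfig, build_transfer_vocabs
from .models import TriggerModel, TriggerResults
from .network import ParameterBundle

CELL_SUFFIXES = ("W_x", "W_h", "p_i", "p_f", "p_o", "b")


@dataclass(frozen=True)
class DomainSpec:
    """One domain's label inventory, feature configuration and the channels
    whose parameters are domain-dependent (entity type by default)."""

    name: str
    label_set: LabelSet
    feature_config: FeatureConfig
    domain_dependent_channels: tuple = ("entity",)


@dataclass(frozen=True)
class SharedBlock:
    """One shared block address with optional index maps.

    ``src_index``/``tgt_index`` select entries along ``axis`` (rows of the
    BiLSTM input weights grouped by channel; columns of the label projection
    indexed by tag).  ``both_axes`` applies the maps to both axes (CRF
    transitions).  ``None`` indices mean the whole block.
    """

    block: str
    axis: int = 0
    src_index: tuple | None = None
    tgt_index: tuple | None = None
    both_axes: bool = False


@dataclass(frozen=True)
class TransferPlan:
    """The machine-readable statement of which blocks two domains share."""

    variant: str
    shared: tuple  # of SharedBlock
    source_domain: str = ""
    target_domain: str = ""

    def is_empty(self) -> bool:
        return len(self.shared) == 0

    def block_names(self) -> tuple:
        return tuple(s.block for s in self.shared)

    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant,
            "source_domain": self.source_domain,
            "target_domain": self.target_domain,
            "shared": [{"block": s.block, "axis": s.axis,
                        "src_index": None if s.src_index is None else list(s.src_index),
                        "tgt_index": None if s.tgt_index is None else list(s.tgt_index),
                        "both_axes": s.both_axes}
                       for s in self.shared],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TransferPlan":
        d = json.loads(text)
        shared = tuple(SharedBlock(
            s["block"], s["axis"],
            None if s["src_index"] is None else tuple(s["src_index"]),
            None if s["tgt_index"] is None else tuple(s["tgt_index"]),
            s["both_axes"]) for s in d["shared"])
        return cls(d["variant"], shared, d["source_domain"], d["target_domain"])


def _shareable_channels(source: DomainSpec, target: DomainSpec) -> tuple:
    """Channels shared between two domains: active in both, equal width,
    domain-independent in both."""
    s_dims = source.feature_config.channel_dims()
    t_dims = target.feature_config.channel_dims()
    out = []
    for ch in CHANNELS:
        if ch not in s_dims or ch not in t_dims:
            continue
        if s_dims[ch] != t_dims[ch]:
            continue
        if ch in source.domain_dependent_channels or ch in target.domain_dependent_channels:
            continue
        out.append(ch)
    return tuple(out)


def _features_identical(source: DomainSpec, target: DomainSpec) -> bool:
    return (_shareable_channels(source, target)
            == tuple(source.feature_config.channel_dims())
            == tuple(target.feature_config.channel_dims()))


def _embedding_blocks(channels) -> list:
    blocks = []
    for ch in channels:
        blocks.append(SharedBlock(f"emb.{ch}"))
        if ch == "char":
            blocks.extend(SharedBlock(f"emb.char_lstm.{s}") for s in CELL_SUFFIXES)
    return blocks


def _bilstm_blocks(source: DomainSpec, target: DomainSpec, channels) -> list:
    """Recurrent/peephole/bias blocks fully shared; input-weight rows shared
    for the shared channels through per-domain row-index maps."""
    s_ranges = source.feature_config.channel_ranges()
    t_ranges = target.feature_config.channel_ranges()
    full_rows = channels == tuple(s_ranges) == tuple(t_ranges)
    src_rows = tuple(i for ch in channels for i in range(*s_ranges[ch]))
    tgt_rows = tuple(i for ch in channels for i in range(*t_ranges[ch]))
    blocks = []
    for d in ("f", "b"):
        if full_rows:
            blocks.append(SharedBlock(f"lstm.{d}.W_x"))
        else:
            blocks.append(SharedBlock(f"lstm.{d}.W_x", axis=0,
                                      src_index=src_rows, tgt_index=tgt_rows))
        for s in ("W_h", "p_i", "p_f", "p_o", "b"):
            blocks.append(SharedBlock(f"lstm.{d}.{s}"))
    return blocks


def build_transfer_plan(source: DomainSpec, target: DomainSpec,
                        variant: str = "D",
                        share_crf: bool = False) -> TransferPlan:
    """Construct the sharing plan for one of the four model variants.

    * ``A`` — no transfer: the empty plan.
    * ``B`` — identical feature sets, disjoint labels: all embedding tables
      and the full BiLSTM; nothing from the fully-connected layer.
    * ``C`` — inconsistent feature sets: domain-independent embedding tables
      only.
    * ``D`` — the generalized plan: shared-channel embeddings; when the
      label overlap is non-empty also the vertically partitioned BiLSTM, the
      FC hidden block and the shared-label projection rows.  With an empty
      overlap it degenerates to B or C according to feature consistency.
    """
    variant = variant.upper()
    if variant not in "ABCD" or len(variant) != 1:
        raise ConfigError(f"unknown transfer variant {variant!r}")
    shareable = _shareable_channels(source, target)
    identical = _features_identical(source, target)
    overlap = compute_label_overlap(source.label_set, target.label_set)
    blocks: list = []

    if variant == "A":
        blocks = []
    elif variant == "B":
        if not identical:
            raise PlanError(
                "variant B requires identical source/target feature sets; "
                f"shapes conflict outside channels {shareable}")
        blocks = _embedding_blocks(shareable) + _bilstm_blocks(source, target,
                                                               shareable)
    elif variant == "C":
        blocks = _embedding_blocks(shareable)
    else:  # D
        blocks = _embedding_blocks(shareable)
        if overlap.shared:
            blocks += _bilstm_blocks(source, target, shareable)
            blocks += [SharedBlock("fc.W"), SharedBlock("fc.b")]
            s_tags = {t: i for i, t in enumerate(source.label_set.tags)}
            t_tags = {t: i for i, t in enumerate(target.label_set.tags)}
            shared_labels = overlap.shared
            src_cols = tuple(s_tags[l] for l in shared_labels)
            tgt_cols = tuple(t_tags[l] for l in shared_labels)
            blocks.append(SharedBlock("proj.W", axis=1,
                                      src_index=src_cols, tgt_index=tgt_cols))
            blocks.append(SharedBlock("proj.b", axis=0,
                                      src_index=src_cols, tgt_index=tgt_cols))
            if share_crf:
                if tuple(source.label_set.tags) == tuple(target.label_set.tags):
                    blocks.append(SharedBlock("crf.trans"))
                else:
                    n_s = source.label_set.tag_count
                    n_t = target.label_set.tag_count
                    src_ix = src_cols + (n_s, n_s + 1)
                    tgt_ix = tgt_cols + (n_t, n_t + 1)
                    blocks.append(SharedBlock("crf.trans", src_index=src_ix,
                                              tgt_index=tgt_ix, both_axes=True))
        elif identical:
            blocks += _bilstm_blocks(source, target, shareable)
    return TransferPlan(variant, tuple(blocks), source.name, target.name)


@dataclass(frozen=True)
class TransferAudit:
    """Which blocks a transfer actually copied, with parameter counts."""

    copied: tuple  # of (block address, n parameters)

    @property
    def total_params(self) -> int:
        return sum(n for _, n in self.copied)

    def block_names(self) -> tuple:
        return tuple(b for b, _ in self.copied)


def transfer_parameters(source_bundle: ParameterBundle, plan: TransferPlan,
                        target_bundle: ParameterBundle) -> TransferAudit:
    """Copy every plan-shared block from source to target (in place).

    Target-specific blocks are left at their initialization; CRF blocks are
    touched only if the plan explicitly lists them.  Idempotent.  Returns an
    audit of copied blocks and parameter counts.
    """
    copied = []
    for sb in plan.shared:
        if sb.block not in source_bundle.blocks:
            raise PlanError(f"source bundle missing block {sb.block!r}")
        if sb.block not in target_bundle.blocks:
            raise PlanError(f"target bundle missing block {sb.block!r}")
        src = source_bundle.blocks[sb.block]
        tgt = target_bundle.blocks[sb.block]
        if sb.src_index is None:
            if src.shape != tgt.shape:
                raise PlanError(
                    f"shape conflict on shared block {sb.block!r}: "
                    f"{src.shape} vs {tgt.shape}")
            tgt[...] = src
            copied.append((sb.block, int(src.size)))
        elif sb.both_axes:
            s_ix = np.asarray(sb.src_index, dtype=np.intp)
            t_ix = np.asarray(sb.tgt_index, dtype=np.intp)
            tgt[np.ix_(t_ix, t_ix)] = src[np.ix_(s_ix, s_ix)]
            copied.append((sb.block, int(len(s_ix) ** 2)))
        else:
            s_ix = np.asarray(sb.src_index, dtype=np.intp)
            t_ix = np.asarray(sb.tgt_index, dtype=np.intp)
            if len(s_ix) != len(t_ix):
                raise PlanError(f"index maps of {sb.block!r} differ in length")
            src_slice = np.take(src, s_ix, axis=sb.axis)
            expected = np.take(tgt, t_ix, axis=sb.axis).shape
            if src_slice.shape != expected:
                raise PlanError(
                    f"shape conflict on shared block {sb.block!r}: "
                    f"{src_slice.shape} vs {expected}")
            if sb.axis == 0:
                tgt[t_ix] = src_slice
            else:
                tgt[:, t_ix] = src_slice
            copied.append((sb.block, int(src_slice.size)))
    return TransferAudit(tuple(copied))


# ---------------------------------------------------------------------------
# partitioned-layer forward maps (the vertical-split laws)


def partitioned_middle_forward(x_specific, x_shared, W_specific, W_shared, b,
                               active_function=None) -> np.ndarray:
    """A middle layer whose input is split into specific/shared channel
    groups: equals the dense layer on the concatenated input with weights
    assembled from the two blocks; the bias is a shared parameter."""
    x_specific = np.asarray(x_specific, dtype=np.float64)
    x_shared = np.asarray(x_shared, dtype=np.float64)
    W_specific = np.asarray(W_specific, dtype=np.float64)
    W_shared = np.asarray(W_shared, dtype=np.float64)
    if x_specific.shape[-1] != W_specific.shape[0] \
            or x_shared.shape[-1] != W_shared.shape[0]:
        raise ConfigError("partitioned middle layer: block dims inconsistent")
    y = x_specific @ W_specific + x_shared @ W_shared + np.asarray(b)
    return active_function(y) if active_function is not None else y


def partitioned_output_forward(x, shared_rows: dict, specific_rows: dict,
                               tag_order, active_function=None) -> np.ndarray:
    """An output layer partitioned by label: the score of a shared label uses
    the shared row and bias, a specific label its specific row and bias;
    stacking all rows in tag order equals one dense projection."""
    x = np.asarray(x, dtype=np.float64)
    scores = np.empty(len(tag_order))
    for j, label in enumerate(tag_order):
        if label in shared_rows:
            w, b = shared_rows[label]
        elif label in specific_rows:
            w, b = specific_rows[label]
        else:
            raise ConfigError(f"label {label!r} in neither partition")
        scores[j] = x @ np.asarray(w) + b
    return active_function(scores) if active_function is not None else scores


# ---------------------------------------------------------------------------
# data subsampling and three-phase training


def subsample_source(corpus: Corpus, ratio: float, seed=0) -> Corpus:
    """Uniform document-level subset of size floor(ratio * n_documents),
    drawn without replacement; document order is preserved."""
    if not (0.0 <= ratio <= 1.0):
        raise ConfigError("ratio must lie in [0, 1]")
    n = corpus.n_documents
    k = int(np.floor(ratio * n))
    if k == n:
        return Corpus(corpus.domain, list(corpus.documents))
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=k, replace=False))
    return Corpus(corpus.domain, [corpus.documents[i] for i in keep])


def _derived_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0]
               >> 1)  # < 2**31


class TransferModel:
    """Three-phase transfer training of a target-domain tagger.

    Built from a source corpus, target train/dev corpora and the two
    :class:`DomainSpec`s; ``fit()`` returns a :class:`TransferResults`.
    With an empty plan (variant A, or a zero source ratio) the run collapses
    to the no-transfer baseline and is bit-identical to
    :func:`trigrec.models.train_basic` at the same seed.
    """

    def __init__(self, source_corpus: Corpus, target_train: Corpus,
                 source_spec: DomainSpec, target_spec: DomainSpec,
                 variant: str = "D", target_dev: Corpus | None = None,
                 train_config: TrainConfig | None = None,
                 plan: TransferPlan | None = None):
        self.source_corpus = source_corpus
        self.target_train = target_train
        self.target_dev = target_dev
        self.source_spec = source_spec
        self.target_spec = target_spec
        self.tconfig = train_config or TrainConfig()
        self.plan = plan if plan is not None else build_transfer_plan(
            source_spec, target_spec, variant, share_crf=self.tconfig.share_crf)

    # -- phase 1 -------------------------------------------------------
    def fit_source(self, seed: int, sub_source: Corpus | None = None) -> TriggerResults:
        """Train the source network on the (subsampled) source corpus."""
        cfg = self.tconfig
        if sub_source is None:
            sub_source = subsample_source(self.source_corpus, cfg.source_ratio,
                                          _derived_seed(seed, 17))
        src_vocab, _ = build_transfer_vocabs(sub_source, self.target_train,
                                             cfg.min_count)
        docs = sub_source.documents
        n_dev = int(len(docs) * cfg.source_dev_fraction)
        if n_dev > 0 and len(docs) - n_dev > 0:
            train = Corpus(sub_source.domain, docs[:-n_dev])
            dev = Corpus(sub_source.domain, docs[-n_dev:])
        else:
            train, dev = sub_source, None
        src_cfg = cfg if cfg.epochs_source is None \
            else cfg.with_(epochs=cfg.epochs_source)
        model = TriggerModel(train, self.source_spec.label_set,
                             self.source_spec.feature_config, src_cfg,
                             dev_corpus=dev, vocab=src_vocab)
        return model.fit(seed=_derived_seed(seed, 1), phase="source")

    # -- phases 2 + 3 --------------------------------------------------
    def fit_target(self, source_results: TriggerResults | None, seed: int,
                   plan: TransferPlan | None = None) -> "TransferResults":
        """Initialize the target network, copy the plan-shared blocks from
        the fitted source network, then train on the target corpus."""
        cfg = self.tconfig
        plan = plan if plan is not None else self.plan
        if source_results is None or plan.is_empty():
            model = TriggerModel(self.target_train, self.target_spec.label_set,
                                 self.target_spec.feature_config, cfg,
                                 dev_corpus=self.target_dev)
            target = model.fit(seed=seed, phase="target")
            return TransferResults(target=target, source=None, plan=plan,
                                   audit=TransferAudit(()), seed=seed)
        _, tgt_vocab = build_transfer_vocabs(
            source_results.model.corpus, self.target_train, cfg.min_count)
        # joint vocabulary must match the one the source network trained with
        tgt_vocab = type(tgt_vocab)(
            words=source_results.model.vocab.words,
            chars=source_results.model.vocab.chars,
            pos=source_results.model.vocab.pos,
            entities=tgt_vocab.entities,
            deps=source_results.model.vocab.deps)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        bundle = network.init_parameters(
            tgt_vocab, self.target_spec.feature_config,
            self.target_spec.label_set.tags, cfg.hidden_size, cfg.fc_size, rng)
        audit = transfer_parameters(source_results.params, plan, bundle)
        if cfg.freeze_shared_phase3:
            bundle.meta["frozen"] = sorted(set(plan.block_names()))
        model = TriggerModel(self.target_train, self.target_spec.label_set,
                             self.target_spec.feature_config, cfg,
                             dev_corpus=self.target_dev, vocab=tgt_vocab)
        target = model.fit(seed=seed, init_bundle=bundle, phase="target")
        return TransferResults(target=target, source=source_results, plan=plan,
                               audit=audit, seed=seed)

    def fit(self, seed: int = 0) -> "TransferResults":
        cfg = self.tconfig
        if self.plan.is_empty():
            return self.fit_target(None, seed)
        sub_source = subsample_source(self.source_corpus, cfg.source_ratio,
                                      _derived_seed(seed, 17))
        if sub_source.n_sentences == 0:
            return self.fit_target(None, seed)
        source_results = self.fit_source(seed, sub_source=sub_source)
        return self.fit_target(source_results, seed)


@dataclass
class TransferResults:
    """Outcome of a transfer run: the fitted target tagger plus the plan,
    the copy audit and (when transfer happened) the fitted source tagger."""

    target: TriggerResults
    source: TriggerResults | None
    plan: TransferPlan
    audit: TransferAudit
    seed: int = 0

    @property
    def params(self) -> ParameterBundle:
        return self.target.params

    @property
    def history(self) -> list:
        src = self.source.history if self.source is not None else []
        return src + self.target.history

    def predict_tags(self, corpus):
        return self.target.predict_tags(corpus)

    def evaluate(self, corpus, run_id=""):
        return self.target.evaluate(corpus, run_id=run_id)

    def report_jsonl(self) -> str:
        """Training report: one JSON object per epoch (phase, loss, dev P/R/F1)."""
        return "\n".join(json.dumps(h) for h in self.history) + "\n"

    def summary(self) -> str:
        lines = [
            f"Transfer run (variant {self.plan.variant}: "
            f"{self.plan.source_domain or 'source'} -> "
            f"{self.plan.target_domain or 'target'})",
            "=" * 46,
            f"shared blocks copied: {len(self.audit.copied)} "
            f"({self.audit.total_params:,} parameters)",
        ]
        return "\n".join(lines) + "\n" + self.target.summary()


def three_phase_train(source_corpus: Corpus, target_train: Corpus,
                      target_dev: Corpus | None, source_spec: DomainSpec,
                      target_spec: DomainSpec, variant: str = "D",
                      train_config: TrainConfig | None = None,
                      seed: int = 0,
                      plan: TransferPlan | None = None) -> TransferResults:
    """Functional wrapper around :class:`TransferModel`. """
    return TransferModel(source_corpus, target_train, source_spec, target_spec,
                         variant=variant, target_dev=target_dev,
                         train_config=train_config, plan=plan).fit(seed=seed)


def run_ratio_sweep(source_corpus: Corpus, target_train: Corpus,
                    target_eval: Corpus, source_spec: DomainSpec,
                    target_spec: DomainSpec, ratios, seeds,
                    variant: str = "D",
                    train_config: TrainConfig | None = None) -> list:
    """One three-phase run per (ratio, seed); returns one row per ratio with
    the per-seed and mean F1 on ``target_eval`` — the data behind
    source-ratio effect curves."""
    cfg = train_config or TrainConfig()
    rows = []
    for ratio in ratios:
        f1s = []
        for seed in seeds:
            res = three_phase_train(source_corpus, target_train, target_eval,
                                    source_spec, target_spec, variant=variant,
                                    train_config=cfg.with_(source_ratio=ratio),
                                    seed=seed)
            f1s.append(res.evaluate(target_eval).total_f1)
        rows.append({"ratio": float(ratio), "f1_per_seed": f1s,
                     "mean_f1": float(np.mean(f1s))})
    return rows
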