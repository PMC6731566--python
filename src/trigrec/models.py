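"""Model / Results objects for the BiLSTM-CRF trigger tagger.

:class:`TriggerModel` is built from a training corpus and a label inventory;
``fit()`` runs seeded mini-batch training of the negative CRF log-likelihood
and returns a :class:`TriggerResults` carrying the trained parameter bundle,
the loss/metric history and prediction/evaluation methods.  Training is
fully reproducible: the same seed and data yield bit-identical parameter
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from . import network
from .config import TrainConfig
from .corpus_io import Corpus, LabelSet
from .errors import ConfigError
from .evaluation import MetricsReport, compute_metrics, count_confusion
from .features import FeatureConfig, Vocab, build_vocab, encode_sentence


class _Optimizer:
    """Adam (default) or plain SGD over the bundle's trainable blocks."""

    def __init__(self, bundle, config: TrainConfig):
        self.config = config
        self.names = bundle.trainable_blocks()
        if config.optimizer == "adam":
            self.m = {k: np.zeros_like(bundle.blocks[k]) for k in self.names}
            self.v = {k: np.zeros_like(bundle.blocks[k]) for k in self.names}
            self.t = 0

    def step(self, bundle, grads: dict) -> None:
        cfg = self.config
        if cfg.clip_norm > 0:
            sq = sum(float(np.sum(g * g)) for g in grads.values())
            norm = np.sqrt(sq)
            if norm > cfg.clip_norm:
                scale = cfg.clip_norm / norm
                grads = {k: g * scale for k, g in grads.items()}
        if cfg.optimizer == "sgd":
            for k in self.names:
                if k in grads:
                    bundle.blocks[k] -= cfg.learning_rate * grads[k]
            return
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k in self.names:
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            bundle.blocks[k] -= cfg.learning_rate * (self.m[k] / bias1) / (
                np.sqrt(self.v[k] / bias2) + eps)


class TriggerModel:
    """A BiLSTM-CRF tagger specification bound to its training data.

    Parameters
    ----------
    train_corpus : Corpus
        Tagged training sentences; all tags must come from ``label_set``
        (plus its negative label).
    label_set : LabelSet
        The domain's trigger-type inventory.
    feature_config, train_config : optional
        Channel dimensions and optimisation settings.
    dev_corpus : Corpus, optional
        Held-out sentences for early stopping on micro F1.
    vocab : Vocab, optional
        Pre-built vocabulary (used by transfer training to share symbol
        indices across domains); built from the training corpus otherwise.
    """

    def __init__(self, train_corpus: Corpus, label_set: LabelSet,
                 feature_config: FeatureConfig | None = None,
                 train_config: TrainConfig | None = None,
                 dev_corpus: Corpus | None = None,
                 vocab: Vocab | None = None):
        if train_corpus.n_sentences == 0:
            raise ConfigError("cannot fit on an empty corpus")
        self.corpus = train_corpus
        self.dev_corpus = dev_corpus
        self.label_set = label_set
        self.fconfig = feature_config or FeatureConfig.target_default()
        self.tconfig = train_config or TrainConfig()
        self.vocab = vocab or build_vocab(train_corpus, self.tconfig.min_count)
        tag_index = label_set.tag_index()
        for sentence in train_corpus.sentences():
            for tok in sentence:
                if tok.tag not in tag_index:
                    raise ConfigError(
                        f"tag {tok.tag!r} outside the domain label set")

    @classmethod
    def from_corpus(cls, corpus: Corpus, negative_label: str = "O", **kw):
        """Infer the label inventory from the corpus tags."""
        labels = sorted({t.tag for s in corpus.sentences() for t in s}
                        - {negative_label})
        return cls(corpus, LabelSet(tuple(labels), negative_label), **kw)

    # ------------------------------------------------------------------
    def _encode(self, corpus: Corpus):
        tag_index = self.label_set.tag_index()
        return [encode_sentence(s, self.vocab, tag_index, self.fconfig)
                for s in corpus.sentences()]

    def fit(self, seed: int = 0, init_bundle=None, start_epoch: int = 0,
            history: list | None = None, phase: str = "train"):
        """Train and return a :class:`TriggerResults`.

        ``init_bundle`` optionally replaces the fresh random initialization
        (after the same number of rng draws, so downstream shuffling is
        unaffected); transfer training passes the post-copy bundle here.
        """
        cfg = self.tconfig
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        bundle = network.init_parameters(self.vocab, self.fconfig,
                                         self.label_set.tags,
                                         cfg.hidden_size, cfg.fc_size, rng)
        if init_bundle is not None:
            bundle = init_bundle
        encoded = self._encode(self.corpus)
        dev_encoded = self._encode(self.dev_corpus) if self.dev_corpus else None
        optimizer = _Optimizer(bundle, cfg)
        history = history if history is not None else []
        best = (None, -1.0, 0)  # (bundle copy, dev F1, epoch)
        n_tokens = sum(len(e) for e in encoded)

        for epoch in range(start_epoch, start_epoch + cfg.epochs):
            order = rng.permutation(len(encoded)) if cfg.shuffle \
                else np.arange(len(encoded))
            total_nll = 0.0
            for lo in range(0, len(order), cfg.batch_size):
                batch = order[lo:lo + cfg.batch_size]
                tensors = {k: (ad.parameter(v) if k in set(bundle.trainable_blocks())
                               else ad.constant(v))
                           for k, v in bundle.blocks.items()}
                loss = None
                for si in batch:
                    nll = network.sentence_nll(
                        tensors, encoded[si], self.fconfig, cfg.hidden_size,
                        peephole=cfg.peephole, dropout_p=cfg.dropout, rng=rng)
                    total_nll += float(nll.data)
                    loss = nll if loss is None else ad.add(loss, nll)
                ad.backward(loss, grad=1.0 / len(batch))
                grads = {k: t.grad for k, t in tensors.items()
                         if t.requires_grad and t.grad is not None}
                optimizer.step(bundle, grads)
            record = {"phase": phase, "epoch": epoch,
                      "loss": total_nll / max(n_tokens, 1)}
            if dev_encoded is not None:
                report = _evaluate_encoded(bundle, dev_encoded, self.label_set,
                                           self.fconfig, cfg.peephole)
                record["dev_p"], record["dev_r"], record["dev_f1"] = report.total
                if record["dev_f1"] > best[1]:
                    best = (bundle.copy(), record["dev_f1"], epoch)
            history.append(record)
            if (dev_encoded is not None and cfg.early_stopping
                    and epoch - best[2] >= cfg.patience):
                break
        if best[0] is not None and cfg.early_stopping:
            bundle = best[0]
        return TriggerResults(model=self, params=bundle, history=history,
                              seed=seed)


@dataclass
class TriggerResults:
    """A fitted tagger: parameter bundle, training history and diagnostics."""

    model: TriggerModel
    params: network.ParameterBundle
    history: list = field(default_factory=list)
    seed: int = 0

    def predict_tags(self, corpus: Corpus):
        """Viterbi tag sequences (as label strings), one list per sentence."""
        enc = self.model._encode(corpus)
        tags = self.model.label_set.tags
        return [[tags[i] for i in network.decode_sentence(
            self.params, e, self.model.fconfig,
            peephole=self.model.tconfig.peephole)] for e in enc]

    def predict(self, corpus: Corpus) -> Corpus:
        """A copy of ``corpus`` with predicted tags written onto the tokens."""
        import copy

        tagged = copy.deepcopy(corpus)
        predictions = iter(self.predict_tags(tagged))
        for sentence in tagged.sentences():
            for tok, tag in zip(sentence, next(predictions)):
                tok.tag = tag
        return tagged

    def evaluate(self, corpus: Corpus, run_id: str = "") -> MetricsReport:
        gold = [[t.tag for t in s] for s in corpus.sentences()]
        pred = self.predict_tags(corpus)
        counts = count_confusion(gold, pred, self.model.label_set.negative_label)
        return compute_metrics(counts, labels=self.model.label_set.labels,
                               run_id=run_id)

    @property
    def final_loss(self) -> float:
        return self.history[-1]["loss"] if self.history else float("nan")

    def summary(self) -> str:
        m = self.model
        lines = [
            "BiLSTM-CRF trigger tagger",
            "=" * 46,
            f"labels:            {len(m.label_set.labels)} trigger types "
            f"(+ {m.label_set.negative_label!r})",
            f"input dim:         {m.fconfig.total_dim} "
            f"({', '.join(f'{k}={v}' for k, v in m.fconfig.channel_dims().items())})",
            f"hidden/fc size:    {m.tconfig.hidden_size}/{m.tconfig.fc_size}",
            f"parameters:        {self.params.n_params():,}",
            f"training sentences:{m.corpus.n_sentences:>6}",
            f"epochs run:        {len(self.history)}",
            f"final mean NLL/token: {self.final_loss:.4f}",
            f"seed:              {self.seed}",
        ]
        devs = [h for h in self.history if "dev_f1" in h]
        if devs:
            best = max(devs, key=lambda h: h["dev_f1"])
            lines.append(f"best dev F1:       {best['dev_f1']:.2f} "
                         f"(epoch {best['epoch']})")
        return "\n".join(lines)

    def save(self, path) -> None:
        self.params.save(path)


def _evaluate_encoded(bundle, encoded, label_set, fconfig, peephole) -> MetricsReport:
    tags = label_set.tags
    gold, pred = [], []
    for e in encoded:
        gold.append([tags[i] for i in e.tags])
        pred.append([tags[i] for i in network.decode_sentence(
            bundle, e, fconfig, peephole=peephole)])
    return compute_metrics(count_confusion(gold, pred, label_set.negative_label),
                           labels=label_set.labels)


def save_tagger(results: TriggerResults, path) -> None:
    """Persist a fitted tagger (parameter checkpoint + vocab/label/config
    sidecar) so it can be reloaded for prediction without the training data."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    results.params.save(path)
    m = results.model
    sidecar = {
        "labels": list(m.label_set.labels),
        "negative_label": m.label_set.negative_label,
        "feature_config": dataclasses.asdict(m.fconfig),
        "peephole": m.tconfig.peephole,
        "vocab": {k: getattr(m.vocab, k)
                  for k in ("words", "chars", "pos", "entities", "deps")},
        "seed": results.seed,
    }
    (path / "tagger.json").write_text(json.dumps(sidecar))


@dataclass
class LoadedTagger:
    """A prediction-only tagger reloaded from :func:`save_tagger` output."""

    params: network.ParameterBundle
    label_set: LabelSet
    vocab: Vocab
    fconfig: FeatureConfig
    peephole: bool = True

    @classmethod
    def load(cls, path) -> "LoadedTagger":
        import json
        from pathlib import Path

        path = Path(path)
        sidecar = json.loads((path / "tagger.json").read_text())
        return cls(
            params=network.ParameterBundle.load(path),
            label_set=LabelSet(tuple(sidecar["labels"]),
                               sidecar["negative_label"]),
            vocab=Vocab(**sidecar["vocab"]),
            fconfig=FeatureConfig(**sidecar["feature_config"]),
            peephole=sidecar["peephole"],
        )

    def predict_tags(self, corpus: Corpus):
        tag_index = self.label_set.tag_index()
        tags = self.label_set.tags
        out = []
        for s in corpus.sentences():
            enc = encode_sentence(s, self.vocab, tag_index, self.fconfig)
            out.append([tags[i] for i in network.decode_sentence(
                self.params, enc, self.fconfig, peephole=self.peephole)])
        return out


def train_basic(corpus: Corpus, label_set: LabelSet,
                feature_config: FeatureConfig | None = None,
                train_config: TrainConfig | None = None, seed: int = 0,
                dev_corpus: Corpus | None = None,
                vocab: Vocab | None = None) -> TriggerResults:
    """The no-transfer baseline: fit the tagger on one domain's data."""
    return TriggerModel(corpus, label_set, feature_config, train_config,
                        dev_corpus=dev_corpus, vocab=vocab).fit(seed=seed)
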