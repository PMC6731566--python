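# Methods

## Task and model

Event-trigger recognition is cast as sentence-level sequence labelling: for
an input sentence {word_1, …, word_n} the tagger emits {tag_1, …, tag_n},
where each tag is an event type from the domain's trigger inventory or the
negative tag `O` (raw type-per-token, no BIO prefixes; adjacent same-type
tokens are merged into one span only when writing standoff output).

The network is a BiLSTM-CRF:

1. **Embedding layer.** Each token is the concatenation
   `x_i = [E^w; E^c; E^p; E^e; E^d]` of five channels: a word lookup, the
   final hidden state of a character-level LSTM run over the token's
   characters, a POS-tag lookup, a named-entity-type lookup and a
   dependency-context-word lookup. POS, entity and dependency-context
   columns are **inputs** (consumed from the corpus files), not computed —
   the package does not run taggers or parsers. Word and dependency tables
   may be loaded from word2vec text files; randomly initialized tables are
   trainable, pre-trained ones are frozen by default (config flag to
   unfreeze).
2. **BiLSTM layer.** A peephole LSTM in each direction
   (`i_t = σ(W_xi x_t + W_hi h_{t−1} + w_ci c_{t−1} + b_i)` and so on, with
   the cell state feeding the input/forget gates at t−1 and the output gate
   at t); the token representation is `h_t = [h_t^F; h_t^B]`. A config
   switch disables the peepholes.
3. **Fully-connected layer.** `y_t = max(0, W h_t + b)` (ReLU), followed by
   a linear projection to per-tag emission scores. The two-stage form is
   deliberate: the hidden block is label-free while the projection rows are
   indexed by tag, which is exactly the axis the transfer scheme partitions.
4. **CRF layer.** A linear-chain CRF with two virtual states (START, STOP)
   couples the output tags. Training maximises the sequence
   log-likelihood; the partition function uses the log-space forward
   recursion, and the gradient uses the exact forward–backward marginals.
   Decoding is Viterbi. No BIO-style transition constraints are imposed.

All tensors are float64 numpy arrays; gradients flow through a small
in-package reverse-mode autodiff tape. Determinism is a design goal: every
random draw (initialization, shuffling, dropout, subsampling) comes from a
seeded generator, and the same seed with the same data reproduces parameter
trajectories bit for bit.

## Transfer learning by vertical parameter partitioning

Let s and t be the source and target domains. Classic layer-wise transfer
shares whole layers and must discard a layer whose shape or meaning differs
across domains: with disjoint label sets the output layer cannot be shared
(**variant B**: embeddings + BiLSTM only), and with inconsistent input
feature sets the BiLSTM cannot be shared either (**variant C**:
domain-independent embedding tables only). **Variant A** is the no-transfer
baseline.

The generalized scheme (**variant D**) splits each layer's parameters
*vertically* into `θ_specific + θ_shared`:

* **Embedding:** tables of channels that are active in both domains, have
  equal width and are domain-independent (word, char, POS, dep by default)
  are shared; the entity channel is domain-dependent (different inventories
  and widths, e.g. 10-dim source vs 50-dim target) and stays specific.
* **BiLSTM:** recurrent, peephole and bias blocks are shared (hidden sizes
  match across domains); the input-weight matrix is partitioned by input
  channel, sharing the rows of shared channels through explicit row-index
  maps (the entity rows stay specific).
* **Fully-connected:** the hidden ReLU block is shared; the label
  projection is partitioned by output label, sharing rows and biases of
  labels present in both inventories (matched by name equality).
* **CRF:** transitions are never transferred. An experimental config flag
  (`share_crf`) can copy the transition sub-matrix between shared labels;
  it is off by default.

The BiLSTM/FC sharing in variant D is conditioned on a non-empty label
overlap. This makes the degenerate cases exact: with an empty overlap the
variant-D plan equals the variant-B plan when the feature sets are
identical, and the variant-C plan when they are not — both reductions are
enforced by tests. A plan is a data object (block addresses plus index
maps, JSON-serializable), so what is shared is auditable before and after
the copy; `transfer_parameters` is idempotent and returns an audit of
copied blocks and parameter counts.

**Three-phase training.** Phase 1 trains the source network on the source
corpus subsampled at document granularity to `source_ratio` (a transfer
hyperparameter in [0, 1]; 10% of the source documents is held out for
phase-1 early stopping). Phase 2 copies every plan-shared block into a
freshly initialized target bundle. Phase 3 trains on the target corpus with
shared and specific parameters updated alike (an optional config freezes
the shared blocks instead). For the shared tables to index consistently,
the word/char/POS/dep vocabularies are built jointly over both corpora;
each domain keeps its own entity vocabulary. With an empty plan or an empty
subsampled source, the run collapses to phase 3 alone and is bit-identical
to the no-transfer baseline at the same seed.

## Evaluation

Token-level per-type TP/FP/FN with `P = TP/(TP+FP)`, `R = TP/(TP+FN)`,
`F1 = 2PR/(P+R)`; the TOTAL row is micro-averaged over summed counts. All
three are reported on the percent scale with half-up rounding to two
decimals for display; any 0/0 ratio is defined as 0, and run deltas are
computed on the rounded percent scale. A span-level mode (exact boundary +
type) is provided for standoff outputs; token-level is the default because
the model emits one tag per token.

## Defaults that matter

| parameter | default | note |
|---|---|---|
| word / char / POS / dep dims | 200 / 100 / 50 / 300 | reference setting |
| entity dim | 10 (source), 50 (target) | the domain-dependent channel |
| BiLSTM hidden | 300 per direction | output 600 |
| FC hidden | 600, ReLU | |
| dropout | 0.5 before BiLSTM and FC inputs | training only; inference is deterministic |
| optimizer | Adam, lr 1e-3, batch 16 sentences | unspecified upstream; overridable |
| early stopping | dev micro F1, patience 5 | |
| gradient clipping | global norm 5.0 | stability choice |
| embedding init | uniform [−0.05, 0.05], PAD row zero | |
| dense init | Glorot uniform; forget-gate bias 1 | |
| char LSTM | unidirectional, final hidden state | per-character input embedding 30-dim |
| word lookup fallback | lowercased form before UNK | lowercasing otherwise off |
| source subsampling | document granularity, floor(ratio·n) | |
| overlapping trigger spans on one token | error; lenient first-wins mode behind a flag | |

## Synthetic data: what it emulates and what it does not

The generator emits paired source/target corpora with (i) label-set overlap
implied by shared label names, with shared labels using identical trigger
lexicons in both domains; (ii) per-domain entity-type columns (the
domain-dependent channel); (iii) a configurable per-token trigger density
and corpus-size asymmetry; and (iv) an ambiguity mechanism: a configurable
fraction of trigger insertions use words from an ambiguous pool whose label
is determined solely by a marker word within a ±2-token window, so a
context-blind lexicon lookup cannot solve them. Marker placement is
constrained so the construction stays invertible: `oracle_tag` recovers the
gold column exactly and serves as the learnability ceiling, and the
generator's ledger agrees with `corpus_stats` by construction.

It does **not** emulate real biomedical language: no morphology (trigger
stems are label-stamped synthetic tokens), no realistic class imbalance, no
document discourse structure, flat fixed-size documents, and POS tags are a
deterministic function of the surface. Passing tests therefore demonstrate
the *mechanics* of the method — learnability, the value of context, and the
direction of transfer gains under controlled overlap — not corpus-level
performance numbers on MLEE-class data, which require the licensed corpora.

## Problem sizes used by the test suite and benchmark

The suite runs the real training loop at reduced dimensions, the package's
chosen benchmark scale: feature dims 8–32, hidden 6–32, sentences 6–10
tokens. The transfer-gain benchmark (`trigrec.experiments`) uses a 9-label
source / 19-label target pair sharing 9 labels (the geometry of the
molecular-level vs multiple-level inventories), 160 source sentences, 40
target training sentences, 60 dev sentences, ambiguity 0.3, density 0.3,
dropout 0.5, Adam lr 0.02, batch 4, ≤24 epochs with patience 5, 5 seeds,
and disables the char channel (trigger identity in the generator is
lexical; the char LSTM has its own unit and gradient tests). The
learnability check uses 500 training sentences at ambiguity 0.3 with a
32-dim hidden model. Under these conditions the generalized variant-D
transfer consistently outperforms both the baseline and embedding-only
transfer in mean dev F1.

## Numerical choices and degenerate inputs

* CRF recursions are entirely in log space; Viterbi ties break toward the
  lowest tag index, so decoding is deterministic.
* Partitioned-layer assembly is numerically identical to the dense layer
  (≤ 1e-10 elementwise, float64); CRF forward/Viterbi match exhaustive path
  enumeration to 1e-8 on all tested instances.
* Empty sentence or empty word: rejected with a typed error.
* Unknown symbols at inference fold to UNK; an absent entity column maps to
  a dedicated `<none>` entity symbol.
* Checkpoints are a named-block npz plus a JSON manifest of shapes,
  versioned, with partial loads by block address.

## Known limitations

* CPU-only, sentence-at-a-time graphs: intended for research-scale corpora
  and the synthetic benchmark, not for training at full reference dims on
  large corpora in seconds.
* Event arguments (standoff `E` lines) are out of scope; only triggers and
  entities are parsed.
* Transfer across languages and multi-source transfer are not supported.
* Label matching between domains is by name equality; no ontology-based
  mapping of near-synonymous types.
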