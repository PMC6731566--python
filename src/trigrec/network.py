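"""The BiLSTM-CRF computation graph.

The tagger scores a sentence in four stages: an embedding layer concatenates
the per-token feature channels, a bidirectional peephole LSTM contextualises
them, a ReLU fully-connected layer plus a linear label projection produce
per-tag emission scores, and a linear-chain CRF couples the output tags.

The LSTM cell follows the peephole formulation (cell state feeding the input
and forget gates at t-1 and the output gate at t)::

    i_t = sigma(W_xi x_t + W_hi h_{t-1} + w_ci c_{t-1} + b_i)
    f_t = sigma(W_xf x_t + W_hf h_{t-1} + w_cf c_{t-1} + b_f)
    c_t = f_t c_{t-1} + i_t tanh(W_xc x_t + W_hc h_{t-1} + b_c)
    o_t = sigma(W_xo x_t + W_ho h_{t-1} + w_co c_t + b_o)
    h_t = o_t tanh(c_t)

with the peephole weights acting elementwise.  A config switch degrades the
cell to a standard (non-peephole) LSTM.  Gate weights are stored stacked as
``W_x (D, 4H)`` / ``W_h (H, 4H)`` in gate order (i, f, g, o); the input-axis
rows of ``W_x`` are grouped by feature channel so transfer plans can share
per-channel column groups.

The CRF uses two virtual states (START, STOP) appended to the tag inventory;
training maximises the sequence log-likelihood (forward recursion in log
space) and decoding is Viterbi with ties broken toward the lowest tag index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from . import _autodiff as ad
from ._autodiff import Tensor
from .errors import ConfigError, PlanError
from .features import EncodedSentence, FeatureConfig, Vocab

# ---------------------------------------------------------------------------
# parameter container


@dataclass
class ParameterBundle:
    """All trainable tensors of one domain's network, addressable by block.

    Block addresses (``layer.block``) cover every trainable tensor exactly
    once: ``emb.*`` lookup tables and char-LSTM weights, ``lstm.f.*`` /
    ``lstm.b.*`` forward/backward cell weights, ``fc.*`` the ReLU hidden
    layer, ``proj.*`` the label projection (columns indexed by tag) and
    ``crf.trans`` the transition matrix (tags + START/STOP).
    """

    blocks: dict
    meta: dict

    VERSION = 1

    def copy(self) -> "ParameterBundle":
        return ParameterBundle({k: v.copy() for k, v in self.blocks.items()},
                               json.loads(json.dumps(self.meta)))

    def n_params(self) -> int:
        return sum(int(v.size) for v in self.blocks.values())

    def trainable_blocks(self):
        frozen = set(self.meta.get("frozen", ()))
        return [k for k in self.blocks if k not in frozen]

    def allclose(self, other: "ParameterBundle", atol=0.0) -> bool:
        if set(self.blocks) != set(other.blocks):
            return False
        return all(np.allclose(self.blocks[k], other.blocks[k], atol=atol, rtol=0.0)
                   for k in self.blocks)

    # -- checkpoint container: named-block npz + JSON manifest -------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "blocks.npz", **self.blocks)
        manifest = {
            "version": self.VERSION,
            "shapes": {k: list(v.shape) for k, v in self.blocks.items()},
            "meta": self.meta,
        }
        (path / "blocks.manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path, blocks=None) -> "ParameterBundle":
        """Load a checkpoint; ``blocks`` restricts to a subset of addresses."""
        path = Path(path)
        manifest = json.loads((path / "blocks.manifest.json").read_text())
        if manifest.get("version") != cls.VERSION:
            raise ConfigError(f"unsupported checkpoint version {manifest.get('version')}")
        with np.load(path / "blocks.npz") as data:
            wanted = data.files if blocks is None else list(blocks)
            missing = [b for b in wanted if b not in data.files]
            if missing:
                raise PlanError(f"missing blocks in checkpoint: {missing}")
            loaded = {k: data[k] for k in wanted}
        return cls(loaded, manifest["meta"])


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _init_cell(rng, in_dim, hidden, prefix, blocks):
    blocks[f"{prefix}.W_x"] = _glorot(rng, in_dim, hidden, (in_dim, 4 * hidden))
    blocks[f"{prefix}.W_h"] = _glorot(rng, hidden, hidden, (hidden, 4 * hidden))
    for p in ("p_i", "p_f", "p_o"):
        blocks[f"{prefix}.{p}"] = np.zeros(hidden)
    b = np.zeros(4 * hidden)
    b[hidden:2 * hidden] = 1.0  # forget-gate bias at 1 for gradient flow
    blocks[f"{prefix}.b"] = b


def init_parameters(vocab: Vocab, fconfig: FeatureConfig, tags: tuple,
                    hidden_size: int, fc_size: int,
                    rng: np.random.Generator) -> ParameterBundle:
    """Freshly initialized bundle.  Embedding tables are uniform in
    [-0.05, 0.05] (PAD row zeroed); dense weights use Glorot-uniform; CRF
    transitions start at zero.  Draw order is fixed, so a given rng state
    yields a bit-reproducible bundle."""
    blocks = {}
    sizes = vocab.sizes()

    def table(name, n, d):
        m = rng.uniform(-0.05, 0.05, size=(n, d))
        m[0] = 0.0
        blocks[name] = m

    if fconfig.use_word:
        table("emb.word", sizes["word"], fconfig.dim_word)
    if fconfig.use_char:
        table("emb.char", sizes["char"], fconfig.dim_char_in)
        _init_cell(rng, fconfig.dim_char_in, fconfig.dim_char,
                   "emb.char_lstm", blocks)
    if fconfig.use_pos:
        table("emb.pos", sizes["pos"], fconfig.dim_pos)
    if fconfig.use_entity:
        table("emb.entity", sizes["entity"], fconfig.dim_entity)
    if fconfig.use_dep:
        table("emb.dep", sizes["dep"], fconfig.dim_dep)

    in_dim = fconfig.total_dim
    _init_cell(rng, in_dim, hidden_size, "lstm.f", blocks)
    _init_cell(rng, in_dim, hidden_size, "lstm.b", blocks)
    blocks["fc.W"] = _glorot(rng, 2 * hidden_size, fc_size, (2 * hidden_size, fc_size))
    blocks["fc.b"] = np.zeros(fc_size)
    n_tags = len(tags)
    blocks["proj.W"] = _glorot(rng, fc_size, n_tags, (fc_size, n_tags))
    blocks["proj.b"] = np.zeros(n_tags)
    blocks["crf.trans"] = np.zeros((n_tags + 2, n_tags + 2))

    meta = {
        "tags": list(tags),
        "channel_ranges": {k: list(v) for k, v in fconfig.channel_ranges().items()},
        "hidden_size": hidden_size,
        "fc_size": fc_size,
        "frozen": [],
    }
    return ParameterBundle(blocks, meta)


# ---------------------------------------------------------------------------
# LSTM cell


def _cell_params(p: dict) -> dict:
    """Accept either Tensors or numpy arrays for a cell parameter group."""
    return {k: (v if isinstance(v, Tensor) else ad.constant(v)) for k, v in p.items()}


def lstm_step(x, h_prev, c_prev, params: dict, peephole: bool = True):
    """One peephole-LSTM step on row tensors ``(B, D) -> (B, H)``.

    Returns (h_t, c_t).  With all-zero parameters the gates sit at 0.5 and
    both outputs are exactly zero; every component of h_t lies in (-1, 1).
    """
    p = _cell_params(params)
    hidden = p["W_h"].data.shape[0]
    if x.data.ndim != 2 or x.data.shape[1] != p["W_x"].data.shape[0]:
        raise ConfigError(
            f"lstm_step: input shape {x.data.shape} incompatible with "
            f"W_x {p['W_x'].data.shape}")
    z = ad.add(ad.add(ad.matmul(x, p["W_x"]), ad.matmul(h_prev, p["W_h"])), p["b"])
    zi = ad.narrow(z, 1, 0, hidden)
    zf = ad.narrow(z, 1, hidden, hidden)
    zg = ad.narrow(z, 1, 2 * hidden, hidden)
    zo = ad.narrow(z, 1, 3 * hidden, hidden)
    if peephole:
        zi = ad.add(zi, ad.mul(p["p_i"], c_prev))
        zf = ad.add(zf, ad.mul(p["p_f"], c_prev))
    i = ad.sigmoid(zi)
    f = ad.sigmoid(zf)
    g = ad.tanh(zg)
    c = ad.add(ad.mul(f, c_prev), ad.mul(i, g))
    if peephole:
        zo = ad.add(zo, ad.mul(p["p_o"], c))
    o = ad.sigmoid(zo)
    h = ad.mul(o, ad.tanh(c))
    return h, c


def lstm_step_np(x, h_prev, c_prev, params: dict, peephole: bool = True):
    """Numpy convenience wrapper around :func:`lstm_step` for single vectors."""
    h, c = lstm_step(ad.constant(np.atleast_2d(x)), ad.constant(np.atleast_2d(h_prev)),
                     ad.constant(np.atleast_2d(c_prev)), params, peephole=peephole)
    return h.data[0], c.data[0]


def _run_direction(X: Tensor, params: dict, hidden: int, reverse: bool,
                   peephole: bool) -> list:
    """Run one LSTM direction over (T, D) input; returns T hidden-row tensors
    in sentence order.  The input projection X @ W_x is hoisted out of the
    recurrence."""
    p = _cell_params(params)
    T = X.data.shape[0]
    XP = ad.matmul(X, p["W_x"])  # (T, 4H)
    h = ad.constant(np.zeros((1, hidden)))
    c = ad.constant(np.zeros((1, hidden)))
    order = range(T - 1, -1, -1) if reverse else range(T)
    out = [None] * T
    for t in order:
        z = ad.add(ad.add(ad.narrow(XP, 0, t, 1), ad.matmul(h, p["W_h"])), p["b"])
        zi = ad.narrow(z, 1, 0, hidden)
        zf = ad.narrow(z, 1, hidden, hidden)
        zg = ad.narrow(z, 1, 2 * hidden, hidden)
        zo = ad.narrow(z, 1, 3 * hidden, hidden)
        if peephole:
            zi = ad.add(zi, ad.mul(p["p_i"], c))
            zf = ad.add(zf, ad.mul(p["p_f"], c))
        i = ad.sigmoid(zi)
        f = ad.sigmoid(zf)
        g = ad.tanh(zg)
        c = ad.add(ad.mul(f, c), ad.mul(i, g))
        if peephole:
            zo = ad.add(zo, ad.mul(p["p_o"], c))
        o = ad.sigmoid(zo)
        h = ad.mul(o, ad.tanh(c))
        out[t] = h
    return out


def bilstm_forward(X, fwd_params: dict, bwd_params: dict, hidden: int,
                   peephole: bool = True) -> Tensor:
    """Bidirectional pass over a (T, D) input; returns (T, 2H) with
    h_t = [h_t^F ; h_t^B].  The forward half of position t depends only on
    positions <= t, the backward half only on positions >= t."""
    if not isinstance(X, Tensor):
        X = ad.constant(X)
    if X.data.ndim != 2 or X.data.shape[0] == 0:
        raise ConfigError("bilstm_forward requires a non-empty (T, D) input")
    hf = _run_direction(X, fwd_params, hidden, reverse=False, peephole=peephole)
    hb = _run_direction(X, bwd_params, hidden, reverse=True, peephole=peephole)
    Hf = ad.concat(hf, axis=0)
    Hb = ad.concat(hb, axis=0)
    return ad.concat([Hf, Hb], axis=1)


def fc_project(H, fc_params: dict, proj_params: dict) -> Tensor:
    """ReLU hidden layer y_t = max(0, W h_t + b) followed by an affine label
    projection to emission scores (no nonlinearity on the scores)."""
    if not isinstance(H, Tensor):
        H = ad.constant(H)
    p = _cell_params(fc_params)
    q = _cell_params(proj_params)
    if H.data.shape[-1] != p["W"].data.shape[0]:
        raise ConfigError(f"fc_project: input dim {H.data.shape[-1]} != "
                          f"W rows {p['W'].data.shape[0]}")
    y = ad.relu(ad.add(ad.matmul(H, p["W"]), p["b"]))
    return ad.add(ad.matmul(y, q["W"]), q["b"])


# ---------------------------------------------------------------------------
# linear-chain CRF


def _crf_check(emissions: np.ndarray, trans: np.ndarray):
    T, L = emissions.shape
    if trans.shape != (L + 2, L + 2):
        raise ConfigError(f"transition matrix {trans.shape} does not match "
                          f"{L} tags + START/STOP")
    return T, L


def crf_forward_np(emissions: np.ndarray, trans: np.ndarray):
    """Log-space forward recursion; returns (logZ, alphas (T, L))."""
    T, L = _crf_check(emissions, trans)
    START, STOP = L, L + 1
    alphas = np.empty((T, L))
    alphas[0] = trans[START, :L] + emissions[0]
    for t in range(1, T):
        alphas[t] = logsumexp(alphas[t - 1][:, None] + trans[:L, :L], axis=0) \
            + emissions[t]
    logZ = logsumexp(alphas[T - 1] + trans[:L, STOP])
    return logZ, alphas


def crf_path_score(emissions: np.ndarray, tags, trans: np.ndarray) -> float:
    T, L = _crf_check(emissions, trans)
    tags = np.asarray(tags, dtype=np.intp)
    if tags.min() < 0 or tags.max() >= L:
        raise ConfigError("tag index outside inventory")
    START, STOP = L, L + 1
    score = trans[START, tags[0]] + emissions[np.arange(T), tags].sum() \
        + trans[tags[-1], STOP]
    score += trans[tags[:-1], tags[1:]].sum()
    return float(score)


def crf_log_likelihood(emissions, tags, trans) -> Tensor:
    """log P(tags | emissions) = score(path) - logZ, always <= 0.

    A single autodiff node: the backward pass uses the exact
    forward-backward marginals (d logZ / d emission = unary marginal,
    d logZ / d transition = expected transition count).
    """
    e_t = emissions if isinstance(emissions, Tensor) else ad.constant(emissions)
    w_t = trans if isinstance(trans, Tensor) else ad.constant(trans)
    e, w = e_t.data, w_t.data
    T, L = _crf_check(e, w)
    tags = np.asarray(tags, dtype=np.intp)
    if len(tags) != T:
        raise ConfigError("emissions/tags length mismatch")
    START, STOP = L, L + 1

    logZ, alphas = crf_forward_np(e, w)
    score = crf_path_score(e, tags, w)
    out = Tensor(np.float64(score - logZ), ad._track(e_t, w_t), (e_t, w_t))

    def bwd(g):
        g = float(g)
        # backward recursion
        betas = np.empty((T, L))
        betas[T - 1] = w[:L, STOP]
        for t in range(T - 2, -1, -1):
            betas[t] = logsumexp(w[:L, :L] + (e[t + 1] + betas[t + 1])[None, :],
                                 axis=1)
        unary = np.exp(alphas + betas - logZ)  # (T, L) marginals
        if e_t.requires_grad:
            ge = -unary.copy()
            ge[np.arange(T), tags] += 1.0
            ad._accum(e_t, g * ge)
        if w_t.requires_grad:
            gw = np.zeros_like(w)
            pair_expect = np.zeros((L, L))
            for t in range(T - 1):
                pair_expect += np.exp(alphas[t][:, None] + w[:L, :L]
                                      + (e[t + 1] + betas[t + 1])[None, :] - logZ)
            np.add.at(pair_expect, (tags[:-1], tags[1:]), -1.0)
            gw[:L, :L] = -pair_expect
            gw[START, :L] = -unary[0]
            gw[START, tags[0]] += 1.0
            gw[:L, STOP] = -unary[T - 1]
            gw[tags[-1], STOP] += 1.0
            ad._accum(w_t, g * gw)

    out._bwd = bwd
    return out


def crf_viterbi(emissions: np.ndarray, trans: np.ndarray):
    """Most likely tag sequence and its score.  Ties break toward the lowest
    tag index (argmax keeps the first maximum), so decoding is deterministic.
    """
    emissions = np.asarray(emissions, dtype=np.float64)
    T, L = _crf_check(emissions, trans)
    START, STOP = L, L + 1
    delta = trans[START, :L] + emissions[0]
    back = np.empty((T, L), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, None] + trans[:L, :L]
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(L)] + emissions[t]
    final = delta + trans[:L, STOP]
    best = int(np.argmax(final))
    path = [best]
    for t in range(T - 1, 0, -1):
        best = int(back[t, best])
        path.append(best)
    path.reverse()
    return path, float(final[path[-1]])


# ---------------------------------------------------------------------------
# full sentence graph


def forward_sentence(tensors: dict, enc: EncodedSentence, fconfig: FeatureConfig,
                     hidden_size: int, peephole: bool = True,
                     dropout_p: float = 0.0,
                     rng: np.random.Generator | None = None) -> Tensor:
    """Emission scores (T, L) for one encoded sentence.

    ``tensors`` maps block addresses to Tensors (trainable or constant).
    Dropout (applied before the BiLSTM and fully-connected layers) is active
    only when an rng is supplied, so inference is deterministic.
    """
    parts = []
    if fconfig.use_word:
        parts.append(ad.rows(tensors["emb.word"], enc.word))
    if fconfig.use_char:
        cell = {k.split(".")[-1]: tensors[f"emb.char_lstm.{k.split('.')[-1]}"]
                for k in ("W_x", "W_h", "p_i", "p_f", "p_o", "b")}
        h0 = ad.constant(np.zeros((1, fconfig.dim_char)))
        c0 = ad.constant(np.zeros((1, fconfig.dim_char)))
        embs = []
        for char_idx in enc.chars:
            C = ad.rows(tensors["emb.char"], char_idx)
            h, c = h0, c0
            CP = ad.matmul(C, cell["W_x"])
            for t in range(len(char_idx)):
                z = ad.add(ad.add(ad.narrow(CP, 0, t, 1),
                                  ad.matmul(h, cell["W_h"])), cell["b"])
                hc = fconfig.dim_char
                zi, zf = ad.narrow(z, 1, 0, hc), ad.narrow(z, 1, hc, hc)
                zg, zo = ad.narrow(z, 1, 2 * hc, hc), ad.narrow(z, 1, 3 * hc, hc)
                if peephole:
                    zi = ad.add(zi, ad.mul(cell["p_i"], c))
                    zf = ad.add(zf, ad.mul(cell["p_f"], c))
                i, f, g = ad.sigmoid(zi), ad.sigmoid(zf), ad.tanh(zg)
                c = ad.add(ad.mul(f, c), ad.mul(i, g))
                if peephole:
                    zo = ad.add(zo, ad.mul(cell["p_o"], c))
                h = ad.mul(ad.sigmoid(zo), ad.tanh(c))
            embs.append(h)
        parts.append(ad.concat(embs, axis=0))
    if fconfig.use_pos:
        parts.append(ad.rows(tensors["emb.pos"], enc.pos))
    if fconfig.use_entity:
        parts.append(ad.rows(tensors["emb.entity"], enc.entity))
    if fconfig.use_dep:
        parts.append(ad.rows(tensors["emb.dep"], enc.dep))

    X = parts[0] if len(parts) == 1 else ad.concat(parts, axis=1)
    X = ad.dropout(X, dropout_p, rng)
    fwd = {k: tensors[f"lstm.f.{k}"] for k in ("W_x", "W_h", "p_i", "p_f", "p_o", "b")}
    bwd = {k: tensors[f"lstm.b.{k}"] for k in ("W_x", "W_h", "p_i", "p_f", "p_o", "b")}
    H = bilstm_forward(X, fwd, bwd, hidden_size, peephole=peephole)
    H = ad.dropout(H, dropout_p, rng)
    return fc_project(H, {"W": tensors["fc.W"], "b": tensors["fc.b"]},
                      {"W": tensors["proj.W"], "b": tensors["proj.b"]})


def sentence_nll(tensors: dict, enc: EncodedSentence, fconfig: FeatureConfig,
                 hidden_size: int, peephole: bool = True,
                 dropout_p: float = 0.0,
                 rng: np.random.Generator | None = None) -> Tensor:
    """Negative CRF log-likelihood of the gold tags for one sentence."""
    emissions = forward_sentence(tensors, enc, fconfig, hidden_size,
                                 peephole=peephole, dropout_p=dropout_p, rng=rng)
    llh = crf_log_likelihood(emissions, enc.tags, tensors["crf.trans"])
    return ad.mul(llh, ad.constant(-1.0))


def decode_sentence(bundle: ParameterBundle, enc: EncodedSentence,
                    fconfig: FeatureConfig, peephole: bool = True) -> list:
    """Viterbi tag indices for one sentence (dropout off, deterministic)."""
    tensors = {k: ad.constant(v) for k, v in bundle.blocks.items()}
    emissions = forward_sentence(tensors, enc, fconfig,
                                 bundle.meta["hidden_size"], peephole=peephole)
    path, _ = crf_viterbi(emissions.data, bundle.blocks["crf.trans"])
    return path
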