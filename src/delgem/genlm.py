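"""Trainable SMILES language model (single-layer GRU, pure numpy).

The model is a character/token-level recurrent network over SMILES strings:
pretrained on a general drug-like corpus, then *biased* (fine-tuned) on a
small set of top-scoring molecules so that sampling shifts toward their
chemistry. The architecture is deliberately small — a single GRU layer sized
for CPU training in minutes — because the pipeline contract is about the
pretrain/bias/sample interface, not a particular network.

Determinism contract: every stochastic operation (weight init, batch
shuffling, sampling) takes an explicit integer seed, and repeated calls with
the same seed are bit-identical. Checkpoints round-trip through
:func:`save_model`/:func:`load_model` with identical sampling behaviour.

Tokenization uses the standard SMILES regex: bracket atoms, two-letter
halogens, ring-bond ``%nn`` labels and stereo markers are single tokens, so
every corpus string round-trips through tokenize -> detokenize exactly.
"""

from __future__ import annotations

import copy

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import chem
from .chem import Molecule
from .errors import ConfigError, ParseError

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br?|Cl?|N|O|S|P|F|I|b|c|n|o|s|p"
    r"|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)

PAD, BOS, EOS = "<pad>", "<bos>", "<eos>"


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into vocabulary tokens; exact round-trip required."""
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ParseError(f"SMILES does not tokenize cleanly: {smiles!r}")
    return tokens


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token list with reserved pad/bos/eos slots at indices 0..2."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tokens[:3] != (PAD, BOS, EOS):
            raise ConfigError("vocabulary must start with <pad>, <bos>, <eos>")
        if len(set(self.tokens)) != len(self.tokens):
            raise ConfigError("vocabulary tokens must be unique")
        object.__setattr__(
            self, "_index", {t: i for i, t in enumerate(self.tokens)}
        )

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def bos_id(self) -> int:
        return 1

    @property
    def eos_id(self) -> int:
        return 2

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(self, smiles: str) -> list[int]:
        idx = self._index
        try:
            return [self.bos_id] + [idx[t] for t in tokenize(smiles)] + [self.eos_id]
        except KeyError as exc:
            raise ParseError(f"token {exc.args[0]!r} not in vocabulary: {smiles!r}") from exc

    def decode(self, ids: Sequence[int]) -> str:
        out = []
        for i in ids:
            if i == self.eos_id:
                break
            if i in (self.pad_id, self.bos_id):
                continue
            out.append(self.tokens[i])
        return "".join(out)

    @classmethod
    def from_corpus(cls, smiles_list: Sequence[str]) -> "TokenVocabulary":
        seen: set[str] = set()
        for s in smiles_list:
            seen.update(tokenize(s))
        return cls(tokens=(PAD, BOS, EOS) + tuple(sorted(seen)))


# --------------------------------------------------------------------------
# GRU parameters and math
# --------------------------------------------------------------------------

def _init_params(vocab_size: int, embed_dim: int, hidden_dim: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    def glorot(fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_in, fan_out)).astype(np.float64)

    H = hidden_dim
    return {
        "E": glorot(vocab_size, embed_dim),
        "W": glorot(embed_dim, 3 * H),   # input -> [z, r, candidate]
        "U_zr": glorot(H, 2 * H),        # hidden -> [z, r]
        "U_h": glorot(H, H),             # (r * hidden) -> candidate
        "b": np.zeros(3 * H),
        "Wo": glorot(H, vocab_size),
        "bo": np.zeros(vocab_size),
    }


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _gru_step(params, x_emb, h_prev):
    """One GRU step. Returns h_t and the intermediates needed for backprop."""
    H = h_prev.shape[1]
    xW = x_emb @ params["W"] + params["b"]
    zr = _sigmoid(xW[:, : 2 * H] + h_prev @ params["U_zr"])
    z, r = zr[:, :H], zr[:, H:]
    rh = r * h_prev
    h_tilde = np.tanh(xW[:, 2 * H :] + rh @ params["U_h"])
    h = (1.0 - z) * h_prev + z * h_tilde
    return h, (z, r, h_tilde, rh)


def _softmax(logits):
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class GenerativeModel:
    """A SMILES GRU with its vocabulary and training provenance."""

    vocabulary: TokenVocabulary
    params: dict[str, np.ndarray]
    training_meta: dict = field(default_factory=dict)

    @property
    def hidden_dim(self) -> int:
        return self.params["U_h"].shape[0]

    def clone(self) -> "GenerativeModel":
        return GenerativeModel(
            vocabulary=self.vocabulary,
            params={k: v.copy() for k, v in self.params.items()},
            training_meta=copy.deepcopy(self.training_meta),
        )


# --------------------------------------------------------------------------
# Loss and gradients
# --------------------------------------------------------------------------

def _batch_arrays(encoded: Sequence[Sequence[int]], pad_id: int) -> np.ndarray:
    T = max(len(e) for e in encoded)
    out = np.full((len(encoded), T), pad_id, dtype=np.int64)
    for i, e in enumerate(encoded):
        out[i, : len(e)] = e
    return out


def _forward_loss(params, batch, pad_id, with_grads=False):
    """Mean next-token cross-entropy over non-pad targets; optional BPTT grads."""
    inputs, targets = batch[:, :-1], batch[:, 1:]
    B, T = inputs.shape
    H = params["U_h"].shape[0]
    mask = (targets != pad_id).astype(np.float64)
    n_tok = mask.sum()
    h = np.zeros((B, H))
    caches, hs, dlogits_steps = [], [h], []
    loss = 0.0
    for t in range(T):
        x_emb = params["E"][inputs[:, t]]
        h, cache = _gru_step(params, x_emb, h)
        logits = h @ params["Wo"] + params["bo"]
        probs = _softmax(logits)
        tgt = targets[:, t]
        loss -= (np.log(probs[np.arange(B), tgt] + 1e-12) * mask[:, t]).sum()
        if with_grads:
            d = probs.copy()
            d[np.arange(B), tgt] -= 1.0
            d *= mask[:, t][:, None] / n_tok
            dlogits_steps.append(d)
            caches.append((x_emb, cache))
            hs.append(h)
    loss /= max(n_tok, 1.0)
    if not with_grads:
        return loss, None

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dh_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x_emb, (z, r, h_tilde, rh) = caches[t]
        h_prev = hs[t]
        h_t = hs[t + 1]
        d = dlogits_steps[t]
        grads["Wo"] += h_t.T @ d
        grads["bo"] += d.sum(axis=0)
        dh = d @ params["Wo"].T + dh_next
        dz = dh * (h_tilde - h_prev)
        dht = dh * z
        dh_prev = dh * (1.0 - z)
        da_h = dht * (1.0 - h_tilde ** 2)
        grads["U_h"] += rh.T @ da_h
        drh = da_h @ params["U_h"].T
        dh_prev += drh * r
        dr = drh * h_prev
        da_z = dz * z * (1.0 - z)
        da_r = dr * r * (1.0 - r)
        da_zr = np.concatenate([da_z, da_r], axis=1)
        grads["U_zr"] += h_prev.T @ da_zr
        dh_prev += da_zr @ params["U_zr"].T
        da_all = np.concatenate([da_zr, da_h], axis=1)
        grads["W"] += x_emb.T @ da_all
        grads["b"] += da_all.sum(axis=0)
        dx = da_all @ params["W"].T
        np.add.at(grads["E"], inputs[:, t], dx)
        dh_next = dh_prev
    return loss, grads


class _Adam:
    def __init__(self, params, lr=3e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads, clip=5.0):
        norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
        scale = clip / norm if norm > clip else 1.0
        self.t += 1
        for k in params:
            g = grads[k] * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _as_smiles(items) -> list[str]:
    """Accept Molecules, ScoredMolecules, or raw SMILES strings."""
    out = []
    for it in items:
        if isinstance(it, Molecule):
            out.append(it.smiles_canonical)
        elif isinstance(it, str):
            out.append(it)
        elif hasattr(it, "molecule"):
            out.append(it.molecule.smiles_canonical)
        else:
            raise ConfigError(f"cannot interpret corpus item {it!r}")
    return out


def _train(model: GenerativeModel, smiles: list[str], epochs: int, seed: int,
           lr: float, batch_size: int) -> None:
    """In-place training loop over encoded SMILES (no validation logic)."""
    vocab = model.vocabulary
    encoded = []
    for s in smiles:
        try:
            encoded.append(vocab.encode(s))
        except ParseError as exc:
            warnings.warn(f"skipping untokenizable SMILES: {exc}", stacklevel=3)
    if not encoded:
        raise ConfigError("no trainable SMILES after tokenization")
    opt = _Adam(model.params, lr=lr)
    rng = np.random.default_rng(seed)
    for _epoch in range(epochs):
        order = rng.permutation(len(encoded))
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            batch = _batch_arrays([encoded[i] for i in idx], vocab.pad_id)
            _, grads = _forward_loss(model.params, batch, vocab.pad_id, with_grads=True)
            opt.step(model.params, grads)


def held_out_loss(model: GenerativeModel, smiles: Sequence[str],
                  batch_size: int = 256) -> float:
    """Mean next-token cross-entropy of the model on a SMILES list."""
    vocab = model.vocabulary
    encoded = [vocab.encode(s) for s in smiles]
    total, n = 0.0, 0
    for start in range(0, len(encoded), batch_size):
        chunk = encoded[start : start + batch_size]
        batch = _batch_arrays(chunk, vocab.pad_id)
        ntok = int((batch[:, 1:] != vocab.pad_id).sum())
        loss, _ = _forward_loss(model.params, batch, vocab.pad_id)
        total += loss * ntok
        n += ntok
    return total / max(n, 1)


def pretrain(
    corpus,
    epochs: int,
    seed: int,
    embed_dim: int = 48,
    hidden_dim: int = 128,
    lr: float = 3e-3,
    batch_size: int = 64,
    val_fraction: float = 0.1,
) -> GenerativeModel:
    """Pretrain a GRU on a general SMILES corpus.

    The vocabulary is built from the corpus; 10% (seeded split) is held out
    and its cross-entropy recorded per epoch in ``training_meta`` (epoch 0 =
    untrained). ``epochs=0`` returns the randomly initialized model.
    """
    smiles = _as_smiles(corpus)
    if len(smiles) == 0:
        raise ConfigError("empty pretraining corpus")
    vocab = TokenVocabulary.from_corpus(smiles)
    rng = np.random.default_rng(seed)
    params = _init_params(len(vocab), embed_dim, hidden_dim, rng)
    model = GenerativeModel(vocabulary=vocab, params=params)
    order = rng.permutation(len(smiles))
    n_val = max(1, int(round(val_fraction * len(smiles)))) if len(smiles) > 10 else 0
    val = [smiles[i] for i in order[:n_val]]
    train = [smiles[i] for i in order[n_val:]] or smiles
    val_losses = [held_out_loss(model, val)] if val else []
    for e in range(epochs):
        _train(model, train, epochs=1, seed=seed + 7919 * (e + 1), lr=lr,
               batch_size=batch_size)
        if val:
            val_losses.append(held_out_loss(model, val))
    model.training_meta = {
        "kind": "pretrain",
        "epochs": epochs,
        "seed": seed,
        "corpus_size": len(smiles),
        "corpus_fingerprint": _corpus_fingerprint(smiles),
        "val_losses": val_losses,
        "embed_dim": embed_dim,
        "hidden_dim": hidden_dim,
        "lr": lr,
        "batch_size": batch_size,
    }
    return model


def bias(
    model: GenerativeModel,
    top_set,
    epochs: int,
    seed: int,
    lr: float = 1e-3,
    batch_size: int = 32,
) -> GenerativeModel:
    """Fine-tune a copy of the model on a top-scoring set (input unchanged).

    Members that cannot be tokenized under the model's vocabulary are
    skipped with a warning, not fatal. ``epochs=0`` returns an exact copy,
    so seeded sampling is bit-identical to the input model.
    """
    smiles = _as_smiles(top_set)
    if len(smiles) == 0:
        raise ConfigError("empty biasing set")
    new = model.clone()
    if epochs > 0:
        _train(new, smiles, epochs=epochs, seed=seed, lr=lr, batch_size=batch_size)
    new.training_meta = dict(model.training_meta)
    new.training_meta.update(
        {
            "kind": "biased",
            "bias_epochs": epochs,
            "bias_seed": seed,
            "bias_set_size": len(smiles),
            "bias_lr": lr,
        }
    )
    return new


def _corpus_fingerprint(smiles: Sequence[str]) -> str:
    import hashlib

    h = hashlib.sha256()
    for s in smiles:
        h.update(s.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


# --------------------------------------------------------------------------
# Sampling
# --------------------------------------------------------------------------

def sample_raw(
    model: GenerativeModel,
    n: int,
    seed: int,
    max_len: int = 120,
    temperature: float = 1.0,
) -> list[str]:
    """Draw ``n`` raw token strings (may be invalid SMILES), seeded.

    All ``n`` sequences advance in one batch, so sampling is fast and
    deterministic: same (model, n, seed, max_len, temperature) -> same list.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    if temperature <= 0:
        raise ConfigError(f"temperature must be > 0, got {temperature}")
    vocab = model.vocabulary
    rng = np.random.default_rng(seed)
    params = model.params
    H = model.hidden_dim
    h = np.zeros((n, H))
    prev = np.full(n, vocab.bos_id, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    seqs = np.full((n, max_len), vocab.pad_id, dtype=np.int64)
    for t in range(max_len):
        x_emb = params["E"][prev]
        h_new, _ = _gru_step(params, x_emb, h)
        h = np.where(alive[:, None], h_new, h)
        logits = h @ params["Wo"] + params["bo"]
        logits[:, vocab.pad_id] = -1e30
        logits[:, vocab.bos_id] = -1e30
        probs = _softmax(logits / temperature)
        u = rng.random(n)
        nxt = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        nxt = np.minimum(nxt, len(vocab) - 1)
        nxt = np.where(alive, nxt, vocab.pad_id)
        seqs[:, t] = nxt
        alive &= nxt != vocab.eos_id
        prev = np.where(alive, nxt, prev)
        if not alive.any():
            break
    return [vocab.decode(seqs[i]) for i in range(n)]


def sample(
    model: GenerativeModel,
    n: int,
    seed: int,
    max_len: int = 120,
    temperature: float = 1.0,
) -> list[Molecule]:
    """Valid, deduplicated molecules among ``n`` raw samples.

    Each molecule's ``source_id`` records the raw-sample index of its first
    occurrence. ``len(result) <= n``. Validity statistics are available via
    :func:`sample_with_stats`.
    """
    mols, _stats = sample_with_stats(model, n, seed, max_len, temperature)
    return mols


def sample_with_stats(
    model: GenerativeModel,
    n: int,
    seed: int,
    max_len: int = 120,
    temperature: float = 1.0,
) -> tuple[list[Molecule], dict]:
    raw = sample_raw(model, n, seed, max_len, temperature)
    mols: list[Molecule] = []
    seen: set[str] = set()
    n_valid = 0
    for i, smi in enumerate(raw):
        if not smi:
            continue
        try:
            mol = chem.canonicalize(smi, source_id=f"sample{i}")
        except ParseError:
            continue
        n_valid += 1
        if mol.smiles_canonical in seen:
            continue
        seen.add(mol.smiles_canonical)
        mols.append(mol)
    stats = {
        "n_raw": n,
        "n_valid": n_valid,
        "n_unique": len(mols),
        "validity_rate": n_valid / n,
    }
    return mols, stats


def validity_rate(model: GenerativeModel, n: int, seed: int,
                  max_len: int = 120, temperature: float = 1.0) -> float:
    _, stats = sample_with_stats(model, n, seed, max_len, temperature)
    return stats["validity_rate"]


# --------------------------------------------------------------------------
# Serialization: single-file .npz checkpoint with embedded vocabulary/meta
# --------------------------------------------------------------------------

def save_model(model: GenerativeModel, path) -> None:
    np.savez_compressed(
        path,
        vocab_json=np.frombuffer(
            json.dumps(list(model.vocabulary.tokens)).encode(), dtype=np.uint8
        ),
        meta_json=np.frombuffer(
            json.dumps(model.training_meta).encode(), dtype=np.uint8
        ),
        **{f"param_{k}": v for k, v in model.params.items()},
    )


def load_model(path) -> GenerativeModel:
    with np.load(path, allow_pickle=False) as z:
        tokens = tuple(json.loads(bytes(z["vocab_json"]).decode()))
        meta = json.loads(bytes(z["meta_json"]).decode())
        params = {
            k[len("param_"):]: z[k].copy() for k in z.files if k.startswith("param_")
        }
    return GenerativeModel(
        vocabulary=TokenVocabulary(tokens=tokens), params=params, training_meta=meta
    )
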