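"""A small decoder-only transformer over binding-interaction tokens.

GPT-2 style architecture in plain numpy: learned token + positional
embeddings, pre-layer-norm blocks (causal multi-head self-attention and a
GELU MLP), a final layer norm, and an output head tied to the token
embedding.  Training uses AdamW with linear warmup followed by linear decay
of the learning rate, next-token cross-entropy, and full masking of [PAD]
positions in both attention and the loss.  Forward and backward passes are
written out explicitly; everything is deterministic for a fixed seed.

The desk-scale configurations used in tests (hidden 32-64, 2 layers) are
first-class; the classic GPT-2 small/medium shapes are provided as presets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .corpus import PAD_ID, TokenizedSample

_NEG_INF = -1e9
_GELU_C = math.sqrt(2.0 / math.pi)
_GELU_A = 0.044715


@dataclass
class LMConfig:
    hidden_size: int = 32
    n_layers: int = 2
    n_heads: int = 2
    max_seq_len: int = 64
    batch_size: int = 8
    peak_lr: float = 6e-4
    warmup_steps: int = 20
    linear_decay: bool = True
    epochs: int = 1
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hidden_size", "n_layers", "n_heads", "max_seq_len",
                     "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")


#: the published GPT-2 shapes, as configuration presets only
GPT2_SMALL = dict(hidden_size=768, n_layers=12, n_heads=12, max_seq_len=1024,
                  batch_size=112, peak_lr=6e-4, warmup_steps=1600)
GPT2_MEDIUM = dict(hidden_size=1024, n_layers=24, n_heads=16, max_seq_len=1024,
                   batch_size=100, peak_lr=2e-4, warmup_steps=1600)


@dataclass
class GenerationParams:
    temperature: float = 0.7
    repetition_penalty: float = 2.0
    max_new_words: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.repetition_penalty < 1:
            raise ValueError("repetition penalty must be >= 1")


@dataclass
class ModelState:
    params: dict[str, np.ndarray]
    config: LMConfig
    vocab_size: int
    step: int = 0
    opt_state: dict = field(default_factory=dict, repr=False)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.params)
        (d / "config.json").write_text(json.dumps(
            {"config": asdict(self.config), "vocab_size": self.vocab_size,
             "step": self.step}), encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelState":
        d = Path(directory)
        meta = json.loads((d / "config.json").read_text(encoding="utf-8"))
        with np.load(d / "weights.npz") as data:
            params = {k: data[k].copy() for k in data.files}
        return cls(params=params, config=LMConfig(**meta["config"]),
                   vocab_size=meta["vocab_size"], step=meta["step"])


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_model(config: LMConfig, vocab_size: int) -> ModelState:
    """Seeded GPT-2 style initialization (N(0, 0.02), residual projections
    scaled down by 1/sqrt(2*n_layers), tied output head)."""
    rng = np.random.default_rng(config.seed)
    d, L = config.hidden_size, config.n_layers
    res_scale = 1.0 / math.sqrt(2 * L)

    def normal(*shape, scale=0.02):
        return rng.normal(0.0, scale, size=shape)

    p: dict[str, np.ndarray] = {
        "wte": normal(vocab_size, d),
        "wpe": normal(config.max_seq_len, d),
        "lnf_g": np.ones(d), "lnf_b": np.zeros(d),
    }
    for i in range(L):
        p[f"h{i}.ln1_g"] = np.ones(d)
        p[f"h{i}.ln1_b"] = np.zeros(d)
        p[f"h{i}.qkv_w"] = normal(d, 3 * d)
        p[f"h{i}.qkv_b"] = np.zeros(3 * d)
        p[f"h{i}.attn_out_w"] = normal(d, d, scale=0.02 * res_scale)
        p[f"h{i}.attn_out_b"] = np.zeros(d)
        p[f"h{i}.ln2_g"] = np.ones(d)
        p[f"h{i}.ln2_b"] = np.zeros(d)
        p[f"h{i}.mlp_fc_w"] = normal(d, 4 * d)
        p[f"h{i}.mlp_fc_b"] = np.zeros(4 * d)
        p[f"h{i}.mlp_out_w"] = normal(4 * d, d, scale=0.02 * res_scale)
        p[f"h{i}.mlp_out_b"] = np.zeros(d)
    return ModelState(params=p, config=config, vocab_size=vocab_size)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _layernorm_fwd(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dg, db


def _gelu_fwd(x):
    u = _GELU_C * (x + _GELU_A * x ** 3)
    t = np.tanh(u)
    return 0.5 * x * (1.0 + t), (x, t)


def _gelu_bwd(dy, cache):
    x, t = cache
    du = _GELU_C * (1.0 + 3.0 * _GELU_A * x * x)
    return dy * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du)


def _softmax(z):
    z = z - z.max(-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(-1, keepdims=True)


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _forward(model: ModelState, ids: np.ndarray, n_real: np.ndarray,
             want_cache: bool = False):
    """Logits (B, T, V) for a batch; attention sees neither future positions
    nor [PAD] keys."""
    p = model.params
    cfg = model.config
    B, T = ids.shape
    d, nh = cfg.hidden_size, cfg.n_heads
    hd = d // nh

    x = p["wte"][ids] + p["wpe"][:T][None, :, :]
    causal = np.tril(np.ones((T, T), dtype=bool))
    key_ok = np.arange(T)[None, :] < n_real[:, None]          # (B, T)
    mask = causal[None, None, :, :] & key_ok[:, None, None, :]  # (B,1,T,T)

    caches = []
    for i in range(cfg.n_layers):
        ln1, c_ln1 = _layernorm_fwd(x, p[f"h{i}.ln1_g"], p[f"h{i}.ln1_b"])
        qkv = ln1 @ p[f"h{i}.qkv_w"] + p[f"h{i}.qkv_b"]
        q, k, v = np.split(qkv, 3, axis=-1)
        q = q.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        k = k.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        v = v.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        att = (q @ k.transpose(0, 1, 3, 2)) / math.sqrt(hd)
        att = np.where(mask, att, _NEG_INF)
        P = _softmax(att)
        y = (P @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        attn_out = y @ p[f"h{i}.attn_out_w"] + p[f"h{i}.attn_out_b"]
        x1 = x + attn_out
        ln2, c_ln2 = _layernorm_fwd(x1, p[f"h{i}.ln2_g"], p[f"h{i}.ln2_b"])
        fc = ln2 @ p[f"h{i}.mlp_fc_w"] + p[f"h{i}.mlp_fc_b"]
        act, c_gelu = _gelu_fwd(fc)
        mlp_out = act @ p[f"h{i}.mlp_out_w"] + p[f"h{i}.mlp_out_b"]
        x2 = x1 + mlp_out
        if want_cache:
            caches.append((c_ln1, ln1, q, k, v, P, y, c_ln2, ln2, act, c_gelu, x, x1))
        x = x2

    hf, c_lnf = _layernorm_fwd(x, p["lnf_g"], p["lnf_b"])
    logits = hf @ p["wte"].T
    if want_cache:
        return logits, (ids, mask, caches, hf, c_lnf)
    return logits


def forward_logits(model: ModelState, ids: np.ndarray, n_real) -> np.ndarray:
    """Public forward pass.  ``ids``: (T,) or (B, T); returns matching logits."""
    ids = np.asarray(ids, dtype=np.int64)
    single = ids.ndim == 1
    if single:
        ids = ids[None, :]
    n_real = np.atleast_1d(np.asarray(n_real, dtype=np.int64))
    logits = _forward(model, ids, n_real)
    return logits[0] if single else logits


def _backward(model: ModelState, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
    p = model.params
    cfg = model.config
    ids, mask, caches, hf, c_lnf = cache
    B, T = ids.shape
    d, nh = cfg.hidden_size, cfg.n_heads
    hd = d // nh

    grads = {k: np.zeros_like(v) for k, v in p.items()}
    grads["wte"] += np.einsum("btv,btd->vd", dlogits, hf)
    dhf = dlogits @ p["wte"]
    dx, grads["lnf_g"], grads["lnf_b"] = _layernorm_bwd(dhf, c_lnf)

    for i in reversed(range(cfg.n_layers)):
        (c_ln1, ln1, q, k, v, P, y, c_ln2, ln2, act, c_gelu, x_in, x1) = caches[i]
        # MLP branch
        dmlp_out = dx
        grads[f"h{i}.mlp_out_w"] += act.reshape(-1, 4 * d).T @ dmlp_out.reshape(-1, d)
        grads[f"h{i}.mlp_out_b"] += dmlp_out.sum((0, 1))
        dact = dmlp_out @ p[f"h{i}.mlp_out_w"].T
        dfc = _gelu_bwd(dact, c_gelu)
        grads[f"h{i}.mlp_fc_w"] += ln2.reshape(-1, d).T @ dfc.reshape(-1, 4 * d)
        grads[f"h{i}.mlp_fc_b"] += dfc.sum((0, 1))
        dln2 = dfc @ p[f"h{i}.mlp_fc_w"].T
        dx1_ln, grads[f"h{i}.ln2_g"], grads[f"h{i}.ln2_b"] = _layernorm_bwd(dln2, c_ln2)
        dx1 = dx + dx1_ln
        # attention branch
        dattn_out = dx1
        grads[f"h{i}.attn_out_w"] += y.reshape(-1, d).T @ dattn_out.reshape(-1, d)
        grads[f"h{i}.attn_out_b"] += dattn_out.sum((0, 1))
        dy = (dattn_out @ p[f"h{i}.attn_out_w"].T).reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        dP = dy @ v.transpose(0, 1, 3, 2)
        dv = P.transpose(0, 1, 3, 2) @ dy
        datt = P * (dP - (dP * P).sum(-1, keepdims=True))
        datt = np.where(mask, datt, 0.0) / math.sqrt(hd)
        dq = datt @ k
        dk = datt.transpose(0, 1, 3, 2) @ q
        dqkv = np.concatenate([
            g.transpose(0, 2, 1, 3).reshape(B, T, d) for g in (dq, dk, dv)], axis=-1)
        grads[f"h{i}.qkv_w"] += ln1.reshape(-1, d).T @ dqkv.reshape(-1, 3 * d)
        grads[f"h{i}.qkv_b"] += dqkv.sum((0, 1))
        dln1 = dqkv @ p[f"h{i}.qkv_w"].T
        dx_ln, grads[f"h{i}.ln1_g"], grads[f"h{i}.ln1_b"] = _layernorm_bwd(dln1, c_ln1)
        dx = dx1 + dx_ln

    # embeddings
    np.add.at(grads["wte"], ids.reshape(-1), dx.reshape(-1, d))
    grads["wpe"][:T] += dx.sum(0)
    return grads


def _loss_and_dlogits(logits: np.ndarray, ids: np.ndarray):
    """Mean next-token cross-entropy over positions whose target is not [PAD];
    padded positions contribute exactly zero."""
    B, T, V = logits.shape
    targets = ids[:, 1:]
    valid = targets != PAD_ID
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, np.zeros_like(logits)
    lg = logits[:, :-1, :]
    lse = lg - lg.max(-1, keepdims=True)
    log_probs = lse - np.log(np.exp(lse).sum(-1, keepdims=True))
    picked = np.take_along_axis(log_probs, targets[..., None], axis=-1)[..., 0]
    loss = -(picked * valid).sum() / n_valid
    probs = np.exp(log_probs)
    dlg = probs.copy()
    np.put_along_axis(dlg, targets[..., None],
                      np.take_along_axis(dlg, targets[..., None], axis=-1) - 1.0, axis=-1)
    dlg *= valid[..., None] / n_valid
    dlogits = np.zeros_like(logits)
    dlogits[:, :-1, :] = dlg
    return float(loss), dlogits


def batch_loss(model: ModelState, samples: list[TokenizedSample]) -> float:
    ids = np.stack([s.ids for s in samples])
    n_real = np.array([s.n_real for s in samples])
    logits = _forward(model, ids, n_real)
    loss, _ = _loss_and_dlogits(logits, ids)
    return loss


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _lr_at(step: int, cfg: LMConfig, total_steps: int) -> float:
    if step <= cfg.warmup_steps:
        return cfg.peak_lr * step / max(1, cfg.warmup_steps)
    if not cfg.linear_decay:
        return cfg.peak_lr
    rest = max(1, total_steps - cfg.warmup_steps)
    return cfg.peak_lr * max(0.0, (total_steps - step) / rest)


def train(model: ModelState, samples: list[TokenizedSample],
          config: LMConfig | None = None) -> list[float]:
    """AdamW training for ``config.epochs`` epochs (default one, matching a
    single pass over the training tokens).  Mutates the model in place and
    returns the per-step loss trace."""
    if not samples:
        raise ValueError("cannot train on an empty sample list")
    cfg = config or model.config
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(samples)
    n_batches = math.ceil(n / cfg.batch_size)
    total_steps = cfg.epochs * n_batches

    opt = model.opt_state
    if not opt:
        opt.update(m={k: np.zeros_like(v) for k, v in model.params.items()},
                   v={k: np.zeros_like(v) for k, v in model.params.items()})
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    losses: list[float] = []

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for b in range(n_batches):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            ids = np.stack([samples[i].ids for i in idx])
            n_real = np.array([samples[i].n_real for i in idx])
            logits, cache = _forward(model, ids, n_real, want_cache=True)
            loss, dlogits = _loss_and_dlogits(logits, ids)
            grads = _backward(model, dlogits, cache)

            model.step += 1
            lr = _lr_at(model.step, cfg, total_steps)
            t = model.step
            for k, g in grads.items():
                opt["m"][k] = beta1 * opt["m"][k] + (1 - beta1) * g
                opt["v"][k] = beta2 * opt["v"][k] + (1 - beta2) * g * g
                mhat = opt["m"][k] / (1 - beta1 ** t)
                vhat = opt["v"][k] / (1 - beta2 ** t)
                update = mhat / (np.sqrt(vhat) + eps)
                if model.params[k].ndim >= 2:
                    update = update + cfg.weight_decay * model.params[k]
                model.params[k] -= lr * update
            losses.append(loss)
    return losses


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def sequence_logits(model: ModelState, sample: TokenizedSample) -> np.ndarray:
    """Per-token logits averaged over the sample's non-padding positions:
    one vector of length V per sentence."""
    if sample.n_real < 1:
        raise ValueError("sample has no real tokens")
    T = sample.n_real
    logits = forward_logits(model, sample.ids[:T], T)
    return logits.mean(axis=0)


def next_token_logits(model: ModelState, prompt_ids: list[int] | np.ndarray) -> np.ndarray:
    """Logits for the token following the prompt (length-V vector)."""
    prompt_ids = np.asarray(prompt_ids, dtype=np.int64)
    if prompt_ids.size == 0:
        raise ValueError("prompt must be non-empty")
    logits = forward_logits(model, prompt_ids, prompt_ids.size)
    return logits[-1]


def _penalized(logits: np.ndarray, seen_ids: set[int], penalty: float) -> np.ndarray:
    out = logits.copy()
    for i in seen_ids:
        out[i] = out[i] / penalty if out[i] > 0 else out[i] * penalty
    return out


def sample_next_token(model: ModelState, prompt_ids, params: GenerationParams,
                      rng: np.random.Generator | None = None,
                      extra_seen: set[int] | None = None) -> int:
    """One token from softmax(penalized_logits / temperature).  Tokens already
    present in the prompt (or emitted earlier) have positive logits divided
    by — and negative logits multiplied by — the repetition penalty."""
    rng = rng or np.random.default_rng(params.seed)
    seen = set(int(i) for i in np.asarray(prompt_ids).ravel())
    if extra_seen:
        seen |= extra_seen
    logits = _penalized(next_token_logits(model, prompt_ids), seen,
                        params.repetition_penalty)
    probs = _softmax(logits / params.temperature)
    return int(rng.choice(len(probs), p=probs))


def generate_next_word(model: ModelState, prompt_ids, params: GenerationParams,
                       vocab, rng: np.random.Generator | None = None) -> str:
    """Sample the next binding-interaction word after the prompt.

    With a word-level :class:`~bindtext.corpus.Vocabulary` one token is one
    word.  With a :class:`~bindtext.corpus.BpeTokenizer` sub-tokens are
    sampled and concatenated until the accumulated string parses as a
    complete word (whitespace never appears in the token stream, so the
    grammar itself provides the word boundary), capped at 32 sub-tokens."""
    from .corpus import BpeTokenizer
    from .words import parse_word

    rng = rng or np.random.default_rng(params.seed)
    if isinstance(vocab, BpeTokenizer):
        ids = list(np.asarray(prompt_ids).ravel())
        pieces: list[int] = []
        for _ in range(32):
            tok = sample_next_token(model, ids, params, rng=rng, extra_seen=set(pieces))
            pieces.append(tok)
            ids.append(tok)
            text = vocab.decode(pieces)
            try:
                parse_word(text)
                return text
            except ValueError:
                continue
        return vocab.decode(pieces)
    tok = sample_next_token(model, prompt_ids, params, rng=rng)
    return vocab.token_of(tok)
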