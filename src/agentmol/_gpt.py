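"""A small decoder-only transformer (GPT-style) in numpy with manual backprop.

Pre-norm blocks: x + attn(ln1(x)), then x + mlp(ln2(x)); learned positional
embeddings; causal masked multi-head self-attention; weight-tied output
head. Big enough for protein-conditioned SMILES modelling at fixture scale,
small enough to train on one CPU.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ._nn import gelu, gelu_grad, layernorm_backward, layernorm_forward, softmax

NEG_INF = -1e9


class TinyGPT:
    def __init__(self, vocab_size: int, context_window: int, n_layers: int,
                 n_heads: int, d_model: int, seed: int = 0):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.vocab_size = vocab_size
        self.context_window = context_window
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_model = d_model
        rng = np.random.default_rng(seed)
        d = d_model
        sd = 0.02
        p: dict[str, np.ndarray] = {
            "wte": rng.normal(0, sd, (vocab_size, d)),
            "wpe": rng.normal(0, sd, (context_window, d)),
            "lnf.g": np.ones(d),
            "lnf.b": np.zeros(d),
        }
        # residual projections get the 1/sqrt(2L) shrink customary for GPT inits
        proj_sd = sd / np.sqrt(2 * n_layers)
        for l in range(n_layers):
            p[f"l{l}.ln1.g"] = np.ones(d)
            p[f"l{l}.ln1.b"] = np.zeros(d)
            p[f"l{l}.attn.w"] = rng.normal(0, sd, (d, 3 * d))
            p[f"l{l}.attn.b"] = np.zeros(3 * d)
            p[f"l{l}.proj.w"] = rng.normal(0, proj_sd, (d, d))
            p[f"l{l}.proj.b"] = np.zeros(d)
            p[f"l{l}.ln2.g"] = np.ones(d)
            p[f"l{l}.ln2.b"] = np.zeros(d)
            p[f"l{l}.fc.w"] = rng.normal(0, sd, (d, 4 * d))
            p[f"l{l}.fc.b"] = np.zeros(4 * d)
            p[f"l{l}.fc2.w"] = rng.normal(0, proj_sd, (4 * d, d))
            p[f"l{l}.fc2.b"] = np.zeros(d)
        self.params = p

    # ------------------------------------------------------------------
    def _forward(self, ids: np.ndarray, need_cache: bool):
        p = self.params
        B, T = ids.shape
        if T > self.context_window:
            raise ValueError(f"sequence length {T} exceeds context window")
        H, d = self.n_heads, self.d_model
        dh = d // H
        scale = 1.0 / np.sqrt(dh)
        causal = np.triu(np.full((T, T), NEG_INF), k=1)

        x = p["wte"][ids] + p["wpe"][:T]
        caches = []
        for l in range(self.n_layers):
            y, ln1c = layernorm_forward(x, p[f"l{l}.ln1.g"], p[f"l{l}.ln1.b"])
            qkv = y @ p[f"l{l}.attn.w"] + p[f"l{l}.attn.b"]
            q, k, v = np.split(qkv, 3, axis=-1)
            q = q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            k = k.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            v = v.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            att = q @ k.transpose(0, 1, 3, 2) * scale + causal
            P = softmax(att)
            ctx = (P @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
            attn_out = ctx @ p[f"l{l}.proj.w"] + p[f"l{l}.proj.b"]
            x1 = x + attn_out
            y2, ln2c = layernorm_forward(x1, p[f"l{l}.ln2.g"], p[f"l{l}.ln2.b"])
            h = y2 @ p[f"l{l}.fc.w"] + p[f"l{l}.fc.b"]
            a = gelu(h)
            mlp_out = a @ p[f"l{l}.fc2.w"] + p[f"l{l}.fc2.b"]
            x2 = x1 + mlp_out
            if need_cache:
                caches.append((y, ln1c, q, k, v, P, ctx, x1, y2, ln2c, h, a))
            x = x2
        hf, lnfc = layernorm_forward(x, p["lnf.g"], p["lnf.b"])
        logits = hf @ p["wte"].T
        return logits, (ids, caches, hf, lnfc)

    def logits(self, ids: np.ndarray) -> np.ndarray:
        """Forward pass only; ``ids`` is (B, T) int."""
        out, _ = self._forward(np.asarray(ids), need_cache=False)
        return out

    # ------------------------------------------------------------------
    def loss_and_grads(self, ids: np.ndarray, pad_id: int):
        """Mean next-token cross-entropy (pad targets masked) and gradients.

        ``ids`` is (B, T); inputs are ids[:, :-1], targets ids[:, 1:].
        """
        ids = np.asarray(ids)
        inp, tgt = ids[:, :-1], ids[:, 1:]
        mask = (tgt != pad_id).astype(float)
        denom = max(mask.sum(), 1.0)
        logits, (_, caches, hf, lnfc) = self._forward(inp, need_cache=True)
        B, T, V = logits.shape
        probs = softmax(logits)
        idx_b, idx_t = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
        nll = -np.log(np.clip(probs[idx_b, idx_t, tgt], 1e-12, None))
        loss = float((nll * mask).sum() / denom)

        dlogits = probs.copy()
        dlogits[idx_b, idx_t, tgt] -= 1.0
        dlogits *= (mask / denom)[..., None]

        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        H, d = self.n_heads, self.d_model
        dh = d // H
        scale = 1.0 / np.sqrt(dh)

        grads["wte"] += np.einsum("btv,btd->vd", dlogits, hf)
        dhf = dlogits @ p["wte"]
        dx, dg, db = layernorm_backward(dhf, lnfc)
        grads["lnf.g"] += dg
        grads["lnf.b"] += db

        for l in reversed(range(self.n_layers)):
            y, ln1c, q, k, v, P, ctx, x1, y2, ln2c, h, a = caches[l]
            # mlp branch
            dmlp = dx
            grads[f"l{l}.fc2.w"] += a.reshape(-1, 4 * d).T @ dmlp.reshape(-1, d)
            grads[f"l{l}.fc2.b"] += dmlp.sum(axis=(0, 1))
            da = dmlp @ p[f"l{l}.fc2.w"].T
            dhh = da * gelu_grad(h)
            grads[f"l{l}.fc.w"] += y2.reshape(-1, d).T @ dhh.reshape(-1, 4 * d)
            grads[f"l{l}.fc.b"] += dhh.sum(axis=(0, 1))
            dy2 = dhh @ p[f"l{l}.fc.w"].T
            dx1_ln, dg, db = layernorm_backward(dy2, ln2c)
            grads[f"l{l}.ln2.g"] += dg
            grads[f"l{l}.ln2.b"] += db
            dx1 = dx + dx1_ln
            # attention branch
            dattn_out = dx1
            grads[f"l{l}.proj.w"] += ctx.reshape(-1, d).T @ dattn_out.reshape(-1, d)
            grads[f"l{l}.proj.b"] += dattn_out.sum(axis=(0, 1))
            dctx = (dattn_out @ p[f"l{l}.proj.w"].T).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            dP = dctx @ v.transpose(0, 1, 3, 2)
            dv = P.transpose(0, 1, 3, 2) @ dctx
            datt = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
            dq = datt @ k * scale
            dk = datt.transpose(0, 1, 3, 2) @ q * scale
            dqkv = np.concatenate(
                [
                    dq.transpose(0, 2, 1, 3).reshape(B, T, d),
                    dk.transpose(0, 2, 1, 3).reshape(B, T, d),
                    dv.transpose(0, 2, 1, 3).reshape(B, T, d),
                ],
                axis=-1,
            )
            grads[f"l{l}.attn.w"] += y.reshape(-1, d).T @ dqkv.reshape(-1, 3 * d)
            grads[f"l{l}.attn.b"] += dqkv.sum(axis=(0, 1))
            dy = dqkv @ p[f"l{l}.attn.w"].T
            dx_ln, dg, db = layernorm_backward(dy, ln1c)
            grads[f"l{l}.ln1.g"] += dg
            grads[f"l{l}.ln1.b"] += db
            dx = dx1 + dx_ln

        np.add.at(grads["wte"], inp, dx)
        grads["wpe"][:T] += dx.sum(axis=0)
        return loss, grads

    def eval_loss(self, ids: np.ndarray, pad_id: int) -> float:
        ids = np.asarray(ids)
        inp, tgt = ids[:, :-1], ids[:, 1:]
        mask = (tgt != pad_id).astype(float)
        logits = self.logits(inp)
        probs = softmax(logits)
        B, T, _ = logits.shape
        idx_b, idx_t = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
        nll = -np.log(np.clip(probs[idx_b, idx_t, tgt], 1e-12, None))
        return float((nll * mask).sum() / max(mask.sum(), 1.0))

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cfg = {
            "vocab_size": self.vocab_size,
            "context_window": self.context_window,
            "n_layers": self.n_layers,
            "n_heads": self.n_heads,
            "d_model": self.d_model,
        }
        (path / "model.json").write_text(json.dumps(cfg))
        np.savez(path / "weights.npz", **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "TinyGPT":
        path = Path(path)
        cfg = json.loads((path / "model.json").read_text())
        model = cls(**cfg)
        with np.load(path / "weights.npz") as blob:
            model.params = {k: blob[k].copy() for k in blob.files}
        return model
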