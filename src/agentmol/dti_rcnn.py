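"""Regression convolutional network for drug-target affinity (pKi) prediction.

Input is the character-encoded protein+SMILES pair (800 integer codes, 0 =
pad). An 8-dimensional embedding feeds six 1-D convolution blocks
(kernel 8, "same" padding, filters 32..64), each: conv -> batch
normalization -> leaky ReLU (slope 0.01) -> max-pool (size 2, floor on odd
lengths, 800 -> 400 -> 200 -> 100 -> 50 -> 25 -> 12). The flattened
features pass through dense layers of 512 and 10 units (leaky ReLU) and a
final linear neuron producing the continuous pKi. Training uses RMSprop
(lr 1e-3) with MSE or MAE loss; evaluation reports Pearson's R, R^2 and
RMSE, and the whole experiment can be repeated over randomized 70/30
partitions to summarize stability.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import pearsonr
from sklearn.metrics import mean_squared_error, r2_score

from ._nn import RMSprop
from .data_io import AffinityDataset, split_dataset
from .tokenization import CharVocab, build_char_vocab, encode_for_rcnn

__all__ = [
    "RcnnConfig",
    "RcnnModel",
    "RegressionMetrics",
    "RegressionReport",
    "RepeatSummary",
    "build_rcnn",
    "encode_dataset",
    "train_rcnn",
    "predict_pki",
    "evaluate_regression",
    "repeat_experiment",
]

_BN_EPS = 1e-3
_BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class RcnnConfig:
    embedding_dim: int = 8
    n_conv_layers: int = 6
    kernel_size: int = 8
    filters: tuple[int, ...] = (32, 32, 32, 64, 64, 64)
    pool_size: int = 2
    leaky_slope: float = 0.01
    dense_sizes: tuple[int, ...] = (512, 10)
    learning_rate: float = 0.001
    epochs: int = 200
    loss: str = "mse"
    batch_size: int = 32
    input_length: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.filters) != self.n_conv_layers:
            raise ValueError("filters length must equal n_conv_layers")
        if any(not 32 <= f <= 64 for f in self.filters):
            raise ValueError("every filter count must lie in [32, 64]")
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("bad training hyperparameters")


def _leaky(x: np.ndarray, a: float) -> np.ndarray:
    return np.where(x > 0, x, a * x)


def _leaky_grad(x: np.ndarray, a: float) -> np.ndarray:
    return np.where(x > 0, 1.0, a)


class RcnnModel:
    """The convolutional pKi regressor; parameters in a flat dict."""

    def __init__(self, cfg: RcnnConfig, vocab_size: int):
        if vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        self.cfg = cfg
        self.vocab_size = vocab_size
        rng = np.random.default_rng(cfg.seed)
        K = cfg.kernel_size
        p: dict[str, np.ndarray] = {"emb": rng.normal(0, 0.1, (vocab_size, cfg.embedding_dim))}
        self.bn_state: dict[str, np.ndarray] = {}
        in_ch, L = cfg.embedding_dim, cfg.input_length
        self.conv_lengths = [L]
        for i, f in enumerate(cfg.filters):
            p[f"c{i}.w"] = rng.normal(0, np.sqrt(2.0 / (K * in_ch)), (K * in_ch, f))
            p[f"c{i}.b"] = np.zeros(f)
            p[f"c{i}.g"] = np.ones(f)
            p[f"c{i}.beta"] = np.zeros(f)
            self.bn_state[f"c{i}.mean"] = np.zeros(f)
            self.bn_state[f"c{i}.var"] = np.ones(f)
            in_ch = f
            L = L // cfg.pool_size
            self.conv_lengths.append(L)
        self.flat_len = L * cfg.filters[-1]
        sizes = [self.flat_len, *cfg.dense_sizes, 1]
        for j in range(len(sizes) - 1):
            p[f"d{j}.w"] = rng.normal(0, np.sqrt(2.0 / sizes[j]), (sizes[j], sizes[j + 1]))
            p[f"d{j}.b"] = np.zeros(sizes[j + 1])
        self.params = p

    # ------------------------------------------------------------------
    def _forward(self, x_ids: np.ndarray, training: bool):
        cfg = self.cfg
        p = self.params
        K, a = cfg.kernel_size, cfg.leaky_slope
        padl = (K - 1) // 2
        padr = K // 2
        x = p["emb"][x_ids]  # (B, L, E)
        caches = []
        for i in range(cfg.n_conv_layers):
            B, L, C = x.shape
            xp = np.pad(x, ((0, 0), (padl, padr), (0, 0)))
            patches = sliding_window_view(xp, K, axis=1).transpose(0, 1, 3, 2)  # (B,L,K,C)
            flat = patches.reshape(B, L, K * C)
            z = flat @ p[f"c{i}.w"] + p[f"c{i}.b"]
            if training:
                mean = z.mean(axis=(0, 1))
                var = z.var(axis=(0, 1))
                self.bn_state[f"c{i}.mean"] = (
                    _BN_MOMENTUM * self.bn_state[f"c{i}.mean"] + (1 - _BN_MOMENTUM) * mean
                )
                self.bn_state[f"c{i}.var"] = (
                    _BN_MOMENTUM * self.bn_state[f"c{i}.var"] + (1 - _BN_MOMENTUM) * var
                )
            else:
                mean = self.bn_state[f"c{i}.mean"]
                var = self.bn_state[f"c{i}.var"]
            inv = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mean) * inv
            bn = p[f"c{i}.g"] * zhat + p[f"c{i}.beta"]
            act = _leaky(bn, a)
            L2 = L // cfg.pool_size
            win = act[:, : L2 * cfg.pool_size].reshape(B, L2, cfg.pool_size, -1)
            arg = win.argmax(axis=2)
            pooled = win.max(axis=2)
            caches.append((x.shape, flat, zhat, inv, bn, arg, L))
            x = pooled
        B = x.shape[0]
        h = x.reshape(B, self.flat_len)
        dense_caches = []
        n_dense = len(self.cfg.dense_sizes) + 1
        for j in range(n_dense):
            z = h @ p[f"d{j}.w"] + p[f"d{j}.b"]
            last = j == n_dense - 1
            out = z if last else _leaky(z, a)
            dense_caches.append((h, z))
            h = out
        pred = h[:, 0]
        return pred, (x_ids, caches, dense_caches)

    def predict(self, x_ids: np.ndarray) -> np.ndarray:
        """Inference-mode predictions (running batch-norm statistics)."""
        pred, _ = self._forward(np.asarray(x_ids), training=False)
        return pred

    # ------------------------------------------------------------------
    def loss_and_grads(self, x_ids: np.ndarray, y: np.ndarray):
        cfg = self.cfg
        p = self.params
        a = cfg.leaky_slope
        K = cfg.kernel_size
        padl = (K - 1) // 2
        pred, (ids, caches, dense_caches) = self._forward(x_ids, training=True)
        resid = pred - y
        B = len(y)
        if cfg.loss == "mse":
            loss = float(np.mean(resid**2))
            dpred = 2.0 * resid / B
        else:
            loss = float(np.mean(np.abs(resid)))
            dpred = np.sign(resid) / B

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dh = dpred[:, None]
        n_dense = len(cfg.dense_sizes) + 1
        for j in reversed(range(n_dense)):
            h_in, z = dense_caches[j]
            dz = dh if j == n_dense - 1 else dh * _leaky_grad(z, a)
            grads[f"d{j}.w"] += h_in.T @ dz
            grads[f"d{j}.b"] += dz.sum(axis=0)
            dh = dz @ p[f"d{j}.w"].T

        dx = dh.reshape(-1, self.conv_lengths[-1], cfg.filters[-1])
        for i in reversed(range(cfg.n_conv_layers)):
            x_shape, flat, zhat, inv, bn, arg, L = caches[i]
            Bc = x_shape[0]
            L2 = L // cfg.pool_size
            F = dx.shape[-1]
            dwin = np.zeros((Bc, L2, cfg.pool_size, F))
            np.put_along_axis(dwin, arg[:, :, None, :], dx[:, :, None, :], axis=2)
            dact = np.zeros((Bc, L, F))
            dact[:, : L2 * cfg.pool_size] = dwin.reshape(Bc, L2 * cfg.pool_size, F)
            dbn = dact * _leaky_grad(bn, a)
            # batch-norm backward over the (batch, position) axes
            N = Bc * L
            grads[f"c{i}.g"] += (dbn * zhat).sum(axis=(0, 1))
            grads[f"c{i}.beta"] += dbn.sum(axis=(0, 1))
            dzhat = dbn * p[f"c{i}.g"]
            dz = inv * (
                dzhat
                - dzhat.mean(axis=(0, 1))
                - zhat * (dzhat * zhat).mean(axis=(0, 1))
            )
            grads[f"c{i}.w"] += flat.reshape(N, -1).T @ dz.reshape(N, F)
            grads[f"c{i}.b"] += dz.sum(axis=(0, 1))
            dflat = dz @ p[f"c{i}.w"].T  # (B, L, K*C)
            C = x_shape[2]
            dpatches = dflat.reshape(Bc, L, K, C)
            dxp = np.zeros((Bc, L + K - 1, C))
            for k in range(K):
                dxp[:, k : k + L] += dpatches[:, :, k]
            dx = dxp[:, padl : padl + L]
        np.add.at(grads["emb"], ids, dx)
        return loss, grads

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "model.json").write_text(
            json.dumps({"cfg": dataclasses.asdict(self.cfg), "vocab_size": self.vocab_size})
        )
        np.savez(path / "weights.npz", **self.params, **{f"bn::{k}": v for k, v in self.bn_state.items()})

    @classmethod
    def load(cls, path: str | Path) -> "RcnnModel":
        path = Path(path)
        blob = json.loads((path / "model.json").read_text())
        cfg_d = blob["cfg"]
        cfg_d["filters"] = tuple(cfg_d["filters"])
        cfg_d["dense_sizes"] = tuple(cfg_d["dense_sizes"])
        model = cls(RcnnConfig(**cfg_d), blob["vocab_size"])
        with np.load(path / "weights.npz") as data:
            for k in data.files:
                if k.startswith("bn::"):
                    model.bn_state[k[4:]] = data[k].copy()
                else:
                    model.params[k] = data[k].copy()
        return model


def build_rcnn(cfg: RcnnConfig, vocab_size: int) -> RcnnModel:
    """Construct the network for a given character-vocabulary size."""
    return RcnnModel(cfg, vocab_size)


def encode_dataset(
    ds: AffinityDataset, vocab: CharVocab
) -> tuple[np.ndarray, np.ndarray]:
    """Character-encode a dataset into (X, y) arrays for the regressor."""
    X = np.array([encode_for_rcnn(p, vocab) for p in ds], dtype=np.int64)
    y = np.array([p.pki for p in ds], dtype=float)
    return X, y


@dataclass(frozen=True)
class RegressionMetrics:
    """Pearson's R, coefficient of determination, and RMSE."""

    pearson_r: float
    r_squared: float
    rmse: float


def evaluate_regression(
    y_true: Sequence[float], y_pred: Sequence[float]
) -> RegressionMetrics:
    """Standard regression scores: sample Pearson R, R^2 = 1-SSres/SStot, RMSE.

    Raises
    ------
    ValueError
        On length mismatch, fewer than two points, or constant ``y_true``
        (correlation undefined).
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size < 2:
        raise ValueError("need at least two observations")
    if np.allclose(yt, yt[0]):
        raise ValueError("y_true is constant; Pearson correlation undefined")
    r = float(pearsonr(yt, yp).statistic)
    r2 = float(r2_score(yt, yp))
    rmse = float(np.sqrt(mean_squared_error(yt, yp)))
    return RegressionMetrics(pearson_r=r, r_squared=r2, rmse=rmse)


@dataclass(frozen=True)
class RegressionReport:
    """Final and first-epoch scores for one training run on one set."""

    pearson_r: float
    r_squared: float
    rmse: float
    final_loss: float
    epoch1_loss: float
    epoch1_rmse: float
    epoch1_r2: float


def train_rcnn(
    model: RcnnModel,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    cfg: RcnnConfig | None = None,
) -> tuple[RcnnModel, list[dict[str, float]]]:
    """Train with RMSprop on the configured loss; returns per-epoch history.

    Each history row holds ``epoch, train_loss, val_loss, val_rmse, val_r2,
    val_r`` (validation scores from inference-mode predictions).
    """
    cfg = model.cfg if cfg is None else cfg
    X, y = train
    Xv, yv = val
    if len(X) == 0 or len(Xv) == 0:
        raise ValueError("train and validation sets must be non-empty")
    opt = RMSprop(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict[str, float]] = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(X))
        losses = []
        for i in range(0, len(X), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            loss, grads = model.loss_and_grads(X[idx], y[idx])
            opt.step(model.params, grads)
            losses.append(loss)
        pv = predict_pki(model, Xv)
        m = evaluate_regression(yv, pv)
        val_loss = (
            float(np.mean((pv - yv) ** 2))
            if cfg.loss == "mse"
            else float(np.mean(np.abs(pv - yv)))
        )
        history.append(
            {
                "epoch": float(epoch),
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_rmse": m.rmse,
                "val_r2": m.r_squared,
                "val_r": m.pearson_r,
            }
        )
    return model, history


def predict_pki(model: RcnnModel, encoded) -> float | np.ndarray:
    """Predict pKi for one encoded pair (length-800 ints) or a batch.

    Raises
    ------
    ValueError
        If the trailing dimension is not the model's input length.
    """
    arr = np.asarray(encoded)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.shape[1] != model.cfg.input_length:
        raise ValueError(
            f"expected encodings of length {model.cfg.input_length}, got {arr.shape[1]}"
        )
    preds = model.predict(arr)
    return float(preds[0]) if single else preds


@dataclass(frozen=True)
class RepeatSummary:
    """Mean (SD) per metric over repeated randomized partitions."""

    n_repeats: int
    metrics: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"n_repeats": self.n_repeats,
                 "metrics": {k: {"mean": m, "sd": s} for k, (m, s) in self.metrics.items()}},
                indent=2,
            )
        )


def _run_once(ds: AffinityDataset, cfg: RcnnConfig, vocab: CharVocab, seed: int):
    train_ds, val_ds = split_dataset(ds, 0.7, seed=seed)
    Xt, yt = encode_dataset(train_ds, vocab)
    Xv, yv = encode_dataset(val_ds, vocab)
    model = build_rcnn(dataclasses.replace(cfg, seed=seed), vocab.size)
    model, history = train_rcnn(model, (Xt, yt), (Xv, yv))
    out: dict[str, float] = {}
    for name, X, yy in (("train", Xt, yt), ("val", Xv, yv)):
        preds = predict_pki(model, X)
        m = evaluate_regression(yy, preds)
        loss = (
            float(np.mean((preds - yy) ** 2))
            if cfg.loss == "mse"
            else float(np.mean(np.abs(preds - yy)))
        )
        out[f"{name}_r"] = m.pearson_r
        out[f"{name}_r2_final"] = m.r_squared
        out[f"{name}_rmse_final"] = m.rmse
        out[f"{name}_loss_final"] = loss
    first = history[0]
    out["val_loss_epoch1"] = first["val_loss"]
    out["val_rmse_epoch1"] = first["val_rmse"]
    out["val_r2_epoch1"] = first["val_r2"]
    return out


def repeat_experiment(
    ds: AffinityDataset,
    cfg: RcnnConfig,
    n_repeats: int = 5,
    seeds: Sequence[int] | None = None,
) -> RepeatSummary:
    """Repeat split/train/evaluate over randomized partitions.

    Each repeat re-splits 70/30 with its own seed, trains a fresh model and
    scores both sets after the first and the final epoch; the summary holds
    the mean and sample SD of every metric over the repeats.
    """
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("need exactly one seed per repeat")
    vocab = build_char_vocab(ds)
    runs = [_run_once(ds, cfg, vocab, int(s)) for s in seeds]
    metrics: dict[str, tuple[float, float]] = {}
    for key in runs[0]:
        vals = np.array([r[key] for r in runs])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        metrics[key] = (float(vals.mean()), sd)
    return RepeatSummary(n_repeats=n_repeats, metrics=metrics)
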