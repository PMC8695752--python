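"""LSTM binary classifier for fixed-length actigraphy tensors.

Architecture: an LSTM layer returning the full hidden sequence, a per-timestep
affine map (a dense layer applied identically at every timestep), a flatten,
and a final affine map to one sigmoid output.  Training uses the Adam
optimiser on mean-absolute-error loss against the binary outcome label.

The network is implemented directly in numpy — forward pass, full
backpropagation through time, and Adam — with one fused input/recurrent
matrix multiply per timestep.  Given a seed and single-threaded BLAS the
whole procedure is bit-reproducible.

LSTM cell (gate order: input i, forget f, candidate g, output o):

    z_t = x_t W_x + h_{t-1} W_h + b
    i, f, o = sigmoid(z_i), sigmoid(z_f), sigmoid(z_o);  g = tanh(z_g)
    c_t = f * c_{t-1} + i * g
    h_t = o * tanh(c_t)
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .preprocess import ProcessedTensor

__all__ = [
    "ModelConfig",
    "LSTMClassifier",
    "build_model",
    "train",
    "predict_proba",
    "classify",
    "lstm_param_count",
    "to_arrays",
]

_F = np.float32


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the classifier.

    The two configurations used in practice are (units=64, batch_size=8,
    epochs=50) and (units=256, batch_size=16, epochs=100), both with Adam at
    its default learning rate and MAE loss.
    """

    units: int = 256
    batch_size: int = 16
    epochs: int = 100
    optimizer: str = "adam"
    loss: str = "mae"
    per_step_dense_width: int = 1
    classification_threshold: float = 0.5
    seed: int = 0
    learning_rate: float = 1e-3
    mask_padding: bool = False
    normalize: bool = False

    def __post_init__(self) -> None:
        for name in ("units", "batch_size", "epochs", "per_step_dense_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 < self.classification_threshold < 1.0:
            raise ValueError("classification_threshold must lie strictly in (0, 1)")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss.lower() not in ("mae", "mean_absolute_error"):
            raise ValueError("only mean-absolute-error loss is supported")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def lstm_param_count(units: int, n_inputs: int) -> int:
    """Closed-form LSTM layer parameter count: 4*(units*(units+n_inputs)+units)."""
    return 4 * (units * (units + n_inputs) + units)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape).astype(_F)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return (q * np.sign(np.diag(r))).astype(_F)


class LSTMClassifier:
    """The sequence classifier; holds parameters, config, and training history."""

    N_CHANNELS = 3

    def __init__(self, cfg: ModelConfig, input_length: int):
        if input_length < 1:
            raise ValueError("input_length must be >= 1")
        self.cfg = cfg
        self.input_length = int(input_length)
        u, w, c = cfg.units, cfg.per_step_dense_width, self.N_CHANNELS

        init_ss, shuffle_ss = np.random.SeedSequence(cfg.seed).spawn(2)
        rng = np.random.default_rng(init_ss)
        self._shuffle_rng = np.random.default_rng(shuffle_ss)

        b = np.zeros(4 * u, dtype=_F)
        b[u : 2 * u] = 1.0  # forget-gate bias init, standard practice
        self.p: dict[str, np.ndarray] = {
            "Wx": _glorot(rng, (c, 4 * u)),
            "Wh": np.concatenate(
                [_orthogonal(rng, u) for _ in range(4)], axis=1
            ),
            "b": b,
            "Wd": _glorot(rng, (u, w)),
            "bd": np.zeros(w, dtype=_F),
            "Wo": _glorot(rng, (self.input_length * w, 1)),
            "bo": np.zeros(1, dtype=_F),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.p.items()}
        self._adam_t = 0
        self.norm_mean: Optional[np.ndarray] = None
        self.norm_std: Optional[np.ndarray] = None
        self.history: dict[str, list[float]] = {
            "epoch": [],
            "train_loss": [],
            "train_acc": [],
            "val_loss": [],
            "val_acc": [],
        }
        self.trained = False

    # -- forward / backward -------------------------------------------------

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.p.values()))

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=_F)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != self.input_length or X.shape[2] != self.N_CHANNELS:
            raise ValueError(
                f"input shape {X.shape[1:]} does not match expected "
                f"({self.input_length}, {self.N_CHANNELS})"
            )
        if self.norm_mean is not None:
            X = (X - self.norm_mean) / self.norm_std
        return X

    def _forward(
        self,
        X: np.ndarray,
        lengths: Optional[np.ndarray] = None,
        want_cache: bool = False,
    ):
        p = self.p
        B, T, _ = X.shape
        u = self.cfg.units
        dt = p["b"].dtype
        h = np.zeros((B, u), dtype=dt)
        c = np.zeros((B, u), dtype=dt)
        H = np.empty((T, B, u), dtype=dt)
        if want_cache:
            I = np.empty((T, B, u), dtype=dt)
            F = np.empty((T, B, u), dtype=dt)
            G = np.empty((T, B, u), dtype=dt)
            O = np.empty((T, B, u), dtype=dt)
            C = np.empty((T, B, u), dtype=dt)
            TC = np.empty((T, B, u), dtype=dt)
        masking = self.cfg.mask_padding and lengths is not None
        if masking:
            lengths = np.asarray(lengths)
        Wx, Wh, b = p["Wx"], p["Wh"], p["b"]
        for t in range(T):
            z = X[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if masking:
                m = (t < lengths)[:, None]
                c_new = np.where(m, c_new, c)
                h_new = np.where(m, h_new, h)
            if want_cache:
                I[t], F[t], G[t], O[t], C[t], TC[t] = i, f, g, o, c_new, tc
            c, h = c_new, h_new
            H[t] = h
        Hb = H.transpose(1, 0, 2)  # (B, T, u)
        S = Hb @ p["Wd"] + p["bd"]  # (B, T, w)
        flat = S.reshape(B, -1)
        logit = flat @ p["Wo"] + p["bo"]
        y = _sigmoid(logit)[:, 0]
        if not want_cache:
            return y
        cache = dict(X=X, I=I, F=F, G=G, O=O, C=C, TC=TC, H=H, flat=flat, y=y,
                     lengths=lengths if masking else None)
        return y, cache

    def _backward(self, cache: dict, targets: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean MAE loss w.r.t. every parameter array."""
        p = self.p
        X, H, flat, y = cache["X"], cache["H"], cache["flat"], cache["y"]
        I, F, G, O, C, TC = (
            cache["I"], cache["F"], cache["G"], cache["O"], cache["C"], cache["TC"]
        )
        lengths = cache["lengths"]
        B, T, _ = X.shape
        u = self.cfg.units
        w = self.cfg.per_step_dense_width
        dt = self.p["b"].dtype

        dy = np.sign(y - targets).astype(dt) / B
        dlogit = (dy * y * (1.0 - y))[:, None]  # (B, 1)
        grads = {
            "Wo": flat.T @ dlogit,
            "bo": dlogit.sum(axis=0),
        }
        dflat = dlogit @ p["Wo"].T  # (B, T*w)
        dS = dflat.reshape(B, T, w)
        Hb = H.transpose(1, 0, 2)
        grads["Wd"] = np.einsum("btu,btw->uw", Hb, dS).astype(dt)
        grads["bd"] = dS.sum(axis=(0, 1))
        dH = (dS @ p["Wd"].T).transpose(1, 0, 2)  # (T, B, u)

        dWx = np.zeros_like(p["Wx"])
        dWh = np.zeros_like(p["Wh"])
        db = np.zeros_like(p["b"])
        WhT = p["Wh"].T
        dh_next = np.zeros((B, u), dtype=dt)
        dc_next = np.zeros((B, u), dtype=dt)
        for t in range(T - 1, -1, -1):
            dh = dH[t] + dh_next
            dc_in = dc_next
            if lengths is not None:
                m = ((t < lengths)[:, None]).astype(dt)
            else:
                m = None
            if m is not None:
                carry_h = dh * (1.0 - m)
                dh = dh * m
                carry_c = dc_in * (1.0 - m)
                dc_in = dc_in * m
            i, f, g, o, tc = I[t], F[t], G[t], O[t], TC[t]
            c_prev = C[t - 1] if t > 0 else np.zeros((B, u), dtype=dt)
            do = dh * tc
            dc = dc_in + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_prev = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += X[:, t].T @ dz
            h_prev = H[t - 1] if t > 0 else np.zeros((B, u), dtype=dt)
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ WhT
            dc_next = dc_prev
            if m is not None:
                dh_next = dh_next + carry_h
                dc_next = dc_next + carry_c
        grads["Wx"], grads["Wh"], grads["b"] = dWx, dWh, db
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        beta1, beta2, eps = 0.9, 0.999, 1e-7
        self._adam_t += 1
        lr = self.cfg.learning_rate * (
            np.sqrt(1.0 - beta2**self._adam_t) / (1.0 - beta1**self._adam_t)
        )
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m += (1.0 - beta1) * (g - m)
            v += (1.0 - beta2) * (g * g - v)
            self.p[k] -= (lr * m / (np.sqrt(v) + eps)).astype(_F)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights as .npz plus a JSON sidecar with config and seed."""
        path = Path(path)
        arrays = dict(self.p)
        if self.norm_mean is not None:
            arrays["norm_mean"] = self.norm_mean
            arrays["norm_std"] = self.norm_std
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "config": asdict(self.cfg),
            "input_length": self.input_length,
            "trained": self.trained,
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LSTMClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = ModelConfig(**sidecar["config"])
        model = cls(cfg, sidecar["input_length"])
        with np.load(path.with_suffix(".npz")) as data:
            for k in model.p:
                model.p[k] = data[k]
            if "norm_mean" in data:
                model.norm_mean = data["norm_mean"]
                model.norm_std = data["norm_std"]
        model.history = sidecar["history"]
        model.trained = sidecar["trained"]
        return model


def build_model(cfg: ModelConfig, input_length: int) -> LSTMClassifier:
    """Construct an untrained classifier for sequences of ``input_length`` steps."""
    return LSTMClassifier(cfg, input_length)


def to_arrays(
    tensors: Sequence[ProcessedTensor],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack processed tensors into (X, y, lengths) arrays for the model."""
    if not tensors:
        raise ValueError("tensor list is empty")
    if any(t.label is None for t in tensors):
        raise ValueError("all tensors must carry a binary label")
    lengths = {len(t) for t in tensors}
    if len(lengths) != 1:
        raise ValueError(f"tensors have mixed padded lengths {sorted(lengths)}")
    X = np.stack([t.values for t in tensors]).astype(_F)
    y = np.array([t.label for t in tensors], dtype=_F)
    valid = np.array([t.valid_length for t in tensors], dtype=np.int64)
    return X, y, valid


def train(
    model: LSTMClassifier,
    train_set: tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray],
    val_set: Optional[tuple] = None,
) -> LSTMClassifier:
    """Train in place for exactly cfg.epochs over shuffled minibatches.

    ``train_set``/``val_set`` are (X, y) or (X, y, valid_lengths) with X of
    shape (n, input_length, 3) and binary y.  Records per-epoch loss and
    accuracy; raises on an empty training set or a NaN loss.
    """
    cfg = model.cfg
    X, y = np.asarray(train_set[0], dtype=_F), np.asarray(train_set[1], dtype=_F)
    lengths = np.asarray(train_set[2]) if len(train_set) > 2 else None
    if len(X) == 0:
        raise ValueError("training set is empty")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")

    if cfg.normalize:
        mu = X.reshape(-1, X.shape[-1]).mean(axis=0)
        sd = X.reshape(-1, X.shape[-1]).std(axis=0)
        sd[sd == 0] = 1.0
        model.norm_mean = mu.astype(_F)
        model.norm_std = sd.astype(_F)
    Xp = model._prepare(X)

    val = None
    if val_set is not None and len(val_set[0]) > 0:
        val = (
            np.asarray(val_set[0], dtype=_F),
            np.asarray(val_set[1], dtype=_F),
            np.asarray(val_set[2]) if len(val_set) > 2 else None,
        )

    n = len(Xp)
    thr = cfg.classification_threshold
    for epoch in range(cfg.epochs):
        order = model._shuffle_rng.permutation(n)
        loss_sum = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xp[idx], y[idx]
            lb = lengths[idx] if lengths is not None else None
            probs, cache = model._forward(xb, lengths=lb, want_cache=True)
            batch_loss = float(np.abs(probs - yb).sum())
            if not np.isfinite(batch_loss):
                raise RuntimeError(f"NaN loss at epoch {epoch + 1}")
            loss_sum += batch_loss
            correct += int(((probs >= thr).astype(int) == yb.astype(int)).sum())
            grads = model._backward(cache, yb)
            model._adam_step(grads)
        model.history["epoch"].append(epoch + 1)
        model.history["train_loss"].append(loss_sum / n)
        model.history["train_acc"].append(correct / n)
        if val is not None:
            vp = predict_proba(model, val[0], lengths=val[2])
            model.history["val_loss"].append(float(np.abs(vp - val[1]).mean()))
            model.history["val_acc"].append(
                float(((vp >= thr).astype(int) == val[1].astype(int)).mean())
            )
        else:
            model.history["val_loss"].append(float("nan"))
            model.history["val_acc"].append(float("nan"))
    model.trained = True
    return model


def predict_proba(
    model: LSTMClassifier,
    X: np.ndarray | Sequence[ProcessedTensor],
    lengths: Optional[np.ndarray] = None,
    batch_size: int = 128,
) -> np.ndarray:
    """Per-patient death-probability scores in [0, 1]."""
    if len(X) > 0 and isinstance(X[0], ProcessedTensor):
        X, _, lengths = _tensors_to_unlabelled(X)
    X = np.asarray(X, dtype=_F)
    if X.ndim == 2:
        X = X[None]
    Xp = model._prepare(X)
    out = []
    for start in range(0, len(Xp), batch_size):
        xb = Xp[start : start + batch_size]
        lb = lengths[start : start + batch_size] if lengths is not None else None
        out.append(model._forward(xb, lengths=lb))
    return np.concatenate(out)


def _tensors_to_unlabelled(tensors: Sequence[ProcessedTensor]):
    lengths = {len(t) for t in tensors}
    if len(lengths) != 1:
        raise ValueError(f"tensors have mixed padded lengths {sorted(lengths)}")
    X = np.stack([t.values for t in tensors]).astype(_F)
    valid = np.array([t.valid_length for t in tensors], dtype=np.int64)
    return X, None, valid


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary predictions: 1 iff probability >= threshold (ties are positive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    return (np.asarray(probabilities) >= threshold).astype(int)
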