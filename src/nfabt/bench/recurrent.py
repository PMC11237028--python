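"""Minimal numpy LSTM sequence classifier.

A stacked (optionally bidirectional) LSTM with a per-timestep linear +
log-softmax head, trained with full-batch backpropagation through time and
Adam. Scale is desk-sized cohorts (tens of patients, days-long sequences),
where full-batch BPTT in numpy is more than fast enough and keeps the
implementation dependency-free and exactly reproducible.

Shapes: inputs are (batch, time, features); labels (batch, time) with
integer classes; log-probabilities (batch, time, classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LSTMClassifier"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _log_softmax(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=-1, keepdims=True)
    s = x - m
    return s - np.log(np.exp(s).sum(axis=-1, keepdims=True))


@dataclass
class _Cell:
    """One LSTM direction: gate order [i, f, g, o] stacked column-wise."""

    Wx: np.ndarray
    Wh: np.ndarray
    b: np.ndarray

    @classmethod
    def init(cls, n_in: int, hidden: int, rng: np.random.Generator) -> "_Cell":
        s = 1.0 / np.sqrt(hidden)
        cell = cls(
            Wx=rng.uniform(-s, s, (n_in, 4 * hidden)),
            Wh=rng.uniform(-s, s, (hidden, 4 * hidden)),
            b=np.zeros(4 * hidden),
        )
        cell.b[hidden : 2 * hidden] = 1.0  # forget-gate bias, standard trick
        return cell

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        B, T, _ = X.shape
        H = self.Wh.shape[0]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = {"X": X, "i": [], "f": [], "g": [], "o": [], "c": [], "h": [], "tc": []}
        Hs = np.empty((B, T, H))
        for t in range(T):
            a = X[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            Hs[:, t] = h
            for k, v in zip(("i", "f", "g", "o", "c", "h", "tc"), (i, f, g, o, c, h, tc)):
                cache[k].append(v)
        return Hs, cache

    def backward(self, dH: np.ndarray, cache: dict) -> tuple[np.ndarray, "_Cell"]:
        X = cache["X"]
        B, T, _ = X.shape
        H = self.Wh.shape[0]
        grads = _Cell(Wx=np.zeros_like(self.Wx), Wh=np.zeros_like(self.Wh), b=np.zeros_like(self.b))
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
            tc = cache["tc"][t]
            c_prev = cache["c"][t - 1] if t > 0 else np.zeros((B, H))
            h_prev = cache["h"][t - 1] if t > 0 else np.zeros((B, H))
            dh = dH[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di, dg, df = dc * g, dc * i, dc * c_prev
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            grads.Wx += X[:, t].T @ da
            grads.Wh += h_prev.T @ da
            grads.b += da.sum(axis=0)
            dX[:, t] = da @ self.Wx.T
            dh_next = da @ self.Wh.T
            dc_next = dc * f
        return dX, grads

    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]


class LSTMClassifier:
    """Stacked (bi)LSTM with log-softmax head and per-day class labels.

    Defaults mirror the benchmark configuration: 2 layers, 128 hidden
    units, initial learning rate 0.01, at most 100 epochs.
    """

    def __init__(
        self,
        hidden: int = 128,
        layers: int = 2,
        n_classes: int = 2,
        bidirectional: bool = False,
        learning_rate: float = 0.01,
        max_epochs: int = 100,
        seed: int = 0,
    ) -> None:
        if layers < 1 or hidden < 1:
            raise ValueError("layers and hidden must be >= 1")
        self.hidden = hidden
        self.layers = layers
        self.n_classes = n_classes
        self.bidirectional = bidirectional
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.seed = seed
        self._cells: list[list[_Cell]] = []  # [layer][direction]
        self.Wy: np.ndarray | None = None
        self.by: np.ndarray | None = None

    # -- construction --

    def _build(self, n_features: int) -> None:
        rng = np.random.default_rng(self.seed)
        dirs = 2 if self.bidirectional else 1
        self._cells = []
        n_in = n_features
        for _ in range(self.layers):
            self._cells.append([_Cell.init(n_in, self.hidden, rng) for _ in range(dirs)])
            n_in = self.hidden * dirs
        s = 1.0 / np.sqrt(n_in)
        self.Wy = rng.uniform(-s, s, (n_in, self.n_classes))
        self.by = np.zeros(self.n_classes)

    def _params(self) -> list[np.ndarray]:
        ps = [p for layer in self._cells for cell in layer for p in cell.params()]
        return ps + [self.Wy, self.by]

    # -- forward / backward --

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        caches = []
        out = X
        for layer in self._cells:
            outs = []
            layer_caches = []
            for d, cell in enumerate(layer):
                inp = out[:, ::-1] if d == 1 else out
                Hs, cache = cell.forward(inp)
                if d == 1:
                    Hs = Hs[:, ::-1]
                outs.append(Hs)
                layer_caches.append(cache)
            out = np.concatenate(outs, axis=2)
            caches.append(layer_caches)
        logits = out @ self.Wy + self.by
        return logits, [caches, out]

    def _loss_grads(self, X: np.ndarray, y: np.ndarray) -> tuple[float, list[np.ndarray]]:
        B, T, _ = X.shape
        logits, (caches, feats) = self._forward(X)
        logp = _log_softmax(logits)
        n = B * T
        loss = -float(logp[np.arange(B)[:, None], np.arange(T)[None, :], y].mean())
        p = np.exp(logp)
        dlogits = p.copy()
        dlogits[np.arange(B)[:, None], np.arange(T)[None, :], y] -= 1.0
        dlogits /= n
        gWy = feats.reshape(n, -1).T @ dlogits.reshape(n, -1)
        gby = dlogits.reshape(n, -1).sum(axis=0)
        dOut = dlogits @ self.Wy.T
        cell_grads: list[list[_Cell]] = [None] * self.layers
        for li in range(self.layers - 1, -1, -1):
            layer = self._cells[li]
            H = self.hidden
            dIn = None
            grads_l = []
            for d, cell in enumerate(layer):
                dH_d = dOut[:, :, d * H : (d + 1) * H]
                if d == 1:
                    dH_d = dH_d[:, ::-1]
                dX_d, g = cell.backward(np.ascontiguousarray(dH_d), caches[li][d])
                if d == 1:
                    dX_d = dX_d[:, ::-1]
                dIn = dX_d if dIn is None else dIn + dX_d
                grads_l.append(g)
            cell_grads[li] = grads_l
            dOut = dIn
        flat = [p for layer in cell_grads for cell in layer for p in cell.params()]
        return loss, flat + [gWy, gby]

    # -- training --

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3 or y.shape != X.shape[:2]:
            raise ValueError("X must be (batch, time, features), y (batch, time)")
        self._build(X.shape[2])
        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.loss_curve_: list[float] = []
        for epoch in range(1, self.max_epochs + 1):
            loss, grads = self._loss_grads(X, y)
            self.loss_curve_.append(loss)
            for k, (p, g) in enumerate(zip(params, grads)):
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mh = m[k] / (1 - b1**epoch)
                vh = v[k] / (1 - b2**epoch)
                p -= self.learning_rate * mh / (np.sqrt(vh) + eps)
        return self

    def predict_log_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        logits, _ = self._forward(X)
        return _log_softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_log_proba(X).argmax(axis=-1)
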