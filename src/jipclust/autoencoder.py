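"""Multimodal autoencoder producing the 8-dimensional patient embedding.

A narrowing encoder (128 -> 64 -> 8) over the concatenated numeric and
categorical blocks, mirrored by a decoder that splits into two output
heads: a sigmoid head with Bernoulli (binary cross-entropy) loss for the
categorical block and a linear head with Gaussian (squared-error) loss for
the standardized numeric block. Training uses Adam on an 80/20
train/validation split with early stopping on the validation loss and
restoration of the best weights.

Implemented directly in numpy (forward pass, backprop and Adam are
self-contained), which keeps the model deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .preprocess import FeatureMatrix

_EPS = 1e-7


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


def modality_loss(reconstruction, target, modality: str) -> float:
    """Reconstruction loss for one modality.

    categorical: mean Bernoulli negative log-likelihood (binary
    cross-entropy), predictions clipped to [1e-7, 1 - 1e-7] so the loss is
    finite at hard 0/1 targets; numeric: mean squared error (Gaussian NLL up
    to constants).
    """
    p = np.asarray(reconstruction, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError("shape mismatch between reconstruction and target")
    if modality == "categorical":
        if (p < 0).any() or (p > 1).any():
            raise ValueError("categorical reconstructions must lie in (0,1)")
        p = np.clip(p, _EPS, 1.0 - _EPS)
        return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())
    if modality == "numeric":
        return float(((p - t) ** 2).mean())
    raise ValueError(f"unknown modality {modality!r}")


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class _Layer:
    W: np.ndarray
    b: np.ndarray


class MultimodalAutoencoder(BaseEstimator, TransformerMixin):
    """Autoencoder over a modality-blocked :class:`FeatureMatrix`.

    Parameters
    ----------
    encoder_widths : hidden/encoder layer widths; the last entry is the
        embedding dimension (default ``(128, 64, 8)``).
    cat_weight, num_weight : modality loss weights in the training
        objective (equal by default).
    random_state : seeds the train/validation split, weight initialization
        and batch order.
    """

    def __init__(self, encoder_widths=(128, 64, 8), learning_rate=1e-3,
                 batch_size=32, max_epochs=500, patience=20,
                 val_fraction=0.20, cat_weight=1.0, num_weight=1.0,
                 weight_decay=2e-3, random_state=None):
        self.encoder_widths = encoder_widths
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.cat_weight = cat_weight
        self.num_weight = num_weight
        self.weight_decay = weight_decay
        self.random_state = random_state

    # ---- internals -------------------------------------------------

    def _init_layers(self, rng, d_in, d_num, d_cat):
        widths = list(self.encoder_widths)
        dims_enc = [d_in] + widths            # e.g. D -> 128 -> 64 -> 8
        dims_dec = [widths[-1]] + widths[-2::-1]   # 8 -> 64 -> 128
        layers = []
        for dims in (dims_enc, dims_dec):
            block = []
            for a, b in zip(dims[:-1], dims[1:]):
                block.append(_Layer(
                    W=rng.normal(0, np.sqrt(2.0 / a), size=(a, b)),
                    b=np.zeros(b)))
            layers.append(block)
        enc, dec = layers
        d_last = dims_dec[-1]
        head_cat = _Layer(W=rng.normal(0, np.sqrt(1.0 / d_last),
                                       size=(d_last, d_cat)),
                          b=np.zeros(d_cat))
        head_num = _Layer(W=rng.normal(0, np.sqrt(1.0 / d_last),
                                       size=(d_last, d_num)),
                          b=np.zeros(d_num))
        return enc, dec, head_cat, head_num

    def _params(self):
        return (self._enc + self._dec + [self._head_cat, self._head_num])

    def _forward(self, X):
        """Returns (embedding, cat probabilities, num reconstruction,
        cached activations for backprop)."""
        acts = [X]
        h = X
        for i, lay in enumerate(self._enc):
            z = h @ lay.W + lay.b
            h = z if i == len(self._enc) - 1 else _relu(z)  # linear code
            acts.append(h)
        for lay in self._dec:
            h = _relu(h @ lay.W + lay.b)
            acts.append(h)
        logits = h @ self._head_cat.W + self._head_cat.b
        p_cat = _sigmoid(logits)
        x_num = h @ self._head_num.W + self._head_num.b
        emb = acts[len(self._enc)]
        return emb, p_cat, x_num, acts

    def _loss(self, p_cat, x_num, X_cat, X_num):
        lc = modality_loss(p_cat, X_cat, "categorical")
        ln = modality_loss(x_num, X_num, "numeric")
        return self.cat_weight * lc + self.num_weight * ln, lc, ln

    def _backward(self, acts, p_cat, x_num, X_cat, X_num):
        n = acts[0].shape[0]
        grads = {}
        h_last = acts[-1]
        # head gradients (mean losses over all elements of each block)
        d_logit = self.cat_weight * (p_cat - X_cat) / (n * X_cat.shape[1])
        d_num = self.num_weight * 2.0 * (x_num - X_num) / (n * X_num.shape[1])
        grads[id(self._head_cat)] = (h_last.T @ d_logit, d_logit.sum(0))
        grads[id(self._head_num)] = (h_last.T @ d_num, d_num.sum(0))
        dh = d_logit @ self._head_cat.W.T + d_num @ self._head_num.W.T
        # decoder (all ReLU)
        k = len(acts) - 1
        for lay in reversed(self._dec):
            dz = dh * (acts[k] > 0)
            grads[id(lay)] = (acts[k - 1].T @ dz, dz.sum(0))
            dh = dz @ lay.W.T
            k -= 1
        # encoder (ReLU except the final linear code layer)
        for i in reversed(range(len(self._enc))):
            lay = self._enc[i]
            dz = dh if i == len(self._enc) - 1 else dh * (acts[k] > 0)
            grads[id(lay)] = (acts[k - 1].T @ dz, dz.sum(0))
            dh = dz @ lay.W.T
            k -= 1
        return grads

    # ---- estimator API ---------------------------------------------

    def fit(self, features: FeatureMatrix, y=None):
        X_num = features.numeric
        X_cat = features.categorical
        n = X_num.shape[0]
        if n < 50:
            raise ValueError("need at least 50 patients to train")
        if np.isnan(X_num).any() or np.isnan(X_cat).any():
            raise ValueError("missing entries in feature matrix")
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n)))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        X = np.hstack([X_num, X_cat])
        d_num, d_cat = X_num.shape[1], X_cat.shape[1]
        self._enc, self._dec, self._head_cat, self._head_num = \
            self._init_layers(rng, X.shape[1], d_num, d_cat)

        params = self._params()
        m_t = {id(p): (np.zeros_like(p.W), np.zeros_like(p.b))
               for p in params}
        v_t = {id(p): (np.zeros_like(p.W), np.zeros_like(p.b))
               for p in params}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        history = {"train_loss": [], "val_loss": [],
                   "train_cat": [], "train_num": [],
                   "val_cat": [], "val_num": []}
        best = (np.inf, None, -1)
        since_best = 0

        for epoch in range(self.max_epochs):
            perm = rng.permutation(tr_idx)
            for start in range(0, len(perm), self.batch_size):
                batch = perm[start:start + self.batch_size]
                Xb = X[batch]
                emb, p_cat, x_num, acts = self._forward(Xb)
                grads = self._backward(acts, p_cat, x_num,
                                       X_cat[batch], X_num[batch])
                if self.weight_decay:
                    # L2 penalty on weights only; keeps the code close to a
                    # minimal-norm (variance-ordered) solution
                    for p in params:
                        gW, gb = grads[id(p)]
                        grads[id(p)] = (gW + self.weight_decay * p.W, gb)
                step += 1
                lr_t = self.learning_rate * \
                    np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
                for p in params:
                    gW, gb = grads[id(p)]
                    mW, mb = m_t[id(p)]
                    vW, vb = v_t[id(p)]
                    mW *= b1; mW += (1 - b1) * gW
                    mb *= b1; mb += (1 - b1) * gb
                    vW *= b2; vW += (1 - b2) * gW * gW
                    vb *= b2; vb += (1 - b2) * gb * gb
                    p.W -= lr_t * mW / (np.sqrt(vW) + eps)
                    p.b -= lr_t * mb / (np.sqrt(vb) + eps)

            tr = self._evaluate(X[tr_idx], X_cat[tr_idx], X_num[tr_idx])
            va = self._evaluate(X[val_idx], X_cat[val_idx], X_num[val_idx])
            if not (np.isfinite(tr[0]) and np.isfinite(va[0])):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}")
            history["train_loss"].append(tr[0])
            history["train_cat"].append(tr[1])
            history["train_num"].append(tr[2])
            history["val_loss"].append(va[0])
            history["val_cat"].append(va[1])
            history["val_num"].append(va[2])
            if va[0] < best[0]:
                best = (va[0], self._snapshot(), epoch)
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break

        self._restore(best[1])
        self.best_epoch_ = best[2]
        self.history_ = history
        self.n_numeric_ = d_num
        self.columns_ = list(features.columns)
        self.embedding_dim_ = self.encoder_widths[-1]
        return self

    def _evaluate(self, X, X_cat, X_num):
        _, p_cat, x_num, _ = self._forward(X)
        return self._loss(p_cat, x_num, X_cat, X_num)

    def _snapshot(self):
        return [(p.W.copy(), p.b.copy()) for p in self._params()]

    def _restore(self, snap):
        for p, (W, b) in zip(self._params(), snap):
            p.W, p.b = W.copy(), b.copy()

    def transform(self, features: FeatureMatrix) -> np.ndarray:
        """Deterministic forward pass through the frozen encoder."""
        check_is_fitted(self, "columns_")
        if list(features.columns) != self.columns_:
            extra = set(features.columns) - set(self.columns_)
            miss = set(self.columns_) - set(features.columns)
            raise ValueError(
                "feature layout mismatch: "
                f"unexpected={sorted(extra)} missing={sorted(miss)}"
                if extra or miss else
                "feature layout mismatch: column order differs")
        X = features.values
        emb, _, _, _ = self._forward(X)
        return emb

    encode = transform

    def reconstruct(self, features: FeatureMatrix):
        """(categorical probabilities, numeric reconstruction)."""
        check_is_fitted(self, "columns_")
        _, p_cat, x_num, _ = self._forward(features.values)
        return p_cat, x_num

    # ---- persistence -----------------------------------------------

    def save(self, path) -> None:
        """Serialize weights + config + feature layout to one .npz archive."""
        check_is_fitted(self, "columns_")
        arrays = {}
        for i, p in enumerate(self._params()):
            arrays[f"W{i}"] = p.W
            arrays[f"b{i}"] = p.b
        meta = dict(self.get_params())
        meta["encoder_widths"] = list(meta["encoder_widths"])
        np.savez(path, __meta__=json.dumps(
            {"params": meta, "columns": self.columns_,
             "n_numeric": self.n_numeric_, "best_epoch": self.best_epoch_}),
            **arrays)

    @classmethod
    def load(cls, path) -> "MultimodalAutoencoder":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        params = meta["params"]
        params["encoder_widths"] = tuple(params["encoder_widths"])
        model = cls(**params)
        widths = list(model.encoder_widths)
        d_cat = len(meta["columns"]) - meta["n_numeric"]
        rng = np.random.default_rng(0)
        model._enc, model._dec, model._head_cat, model._head_num = \
            model._init_layers(rng, len(meta["columns"]),
                               meta["n_numeric"], d_cat)
        for i, p in enumerate(model._params()):
            p.W = data[f"W{i}"]
            p.b = data[f"b{i}"]
        model.columns_ = meta["columns"]
        model.n_numeric_ = meta["n_numeric"]
        model.best_epoch_ = meta["best_epoch"]
        model.embedding_dim_ = widths[-1]
        model.history_ = {}
        return model
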