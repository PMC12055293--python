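"""Conditional mixture density network (MDN) in plain NumPy.

The network maps a conditioning vector x through a tanh multilayer
perceptron to the parameters of a K-component multivariate Gaussian
mixture over the target y: softmax weights, component means, and
full-covariance components parametrized by a lower-triangular Cholesky
factor U of each component *precision* matrix (Lambda = U U^T).  With
z = U^T (y - mu) the component log-density is closed-form,

    log N(y) = sum_j log U_jj - 0.5 ||z||^2 - (P/2) log 2 pi,

so both the loss (mean negative log-likelihood) and its gradients are
exact without matrix inversion.  Training uses Adam with minibatches and
early stopping on a validation split; everything is seeded and
deterministic.

The network operates on standardized arrays; standardization and prior
truncation live one level up in :mod:`reefsbi.npe`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

__all__ = ["MDNConfig", "MixtureDensityNetwork"]

_LOGDIAG_CLIP = 7.0


@dataclass(frozen=True)
class MDNConfig:
    """Architecture and optimization settings.

    Defaults follow the reference architecture: three hidden layers of 90
    units and six mixture components.  Optimization settings (Adam,
    batch 200, learning rate 5e-4, patience 20 on a 10% validation split)
    follow common neural-posterior-estimation practice.
    """

    hidden_layers: int = 3
    units_per_layer: int = 90
    n_components: int = 6
    activation: str = "tanh"
    max_epochs: int = 400
    batch_size: int = 200
    learning_rate: float = 5e-4
    weight_decay: float = 1e-4
    dropout: float = 0.0
    early_stop_patience: int = 20
    validation_fraction: float = 0.1

    def __post_init__(self):
        for name in ("hidden_layers", "units_per_layer", "n_components",
                     "max_epochs", "batch_size", "early_stop_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.activation not in ("tanh", "relu"):
            raise ValueError("activation must be 'tanh' or 'relu'")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


def _tril_indices(p: int):
    return np.tril_indices(p, k=-1)


class MixtureDensityNetwork:
    """MLP emitting mixture parameters; trained by maximum likelihood."""

    def __init__(self, dim_x: int, dim_y: int, config: MDNConfig, seed=0):
        self.dim_x = int(dim_x)
        self.dim_y = int(dim_y)
        self.config = config
        K, P = config.n_components, self.dim_y
        self.n_tril = P * (P - 1) // 2
        # output layout: [logits K | means K*P | logdiag K*P | offdiag K*n_tril]
        self.dim_out = K * (1 + 2 * P + self.n_tril)

        rng = np.random.default_rng(seed)
        sizes = [self.dim_x] + [config.units_per_layer] * config.hidden_layers
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        # small output weights + spread mean-biases: the initial mixture is a
        # broad, input-independent cover of the standardized target space
        self.weights.append(rng.normal(0.0, 0.01, size=(sizes[-1], self.dim_out)))
        b_out = np.zeros(self.dim_out)
        mean_slice = slice(K, K + K * P)
        b_out[mean_slice] = rng.normal(0.0, 0.5, size=K * P)
        self.biases.append(b_out)
        self.training_log: dict = {}

    # ---- forward ----------------------------------------------------

    def _act(self, x):
        return np.tanh(x) if self.config.activation == "tanh" else np.maximum(x, 0.0)

    def _act_grad(self, pre):
        if self.config.activation == "tanh":
            return 1.0 - np.tanh(pre) ** 2
        return (pre > 0).astype(float)

    def _mlp_forward(self, X, dropout_rng=None):
        # inverted dropout on hidden activations during training only
        p = self.config.dropout if dropout_rng is not None else 0.0
        hs, pres, masks = [np.asarray(X, dtype=float)], [], []
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            pre = hs[-1] @ W + b
            pres.append(pre)
            h = self._act(pre)
            if p > 0:
                mask = (dropout_rng.random(h.shape) >= p) / (1.0 - p)
                h = h * mask
                masks.append(mask)
            hs.append(h)
        out = hs[-1] @ self.weights[-1] + self.biases[-1]
        return out, hs, pres, masks

    def _split(self, out):
        K, P, T = self.config.n_components, self.dim_y, self.n_tril
        n = out.shape[0]
        i = 0
        logits = out[:, i : i + K]; i += K
        means = out[:, i : i + K * P].reshape(n, K, P); i += K * P
        logdiag = np.clip(out[:, i : i + K * P].reshape(n, K, P),
                          -_LOGDIAG_CLIP, _LOGDIAG_CLIP); i += K * P
        offdiag = out[:, i : i + K * T].reshape(n, K, T)
        return logits, means, logdiag, offdiag

    def mixture_params(self, X):
        """Mixture parameters for a batch of conditioners.

        Returns (weights (n,K), means (n,K,P), U (n,K,P,P)) with U the
        lower-triangular precision Cholesky factor per component.
        """
        out, _, _, _ = self._mlp_forward(np.atleast_2d(X))
        logits, means, logdiag, offdiag = self._split(out)
        w = np.exp(logits - logsumexp(logits, axis=1, keepdims=True))
        return w, means, self._build_U(logdiag, offdiag)

    def _build_U(self, logdiag, offdiag):
        n, K, P = logdiag.shape
        U = np.zeros((n, K, P, P))
        di = np.arange(P)
        U[:, :, di, di] = np.exp(logdiag)
        if self.n_tril:
            rows, cols = _tril_indices(P)
            U[:, :, rows, cols] = offdiag
        return U

    def _components(self, out, Y):
        """Per-component log-densities and intermediates for the batch."""
        logits, means, logdiag, offdiag = self._split(out)
        U = self._build_U(logdiag, offdiag)
        d = Y[:, None, :] - means                      # (n,K,P)
        z = np.einsum("nkij,nki->nkj", U, d)           # z = U^T d
        logN = (
            logdiag.sum(axis=2)
            - 0.5 * (z**2).sum(axis=2)
            - 0.5 * self.dim_y * np.log(2.0 * np.pi)
        )
        log_w = logits - logsumexp(logits, axis=1, keepdims=True)
        return log_w, logN, U, d, z, logdiag

    def log_prob(self, X, Y):
        """Mixture log-density log q(y | x) per row (standardized units)."""
        out, _, _, _ = self._mlp_forward(np.atleast_2d(X))
        log_w, logN, *_ = self._components(out, np.atleast_2d(Y))
        return logsumexp(log_w + logN, axis=1)

    # ---- loss and gradients ------------------------------------------

    def _loss_and_grads(self, X, Y, dropout_rng=None):
        n = X.shape[0]
        K, P, T = self.config.n_components, self.dim_y, self.n_tril
        out, hs, pres, masks = self._mlp_forward(X, dropout_rng)
        log_w, logN, U, d, z, logdiag = self._components(out, Y)

        log_mix = log_w + logN
        log_q = logsumexp(log_mix, axis=1)
        loss = -np.mean(log_q)

        r = np.exp(log_mix - log_q[:, None])           # responsibilities (n,K)
        w = np.exp(log_w)

        d_logits = (w - r) / n
        Uz = np.einsum("nkij,nkj->nki", U, z)          # (n,K,P) = U z
        d_means = -(r[:, :, None] * Uz) / n
        diag_idx = np.arange(P)
        Udiag = np.exp(logdiag)
        # d/d(logdiag_j) logN = 1 - d_j z_j U_jj  (chain through U_jj = e^s)
        d_logdiag = -(r[:, :, None] * (1.0 - d * z * Udiag)) / n
        grads_out = [d_logits.reshape(n, K), d_means.reshape(n, K * P),
                     d_logdiag.reshape(n, K * P)]
        if T:
            rows, cols = _tril_indices(P)
            # d/dU_ij logN = -d_i z_j for strictly-lower entries
            d_off = (r[:, :, None] * (d[:, :, rows] * z[:, :, cols])) / n
            grads_out.append(d_off.reshape(n, K * T))
        d_out = np.concatenate(grads_out, axis=1)

        # backprop through the MLP
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        delta = d_out
        gW[-1] = hs[-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        for layer in range(len(self.weights) - 2, -1, -1):
            delta = (delta @ self.weights[layer + 1].T) * self._act_grad(pres[layer])
            if masks:
                delta = delta * masks[layer]
            gW[layer] = hs[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
        return loss, gW, gb

    # ---- training ----------------------------------------------------

    def fit(self, X, Y, seed=0, verbose=False, augment=None):
        """Train by minibatch Adam with early stopping; returns the log.

        A ``validation_fraction`` split is held out; the best-validation
        weights are restored at the end.  ``augment``, if given, is a
        callable ``(X_batch, rng) -> X_batch`` applied to each training
        minibatch (e.g. to re-draw observation noise); validation inputs
        are augmented once so early stopping sees a fixed realization.
        Raises on non-finite loss.
        """
        cfg = self.config
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        n_val = max(1, int(round(cfg.validation_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, Ytr, Xval, Yval = X[tr_idx], Y[tr_idx], X[val_idx], Y[val_idx]
        if augment is not None:
            Xval = augment(Xval, rng)

        params = self.weights + self.biases
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        def val_loss():
            return float(-np.mean(self.log_prob(Xval, Yval)))

        history = {"val_loss": [val_loss()], "train_loss": []}
        best_val = history["val_loss"][0]
        best_params = [p.copy() for p in params]
        patience_left = cfg.early_stop_patience
        lr = cfg.learning_rate
        decays_left = 3  # anneal the step size from the best weights before stopping

        n_tr = Xtr.shape[0]
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n_tr)
            ep_loss = 0.0
            n_batches = 0
            for start in range(0, n_tr, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb = Xtr[idx] if augment is None else augment(Xtr[idx], rng)
                loss, gW, gb = self._loss_and_grads(
                    Xb, Ytr[idx],
                    dropout_rng=rng if cfg.dropout > 0 else None,
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "check input scaling and learning rate"
                    )
                ep_loss += loss
                n_batches += 1
                step += 1
                grads = gW + gb
                lr_t = lr * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                wd = cfg.weight_decay
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g**2
                    p -= lr_t * mi / (np.sqrt(vi) + eps)
                    if wd:
                        p -= lr_t * wd * p  # decoupled weight decay
            history["train_loss"].append(ep_loss / max(n_batches, 1))
            vl = val_loss()
            history["val_loss"].append(vl)
            if verbose:
                print(f"epoch {epoch}: train {history['train_loss'][-1]:.4f} val {vl:.4f}")
            if vl < best_val - 1e-6:
                best_val = vl
                best_params = [p.copy() for p in params]
                patience_left = cfg.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    if decays_left > 0:
                        # restart from the best weights with a smaller step
                        decays_left -= 1
                        lr *= 0.3
                        for p, bp in zip(params, best_params):
                            p[...] = bp
                        patience_left = cfg.early_stop_patience
                    else:
                        break

        for p, bp in zip(params, best_params):
            p[...] = bp
        history["best_val_loss"] = best_val
        history["epochs_run"] = len(history["train_loss"])
        self.training_log = history
        return history

    # ---- sampling ----------------------------------------------------

    def sample(self, x, n, seed=0):
        """Draw n samples from the mixture conditioned on a single x.

        Component draws follow the softmax weights; within a component,
        y = mu + U^{-T} eps with eps ~ N(0, I), which has covariance
        (U U^T)^{-1}, i.e. the component covariance.
        """
        w, means, U = self.mixture_params(np.atleast_2d(x))
        w, means, U = w[0], means[0], U[0]
        rng = np.random.default_rng(seed)
        comps = rng.choice(w.size, size=n, p=w)
        eps = rng.standard_normal((n, self.dim_y))
        out = np.empty((n, self.dim_y))
        for k in np.unique(comps):
            mask = comps == k
            sol = solve_triangular(U[k].T, eps[mask].T, lower=False)
            out[mask] = means[k] + sol.T
        return out

    # ---- persistence -------------------------------------------------

    def state_dict(self) -> dict:
        state = {"dim_x": self.dim_x, "dim_y": self.dim_y}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            state[f"W{i}"] = W
            state[f"b{i}"] = b
        return state

    @classmethod
    def from_state(cls, state: dict, config: MDNConfig) -> "MixtureDensityNetwork":
        net = cls(int(state["dim_x"]), int(state["dim_y"]), config, seed=0)
        for i in range(len(net.weights)):
            net.weights[i] = np.asarray(state[f"W{i}"], dtype=float)
            net.biases[i] = np.asarray(state[f"b{i}"], dtype=float)
        return net
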