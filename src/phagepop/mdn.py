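"""Conditional mixture-density network for neural posterior estimation.

A small feed-forward network maps a (standardized) summary-statistic vector to
the parameters of a diagonal-covariance Gaussian mixture over the model
parameters in an unbounded transformed space.  Trained on prior-drawn
(parameter, summary) pairs by minimizing the negative log likelihood, the
network output is a direct amortized approximation of the posterior
density — the classic neural-posterior-estimation construction with a
mixture-density conditional estimator.

Everything is plain NumPy: forward pass, analytic gradients, and Adam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LS_MIN, _LS_MAX = -7.0, 3.0  # clamp on log standard deviations


@dataclass
class MDNSpec:
    """Hyperparameters of the conditional density estimator."""

    n_components: int = 8
    hidden: int = 64
    learning_rate: float = 5e-4
    batch_size: int = 100
    max_epochs: int = 1200
    patience: int = 100
    val_fraction: float = 0.1
    weight_decay: float = 1e-6


class TrainingError(RuntimeError):
    """Raised when the training set cannot support density estimation."""


class ConditionalMDN:
    """p(z | x) as a K-component diagonal Gaussian mixture, x -> MLP -> mixture."""

    def __init__(self, d_in: int, d_out: int, spec: MDNSpec, rng: np.random.Generator):
        self.spec = spec
        self.d_in, self.d_out = d_in, d_out
        K, H = spec.n_components, spec.hidden
        def init(shape, scale):
            return rng.normal(0.0, scale, size=shape)
        self.params = {
            "W1": init((d_in, H), 1.0 / np.sqrt(d_in)),
            "b1": np.zeros(H),
            "W2": init((H, H), 1.0 / np.sqrt(H)),
            "b2": np.zeros(H),
            "Wl": init((H, K), 1.0 / np.sqrt(H)),
            "bl": np.zeros(K),
            "Wm": init((H, K * d_out), 1.0 / np.sqrt(H)),
            "bm": rng.normal(0.0, 0.1, size=K * d_out),
            "Ws": init((H, K * d_out), 0.1 / np.sqrt(H)),
            "bs": np.zeros(K * d_out),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.loss_trajectory: list[float] = []

    # -- forward ------------------------------------------------------------

    def _forward(self, X: np.ndarray):
        p = self.params
        h1 = np.tanh(X @ p["W1"] + p["b1"])
        h2 = np.tanh(h1 @ p["W2"] + p["b2"])
        logits = h2 @ p["Wl"] + p["bl"]
        K, D = self.spec.n_components, self.d_out
        mu = (h2 @ p["Wm"] + p["bm"]).reshape(-1, K, D)
        ls = np.clip((h2 @ p["Ws"] + p["bs"]).reshape(-1, K, D), _LS_MIN, _LS_MAX)
        return h1, h2, logits, mu, ls

    def mixture_params(self, X: np.ndarray):
        """Mixture weights, means and stds for each row of X."""
        _, _, logits, mu, ls = self._forward(np.atleast_2d(X))
        logw = logits - _logsumexp(logits, axis=1, keepdims=True)
        return np.exp(logw), mu, np.exp(ls)

    def log_prob(self, Z: np.ndarray, X: np.ndarray) -> np.ndarray:
        """log p(z | x) for paired rows of Z and X (in transformed z-space)."""
        _, _, logits, mu, ls = self._forward(np.atleast_2d(X))
        Z = np.atleast_2d(Z)
        logw = logits - _logsumexp(logits, axis=1, keepdims=True)
        a = logw + _component_logpdf(Z, mu, ls)
        return _logsumexp(a, axis=1)

    def sample(self, n: int, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw n samples of z from p(z | x) for a single conditioning vector."""
        w, mu, sigma = self.mixture_params(np.atleast_2d(x))
        w, mu, sigma = w[0], mu[0], sigma[0]
        comp = rng.choice(w.size, size=n, p=w / w.sum())
        return mu[comp] + sigma[comp] * rng.standard_normal((n, self.d_out))

    # -- training -----------------------------------------------------------

    def fit(self, Z: np.ndarray, X: np.ndarray, rng: np.random.Generator) -> "ConditionalMDN":
        """Minimize the mixture NLL with Adam and early stopping."""
        Z, X = np.asarray(Z, float), np.asarray(X, float)
        n = Z.shape[0]
        if n < 2 * self.spec.n_components:
            raise TrainingError(f"training set of {n} pairs is too small")
        if np.allclose(X.std(axis=0), 0):
            raise TrainingError("summaries are constant; cannot condition on them")
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.spec.val_fraction * n)))
        val, train = perm[:n_val], perm[n_val:]
        best_val, best_params, stale = np.inf, None, 0
        bs = self.spec.batch_size
        for _ in range(self.spec.max_epochs):
            order = rng.permutation(train.size)
            ep_loss = 0.0
            for i in range(0, train.size, bs):
                idx = train[order[i:i + bs]]
                ep_loss += self._adam_step(Z[idx], X[idx]) * idx.size
            self.loss_trajectory.append(ep_loss / train.size)
            val_nll = float(-self.log_prob(Z[val], X[val]).mean())
            if val_nll < best_val - 1e-5:
                best_val, stale = val_nll, 0
                best_params = {k: v.copy() for k, v in self.params.items()}
            else:
                stale += 1
                if stale >= self.spec.patience:
                    break
        if best_params is not None:
            self.params = best_params
        return self

    def _adam_step(self, Zb: np.ndarray, Xb: np.ndarray) -> float:
        loss, grads = self._loss_and_grads(Zb, Xb)
        self._adam_t += 1
        lr, b1, b2, eps = self.spec.learning_rate, 0.9, 0.999, 1e-8
        for k, g in grads.items():
            if self.spec.weight_decay and k.startswith("W"):
                g = g + self.spec.weight_decay * self.params[k]
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1 ** self._adam_t)
            vhat = self._adam_v[k] / (1 - b2 ** self._adam_t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    def _loss_and_grads(self, Z: np.ndarray, X: np.ndarray):
        p = self.params
        n = Z.shape[0]
        K, D = self.spec.n_components, self.d_out
        h1 = np.tanh(X @ p["W1"] + p["b1"])
        h2 = np.tanh(h1 @ p["W2"] + p["b2"])
        logits = h2 @ p["Wl"] + p["bl"]
        mu_lin = h2 @ p["Wm"] + p["bm"]
        ls_lin = h2 @ p["Ws"] + p["bs"]
        mu = mu_lin.reshape(n, K, D)
        ls_raw = ls_lin.reshape(n, K, D)
        clipped = (ls_raw <= _LS_MIN) | (ls_raw >= _LS_MAX)
        ls = np.clip(ls_raw, _LS_MIN, _LS_MAX)

        logw = logits - _logsumexp(logits, axis=1, keepdims=True)
        a = logw + _component_logpdf(Z, mu, ls)  # (n, K)
        logp = _logsumexp(a, axis=1)
        loss = float(-logp.mean())

        r = np.exp(a - logp[:, None])            # responsibilities (n, K)
        w = np.exp(logw)
        g_logits = (w - r) / n                   # (n, K)
        t = (Z[:, None, :] - mu) / np.exp(ls)    # (n, K, D)
        g_mu = (-r[:, :, None] * t / np.exp(ls)) / n
        g_ls = (-r[:, :, None] * (t * t - 1.0)) / n
        g_ls[clipped] = 0.0
        g_mu_lin = g_mu.reshape(n, K * D)
        g_ls_lin = g_ls.reshape(n, K * D)

        g_h2 = g_logits @ p["Wl"].T + g_mu_lin @ p["Wm"].T + g_ls_lin @ p["Ws"].T
        g_pre2 = g_h2 * (1 - h2 * h2)
        g_h1 = g_pre2 @ p["W2"].T
        g_pre1 = g_h1 * (1 - h1 * h1)
        grads = {
            "Wl": h2.T @ g_logits, "bl": g_logits.sum(0),
            "Wm": h2.T @ g_mu_lin, "bm": g_mu_lin.sum(0),
            "Ws": h2.T @ g_ls_lin, "bs": g_ls_lin.sum(0),
            "W2": h1.T @ g_pre2, "b2": g_pre2.sum(0),
            "W1": X.T @ g_pre1, "b1": g_pre1.sum(0),
        }
        return loss, grads


def _component_logpdf(Z: np.ndarray, mu: np.ndarray, ls: np.ndarray) -> np.ndarray:
    t = (Z[:, None, :] - mu) / np.exp(ls)
    return (-0.5 * np.log(2 * np.pi) - ls - 0.5 * t * t).sum(axis=2)


def _logsumexp(a: np.ndarray, axis=None, keepdims=False) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))
    return out if keepdims else np.squeeze(out, axis=axis)
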