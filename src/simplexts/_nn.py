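"""Minimal feed-forward networks for the generative imputers.

The imputation networks are deliberately tiny — one hidden layer per
component, hidden width equal to the output dimension, latent size 1,
batch size 1 — so they are implemented directly on numpy arrays with
manual backpropagation and an Adam optimizer (step size 1e-3, betas
(0.9, 0.999), eps 1e-8). Hidden activations are hyperbolic tangent; the
discriminator output is a sigmoid. Training runs for at most
``max_epochs`` epochs and stops as soon as the validation objective
worsens (patience 0), restoring the best weights.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "CVAEImputer", "CGANImputer"]


class Adam:
    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int):
    bound = 1.0 / np.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_out, fan_in))
    b = rng.uniform(-bound, bound, size=fan_out)
    return W, b


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _train_val_split(n: int, val_frac: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_val = max(1, int(round(val_frac * n))) if n >= 3 else 0
    return idx[n_val:], idx[:n_val]


class CVAEImputer:
    """Conditional variational autoencoder mapping available time points to a missing one.

    The encoder sees the condition (CLR concatenation of available time
    points) and the target, and produces a 1-dimensional Gaussian latent;
    the decoder reconstructs the target from the condition and a latent
    sample. At imputation time the latent is drawn from N(0, 1).
    """

    def __init__(self, cond_dim: int, out_dim: int, latent_dim: int = 1, seed: int = 0):
        self.cond_dim = cond_dim
        self.out_dim = out_dim
        self.latent_dim = latent_dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        h = out_dim
        p = {}
        p["We1"], p["be1"] = _init_linear(rng, cond_dim + out_dim, h)
        p["We2"], p["be2"] = _init_linear(rng, h, 2 * latent_dim)
        p["Wd1"], p["bd1"] = _init_linear(rng, cond_dim + latent_dim, h)
        p["Wd2"], p["bd2"] = _init_linear(rng, h, out_dim)
        self.params = p

    # -- forward pieces -------------------------------------------------
    def _encode(self, c, y):
        u = np.concatenate([c, y])
        h = np.tanh(self.params["We1"] @ u + self.params["be1"])
        o = self.params["We2"] @ h + self.params["be2"]
        L = self.latent_dim
        return u, h, o[:L], o[L:]

    def decode(self, c, z):
        v = np.concatenate([c, np.atleast_1d(z)])
        hd = np.tanh(self.params["Wd1"] @ v + self.params["bd1"])
        return self.params["Wd2"] @ hd + self.params["bd2"]

    def _loss(self, c, y, z):
        yhat = self.decode(c, z)
        return float(((yhat - y) ** 2).sum())

    def _val_loss(self, C, Y):
        total = 0.0
        for c, y in zip(C, Y):
            _, _, mu, logvar = self._encode(c, y)
            recon = self._loss(c, y, mu)
            kl = 0.5 * float((np.exp(logvar) + mu**2 - 1 - logvar).sum())
            total += recon + kl
        return total / len(C)

    def _step(self, c, y, eps, opt: Adam):
        p = self.params
        u, h, mu, logvar = self._encode(c, y)
        std = np.exp(0.5 * logvar)
        z = mu + std * eps
        v = np.concatenate([c, z])
        a2 = p["Wd1"] @ v + p["bd1"]
        hd = np.tanh(a2)
        yhat = p["Wd2"] @ hd + p["bd2"]

        g = {}
        dyhat = 2.0 * (yhat - y)
        g["Wd2"] = np.outer(dyhat, hd)
        g["bd2"] = dyhat
        da2 = (p["Wd2"].T @ dyhat) * (1 - hd**2)
        g["Wd1"] = np.outer(da2, v)
        g["bd1"] = da2
        dz = p["Wd1"].T @ da2
        dz = dz[self.cond_dim :]
        dmu = dz + mu
        dlogvar = dz * 0.5 * std * eps + 0.5 * (np.exp(logvar) - 1)
        do = np.concatenate([dmu, dlogvar])
        g["We2"] = np.outer(do, h)
        g["be2"] = do
        da1 = (p["We2"].T @ do) * (1 - h**2)
        g["We1"] = np.outer(da1, u)
        g["be1"] = da1
        opt.step(g)

    def fit(
        self,
        C: np.ndarray,
        Y: np.ndarray,
        max_epochs: int = 1000,
        val_frac: float = 0.2,
        early_stopping: bool = True,
    ):
        C = np.atleast_2d(C)
        Y = np.atleast_2d(Y)
        rng = np.random.default_rng([self.seed, 1])
        tr, va = _train_val_split(len(C), val_frac, rng)
        opt = Adam(self.params)
        best = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        self.loss_history: list[float] = []
        for _ in range(max_epochs):
            for i in rng.permutation(tr):
                eps = rng.standard_normal(self.latent_dim)
                self._step(C[i], Y[i], eps, opt)
            self.loss_history.append(self._val_loss(C[tr], Y[tr]))
            monitor = (C[va], Y[va]) if len(va) else (C[tr], Y[tr])
            val = self._val_loss(*monitor)
            if val < best - 1e-12:
                best = val
                best_params = {k: v.copy() for k, v in self.params.items()}
            elif early_stopping:  # patience 0
                break
        if early_stopping:
            self.params = best_params
        return self

    def predict(self, c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.latent_dim)
        return self.decode(c, z)


class CGANImputer:
    """Conditional GAN: a generator fabricates the missing time point from the
    condition and 1-dimensional noise; a discriminator with sigmoid output
    judges (condition, target) pairs."""

    def __init__(self, cond_dim: int, out_dim: int, latent_dim: int = 1, seed: int = 0):
        self.cond_dim = cond_dim
        self.out_dim = out_dim
        self.latent_dim = latent_dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        h = out_dim
        g = {}
        g["W1"], g["b1"] = _init_linear(rng, cond_dim + latent_dim, h)
        g["W2"], g["b2"] = _init_linear(rng, h, out_dim)
        d = {}
        d["W1"], d["b1"] = _init_linear(rng, cond_dim + out_dim, h)
        d["W2"], d["b2"] = _init_linear(rng, h, 1)
        self.G = g
        self.D = d

    def generate(self, c, eps):
        v = np.concatenate([c, np.atleast_1d(eps)])
        h = np.tanh(self.G["W1"] @ v + self.G["b1"])
        return self.G["W2"] @ h + self.G["b2"]

    def _disc_forward(self, c, x):
        u = np.concatenate([c, x])
        h = np.tanh(self.D["W1"] @ u + self.D["b1"])
        o = float((self.D["W2"] @ h + self.D["b2"])[0])
        return u, h, _sigmoid(o)

    def _disc_backward(self, u, h, dout):
        """Gradients of the discriminator for dL/do = dout; returns (grads, dL/dx)."""
        g = {}
        g["W2"] = dout * h[None, :]
        g["b2"] = np.array([dout])
        dh = dout * self.D["W2"][0]
        da = dh * (1 - h**2)
        g["W1"] = np.outer(da, u)
        g["b1"] = da
        du = self.D["W1"].T @ da
        return g, du[self.cond_dim :]

    def _gen_backward(self, c, eps, dx):
        v = np.concatenate([c, np.atleast_1d(eps)])
        a = self.G["W1"] @ v + self.G["b1"]
        h = np.tanh(a)
        g = {}
        g["W2"] = np.outer(dx, h)
        g["b2"] = dx
        da = (self.G["W2"].T @ dx) * (1 - h**2)
        g["W1"] = np.outer(da, v)
        g["b1"] = da
        return g

    def _gen_val_loss(self, C):
        # generator adversarial loss -log D(c, G(c, 0)) on held-out pairs
        total = 0.0
        for c in C:
            fake = self.generate(c, np.zeros(self.latent_dim))
            _, _, s = self._disc_forward(c, fake)
            total += -np.log(max(s, 1e-12))
        return total / len(C)

    def _disc_train_loss(self, C, Y):
        # discriminator objective -log D(real) - log(1 - D(fake)), fake at eps=0
        total = 0.0
        for c, y in zip(C, Y):
            _, _, s_real = self._disc_forward(c, y)
            fake = self.generate(c, np.zeros(self.latent_dim))
            _, _, s_fake = self._disc_forward(c, fake)
            total += -np.log(max(s_real, 1e-12)) - np.log(max(1 - s_fake, 1e-12))
        return total / len(C)

    def fit(
        self,
        C: np.ndarray,
        Y: np.ndarray,
        max_epochs: int = 1000,
        val_frac: float = 0.2,
        early_stopping: bool = True,
    ):
        C = np.atleast_2d(C)
        Y = np.atleast_2d(Y)
        rng = np.random.default_rng([self.seed, 2])
        tr, va = _train_val_split(len(C), val_frac, rng)
        opt_g = Adam(self.G)
        opt_d = Adam(self.D)
        best = np.inf
        best_G = {k: v.copy() for k, v in self.G.items()}
        self.loss_history: list[float] = []
        for _ in range(max_epochs):
            for i in rng.permutation(tr):
                c, y = C[i], Y[i]
                # discriminator: -log D(real) - log(1 - D(fake))
                u, h, s = self._disc_forward(c, y)
                g_real, _ = self._disc_backward(u, h, s - 1.0)
                eps = rng.standard_normal(self.latent_dim)
                fake = self.generate(c, eps)
                u, h, s = self._disc_forward(c, fake)
                g_fake, _ = self._disc_backward(u, h, s)
                opt_d.step({k: g_real[k] + g_fake[k] for k in g_real})
                # generator: -log D(fake)
                eps = rng.standard_normal(self.latent_dim)
                fake = self.generate(c, eps)
                u, h, s = self._disc_forward(c, fake)
                _, dx = self._disc_backward(u, h, s - 1.0)
                opt_g.step(self._gen_backward(c, eps, dx))
            self.loss_history.append(self._disc_train_loss(C[tr], Y[tr]))
            monitor = C[va] if len(va) else C[tr]
            val = self._gen_val_loss(monitor)
            if val < best - 1e-12:
                best = val
                best_G = {k: v.copy() for k, v in self.G.items()}
            elif early_stopping:  # patience 0
                break
        if early_stopping:
            self.G = best_G
        return self

    def predict(self, c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        eps = rng.standard_normal(self.latent_dim)
        return self.generate(c, eps)
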