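"""A small variational autoencoder for expression and copy-ratio matrices.

The same architecture is used twice in the pipeline:

* stage 1 — trained on the binned expression matrix with a
  negative-binomial likelihood to learn a latent representation per cell
  (the latent space is where diploid and aneuploid populations separate);
* stage 2 — retrained on the pseudo copy matrix with a Gaussian
  likelihood to produce denoised per-bin copy estimates via the decoder
  mean.

Encoder and decoder are single-hidden-layer MLPs (ReLU, 128 units by
default) with a 10-dimensional diagonal-Gaussian latent.  The model is
implemented directly on numpy arrays with hand-written reverse-mode
gradients and an Adam optimizer: the network is tiny and fixed, so a
deep-learning framework buys nothing here, and the closed-form gradients
are checked against finite differences in the test suite.

Negative-binomial parameterization: the decoder emits per-bin proportions
through a softmax which are scaled by the cell's observed total
(library size), matching the mean-dispersion NB used throughout the
single-cell literature; dispersion is a free per-bin parameter.  The
likelihood is evaluated through gamma functions and therefore accepts the
real-valued bin means produced by count binning.

Gaussian parameterization: the decoder mean passes through a softplus
(copy ratios are non-negative) and each bin has a free log-variance.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import gammaln, digamma, expit, softmax
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

_LOGVAR_CLIP = 15.0
_EPS = 1e-10


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Per-row KL(q || N(0, I)) for a diagonal Gaussian posterior.

    KL = 1/2 * sum(mu^2 + sigma^2 - log sigma^2 - 1), always >= 0.
    """
    return 0.5 * np.sum(mu ** 2 + np.exp(logvar) - logvar - 1.0, axis=1)


def nb_log_likelihood(x: np.ndarray, mean: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Elementwise negative-binomial log-likelihood (mean/dispersion form).

    Continuous in ``x`` (gamma-function extension), so it applies to
    binned mean counts as well as integers.  Variance is
    ``mean + mean**2 / theta``; ``theta -> inf`` recovers Poisson.
    """
    mean = np.maximum(mean, _EPS)
    return (
        gammaln(x + theta) - gammaln(theta) - gammaln(x + 1.0)
        + theta * (np.log(theta) - np.log(theta + mean))
        + x * (np.log(mean) - np.log(theta + mean))
    )


def _softplus(x):
    return np.logaddexp(0.0, x)


class CountVAE(TransformerMixin, BaseEstimator):
    """Variational autoencoder over cells x features matrices.

    Parameters
    ----------
    latent_dim : int
        Dimension of the latent space.
    hidden_dim : int
        Width of the single hidden layer in encoder and decoder.
    likelihood : {"nb", "gaussian"}
        Reconstruction likelihood.  ``"nb"`` for (binned) count data,
        ``"gaussian"`` for real-valued copy ratios.
    epochs, batch_size, learning_rate : training schedule (Adam).
    kl_weight : float
        Multiplier on the KL term of the ELBO.
    early_stop_rel_tol : float
        Stop when the full-data ELBO improves by less than this relative
        amount over ``early_stop_patience`` epochs.
    random_state : int
        Seed for initialisation, batching and the reparameterisation
        noise; fixed seed gives a bit-stable loss trajectory.

    Attributes
    ----------
    params_ : dict of numpy arrays (weights, biases, per-feature params)
    history_ : list of per-epoch dicts with keys epoch/elbo/recon/kl
    n_features_in_ : int
    """

    def __init__(
        self,
        latent_dim: int = 10,
        hidden_dim: int = 128,
        likelihood: str = "nb",
        epochs: int = 200,
        batch_size: int = 128,
        learning_rate: float = 1e-3,
        kl_weight: float = 1.0,
        early_stop_rel_tol: float = 1e-3,
        early_stop_patience: int = 20,
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.hidden_dim = hidden_dim
        self.likelihood = likelihood
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.kl_weight = kl_weight
        self.early_stop_rel_tol = early_stop_rel_tol
        self.early_stop_patience = early_stop_patience
        self.random_state = random_state

    # ------------------------------------------------------------------
    # forward / backward
    # ------------------------------------------------------------------

    def _init_params(self, n_features: int, rng: np.random.Generator) -> dict:
        D, H, L = n_features, self.hidden_dim, self.latent_dim

        def glorot(fan_in, fan_out):
            s = np.sqrt(2.0 / (fan_in + fan_out))
            return rng.normal(0.0, s, size=(fan_in, fan_out))

        params = {
            "We": glorot(D, H), "be": np.zeros(H),
            "Wmu": glorot(H, L), "bmu": np.zeros(L),
            "Wlv": glorot(H, L), "blv": np.zeros(L),
            "Wd": glorot(L, H), "bd": np.zeros(H),
            "Wo": glorot(H, D), "bo": np.zeros(D),
            # per-feature auxiliary parameter: log-dispersion (NB) or
            # log-variance (Gaussian)
            "aux": np.zeros(D),
        }
        return params

    def _encoder_input(self, X: np.ndarray) -> np.ndarray:
        # Per-feature standardized log1p for counts: the encoder then sees
        # relative expression changes, which is where CNV structure lives,
        # instead of being dominated by highly expressed bins.  Statistics
        # are frozen at fit time.
        if self.likelihood == "nb":
            X = np.log1p(X)
        if not hasattr(self, "input_center_"):
            self.input_center_ = X.mean(axis=0)
            self.input_scale_ = X.std(axis=0) + 1e-8
        return (X - self.input_center_) / self.input_scale_

    def _encode_params(self, params, X):
        xin = self._encoder_input(X)
        h = np.maximum(xin @ params["We"] + params["be"], 0.0)
        mu = h @ params["Wmu"] + params["bmu"]
        lv = np.clip(h @ params["Wlv"] + params["blv"], -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return xin, h, mu, lv

    def _decode_mean(self, params, z, lib=None):
        h2 = np.maximum(z @ params["Wd"] + params["bd"], 0.0)
        o = h2 @ params["Wo"] + params["bo"]
        if self.likelihood == "nb":
            rho = softmax(o, axis=1)
            mean = lib[:, None] * rho
        else:
            mean = _softplus(o)
        return h2, o, mean

    def _loss_and_grads(self, params, X, eps):
        """Mean negative ELBO over the batch, and gradients.

        ``eps`` is the reparameterisation noise, passed explicitly so the
        gradient can be checked against finite differences at fixed noise.
        """
        B = X.shape[0]
        lib = X.sum(axis=1) if self.likelihood == "nb" else None

        xin, h, mu, lv = self._encode_params(params, X)
        sig = np.exp(0.5 * lv)
        z = mu + sig * eps
        h2, o, mean = self._decode_mean(params, z, lib)

        if self.likelihood == "nb":
            theta = np.exp(params["aux"])[None, :]
            ll = nb_log_likelihood(X, mean, theta)
        else:
            var = np.exp(params["aux"])[None, :]
            ll = -0.5 * ((X - mean) ** 2 / var + params["aux"][None, :]
                         + np.log(2.0 * np.pi))
        kl = gaussian_kl(mu, lv)
        recon = float(ll.sum(axis=1).mean())
        kl_mean = float(kl.mean())
        loss = -(recon - self.kl_weight * kl_mean)

        # ---- backward (d loss / d each param); loss = mean over batch ----
        g = {}
        if self.likelihood == "nb":
            mean_c = np.maximum(mean, _EPS)
            dll_dmean = X / mean_c - (X + theta) / (theta + mean_c)
            dmean = -dll_dmean / B                       # d loss / d mean
            # mean = lib * rho ; softmax backward
            rho = softmax(o, axis=1)
            drho = lib[:, None] * dmean
            do = rho * (drho - np.sum(rho * drho, axis=1, keepdims=True))
            # dispersion gradient
            dll_dtheta = (
                digamma(X + theta) - digamma(theta)
                + np.log(theta) + 1.0 - np.log(theta + mean_c)
                - (theta + X) / (theta + mean_c)
            )
            g["aux"] = -(dll_dtheta * theta).sum(axis=0) / B
        else:
            var = np.exp(params["aux"])[None, :]
            dll_dmean = (X - mean) / var
            dmean = -dll_dmean / B
            do = dmean * expit(o)                        # softplus'
            dll_dlogvar = -0.5 * (1.0 - (X - mean) ** 2 / var)
            g["aux"] = -dll_dlogvar.sum(axis=0) / B

        g["Wo"] = h2.T @ do
        g["bo"] = do.sum(axis=0)
        dh2 = (do @ params["Wo"].T) * (h2 > 0)
        g["Wd"] = z.T @ dh2
        g["bd"] = dh2.sum(axis=0)
        dz = dh2 @ params["Wd"].T

        dmu = dz + self.kl_weight * mu / B
        dlv = dz * eps * 0.5 * sig + self.kl_weight * 0.5 * (np.exp(lv) - 1.0) / B
        # clip is active only at +-_LOGVAR_CLIP; gradient zero there
        pre_lv = h @ params["Wlv"] + params["blv"]
        dlv = np.where(np.abs(pre_lv) < _LOGVAR_CLIP, dlv, 0.0)

        g["Wmu"] = h.T @ dmu
        g["bmu"] = dmu.sum(axis=0)
        g["Wlv"] = h.T @ dlv
        g["blv"] = dlv.sum(axis=0)
        dh = (dmu @ params["Wmu"].T + dlv @ params["Wlv"].T) * (h > 0)
        g["We"] = xin.T @ dh
        g["be"] = dh.sum(axis=0)
        return loss, recon, kl_mean, g

    # ------------------------------------------------------------------
    # sklearn API
    # ------------------------------------------------------------------

    def fit(self, X, y=None):
        """Train on a cells x features matrix of non-negative values."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (cells x features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if self.likelihood not in ("nb", "gaussian"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if X.min() < 0:
            raise ValueError("X must be non-negative")
        if self.likelihood == "nb" and np.any(X.sum(axis=1) <= 0):
            raise ValueError("NB likelihood requires positive per-cell totals")

        n, D = X.shape
        rng = np.random.default_rng(self.random_state)
        params = self._init_params(D, rng)

        # freeze encoder input statistics on the full training matrix
        for attr in ("input_center_", "input_scale_"):
            if hasattr(self, attr):
                delattr(self, attr)
        self._encoder_input(X)

        # Adam state
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in params.items()}
        b1, b2, lr, adam_eps = 0.9, 0.999, self.learning_rate, 1e-8
        t = 0

        self.history_ = []
        best = -np.inf
        best_epoch = 0
        batch = min(self.batch_size, n)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                eps = rng.standard_normal((len(idx), self.latent_dim))
                loss, _, _, grads = self._loss_and_grads(params, X[idx], eps)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        "non-finite training loss; try a lower learning rate"
                    )
                t += 1
                for k in params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mhat = m[k] / (1 - b1 ** t)
                    vhat = v[k] / (1 - b2 ** t)
                    params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + adam_eps)

            elbo, recon, kl = self._full_elbo(params, X)
            self.history_.append(
                {"epoch": epoch, "elbo": elbo, "recon": recon, "kl": kl}
            )
            if elbo > best + self.early_stop_rel_tol * max(abs(best), 1.0):
                best_epoch = epoch
            best = max(best, elbo)
            if epoch - best_epoch >= self.early_stop_patience:
                logger.info("[vae] early stop at epoch %d (elbo %.4f)", epoch, elbo)
                break

        self.params_ = params
        self.n_features_in_ = D
        return self

    def _full_elbo(self, params, X):
        """Deterministic ELBO at the posterior mean (no sampling)."""
        lib = X.sum(axis=1) if self.likelihood == "nb" else None
        _, _, mu, lv = self._encode_params(params, X)
        _, _, mean = self._decode_mean(params, mu, lib)
        if self.likelihood == "nb":
            ll = nb_log_likelihood(X, mean, np.exp(params["aux"])[None, :])
        else:
            var = np.exp(params["aux"])[None, :]
            ll = -0.5 * ((X - mean) ** 2 / var + params["aux"][None, :]
                         + np.log(2.0 * np.pi))
        kl = gaussian_kl(mu, lv)
        recon = float(ll.sum(axis=1).mean())
        klm = float(kl.mean())
        return recon - self.kl_weight * klm, recon, klm

    def _check_X(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected 2-D input with {self.n_features_in_} features, "
                f"got shape {np.shape(X)}"
            )
        return X

    def transform(self, X):
        """Latent posterior means (cells x latent_dim); deterministic."""
        X = self._check_X(X)
        _, _, mu, _ = self._encode_params(self.params_, X)
        return mu

    def encode(self, X):
        """Posterior means and log-variances."""
        X = self._check_X(X)
        _, _, mu, lv = self._encode_params(self.params_, X)
        return mu, lv

    def reconstruct(self, X):
        """Decoder mean at the latent posterior mean; non-negative."""
        X = self._check_X(X)
        lib = X.sum(axis=1) if self.likelihood == "nb" else None
        _, _, mu, _ = self._encode_params(self.params_, X)
        _, _, mean = self._decode_mean(self.params_, mu, lib)
        return mean

    def elbo(self, X):
        """Deterministic full-data ELBO (reconstruction - kl_weight * KL)."""
        X = self._check_X(X)
        return self._full_elbo(self.params_, X)[0]

    def save(self, path):
        """Serialize the trained parameters to an ``.npz`` checkpoint."""
        check_is_fitted(self, "params_")
        np.savez(
            path,
            likelihood=np.array(self.likelihood),
            input_center=self.input_center_,
            input_scale=self.input_scale_,
            **{f"param_{k}": v for k, v in self.params_.items()},
        )

    def load(self, path):
        """Load parameters saved by :meth:`save` into this estimator."""
        data = np.load(path, allow_pickle=False)
        self.params_ = {
            k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")
        }
        self.input_center_ = data["input_center"]
        self.input_scale_ = data["input_scale"]
        self.n_features_in_ = self.params_["We"].shape[0]
        if "history_" not in self.__dict__:
            self.history_ = []
        return self
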