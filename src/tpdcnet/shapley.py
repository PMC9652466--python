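"""Kernel SHAP: Shapley-value attribution for fitted prediction models.

The Shapley value of feature i for an observation x is the weighted average,
over coalitions S of the remaining features, of the change in the model's
expected prediction when feature i joins S:

    phi_i = sum_{S subset of F \\ {i}}  |S|! (m - |S| - 1)! / m!  [v(S u {i}) - v(S)]

with the interventional value function v(S) = E_b[ f(x_S, b_{F \\ S}) ]
estimated by replacing absent features with rows of a background sample
(the model's training fold).

For m <= ``max_exact_features`` all 2^m coalitions are enumerated, which makes
local accuracy (base value + sum_i phi_i = f(x)) exact.  Beyond that, the
weighted-least-squares Kernel SHAP estimator with sampled coalitions is used,
with local accuracy enforced as an equality constraint.
"""

from __future__ import annotations

from math import comb, factorial

import numpy as np

from .datatypes import TpdcError


class KernelShapExplainer:
    """Attribute a model's predictions to its input features.

    Parameters
    ----------
    predict : callable (n, m) -> (n,)
        The fitted model's prediction function (decision values for
        classifiers).
    background : ndarray (n_bg, m)
        Reference sample defining the expectation in the value function;
        typically the model's training fold.
    max_exact_features : int
        Exact coalition enumeration is used for m up to this bound.
    n_coalition_samples : int
        Coalition budget for the sampled estimator.
    seed : int
        Seed for coalition sampling.
    """

    def __init__(
        self,
        predict,
        background: np.ndarray,
        max_exact_features: int = 12,
        n_coalition_samples: int = 2048,
        seed: int = 0,
    ):
        self.predict = predict
        self.background = np.asarray(background, dtype=float)
        if self.background.ndim != 2 or self.background.shape[0] == 0:
            raise TpdcError("background must be a non-empty 2-D array")
        self.max_exact_features = max_exact_features
        self.n_coalition_samples = n_coalition_samples
        self.seed = seed
        self.base_value = float(np.mean(self.predict(self.background)))

    def shap_values(self, X: np.ndarray) -> np.ndarray:
        """Per-observation, per-feature Shapley values, shape (n, m)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = X.shape[1]
        if m != self.background.shape[1]:
            raise TpdcError("observation and background dimensions differ")
        if m <= self.max_exact_features:
            return np.vstack([self._exact_one(x) for x in X])
        return np.vstack([self._sampled_one(x) for x in X])

    # -- exact enumeration ------------------------------------------------

    def _coalition_values(self, x: np.ndarray, masks: np.ndarray) -> np.ndarray:
        """v(S) for each boolean mask row: mean prediction over the background
        with masked features replaced by x."""
        n_bg = self.background.shape[0]
        vals = np.empty(len(masks))
        # batch all synthetic rows into one predict call per chunk
        chunk = max(1, 65536 // max(n_bg, 1))
        for start in range(0, len(masks), chunk):
            block = masks[start : start + chunk]
            Z = np.repeat(self.background[None], len(block), axis=0)  # (c, n_bg, m)
            Z[:, :, :] = np.where(block[:, None, :], x[None, None, :], Z)
            preds = self.predict(Z.reshape(-1, x.size)).reshape(len(block), n_bg)
            vals[start : start + chunk] = preds.mean(axis=1)
        return vals

    def _exact_one(self, x: np.ndarray) -> np.ndarray:
        m = x.size
        n_coal = 1 << m
        masks = (
            (np.arange(n_coal)[:, None] >> np.arange(m)[None, :]) & 1
        ).astype(bool)
        v = self._coalition_values(x, masks)
        sizes = masks.sum(axis=1)
        fact = np.array([factorial(k) for k in range(m + 1)], dtype=float)
        phi = np.zeros(m)
        for i in range(m):
            without = ~masks[:, i]
            S = np.nonzero(without)[0]
            S_with = S | (1 << i)
            w = fact[sizes[S]] * fact[m - sizes[S] - 1] / fact[m]
            phi[i] = np.sum(w * (v[S_with] - v[S]))
        return phi

    # -- sampled WLS (Kernel SHAP) ----------------------------------------

    def _sampled_one(self, x: np.ndarray) -> np.ndarray:
        m = x.size
        rng = np.random.default_rng(self.seed)
        fx = float(self.predict(x[None])[0])

        # deterministic inclusion of all size-1 and size-(m-1) coalitions,
        # then sample intermediate sizes with the Shapley kernel weights
        masks = []
        for i in range(m):
            e = np.zeros(m, bool)
            e[i] = True
            masks.append(e.copy())
            masks.append(~e)
        budget = max(self.n_coalition_samples - len(masks), 0)
        sizes = np.arange(2, m - 1)
        if sizes.size and budget:
            w_size = (m - 1) / (sizes * (m - sizes))
            w_size = w_size / w_size.sum()
            drawn = rng.choice(sizes, size=budget, p=w_size)
            for s in drawn:
                idx = rng.choice(m, size=s, replace=False)
                e = np.zeros(m, bool)
                e[idx] = True
                masks.append(e)
        Zmask = np.array(masks)
        v = self._coalition_values(x, Zmask)
        sizes_all = Zmask.sum(axis=1)
        w = (m - 1) / (
            np.array([comb(m, s) for s in sizes_all]) * sizes_all * (m - sizes_all)
        )
        # enforce local accuracy: phi_m = (fx - base) - sum_{j<m} phi_j
        z = Zmask.astype(float)
        target = v - self.base_value - z[:, -1] * (fx - self.base_value)
        A = z[:, :-1] - z[:, [-1]]
        Aw = A * w[:, None]
        beta, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ target, rcond=None)
        phi = np.empty(m)
        phi[:-1] = beta
        phi[-1] = (fx - self.base_value) - beta.sum()
        return phi
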