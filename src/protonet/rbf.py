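"""Single- and two-layer prototypical RBF network models.

Both models classify 2-s windows as tremor / non-tremor from their distances
to prototype bases. A basis is a (center, diagonal scale) pair; its
activation for input ``x`` is the Gaussian of the Mahalanobis distance,

    rho(x; c, s) = exp(-d^2 / 2),   d^2 = sum_j (x_j - c_j)^2 / s_j,

bounded in (0, 1]. The single-layer network scores a window by a linear
combination of its K basis activations passed through a softmax; weights are
fitted by l2-regularized logistic likelihood.

The two-layer network first maps the 45-dim input to an M-dim embedding
through an inducing-point RBF layer (isotropic Gaussian bases at greedily
selected inducing points), then applies the prototype layer in embedding
space. Training alternates three steps until the loss change falls below
tolerance: (1) gradient descent on the internal embeddings X* under the
cross-entropy loss, (2) least-squares recovery of the first-layer weights
W1 = pinv(Phi1) X*, (3) recompute X* and Phi2 and take a gradient step on
the second-layer weights W2 (with the prototype bases periodically refitted
in the updated embedding space). Optimizing the embeddings instead of
back-propagating through both RBF layers sidesteps the vanishing-gradient
problem of stacked RBF layers.

API shape follows statsmodels: ``Model(endog, exog, ...).fit()`` returns a
Results object carrying estimates, diagnostics and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .dpm import (
    BasisSet,
    NIGPrior,
    PrototypeBasis,
    fit_mapdp,
    select_hyperparameters,
    default_grid,
)

EPS_PROB = 1e-12


# ---------------------------------------------------------------------------
# activations


def rbf_activation(x: np.ndarray, basis: PrototypeBasis) -> float:
    """Gaussian-of-Mahalanobis activation of a single basis, in (0, 1]."""
    x = np.asarray(x, dtype=float)
    if x.shape != basis.center.shape:
        raise ValueError(
            f"input dim {x.shape} does not match basis dim {basis.center.shape}"
        )
    d2 = np.sum((x - basis.center) ** 2 / basis.scale)
    return float(np.exp(-0.5 * d2))


def activations(X: np.ndarray, centers: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """N x K activation matrix for diagonal-scale Gaussian bases."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != centers.shape[1]:
        raise ValueError("input dimensionality does not match basis centers")
    d2 = np.empty((len(X), len(centers)))
    for k in range(len(centers)):
        d2[:, k] = np.sum((X - centers[k]) ** 2 / scales[k], axis=1)
    # floor at the smallest normal float: exp underflows to 0 for distant
    # points, while the activation is mathematically in (0, 1]
    return np.maximum(np.exp(-0.5 * d2), np.finfo(float).tiny)


def loss_cross_entropy(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean binary cross-entropy with probabilities clipped to
    [1e-12, 1 - 1e-12]."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(y_hat, dtype=float), EPS_PROB, 1.0 - EPS_PROB)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _softmax2(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# single-layer model


class SingleLayerRBFNet:
    """Single-layer prototypical RBF network.

    Parameters
    ----------
    endog : array (n,)
        Binary labels (1 = tremor).
    exog : array (n, D)
        Feature matrix (typically z-scored 45-dim window features).
    basis_set : BasisSet
        Prototype bases inferred from prototypical examples (per-sub-class
        DPM components).
    bandwidth : float, optional
        Multiplier on the basis variances in the Mahalanobis metric. The
        squared distance of in-component points under the raw DPM variances
        concentrates near the input dimension D, pushing every activation
        toward exp(-D/2); the default 3*D rescales within-component
        activations to O(1).
    """

    def __init__(self, endog, exog, basis_set: BasisSet, bandwidth: float | None = None):
        self.endog = np.asarray(endog, dtype=int)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.basis_set = basis_set
        self.bandwidth = 3.0 * self.exog.shape[1] if bandwidth is None else bandwidth
        if len(np.unique(self.endog)) < 2:
            raise ValueError("both classes must be present in endog")

    @classmethod
    def from_feature_table(
        cls, table, basis_set: BasisSet, bandwidth: float | None = None
    ) -> "SingleLayerRBFNet":
        return cls(table.y, table.X, basis_set, bandwidth=bandwidth)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return activations(
            X, self.basis_set.centers(), self.basis_set.scales() * self.bandwidth
        )

    def fit(self, reg: float = 1.0) -> "SingleLayerRBFResults":
        """Maximize the l2-regularized logistic likelihood of the basis
        activations (``reg`` is the inverse of sklearn's C)."""
        phi = self.transform(self.exog)
        assert np.all((phi > 0) & (phi <= 1.0))
        clf = LogisticRegression(C=1.0 / reg, solver="lbfgs", max_iter=2000)
        clf.fit(phi, self.endog)
        return SingleLayerRBFResults(
            model=self,
            weights=clf.coef_[0].copy(),
            intercept=float(clf.intercept_[0]),
            reg=reg,
        )


@dataclass
class SingleLayerRBFResults:
    model: SingleLayerRBFNet
    weights: np.ndarray  # one per basis
    intercept: float
    reg: float
    threshold: float | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        phi = self.model.transform(X)
        assert np.all((phi > 0) & (phi <= 1.0))
        score = phi @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-score))

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.threshold is None:
            raise ValueError("decision threshold not set")
        return (self.predict_proba(X) >= self.threshold).astype(int)

    def summary(self) -> str:
        bs = self.model.basis_set
        lines = [
            "Single-layer prototypical RBF network",
            f"  bases (K):          {bs.K}",
            f"  sub-classes:        {bs.Lambda}",
            f"  l2 regularization:  {self.reg:g}",
            f"  intercept:          {self.intercept:+.4f}",
            f"  threshold:          {self.threshold}",
            "  per-sub-class weight sums:",
        ]
        sums: dict[str, float] = {}
        for b, w in zip(bs.bases, self.weights):
            sums[b.sub_class] = sums.get(b.sub_class, 0.0) + float(w)
        for sub in sorted(sums):
            lines.append(f"    {sub}: {sums[sub]:+.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# inducing-point selection


def select_inducing_points(
    X: np.ndarray,
    n_inducing: int,
    lengthscale: float | None = None,
    s1_factor: float = 0.5,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Greedy inducing-point selection by GP posterior-variance reduction.

    Under an isotropic Gaussian kernel, repeatedly pick the candidate with
    the largest current posterior variance (the most informative point); the
    first pick is the kernel medoid. Duplicated rows have zero posterior
    variance once their twin is selected, so no duplicate is chosen while
    distinct candidates remain. Deterministic.

    Returns ``(centers, s1, indices)`` where ``s1`` — the shared isotropic
    first-layer basis scale — is the median pairwise distance among the
    selected points times ``s1_factor``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(X)
    if not 1 <= n_inducing <= n:
        raise ValueError(f"n_inducing must be in [1, {n}], got {n_inducing}")
    sub = X[:: max(1, n // 500)]
    d2_sub = _sq_dists(sub, sub)
    if lengthscale is None:
        med = np.median(np.sqrt(d2_sub[np.triu_indices(len(sub), k=1)])) if len(sub) > 1 else 1.0
        lengthscale = max(float(med), 1e-8)
    k_diag = np.ones(n)
    var = k_diag.copy()
    G = np.zeros((n, n_inducing))
    chosen: list[int] = []
    for j in range(n_inducing):
        if j == 0:
            # kernel medoid: maximal total similarity
            kx = np.exp(-_sq_dists(X, X[:: max(1, n // 500)]) / (2 * lengthscale**2))
            i = int(np.argmax(kx.sum(axis=1)))
        else:
            v = var.copy()
            v[chosen] = -np.inf
            i = int(np.argmax(v))
        chosen.append(i)
        kxi = np.exp(-_sq_dists(X, X[i : i + 1])[:, 0] / (2 * lengthscale**2))
        g = kxi - G[:, :j] @ G[i, :j]
        denom = np.sqrt(max(var[i], 1e-12))
        G[:, j] = g / denom
        var = np.maximum(var - G[:, j] ** 2, 0.0)
    centers = X[chosen]
    if len(chosen) > 1:
        dsel = np.sqrt(_sq_dists(centers, centers)[np.triu_indices(len(chosen), k=1)])
        s1 = float(np.median(dsel)) * s1_factor
    else:
        s1 = lengthscale * s1_factor
    return centers, max(s1, 1e-8), np.asarray(chosen)


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.maximum(d2, 0.0)


def _iso_activations(X: np.ndarray, centers: np.ndarray, s1: float) -> np.ndarray:
    """First-layer activations: isotropic Gaussian, shared scale s1
    (variance s1^2 per coordinate)."""
    return np.maximum(
        np.exp(-0.5 * _sq_dists(np.atleast_2d(X), centers) / s1**2),
        np.finfo(float).tiny,
    )


# ---------------------------------------------------------------------------
# two-layer model


def two_layer_loss_from_embedding(Xstar, centers, scales, W2, y) -> float:
    """Cross-entropy loss as a function of the embeddings (for gradient
    checks): Phi2 -> softmax -> mean binary cross-entropy."""
    phi2 = activations(Xstar, centers, scales)
    scores = phi2 @ W2[:-1] + W2[-1]
    p = _softmax2(scores)[:, 1]
    return loss_cross_entropy(y, p)


def embedding_gradient(Xstar, centers, scales, W2, y) -> np.ndarray:
    """Closed-form dE/dX* via the chain rule through the Gaussian-basis
    Mahalanobis activations: dE/dPhi2 times dPhi2/dX*."""
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    if Xstar.shape[1] != centers.shape[1]:
        raise ValueError("embedding dim does not match second-layer centers")
    n = len(Xstar)
    phi2 = activations(Xstar, centers, scales)
    scores = phi2 @ W2[:-1] + W2[-1]
    P = _softmax2(scores)
    Y = np.stack([1 - np.asarray(y, float), np.asarray(y, float)], axis=1)
    g_phi2 = (P - Y) @ W2[:-1].T / n  # N x K2
    T = g_phi2 * phi2
    inv_s = 1.0 / scales  # K2 x M
    return -(Xstar * (T @ inv_s) - T @ (centers * inv_s))


def w2_gradient(phi2: np.ndarray, y: np.ndarray, W2: np.ndarray) -> np.ndarray:
    """Gradient of the softmax cross-entropy w.r.t. W2 (including the
    intercept row): (1/N) [Phi2, 1]^T (Yhat - Y)."""
    n = len(phi2)
    scores = phi2 @ W2[:-1] + W2[-1]
    P = _softmax2(scores)
    Y = np.stack([1 - np.asarray(y, float), np.asarray(y, float)], axis=1)
    phia = np.hstack([phi2, np.ones((n, 1))])
    return phia.T @ (P - Y) / n


@dataclass
class TwoLayerConfig:
    """Two-layer network hyperparameters.

    ``basis_bandwidth`` multiplies the second-layer basis variances: the
    squared Mahalanobis distance of in-component points under the raw DPM
    variances concentrates near the embedding dimension M (a chi-square
    effect), which would drive every activation toward exp(-M/2) ~ 0 and
    stall training; scaling the metric by c*M keeps within-component
    activations O(1). ``None`` means 3*M.
    """

    embedding_dim: int = 15
    n_inducing: int = 30
    s1_factor: float = 0.5
    eta: float = 0.5
    tol: float = 1e-5
    max_iter: int = 500
    refresh_every: int = 10
    basis_bandwidth: float | None = None
    max_rows_per_subclass: int = 400
    seed: int = 0

    @property
    def bandwidth(self) -> float:
        return (
            self.basis_bandwidth
            if self.basis_bandwidth is not None
            else 3.0 * self.embedding_dim
        )


class TwoLayerRBFNet:
    """Two-layer prototypical RBF network.

    Parameters
    ----------
    endog, exog : labels and (n, D) features as in ``SingleLayerRBFNet``.
    prototype_groups : list of (sub_class, class_label, rows)
        Prototypical example rows per sub-class in the original feature
        space; they are re-embedded through the evolving first layer and
        summarised by per-sub-class DPMs to form the second-layer bases.
    config : TwoLayerConfig
    """

    def __init__(
        self,
        endog,
        exog,
        prototype_groups: Sequence[tuple[str, str, np.ndarray]],
        config: TwoLayerConfig | None = None,
    ):
        self.endog = np.asarray(endog, dtype=int)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.config = config or TwoLayerConfig()
        if len(np.unique(self.endog)) < 2:
            raise ValueError("both classes must be present in endog")
        groups = [(s, c, np.atleast_2d(np.asarray(r, float))) for s, c, r in prototype_groups]
        groups = [(s, c, r) for s, c, r in groups if r.size]
        if not groups:
            raise ValueError("prototype rows must be non-empty")
        self.prototype_groups = groups
        if self.config.embedding_dim >= self.exog.shape[1]:
            raise ValueError("embedding_dim must be smaller than the input dim")

    @classmethod
    def from_feature_table(cls, table, config: TwoLayerConfig | None = None):
        """Build from a labelled feature table: tremor sub-class groups use
        prototype-flagged rows, non-tremor groups all rows of the
        sub-class."""
        from .features import FEATURE_NAMES
        from .io import TREMOR_SUBCLASSES, NONTREMOR_SUBCLASSES

        frame = table.frame
        groups = []
        for sub in TREMOR_SUBCLASSES:
            m = (frame["label"] == "tremor") & (frame["sub_class"] == sub) & frame["prototype"]
            groups.append((sub, "tremor", frame.loc[m, list(FEATURE_NAMES)].to_numpy()))
        for sub in NONTREMOR_SUBCLASSES:
            m = (frame["label"] == "non_tremor") & (frame["sub_class"] == sub)
            groups.append((sub, "non_tremor", frame.loc[m, list(FEATURE_NAMES)].to_numpy()))
        return cls(table.y, table.X, groups, config=config)

    # -- pieces -----------------------------------------------------------

    def _embed_prototype_basis(
        self, embed, rng: np.random.Generator, hyper: dict | None
    ) -> tuple[BasisSet, dict]:
        """DPM-summarise the prototype groups in the current embedding space.

        On the first call the DPM hyperparameters are selected per sub-class
        by complete-data likelihood and cached (as (alpha, b0 factor)); later
        refreshes reuse them against the refreshed embedded rows.
        """
        bases = []
        cache = dict(hyper) if hyper else {}
        # per-dimension variance of the embedded training data anchors the
        # prior scale of tiny prototype groups (a singleton group has zero
        # pooled variance of its own)
        sub_idx = np.arange(0, len(self.exog), max(1, len(self.exog) // 1000))
        gvar = np.maximum(embed(self.exog[sub_idx]).var(axis=0), 1e-12)
        for sub, cls_label, rows in self.prototype_groups:
            if len(rows) > self.config.max_rows_per_subclass:
                idx = rng.choice(len(rows), self.config.max_rows_per_subclass, replace=False)
                rows = rows[idx]
            E = embed(rows)
            pooled = np.maximum(E.var(axis=0), 0.01 * gvar)
            if sub not in cache:
                prior, alpha, fit = select_hyperparameters(
                    E, grid=default_grid(E, 0.01 * gvar), shuffle_seed=self.config.seed
                )
                factor = float(np.median(prior.b0 / pooled))
                cache[sub] = (alpha, factor)
            else:
                alpha, factor = cache[sub]
                prior = NIGPrior(
                    m0=E.mean(axis=0), kappa0=0.01, a0=1.0, b0=factor * pooled
                )
                fit = fit_mapdp(E, prior, alpha, shuffle_seed=self.config.seed)
            for k in range(fit.K):
                # floor at 2% of the global embedded variance: a singleton
                # or near-degenerate component carries no scale of its own
                scale = np.maximum(fit.variances[k], 0.02 * gvar)
                bases.append(
                    PrototypeBasis(
                        center=fit.means[k],
                        scale=scale * self.config.bandwidth,
                        sub_class=sub,
                        class_label=cls_label,
                        component_id=k,
                    )
                )
        return BasisSet(bases=bases), cache

    def fit(self, eta: float | None = None) -> "TwoLayerRBFResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        X, y = self.exog, self.endog
        n = len(X)
        eta = cfg.eta if eta is None else eta

        C1, s1, _ = select_inducing_points(
            X, min(cfg.n_inducing, n), s1_factor=cfg.s1_factor
        )
        phi1 = _iso_activations(X, C1, s1)
        assert np.all((phi1 > 0) & (phi1 <= 1.0))

        # initialization: embeddings from the principal components of the
        # inducing points; W1 recovered from them by least squares
        pca = PCA(n_components=cfg.embedding_dim, svd_solver="full").fit(C1)
        Xstar = pca.transform(X)
        W1 = np.linalg.lstsq(phi1, Xstar, rcond=None)[0]
        Xstar = phi1 @ W1

        def embed(rows):
            return _iso_activations(rows, C1, s1) @ W1

        basis, hyper = self._embed_prototype_basis(embed, rng, None)
        C2c, C2s = basis.centers(), basis.scales()
        W2 = rng.standard_normal((basis.K + 1, 2))

        def forward(Xs):
            phi2 = activations(Xs, C2c, C2s)
            p = _softmax2(phi2 @ W2[:-1] + W2[-1])[:, 1]
            return phi2, p

        phi2, p = forward(Xstar)
        E = loss_cross_entropy(y, p)
        history = [E]
        initial_E = E
        it = 0
        while it < cfg.max_iter and eta > 1e-7:
            it += 1
            snapshot = (Xstar.copy(), W1.copy(), W2.copy(), C2c, C2s)
            # (1) embedding gradient step
            grad = embedding_gradient(Xstar, C2c, C2s, W2, y)
            Xstar_t = Xstar - eta * grad
            # (2) least-squares recovery of the first-layer weights
            W1 = np.linalg.lstsq(phi1, Xstar_t, rcond=None)[0]
            # (3) recompute embeddings, refresh prototype bases periodically,
            #     gradient step on the second-layer weights
            Xstar = phi1 @ W1
            refreshed = it % cfg.refresh_every == 0
            if refreshed:
                # refit the prototype bases in the updated embedding space,
                # then carry the learned decision function across the change
                # of basis: W2 is re-mapped by least squares so the new
                # activations reproduce the pre-refresh scores
                phi2_old = activations(Xstar, C2c, C2s)
                scores_old = phi2_old @ W2[:-1] + W2[-1]
                basis, hyper = self._embed_prototype_basis(embed, rng, hyper)
                C2c, C2s = basis.centers(), basis.scales()
                phi2_new = activations(Xstar, C2c, C2s)
                phia = np.hstack([phi2_new, np.ones((n, 1))])
                W2 = np.linalg.lstsq(phia, scores_old, rcond=None)[0]
            phi2 = activations(Xstar, C2c, C2s)
            W2 = W2 - eta * w2_gradient(phi2, y, W2)
            _, p = forward(Xstar)
            E_new = loss_cross_entropy(y, p)
            if E_new > 10.0 * initial_E and E_new > 10.0:
                raise RuntimeError(
                    f"two-layer training diverged: loss {E_new:.3g} "
                    f"(initial {initial_E:.3g}, eta {eta:.3g})"
                )
            if E_new > E and not refreshed:
                # backoff: restore and retry with halved step
                Xstar, W1, W2, C2c, C2s = snapshot
                Xstar = Xstar.copy()
                eta *= 0.5
                continue
            converged = abs(E - E_new) <= cfg.tol * max(abs(E), 1e-12)
            E = E_new
            history.append(E)
            if converged and not refreshed:
                break

        final_basis = basis
        return TwoLayerRBFResults(
            model=self,
            inducing_centers=C1,
            s1=s1,
            W1=W1,
            basis_set=final_basis,
            W2=W2,
            loss_history=history,
            n_iter=it,
            final_eta=eta,
        )


@dataclass
class TwoLayerRBFResults:
    model: TwoLayerRBFNet
    inducing_centers: np.ndarray
    s1: float
    W1: np.ndarray
    basis_set: BasisSet
    W2: np.ndarray
    loss_history: list[float]
    n_iter: int
    final_eta: float
    threshold: float | None = None

    def embed(self, X: np.ndarray) -> np.ndarray:
        return _iso_activations(X, self.inducing_centers, self.s1) @ self.W1

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        phi2 = activations(
            self.embed(X), self.basis_set.centers(), self.basis_set.scales()
        )
        assert np.all((phi2 > 0) & (phi2 <= 1.0))
        return _softmax2(phi2 @ self.W2[:-1] + self.W2[-1])[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.threshold is None:
            raise ValueError("decision threshold not set")
        return (self.predict_proba(X) >= self.threshold).astype(int)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Two-layer prototypical RBF network",
            f"  input dim (D):        {self.model.exog.shape[1]}",
            f"  embedding dim (M):    {cfg.embedding_dim}",
            f"  inducing points K(1): {len(self.inducing_centers)} (s1 = {self.s1:.4g})",
            f"  prototype bases K(2): {self.basis_set.K}"
            f" over {self.basis_set.Lambda} sub-classes",
            f"  iterations:           {self.n_iter} (final eta {self.final_eta:.3g})",
            f"  training loss:        {self.loss_history[0]:.4f} -> {self.loss_history[-1]:.4f}",
            f"  threshold:            {self.threshold}",
        ]
        return "\n".join(lines)


def predict(results, X: np.ndarray, proba: bool = True) -> np.ndarray:
    """Single dispatch over both result types."""
    if not isinstance(results, (SingleLayerRBFResults, TwoLayerRBFResults)):
        raise TypeError(f"unsupported model type {type(results)}")
    return results.predict_proba(X) if proba else results.predict(X)
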