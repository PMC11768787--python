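"""MAP inference for Dirichlet-process Gaussian mixtures (MAP-DP).

Prototypical examples of each tremor / non-tremor sub-class are summarised by
a diagonal Gaussian DPM with a Normal-inverse-Gamma (NIG) prior on each
dimension's mean and variance. Inference is iterated conditional modes on the
collapsed model: each point joins the existing cluster maximising
``log N_k + log t(x | posterior predictive of cluster minus the point)`` or
opens a new cluster at ``log alpha + log t(x | prior predictive)``. Every
such update cannot decrease the collapsed log posterior
``log CRP(z; alpha) + sum_k log m(X_k)``, so the sweep objective is monotone
and terminates at an assignment fixed point.

The converged components (posterior mean / MAP variance per cluster) become
the RBF basis centers and diagonal scales; the number of components per
sub-class is inferred, and the total basis count is the sum over sub-classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import gammaln

from .io import TREMOR_SUBCLASSES, NONTREMOR_SUBCLASSES

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-8
#: components smaller than this are merged into the nearest surviving one
MIN_COMPONENT_SIZE = 3


@dataclass
class NIGPrior:
    """Diagonal Normal-inverse-Gamma prior: per dimension,
    ``sigma^2 ~ InvGamma(a0, b0)`` and ``mu | sigma^2 ~ N(m0, sigma^2/kappa0)``."""

    m0: np.ndarray
    kappa0: float
    a0: float
    b0: np.ndarray

    def __post_init__(self) -> None:
        self.m0 = np.atleast_1d(np.asarray(self.m0, dtype=float))
        self.b0 = np.broadcast_to(
            np.asarray(self.b0, dtype=float), self.m0.shape
        ).copy()
        if self.kappa0 <= 0 or self.a0 <= 0 or np.any(self.b0 <= 0):
            raise ValueError("kappa0, a0 and b0 must be positive")


@dataclass
class DPMFit:
    assignments: np.ndarray
    means: np.ndarray  # (K, D)
    variances: np.ndarray  # (K, D), strictly positive
    counts: np.ndarray  # (K,)
    alpha: float
    log_likelihood: float  # complete-data log-likelihood of the converged fit

    @property
    def K(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class PrototypeBasis:
    """One RBF basis: center and diagonal scale (variance) vector, tagged
    with the sub-class and class it summarises."""

    center: np.ndarray
    scale: np.ndarray
    sub_class: str
    class_label: str
    component_id: int = 0

    def __post_init__(self) -> None:
        if self.center.shape != self.scale.shape:
            raise ValueError("center and scale dimensionality differ")
        if np.any(self.scale <= 0):
            raise ValueError("basis scales must be strictly positive")


@dataclass
class BasisSet:
    bases: list[PrototypeBasis]
    skipped_sub_classes: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.bases)

    @property
    def Lambda(self) -> int:
        return len({b.sub_class for b in self.bases})

    def centers(self) -> np.ndarray:
        return np.stack([b.center for b in self.bases])

    def scales(self) -> np.ndarray:
        return np.stack([b.scale for b in self.bases])


# ---------------------------------------------------------------------------
# sufficient statistics and predictive densities


@njit(cache=True)
def _score_nb(x, nk, s1k, s2k, m0, kappa0, a0, b0):
    """Posterior-predictive (nk > 0) or prior-predictive (nk == 0) Student-t
    log density of x, summed over dimensions."""
    D = x.shape[0]
    kn = kappa0 + nk
    an = a0 + nk / 2.0
    nu = 2.0 * an
    const = math.lgamma((nu + 1.0) / 2.0) - math.lgamma(nu / 2.0)
    total = 0.0
    for d in range(D):
        if nk > 0:
            xbar = s1k[d] / nk
            ss = s2k[d] - nk * xbar * xbar
            if ss < 0.0:
                ss = 0.0
            bn = b0[d] + 0.5 * ss + kappa0 * nk * (xbar - m0[d]) ** 2 / (2.0 * kn)
            mn = (kappa0 * m0[d] + s1k[d]) / kn
        else:
            bn = b0[d]
            mn = m0[d]
        scale2 = bn * (kn + 1.0) / (an * kn)
        z2 = (x[d] - mn) ** 2 / scale2
        total += const - 0.5 * math.log(nu * math.pi * scale2) - (nu + 1.0) / 2.0 * math.log1p(z2 / nu)
    return total


@njit(cache=True)
def _mapdp_kernel(X, order, m0, kappa0, a0, b0, alpha, max_sweeps):
    """Sequential first pass + ICM sweeps of MAP-DP; returns assignments."""
    N, D = X.shape
    n = np.zeros(N, dtype=np.int64)
    s1 = np.zeros((N, D))
    s2 = np.zeros((N, D))
    assign = np.empty(N, dtype=np.int64)
    log_alpha = math.log(alpha)
    zero = np.zeros(D)

    K = 0
    for idx in range(N):
        i = order[idx]
        x = X[i]
        best_k = -1
        best_s = -1e300
        for k in range(K):
            if n[k] == 0:
                continue
            s = math.log(n[k]) + _score_nb(x, float(n[k]), s1[k], s2[k], m0, kappa0, a0, b0)
            if s > best_s:
                best_s = s
                best_k = k
        new_s = log_alpha + _score_nb(x, 0.0, zero, zero, m0, kappa0, a0, b0)
        if idx == 0 or new_s > best_s:
            best_k = K
            K += 1
        n[best_k] += 1
        for d in range(D):
            s1[best_k, d] += x[d]
            s2[best_k, d] += x[d] * x[d]
        assign[i] = best_k

    for _sweep in range(max_sweeps):
        changed = 0
        for idx in range(N):
            i = order[idx]
            x = X[i]
            old = assign[i]
            n[old] -= 1
            for d in range(D):
                s1[old, d] -= x[d]
                s2[old, d] -= x[d] * x[d]
            best_k = -1
            best_s = -1e300
            for k in range(K):
                if n[k] == 0:
                    continue
                s = math.log(n[k]) + _score_nb(x, float(n[k]), s1[k], s2[k], m0, kappa0, a0, b0)
                if s > best_s:
                    best_s = s
                    best_k = k
            new_s = log_alpha + _score_nb(x, 0.0, zero, zero, m0, kappa0, a0, b0)
            if best_k < 0 or new_s > best_s:
                # reuse an emptied slot if one exists, else extend
                slot = -1
                for k in range(K):
                    if n[k] == 0:
                        slot = k
                        break
                if slot < 0:
                    slot = K
                    K += 1
                best_k = slot
                s1[best_k, :] = 0.0
                s2[best_k, :] = 0.0
            n[best_k] += 1
            for d in range(D):
                s1[best_k, d] += x[d]
                s2[best_k, d] += x[d] * x[d]
            if best_k != old:
                changed += 1
            assign[i] = best_k
        if changed == 0:
            break
    return assign


def _nig_posterior(prior: NIGPrior, n, s1, s2):
    """Per-dimension NIG posterior parameters given sufficient statistics."""
    kappa_n = prior.kappa0 + n
    m_n = (prior.kappa0 * prior.m0 + s1) / kappa_n
    a_n = prior.a0 + n / 2.0
    if np.ndim(n) == 0 and n == 0:
        return kappa_n, prior.m0, a_n, prior.b0
    xbar = s1 / np.maximum(n, 1)
    ss = np.maximum(s2 - n * xbar * xbar, 0.0)
    b_n = prior.b0 + 0.5 * ss + prior.kappa0 * n * (xbar - prior.m0) ** 2 / (2 * kappa_n)
    return kappa_n, m_n, a_n, b_n


def _t_logpdf_sum(x, kappa_n, m_n, a_n, b_n):
    """Sum over dimensions of the Student-t posterior-predictive log density:
    df = 2 a_n, loc = m_n, scale^2 = b_n (kappa_n + 1) / (a_n kappa_n)."""
    nu = 2.0 * a_n
    scale2 = b_n * (kappa_n + 1.0) / (a_n * kappa_n)
    z2 = (x - m_n) ** 2 / scale2
    lp = (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi * scale2)
        - (nu + 1.0) / 2.0 * np.log1p(z2 / nu)
    )
    return lp.sum(axis=-1)


def _cluster_log_marginal(prior: NIGPrior, n, s1, s2) -> float:
    """Collapsed per-cluster marginal likelihood log m(X_k) under the NIG."""
    kappa_n, _, a_n, b_n = _nig_posterior(prior, n, s1, s2)
    lm = (
        gammaln(a_n)
        - gammaln(prior.a0)
        + prior.a0 * np.log(prior.b0)
        - a_n * np.log(b_n)
        + 0.5 * (np.log(prior.kappa0) - np.log(kappa_n))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    return float(np.sum(lm))


def collapsed_log_posterior(X, assignments, prior: NIGPrior, alpha: float) -> float:
    """log CRP(z; alpha) + sum_k log m(X_k) (up to constants in N)."""
    n_total = len(X)
    ks = np.unique(assignments)
    total = (
        len(ks) * np.log(alpha)
        + gammaln(alpha)
        - gammaln(alpha + n_total)
    )
    for k in ks:
        rows = X[assignments == k]
        total += gammaln(len(rows))  # log (N_k - 1)!
        total += _cluster_log_marginal(
            prior, len(rows), rows.sum(axis=0), (rows**2).sum(axis=0)
        )
    return float(total)


# ---------------------------------------------------------------------------
# MAP-DP fitting


def fit_mapdp(
    X: np.ndarray,
    prior: NIGPrior,
    alpha: float,
    max_sweeps: int = 30,
    shuffle_seed: int = 0,
    merge_small: bool = True,
) -> DPMFit:
    """Fit a diagonal Gaussian DPM by MAP (iterated conditional modes on the
    collapsed assignments). Deterministic given data, config and the pinned
    shuffle seed; the update order is a fixed seeded permutation because the
    inference is order-dependent. The first pass assigns points sequentially
    (opening clusters as the data demands — an all-in-one start is a poor ICM
    fixed point for well-separated data); subsequent sweeps reassign until a
    fixed point or ``max_sweeps``.
    """
    X = np.ascontiguousarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n_pts = len(X)
    order = np.random.default_rng(shuffle_seed).permutation(n_pts)

    assignments = _mapdp_kernel(
        X,
        order,
        prior.m0,
        float(prior.kappa0),
        float(prior.a0),
        prior.b0,
        float(alpha),
        int(max_sweeps),
    )
    assignments = _relabel(assignments)
    if merge_small:
        assignments = _merge_small(X, assignments)

    means, variances, counts = [], [], []
    for k in range(assignments.max() + 1):
        rows = X[assignments == k]
        _, m_n, a_n, b_n = _nig_posterior(
            prior, len(rows), rows.sum(axis=0), (rows**2).sum(axis=0)
        )
        means.append(m_n)
        # MAP of the NIG variance (inverse-Gamma mode with the Gaussian
        # exponent): b_n / (a_n + 3/2)
        variances.append(np.maximum(b_n / (a_n + 1.5), _VAR_FLOOR))
        counts.append(len(rows))
    means = np.stack(means)
    variances = np.stack(variances)
    counts = np.asarray(counts)
    ll = complete_data_log_likelihood(X, assignments, means, variances, counts)
    return DPMFit(
        assignments=assignments,
        means=means,
        variances=variances,
        counts=counts,
        alpha=alpha,
        log_likelihood=ll,
    )


def _relabel(assignments: np.ndarray) -> np.ndarray:
    uniq, inv = np.unique(assignments, return_inverse=True)
    return inv.astype(np.int64)


def _merge_small(X: np.ndarray, assignments: np.ndarray) -> np.ndarray:
    """Merge components below MIN_COMPONENT_SIZE into the nearest larger
    component (Euclidean distance between cluster means); avoids singular
    scales in the downstream Mahalanobis metric."""
    assignments = assignments.copy()
    while len(np.unique(assignments)) > 1:
        labels, counts = np.unique(assignments, return_counts=True)
        small = labels[counts < MIN_COMPONENT_SIZE]
        if len(small) == 0:
            break
        k = small[np.argmin(counts[np.isin(labels, small)])]
        means = np.stack([X[assignments == l].mean(axis=0) for l in labels])
        ki = int(np.where(labels == k)[0][0])
        dist = np.linalg.norm(means - means[ki], axis=1)
        dist[ki] = np.inf
        target = labels[int(np.argmin(dist))]
        assignments[assignments == k] = target
        assignments = _relabel(assignments)
    return assignments


def complete_data_log_likelihood(X, assignments, means, variances, counts) -> float:
    """Sum_n log N(x_n | mu_zn, Sigma_zn) + sum_k N_k log(N_k / N): the
    complete-data log-likelihood of the converged fit, used for model
    selection over the hyperparameter grid."""
    total = 0.0
    n_all = len(X)
    for k in range(len(counts)):
        rows = X[assignments == k]
        if len(rows) == 0:
            continue
        var = variances[k]
        ll = -0.5 * ((rows - means[k]) ** 2 / var + np.log(2 * np.pi * var)).sum()
        total += ll + counts[k] * np.log(counts[k] / n_all)
    return float(total)


def default_grid(
    X: np.ndarray, var_floor: np.ndarray | float | None = None
) -> list[tuple[NIGPrior, float]]:
    """Small default hyperparameter grid: alpha in {0.1, 1, 10}, b0 in
    {0.1, 1, 10} x pooled per-dimension variance, m0 = pooled mean,
    kappa0 = 0.01, a0 = 1.

    ``var_floor`` (e.g. a fraction of the global data variance) keeps the
    prior scale sensible for tiny or degenerate groups, where the group's
    own pooled variance collapses to ~0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m0 = X.mean(axis=0)
    floor = _VAR_FLOOR if var_floor is None else np.maximum(var_floor, _VAR_FLOOR)
    pooled = np.maximum(X.var(axis=0), floor)
    grid = []
    for alpha in (0.1, 1.0, 10.0):
        for factor in (0.1, 1.0, 10.0):
            grid.append(
                (NIGPrior(m0=m0, kappa0=0.01, a0=1.0, b0=factor * pooled), alpha)
            )
    return grid


def select_hyperparameters(
    X: np.ndarray,
    grid: list[tuple[NIGPrior, float]] | None = None,
    shuffle_seed: int = 0,
) -> tuple[NIGPrior, float, DPMFit]:
    """Unsupervised model selection: fit every grid point and keep the one
    maximising the complete-data log-likelihood; ties break toward the
    smallest alpha."""
    if grid is None:
        grid = default_grid(X)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    best = None
    for prior, alpha in grid:
        fit = fit_mapdp(X, prior, alpha, shuffle_seed=shuffle_seed)
        key = (fit.log_likelihood, -alpha)
        if best is None or key > best[0]:
            best = (key, prior, alpha, fit)
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# basis construction


def build_basis_set(
    table,
    grid: list[tuple[NIGPrior, float]] | None = None,
    max_rows_per_subclass: int = 400,
    shuffle_seed: int = 0,
) -> BasisSet:
    """Build the prototype basis set from a labelled feature table.

    For tremor sub-classes only prototype-flagged windows are used; for
    non-tremor sub-classes all labelled windows of the sub-class are used.
    Each sub-class with data is summarised by a MAP-DP fit (hyperparameters
    selected per sub-class by complete-data likelihood); each mixture
    component becomes one basis. Sub-classes without rows are skipped with a
    logged warning. ``max_rows_per_subclass`` caps the rows entering a DPM
    fit via a seeded subsample (numerical-scale choice, not a study
    condition).
    """
    frame = table.frame
    from .features import FEATURE_NAMES

    groups: list[tuple[str, str, np.ndarray]] = []
    for sub in TREMOR_SUBCLASSES:
        mask = (
            (frame["label"] == "tremor")
            & (frame["sub_class"] == sub)
            & frame["prototype"]
        )
        groups.append((sub, "tremor", frame.loc[mask, list(FEATURE_NAMES)].to_numpy()))
    for sub in NONTREMOR_SUBCLASSES:
        mask = (frame["label"] == "non_tremor") & (frame["sub_class"] == sub)
        groups.append(
            (sub, "non_tremor", frame.loc[mask, list(FEATURE_NAMES)].to_numpy())
        )

    bases: list[PrototypeBasis] = []
    skipped: list[str] = []
    rng = np.random.default_rng(shuffle_seed)
    # global per-dimension variance anchors the prior scale of tiny groups
    global_var = frame[list(FEATURE_NAMES)].to_numpy(dtype=float).var(axis=0)
    for sub, cls, rows in groups:
        if len(rows) == 0:
            skipped.append(sub)
            logger.warning("sub-class %s has no rows; no bases built for it", sub)
            continue
        if len(rows) > max_rows_per_subclass:
            idx = rng.choice(len(rows), max_rows_per_subclass, replace=False)
            rows = rows[idx]
        sub_grid = grid if grid is not None else default_grid(rows, 0.01 * global_var)
        _, _, fit = select_hyperparameters(rows, grid=sub_grid, shuffle_seed=shuffle_seed)
        for k in range(fit.K):
            bases.append(
                PrototypeBasis(
                    center=fit.means[k],
                    # floored at 2% of the global per-dimension variance so
                    # near-degenerate components keep a usable metric
                    scale=np.maximum(fit.variances[k], 0.02 * global_var),
                    sub_class=sub,
                    class_label=cls,
                    component_id=k,
                )
            )
    if not bases:
        raise ValueError("all sub-classes empty: cannot build a basis set")
    return BasisSet(bases=bases, skipped_sub_classes=skipped)
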