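"""Soft Bayesian additive regression trees with pluggable split-selection priors.

The regression function is a sum of B trees plus a global intercept,
``mu = mu0 + sum_b g(d; T_b, M_b)``.  Decision paths are probabilistic: at an
internal node splitting on variable j at point c the input is routed right
with probability ``psi((d_j - c)/b)`` where ``psi`` is the logistic function
and ``b > 0`` is a per-tree bandwidth, so every leaf receives a weight and
the weights sum to one.  As the bandwidth shrinks the gating converges to
the hard indicator partition of classical BART; ``hard=True`` runs that
limit directly (same code path, indicator gating, no bandwidth updates).

Sampling follows the usual Bayesian backfitting scheme: per tree, a
grow/prune Metropolis-Hastings move on the structure with leaf parameters
integrated out analytically, a random-walk move on the log bandwidth, and a
conjugate draw of the leaf vector; then a conjugate residual-variance draw
(Gaussian case) or a truncated-normal latent refresh (probit case), and an
update of the split-selection probability vector q supplied by the prior
object (uniform / DART / LDART, see :mod:`gfbart.ldart_prior`).

Binary outcomes use the standard probit latent-variable augmentation;
``predict`` then returns event probabilities through the normal CDF.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lapack
from scipy.special import expit, ndtr, ndtri
from scipy.stats import chi2

_dtrtrs = lapack.dtrtrs

from .ldart_prior import UniformSplitPrior

__all__ = [
    "SoftTree",
    "SoftForest",
    "McmcConfig",
    "BartHypers",
    "BartFit",
    "leaf_weights",
    "predict",
    "split_counts",
    "fit_gaussian",
    "fit_probit",
]


@dataclass(frozen=True)
class McmcConfig:
    """MCMC settings; defaults follow the reference simulation protocol
    (1200 warm-up, 2000 saved draws, thinning 4)."""

    n_warmup: int = 1200
    n_save: int = 2000
    thin: int = 4
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_warmup, self.n_save, self.thin, self.n_chains) < 1:
            raise ValueError("all MCMC settings must be positive")


@dataclass(frozen=True)
class BartHypers:
    """Regularization and numerical hyperparameters.

    gamma, beta
        depth prior: split probability gamma*(1+depth)^(-beta).
    k
        leaf shrinkage; leaf sd = 0.5/(k sqrt(B)) on the scaled outcome
        (3/(k sqrt(B)) for probit latents).
    nu, sigma_quantile
        residual-variance prior: scaled-inverse-chi2(nu, lambda) with lambda
        anchored so the prior puts ``sigma_quantile`` mass below the sample SD.
    sigma_lambda
        explicit lambda overriding the data-driven anchor (needed when the
        prior must be fully specified up front, e.g. calibration checks).
    bandwidth_scale
        exponential prior scale for the per-tree gating bandwidth, as a
        fraction of the unit predictor range.
    """

    n_trees: int = 50
    gamma: float = 0.95
    beta: float = 2.0
    max_depth: int = 8
    k: float = 2.0
    nu: float = 3.0
    sigma_quantile: float = 0.9
    sigma_lambda: float | None = None
    bandwidth_scale: float = 0.1
    bandwidth_step: float = 0.6
    hard: bool = False
    scale_y: bool = True
    scale_X: bool = True


class _Node:
    __slots__ = ("feature", "threshold", "left", "right", "leaf_value", "depth")

    def __init__(self, depth: int = 0):
        self.feature: int = -1
        self.threshold: float = 0.0
        self.left: "_Node | None" = None
        self.right: "_Node | None" = None
        self.leaf_value: float = 0.0
        self.depth = depth

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0

    def copy(self) -> "_Node":
        n = _Node(self.depth)
        n.feature, n.threshold, n.leaf_value = self.feature, self.threshold, self.leaf_value
        if not self.is_leaf:
            n.left = self.left.copy()
            n.right = self.right.copy()
        return n


class SoftTree:
    """One soft regression tree (binary structure + per-tree bandwidth)."""

    def __init__(self, bandwidth: float = 0.1, hard: bool = False):
        self.root = _Node(0)
        self.bandwidth = bandwidth
        self.hard = hard

    def copy(self) -> "SoftTree":
        t = SoftTree(self.bandwidth, self.hard)
        t.root = self.root.copy()
        return t

    def leaves(self) -> list[_Node]:
        out: list[_Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.append(nd)
            else:
                stack.append(nd.right)
                stack.append(nd.left)
        return out  # right pushed first, so popping yields left-first DFS order

    def internal_nodes(self) -> list[_Node]:
        out = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            if not nd.is_leaf:
                out.append(nd)
                stack.append(nd.right)
                stack.append(nd.left)
        return out

    def prunable(self) -> list[_Node]:
        return [
            nd for nd in self.internal_nodes()
            if nd.left.is_leaf and nd.right.is_leaf
        ]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaf_values(self) -> np.ndarray:
        return np.array([lf.leaf_value for lf in self.leaves()])

    def set_leaf_values(self, vals: np.ndarray) -> None:
        for lf, v in zip(self.leaves(), vals, strict=True):
            lf.leaf_value = float(v)


def _gate(x: np.ndarray, c: float, b: float, hard: bool) -> np.ndarray:
    """Probability of routing right at a split (x > c side)."""
    if hard or b <= 0:
        return (x > c).astype(float)
    u = np.clip((x - c) / b, -35.0, 35.0)
    return 1.0 / (1.0 + np.exp(-u))


def leaf_weights(tree: SoftTree, d: np.ndarray) -> np.ndarray:
    """Leaf-weight vector (or n x L matrix) for input(s) ``d``.

    Weights are products of gating probabilities along each root-to-leaf
    path; they are nonnegative and sum to one for every input.
    """
    arr = np.asarray(d, dtype=float)
    Phi = _phi_matrix(tree, np.atleast_2d(arr))
    return Phi[0] if arr.ndim == 1 else Phi


def _phi_matrix(tree: SoftTree, X: np.ndarray) -> np.ndarray:
    """n x L matrix of leaf weights, leaves in DFS (left-first) order."""
    n = X.shape[0]
    cols: list[np.ndarray] = []

    def rec(nd: _Node, w: np.ndarray) -> None:
        if nd.is_leaf:
            cols.append(w)
            return
        g = _gate(X[:, nd.feature], nd.threshold, tree.bandwidth, tree.hard)
        rec(nd.left, w * (1.0 - g))
        rec(nd.right, w * g)

    rec(tree.root, np.ones(n))
    return np.column_stack(cols)


def _tree_predict(tree: SoftTree, X: np.ndarray) -> np.ndarray:
    return _phi_matrix(tree, X) @ tree.leaf_values()


@dataclass
class SoftForest:
    """A posterior draw of the ensemble: trees, global intercept and scale
    transforms, residual sd (Gaussian case) and the split-probability
    vector in force when the draw was taken."""

    trees: list[SoftTree]
    mu0: float
    sigma: float
    y_offset: float = 0.0
    y_scale: float = 1.0
    x_lo: np.ndarray | None = None
    x_rng: np.ndarray | None = None
    probit: bool = False
    q: np.ndarray | None = None

    @property
    def B(self) -> int:
        return len(self.trees)

    def _scale_X(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.x_lo is None:
            return X
        return np.clip((X - self.x_lo) / self.x_rng, 0.0, 1.0)

    def latent(self, X: np.ndarray) -> np.ndarray:
        Xs = self._scale_X(X)
        out = np.full(Xs.shape[0], self.mu0)
        for tr in self.trees:
            out += _tree_predict(tr, Xs)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Posterior-mean surface at X: outcome scale, or event probability
        through the normal CDF for probit fits."""
        z = self.latent(X)
        if self.probit:
            return ndtr(z)
        return z * self.y_scale + self.y_offset

    def to_json(self) -> str:
        def dump(nd: _Node):
            if nd.is_leaf:
                return {"leaf": nd.leaf_value}
            return {
                "var": nd.feature, "point": nd.threshold,
                "left": dump(nd.left), "right": dump(nd.right),
            }

        return json.dumps({
            "mu0": self.mu0, "sigma": self.sigma,
            "y_offset": self.y_offset, "y_scale": self.y_scale,
            "probit": self.probit,
            "x_lo": None if self.x_lo is None else self.x_lo.tolist(),
            "x_rng": None if self.x_rng is None else self.x_rng.tolist(),
            "trees": [
                {"bandwidth": t.bandwidth, "hard": t.hard, "root": dump(t.root)}
                for t in self.trees
            ],
        })

    @classmethod
    def from_json(cls, s: str) -> "SoftForest":
        obj = json.loads(s)

        def load(d, depth=0) -> _Node:
            nd = _Node(depth)
            if "leaf" in d:
                nd.leaf_value = d["leaf"]
                return nd
            nd.feature, nd.threshold = d["var"], d["point"]
            nd.left = load(d["left"], depth + 1)
            nd.right = load(d["right"], depth + 1)
            return nd

        trees = []
        for td in obj["trees"]:
            t = SoftTree(td["bandwidth"], td["hard"])
            t.root = load(td["root"])
            trees.append(t)
        return cls(
            trees, obj["mu0"], obj["sigma"], obj["y_offset"], obj["y_scale"],
            None if obj["x_lo"] is None else np.array(obj["x_lo"]),
            None if obj["x_rng"] is None else np.array(obj["x_rng"]),
            obj["probit"],
        )


def predict(forest: SoftForest, d: np.ndarray) -> np.ndarray | float:
    """mu0 plus the sum of leaf-weighted tree contributions at ``d``."""
    out = forest.predict(np.atleast_2d(d))
    return float(out[0]) if np.asarray(d).ndim == 1 else out


def split_counts(forest_or_trees, P: int | None = None) -> np.ndarray:
    """Number of internal nodes splitting on each predictor."""
    trees = forest_or_trees.trees if isinstance(forest_or_trees, SoftForest) else forest_or_trees
    feats: list[int] = []
    for t in trees:
        feats.extend(nd.feature for nd in t.internal_nodes())
    if P is None:
        P = (max(feats) + 1) if feats else 1
    counts = np.zeros(P, dtype=int)
    for f in feats:
        counts[f] += 1
    return counts


# ---------------------------------------------------------------------------
# Sampler internals
# ---------------------------------------------------------------------------

def _log_marginal_score(Phi, R, sigma2, sigma_mu2):
    """log N(R; 0, sigma2 I + sigma_mu2 Phi Phi') dropping terms constant in
    Phi; returns (score, aux) with aux = (cho, w) for M = Phi'Phi +
    (sigma2/sigma_mu2) I = C C', w = C^{-1} Phi'R, reused by the leaf draw."""
    L = Phi.shape[1]
    c = sigma2 / sigma_mu2
    PtR = Phi.T @ R
    if L == 1:
        m = float(Phi[:, 0] @ Phi[:, 0]) + c
        w = float(PtR[0]) / math.sqrt(m)
        logdet_A = math.log(sigma_mu2 / sigma2) + math.log(m)
        return (
            -0.5 * logdet_A + w * w / (2.0 * sigma2),
            (math.sqrt(m), np.array([w])),
        )
    M = Phi.T @ Phi
    M.flat[:: L + 1] += c
    cho = np.linalg.cholesky(M)
    w, _ = _dtrtrs(cho, PtR, lower=1)
    logdet_A = L * math.log(sigma_mu2 / sigma2) + 2.0 * np.log(
        cho.diagonal()
    ).sum()
    return -0.5 * logdet_A + (w @ w) / (2.0 * sigma2), (cho, w)


def _draw_leaves(aux, sigma2, rng):
    cho, w = aux
    z = w + math.sqrt(sigma2) * rng.standard_normal(len(w))
    if len(w) == 1:
        return z / cho
    # mean + noise = C'^{-1} (w + sqrt(sigma2) z0): cov = sigma2 M^{-1}
    out, _ = _dtrtrs(cho, z, lower=1, trans=1)
    return out


def _p_split(depth: int, hy: BartHypers) -> float:
    if depth >= hy.max_depth:
        return 0.0
    return hy.gamma * (1.0 + depth) ** (-hy.beta)


def _grow_phi(Phi: np.ndarray, idx: int, g: np.ndarray) -> np.ndarray:
    col = Phi[:, idx]
    return np.column_stack([Phi[:, :idx], col * (1.0 - g), col * g, Phi[:, idx + 1:]])


def _prune_phi(Phi: np.ndarray, idx: int) -> np.ndarray:
    merged = Phi[:, idx] + Phi[:, idx + 1]
    return np.column_stack([Phi[:, :idx], merged, Phi[:, idx + 2:]])


def _structure_move(tree, Phi, score_old, aux_old, R, sigma2, sigma_mu2, q, X, hy, rng):
    """One grow/prune MH step with leaves integrated out.

    Returns (Phi, score, aux) for the (possibly unchanged) tree."""
    cur = (Phi, score_old, aux_old)
    leaves = tree.leaves()
    L = len(leaves)
    is_stump = L == 1
    p_grow = 1.0 if is_stump else 0.5
    if rng.uniform() < p_grow:  # GROW
        idx = int(rng.integers(L))
        nd = leaves[idx]
        ps = _p_split(nd.depth, hy)
        if ps <= 0.0:
            return cur
        j = min(int(np.searchsorted(q, rng.uniform())), len(q) - 1)
        c = float(rng.uniform())
        g = _gate(X[:, j], c, tree.bandwidth, tree.hard)
        Phi_new = _grow_phi(Phi, idx, g)
        score_new, aux_new = _log_marginal_score(Phi_new, R, sigma2, sigma_mu2)
        # count of prunable nodes after the grow
        n_prun_new = len(tree.prunable()) + 1 - sum(
            1 for p in tree.prunable() if nd in (p.left, p.right)
        )
        log_prior = (
            math.log(ps)
            + 2.0 * math.log(1.0 - _p_split(nd.depth + 1, hy))
            - math.log(1.0 - ps)
        )
        log_prop = (math.log(0.5) - math.log(n_prun_new)) - (
            math.log(p_grow) - math.log(L)
        )
        if math.log(rng.uniform()) < score_new - score_old + log_prior + log_prop:
            nd.feature, nd.threshold = j, c
            nd.left, nd.right = _Node(nd.depth + 1), _Node(nd.depth + 1)
            return Phi_new, score_new, aux_new
        return cur
    # PRUNE
    prunable = tree.prunable()
    if not prunable:
        return cur
    pick = int(rng.integers(len(prunable)))
    nd = prunable[pick]
    # position of nd.left among leaves in DFS order
    idx = leaves.index(nd.left)
    Phi_new = _prune_phi(Phi, idx)
    score_new, aux_new = _log_marginal_score(Phi_new, R, sigma2, sigma_mu2)
    ps = _p_split(nd.depth, hy)
    log_prior = -(
        math.log(ps)
        + 2.0 * math.log(1.0 - _p_split(nd.depth + 1, hy))
        - math.log(1.0 - ps)
    )
    p_grow_new = 1.0 if L - 1 == 1 else 0.5
    log_prop = (math.log(p_grow_new) - math.log(L - 1)) - (
        math.log(0.5) - math.log(len(prunable))
    )
    if math.log(rng.uniform()) < score_new - score_old + log_prior + log_prop:
        nd.feature = -1
        nd.left = nd.right = None
        return Phi_new, score_new, aux_new
    return cur


def _bandwidth_move(tree, Phi, score_old, aux_old, R, sigma2, sigma_mu2, X, hy, rng):
    if tree.hard or tree.root.is_leaf:
        return Phi, score_old, aux_old
    b_old = tree.bandwidth
    b_new = float(b_old * math.exp(hy.bandwidth_step * rng.standard_normal()))
    tree.bandwidth = b_new
    Phi_new = _phi_matrix(tree, X)
    score_new, aux_new = _log_marginal_score(Phi_new, R, sigma2, sigma_mu2)
    # Exp(scale) prior on b, log-normal RW proposal (Jacobian b_new/b_old)
    log_acc = (
        score_new - score_old
        - (b_new - b_old) / hy.bandwidth_scale
        + math.log(b_new / b_old)
    )
    if math.log(rng.uniform()) < log_acc:
        return Phi_new, score_new, aux_new
    tree.bandwidth = b_old
    return Phi, score_old, aux_old


def _sample_truncnorm(mean: np.ndarray, positive: np.ndarray, rng) -> np.ndarray:
    """z ~ N(mean, 1) truncated to z > 0 where positive, z <= 0 elsewhere."""
    u = rng.uniform(size=len(mean))
    a = np.clip(ndtr(-mean), 1e-12, 1 - 1e-12)  # P(z <= 0)
    q = np.where(positive, a + u * (1.0 - a), u * a)
    return mean + ndtri(np.clip(q, 1e-12, 1 - 1e-12))


@dataclass
class BartFit:
    """Posterior draws of the ensemble plus the prior object's trajectory."""

    forests: list[SoftForest]
    sigma_draws: np.ndarray
    split_count_draws: np.ndarray  # n_draws x P
    hypers: BartHypers
    config: McmcConfig

    @property
    def n_draws(self) -> int:
        return len(self.forests)

    def predict(self, X: np.ndarray, draws=None) -> np.ndarray:
        """(n_draws, n) posterior surface (probabilities for probit fits)."""
        idx = range(self.n_draws) if draws is None else draws
        return np.vstack([self.forests[i].predict(X) for i in idx])

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        return self.predict(X).mean(axis=0)


def _prepare_X(X: np.ndarray, hy: BartHypers):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not hy.scale_X:
        return X, None, None
    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    rng_[rng_ == 0] = 1.0
    return (X - lo) / rng_, lo, rng_


def _constant_fit(X, y, cfg, hy, probit: bool) -> BartFit:
    warnings.warn("degenerate outcome: returning a constant forest")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = ndtri(np.clip(np.mean(y), 1e-6, 1 - 1e-6)) if probit else float(np.mean(y))
    f = SoftForest([], mu0=mu, sigma=0.0, probit=probit)
    n_total = cfg.n_save * cfg.n_chains
    return BartFit(
        [f] * n_total, np.zeros(n_total),
        np.zeros((n_total, X.shape[1]), dtype=int), hy, cfg,
    )


def _run_chain(Xs, y_int, prior, cfg, hy, rng, probit, sigma_lambda, sigma_mu, mu0=0.0):
    n, P = Xs.shape
    B = hy.n_trees
    trees = [SoftTree(hy.bandwidth_scale, hy.hard) for _ in range(B)]
    Phis = [np.ones((n, 1)) for _ in range(B)]
    tree_pred = np.zeros((B, n))
    total_pred = np.zeros(n)
    sigma2 = 1.0 if probit else float(max(np.var(y_int), 1e-8))
    nu = hy.nu
    y_work = y_int.copy()
    n_iter = cfg.n_warmup + cfg.n_save * cfg.thin
    forests: list[SoftForest] = []
    sig_draws: list[float] = []
    count_draws: list[np.ndarray] = []
    for it in range(n_iter):
        if probit:
            # latent z ~ N(mu0 + forest, 1); trees model z - mu0
            y_work = _sample_truncnorm(mu0 + total_pred, y_int > 0.5, rng) - mu0
        q = np.cumsum(prior.q)
        q /= q[-1]  # passed to the move as a cumulative distribution
        sm2 = sigma_mu ** 2
        for b in range(B):
            R = y_work - total_pred + tree_pred[b]
            score, aux = _log_marginal_score(Phis[b], R, sigma2, sm2)
            Phi, score, aux = _structure_move(
                trees[b], Phis[b], score, aux, R, sigma2, sm2, q, Xs, hy, rng
            )
            Phi, score, aux = _bandwidth_move(
                trees[b], Phi, score, aux, R, sigma2, sm2, Xs, hy, rng
            )
            leaf = _draw_leaves(aux, sigma2, rng)
            trees[b].set_leaf_values(leaf)
            Phis[b] = Phi
            new_pred = Phi @ leaf
            total_pred += new_pred - tree_pred[b]
            tree_pred[b] = new_pred
        if not probit:
            rss = float(((y_work - total_pred) ** 2).sum())
            sigma2 = (nu * sigma_lambda + rss) / rng.chisquare(nu + n)
        counts = split_counts(trees, P)
        prior.update(counts, rng)
        if it >= cfg.n_warmup and (it - cfg.n_warmup) % cfg.thin == cfg.thin - 1:
            forests.append(
                SoftForest(
                    [t.copy() for t in trees], mu0=0.0,
                    sigma=math.sqrt(sigma2), probit=probit,
                    q=prior.q.copy(),
                )
            )
            sig_draws.append(math.sqrt(sigma2))
            count_draws.append(counts.copy())
    return forests, np.array(sig_draws), np.array(count_draws)


def _fit(X, y, q_source, cfg, hy, probit):
    import copy as _copy

    cfg = cfg or McmcConfig()
    hy = hy or BartHypers()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    if X.shape[0] < 2:
        raise ValueError("need n >= 2")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing entries: caller must handle missingness")
    if probit:
        if not np.isin(y, (0, 1)).all():
            raise ValueError("probit outcome must be 0/1")
        if len(np.unique(y)) < 2:
            return _constant_fit(X, y, cfg, hy, probit=True)
    elif np.ptp(y) == 0:
        return _constant_fit(X, y, cfg, hy, probit=False)

    Xs, x_lo, x_rng = _prepare_X(X, hy)
    P = Xs.shape[1]
    if probit:
        y_offset, y_scale = 0.0, 1.0
        mu0 = float(ndtri(np.clip(y.mean(), 1e-6, 1 - 1e-6)))
        y_int = y.copy()
        sigma_mu = 3.0 / (hy.k * math.sqrt(hy.n_trees))
        sigma_lambda = 1.0
    else:
        if hy.scale_y:
            y_offset = float((y.min() + y.max()) / 2.0)
            y_scale = float(y.max() - y.min())
        else:
            y_offset, y_scale = 0.0, 1.0
        mu0 = 0.0
        y_int = (y - y_offset) / y_scale
        sigma_mu = 0.5 / (hy.k * math.sqrt(hy.n_trees))
        if hy.sigma_lambda is not None:
            sigma_lambda = hy.sigma_lambda
        else:
            s2 = float(np.var(y_int, ddof=1))
            sigma_lambda = s2 * chi2.ppf(1.0 - hy.sigma_quantile, hy.nu) / hy.nu

    if q_source is None:
        q_source = UniformSplitPrior(P)
    forests: list[SoftForest] = []
    sig_all, cnt_all = [], []
    for chain in range(cfg.n_chains):
        rng = np.random.default_rng(cfg.seed + chain)
        prior = _copy.deepcopy(q_source)
        f, s, c = _run_chain(
            Xs, y_int, prior, cfg, hy, rng,
            probit, sigma_lambda, sigma_mu, mu0=mu0,
        )
        forests.extend(f)
        sig_all.append(s)
        cnt_all.append(c)
    offset = mu0
    for f in forests:
        f.mu0 = offset
        f.y_offset, f.y_scale = y_offset, y_scale
        f.x_lo, f.x_rng = x_lo, x_rng
        f.sigma = f.sigma * y_scale
    return BartFit(
        forests, np.concatenate(sig_all) * y_scale,
        np.concatenate(cnt_all), hy, cfg,
    )


def fit_gaussian(X, y, q_source=None, cfg: McmcConfig | None = None,
                 hypers: BartHypers | None = None) -> BartFit:
    """Fit a Gaussian soft BART model; returns pooled posterior draws.

    ``q_source`` is a split-prior object (uniform if None); it is deep-copied
    per chain so chains are independent.  Identical configs and seeds give
    identical draws.
    """
    return _fit(X, y, q_source, cfg, hypers, probit=False)


def fit_probit(X, z, q_source=None, cfg: McmcConfig | None = None,
               hypers: BartHypers | None = None) -> BartFit:
    """Fit a probit soft BART model for a 0/1 outcome via latent-variable
    augmentation; ``predict`` returns event probabilities."""
    return _fit(X, z, q_source, cfg, hypers, probit=True)
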