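"""Sparsity-inducing Dirichlet priors on split-variable selection.

Three priors supply the probability vector ``q`` from which the tree sampler
draws split variables:

* :class:`UniformSplitPrior` — fixed uniform ``q`` (plain BART).
* :class:`DartPrior` — exchangeable sparse Dirichlet, ``q ~ Dir(α/P, …, α/P)``
  with ``α/(α+ρ) ~ Beta(a, b)`` learned from split counts (DART).
* :class:`LdartPrior` — the longitudinal grouped Dirichlet prior (LDART):
  predictors are partitioned into the *current*-wave group (baseline
  predictors included) and one group per past wave.  A Beta-distributed
  weight ``w`` splits mass between current and past; within the current
  group ``v^t ~ Dir(η/P_t)``; across past waves ``u ~ Dir(α_1/(t−1), …,
  α_{t−1}/(t−1))`` with the concentration hyperpriors ordered in time so
  that temporally distant waves get a priori sparser selection; within past
  wave ``k``, ``v^k ~ Dir(φ^k/P_k)``.  The selection probability of the jth
  current predictor is ``w·v^t_j`` and of the jth predictor of past wave k
  is ``(1−w)·u^k·v^k_j``.

All concentration parameters are updated by Gibbs steps on a discretized
grid of the transformed scale ``α/(α+ρ) ∈ (0,1)``, which targets the exact
full conditional without step-size tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "LongitudinalGrouping",
    "LdartState",
    "c_schedule",
    "selection_prob",
    "update_state",
    "dart_prior",
    "UniformSplitPrior",
    "DartPrior",
    "LdartPrior",
]

_EPS = 1e-12
_GRID = 64


def c_schedule(t: int) -> np.ndarray:
    """Beta-hyperprior shape c_j = 1 − 0.5·(t−j)/(t−1) for past waves j=1..t−1.

    c_1 = 0.5 always, increasing toward (but below) 1 for waves closer to the
    current one, so earlier waves receive stochastically smaller concentration
    α_j and hence more sparsity.
    """
    if t < 2:
        return np.empty(0)
    j = np.arange(1, t)
    return 1.0 - 0.5 * (t - j) / (t - 1)


@dataclass(frozen=True)
class LongitudinalGrouping:
    """Partition of the P predictors by measurement wave.

    ``current`` holds indices of wave-``t`` predictors *and* baseline
    predictors; ``past[k-1]`` holds the indices measured at wave k < t.
    """

    t: int
    current: np.ndarray
    past: tuple[np.ndarray, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "current", np.asarray(self.current, dtype=int))
        object.__setattr__(
            self, "past", tuple(np.asarray(g, dtype=int) for g in self.past)
        )
        if len(self.past) != max(self.t - 1, 0):
            raise ValueError("need one past group per wave 1..t-1")
        all_idx = np.concatenate([self.current, *self.past]) if self.past else self.current
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("groups must be disjoint")

    @property
    def P(self) -> int:
        return len(self.current) + sum(len(g) for g in self.past)


@dataclass
class LdartState:
    """Current values of the hierarchy (w, v^t, u, v^k) and concentrations."""

    grouping: LongitudinalGrouping
    w: float
    v_t: np.ndarray
    u: np.ndarray
    v_k: list[np.ndarray]
    eta: float
    phi_k: np.ndarray
    alpha: np.ndarray
    w_ab: tuple[float, float] = (1.0, 1.0)
    c_j: np.ndarray = field(default=None)  # type: ignore[assignment]
    rho_j: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = self.grouping.t
        if self.c_j is None:
            self.c_j = c_schedule(t)
        if self.rho_j is None:
            self.rho_j = np.full(max(t - 1, 0), float(t))


def _init_state(grouping: LongitudinalGrouping, w_ab=(1.0, 1.0)) -> LdartState:
    t = grouping.t
    n_past = max(t - 1, 0)
    P_t = len(grouping.current)
    return LdartState(
        grouping=grouping,
        w=1.0 if n_past == 0 else w_ab[0] / (w_ab[0] + w_ab[1]),
        v_t=np.full(P_t, 1.0 / P_t),
        u=np.full(n_past, 1.0 / n_past) if n_past else np.empty(0),
        v_k=[np.full(len(g), 1.0 / len(g)) if len(g) else np.empty(0)
             for g in grouping.past],
        eta=float(P_t),
        phi_k=np.array([float(len(g)) for g in grouping.past]),
        alpha=np.full(n_past, float(t)),
        w_ab=w_ab,
    )


def selection_prob(state: LdartState, grouping: LongitudinalGrouping | None = None) -> np.ndarray:
    """Assemble the length-P split-probability vector from the hierarchy."""
    g = grouping if grouping is not None else state.grouping
    if len(state.v_t) != len(g.current) or len(state.v_k) != len(g.past):
        raise ValueError("state and grouping sizes are inconsistent")
    q = np.empty(g.P)
    if not g.past:
        q[g.current] = state.v_t
        return q
    q[g.current] = state.w * state.v_t
    for k, idx in enumerate(g.past):
        q[idx] = (1.0 - state.w) * state.u[k] * state.v_k[k]
    return q


def _safe_dirichlet(conc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if len(conc) == 0:
        return np.empty(0)
    if len(conc) == 1:
        return np.ones(1)
    draw = rng.dirichlet(np.maximum(conc, _EPS))
    draw = np.maximum(draw, _EPS)
    return draw / draw.sum()


def _sym_dirichlet_loglik(alpha_grid: np.ndarray, logv_sum: float, K: int) -> np.ndarray:
    """log Dir(v | α/K,…,α/K) as a function of α (terms constant in α kept)."""
    a = alpha_grid / K
    return gammaln(alpha_grid) - K * gammaln(a) + (a - 1.0) * logv_sum


def _grid_sample_concentration(
    loglik, rho: float, a: float, b: float, rng: np.random.Generator
) -> float:
    """Gibbs draw of a concentration α with prior α/(α+ρ) ~ Beta(a, b),
    discretized on a regular grid of the (0,1) transformed scale."""
    psi = (np.arange(_GRID) + 0.5) / _GRID
    alpha = rho * psi / (1.0 - psi)
    logp = (a - 1.0) * np.log(psi) + (b - 1.0) * np.log1p(-psi) + loglik(alpha)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return float(alpha[rng.choice(_GRID, p=p)])


def update_state(
    state: LdartState,
    counts: np.ndarray,
    grouping: LongitudinalGrouping | None = None,
    rng: np.random.Generator | int = 0,
) -> LdartState:
    """One Gibbs sweep of the LDART hierarchy given per-predictor split counts.

    The (w, v, u) layers are conjugate (Beta / Dirichlet); the concentrations
    (η, φ^k, α_j) are drawn from their discretized full conditionals.  With
    all-zero counts this is a draw from the prior.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    g = grouping if grouping is not None else state.grouping
    counts = np.asarray(counts, dtype=float)
    if counts.min(initial=0.0) < 0:
        raise ValueError("negative split counts")
    if len(counts) != g.P:
        raise ValueError("counts length must equal number of predictors")
    t = g.t
    P_t = len(g.current)
    cur_counts = counts[g.current]
    n_cur = cur_counts.sum()

    if not g.past:
        v_t = _safe_dirichlet(state.eta / P_t + cur_counts, rng)
        eta = _grid_sample_concentration(
            lambda al: _sym_dirichlet_loglik(al, np.log(v_t).sum(), P_t),
            rho=float(P_t), a=0.5, b=1.0, rng=rng,
        )
        return LdartState(g, 1.0, v_t, np.empty(0), [], eta, np.empty(0),
                          np.empty(0), state.w_ab, state.c_j, state.rho_j)

    past_counts = [counts[idx] for idx in g.past]
    m_k = np.array([pc.sum() for pc in past_counts])
    a_w, b_w = state.w_ab
    w = float(rng.beta(a_w + n_cur, b_w + m_k.sum()))
    v_t = _safe_dirichlet(state.eta / P_t + cur_counts, rng)
    v_k = [
        _safe_dirichlet(
            (state.phi_k[k] / max(len(g.past[k]), 1)) + past_counts[k], rng
        )
        for k in range(t - 1)
    ]
    u = _safe_dirichlet(state.alpha / (t - 1) + m_k, rng)

    eta = _grid_sample_concentration(
        lambda al: _sym_dirichlet_loglik(al, np.log(v_t).sum(), P_t),
        rho=float(P_t), a=0.5, b=1.0, rng=rng,
    )
    phi_k = np.array([
        _grid_sample_concentration(
            lambda al, k=k: _sym_dirichlet_loglik(
                al, np.log(v_k[k]).sum(), len(g.past[k])
            ),
            rho=float(len(g.past[k])), a=0.5, b=1.0, rng=rng,
        ) if len(g.past[k]) > 0 else state.phi_k[k]
        for k in range(t - 1)
    ])
    # u has a *general* Dirichlet prior Dir(α_1/(t−1), …, α_{t−1}/(t−1));
    # update each α_j given the others on the grid.
    alpha = state.alpha.copy()
    logu = np.log(u)
    K = t - 1
    for j in range(K):
        rest = alpha.sum() - alpha[j]

        def _ll(al, j=j, rest=rest):
            return (
                gammaln((al + rest) / K)
                - gammaln(al / K)
                + (al / K) * logu[j]
            )

        alpha[j] = _grid_sample_concentration(
            _ll, rho=float(state.rho_j[j]), a=float(state.c_j[j]), b=1.0, rng=rng
        )
    return LdartState(g, w, v_t, u, v_k, eta, phi_k, alpha,
                      state.w_ab, state.c_j, state.rho_j)


# ---------------------------------------------------------------------------
# Sampler-facing prior objects
# ---------------------------------------------------------------------------

class UniformSplitPrior:
    """Fixed uniform split probabilities (plain BART)."""

    def __init__(self, P: int):
        self.P = P
        self.q = np.full(P, 1.0 / P)

    def update(self, counts: np.ndarray, rng: np.random.Generator) -> None:
        pass


class DartPrior:
    """Exchangeable Dirichlet sparsity prior with learned concentration.

    q ~ Dir(α/P, …, α/P);  α/(α+ρ) ~ Beta(a, b);  defaults a=0.5, b=1, ρ=P.
    """

    def __init__(self, P: int, a: float = 0.5, b: float = 1.0, rho: float | None = None):
        self.P = P
        self.a, self.b = a, b
        self.rho = float(P) if rho is None else rho
        self.alpha = self.rho  # transformed-scale prior mean ψ ~ 1/2
        self.q = np.full(P, 1.0 / P)

    def update(self, counts: np.ndarray, rng: np.random.Generator) -> None:
        counts = np.asarray(counts, dtype=float)
        if self.P == 1:
            self.q = np.ones(1)
            return
        self.q = _safe_dirichlet(self.alpha / self.P + counts, rng)
        self.alpha = _grid_sample_concentration(
            lambda al: _sym_dirichlet_loglik(al, np.log(self.q).sum(), self.P),
            rho=self.rho, a=self.a, b=self.b, rng=rng,
        )


def dart_prior(P: int, a: float = 0.5, b: float = 1.0, rho: float | None = None) -> DartPrior:
    """Construct the plain (non-longitudinal) DART prior over P predictors."""
    if P < 1:
        raise ValueError("P must be >= 1")
    return DartPrior(P, a=a, b=b, rho=rho)


class LdartPrior:
    """Sampler-facing wrapper holding and updating an :class:`LdartState`."""

    def __init__(self, grouping: LongitudinalGrouping, w_ab=(1.0, 1.0)):
        self.grouping = grouping
        self.state = _init_state(grouping, w_ab)
        self.q = selection_prob(self.state)

    def update(self, counts: np.ndarray, rng: np.random.Generator) -> None:
        self.state = update_state(self.state, counts, self.grouping, rng)
        self.q = selection_prob(self.state)
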