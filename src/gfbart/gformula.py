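"""Sequential-model fitting and Monte-Carlo G-computation.

The observed-data likelihood factorizes wave by wave in the temporal order
S, R, X, A, Y; one regression model is fitted per factor, each on the risk
set its conditional defines (alive, required history observed):

* survival ``s_k``  — probit on (←y_{k−1}, ←a_{k−1}, ←x_{k−1}, ←r_{k−1})
* response ``r_k``  — probit on the same history plus survival at k
* covariates ``x_k`` — one model per component in schema order, each
  conditioning additionally on the earlier components of the same wave
* treatment ``a_k`` — Gaussian on (←y_{k−1}, ←a_{k−1}, ←x_k, ←r_k); under an
  incremental intervention this same model supplies the *natural value of
  treatment*
* outcome ``y_k``  — Gaussian on (←y_{k−1}, ←a_k, ←x_k, ←r_k)

G-computation then simulates N* forward pseudo-trajectories per posterior
draw: baseline covariates are resampled from the empirical baseline rows,
each wave samples survival, response, covariates, the natural treatment
value, the (possibly intervened) treatment, and the outcome.  The survivor
mean E[Y_T | S_T = 1] is Rao-Blackwellized (average of the outcome model's
posterior-mean surface over surviving pseudo-subjects) and the survival
probability ψ uses a one-step Rao-Blackwellization (mean of the final-wave
survival probability among those alive at T−1); both have the same
expectation as their purely sampled counterparts with less Monte-Carlo
noise, and preserve exact null-intervention equivalence under shared seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import CohortTable, RegimeSpec
from .ldart_prior import DartPrior, LdartPrior, LongitudinalGrouping, UniformSplitPrior
from .soft_bart import BartFit, BartHypers, McmcConfig, fit_gaussian, fit_probit

__all__ = [
    "WaveModel",
    "ConstantModel",
    "SequentialModelSet",
    "PseudoCohort",
    "GcompDraw",
    "fit_sequential",
    "apply_intervention",
    "simulate_regime",
    "gcomp_estimates",
]

PRIOR_MODES = ("uniform", "dart", "ldart", "lastwave")


def _col_wave(key: str) -> int:
    """Wave tag of a design column; 0 marks a baseline (time-constant) one."""
    return int(key.split(":")[0][1:])


def _design(state: dict[str, np.ndarray], columns: list[str], rows: np.ndarray) -> np.ndarray:
    return np.column_stack([state[c][rows] for c in columns])


class ConstantModel:
    """Degenerate factor: an empirical constant (probability, or mean + sd)."""

    def __init__(self, kind: str, value: float, sigma: float = 0.0):
        self.kind = kind  # "probit" or "gaussian"
        self.columns: list[str] = []
        self.value = float(value)
        self.sigma0 = float(sigma)

    def mean(self, Xd: np.ndarray, draw: int) -> np.ndarray:
        return np.full(Xd.shape[0], self.value)

    def sigma(self, draw: int) -> float:
        return self.sigma0

    def draw_values(self, Xd: np.ndarray, draw: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "probit":
            return (rng.uniform(size=Xd.shape[0]) < self.value).astype(float)
        return self.value + self.sigma0 * rng.standard_normal(Xd.shape[0])


class WaveModel:
    """One fitted factor of the sequential factorization."""

    def __init__(self, kind: str, fit: BartFit, columns: list[str]):
        self.kind = kind  # "probit" or "gaussian"
        self.fit = fit
        self.columns = columns

    def _forest(self, draw: int):
        return self.fit.forests[draw % self.fit.n_draws]

    def mean(self, Xd: np.ndarray, draw: int) -> np.ndarray:
        """Posterior-draw conditional mean (probability for probit)."""
        return self._forest(draw).predict(Xd)

    def sigma(self, draw: int) -> float:
        return float(self._forest(draw).sigma)

    def draw_values(self, Xd: np.ndarray, draw: int, rng: np.random.Generator) -> np.ndarray:
        m = self.mean(Xd, draw)
        if self.kind == "probit":
            return (rng.uniform(size=len(m)) < m).astype(float)
        return m + self.sigma(draw) * rng.standard_normal(len(m))


@dataclass
class SequentialModelSet:
    """Fitted models for every factor, plus the empirical baseline rows."""

    T: int
    cov_names: tuple[str, ...]
    cov_types: tuple[str, ...]

    @property
    def baseline_names(self) -> tuple[str, ...]:
        return tuple(n for n, t in zip(self.cov_names, self.cov_types)
                     if t == "baseline")

    @property
    def tv_names(self) -> tuple[str, ...]:
        return tuple(n for n, t in zip(self.cov_names, self.cov_types)
                     if t != "baseline")
    has_treatment: bool
    outcome_waves: tuple[int, ...]
    survival: dict[int, object] = field(default_factory=dict)
    response: dict[int, object] = field(default_factory=dict)
    covariate: dict[tuple[int, str], object] = field(default_factory=dict)
    treatment: dict[int, object] = field(default_factory=dict)
    outcome: dict[int, object] = field(default_factory=dict)
    baseline: dict[str, np.ndarray] = field(default_factory=dict)
    n_draws: int = 1

    def baseline_sample(self, n_star: int, rng: np.random.Generator,
                        bayesian_bootstrap: bool = False) -> dict[str, np.ndarray]:
        """Resample observed baseline rows jointly; with
        ``bayesian_bootstrap`` the empirical weights are themselves drawn
        from a flat Dirichlet, propagating baseline-distribution uncertainty.
        """
        n_base = len(next(iter(self.baseline.values())))
        if bayesian_bootstrap:
            w = rng.dirichlet(np.ones(n_base))
            idx = rng.choice(n_base, size=n_star, p=w)
        else:
            idx = rng.integers(0, n_base, size=n_star)
        return {name: vals[idx] for name, vals in self.baseline.items()}


def _history_cols(b_names, tv_names, has_treatment, outcome_waves,
                  y_to: int, a_to: int, x_to: int, r_to: int) -> list[str]:
    cols: list[str] = [f"x0:{nm}" for nm in b_names]
    for t in range(1, y_to + 1):
        if t in outcome_waves:
            cols.append(f"y{t}")
    if has_treatment:
        cols += [f"a{t}" for t in range(1, a_to + 1)]
    for t in range(1, x_to + 1):
        cols += [f"x{t}:{nm}" for nm in tv_names]
    cols += [f"r{t}" for t in range(1, r_to + 1)]
    return cols


def _model_columns(target: str, k: int, b_names, tv_names, has_treatment,
                   outcome_waves, cov_pos: int = 0) -> list[str]:
    """Conditioning sets of the sequential factorization."""
    kw = dict(b_names=b_names, tv_names=tv_names,
              has_treatment=has_treatment, outcome_waves=outcome_waves)
    if target in ("s", "r"):
        return _history_cols(**kw, y_to=k - 1, a_to=k - 1, x_to=k - 1, r_to=k - 1)
    if target == "x":
        cols = _history_cols(**kw, y_to=k - 1, a_to=k - 1, x_to=k - 1, r_to=k)
        cols += [f"x{k}:{nm}" for nm in tv_names[:cov_pos]]
        return cols
    if target == "a":
        return _history_cols(**kw, y_to=k - 1, a_to=k - 1, x_to=k, r_to=k)
    if target == "y":
        return _history_cols(**kw, y_to=k - 1, a_to=k if has_treatment else 0,
                             x_to=k, r_to=k)
    raise ValueError(target)


def _make_prior(prior_mode: str, columns: list[str], k: int):
    P = len(columns)
    if prior_mode in ("uniform",):
        return UniformSplitPrior(P)
    if prior_mode in ("dart", "lastwave"):
        return DartPrior(P)
    # current group = latest wave present in this factor's conditioning set;
    # baseline columns (wave tag 0) are grouped with the current predictors
    waves = np.array([_col_wave(c) for c in columns])
    t_eff = int(waves.max())
    if t_eff <= 1:
        return DartPrior(P)
    current = np.flatnonzero((waves == t_eff) | (waves == 0))
    past = tuple(np.flatnonzero(waves == j) for j in range(1, t_eff))
    return LdartPrior(LongitudinalGrouping(t=t_eff, current=current, past=past))


def _fit_factor(state, rows, target_vals, kind, columns, prior_mode, k, cfg, hypers):
    """Fit one factor on its risk set, dropping constant predictor columns."""
    y = target_vals[rows]
    Xd = _design(state, columns, rows) if columns else np.zeros((rows.sum(), 0))
    keep = [i for i in range(Xd.shape[1]) if np.ptp(Xd[:, i]) > 0]
    cols_kept = [columns[i] for i in keep]
    Xk = Xd[:, keep]
    if kind == "probit":
        if len(np.unique(y)) < 2 or Xk.shape[1] == 0:
            return ConstantModel("probit", float(np.mean(y)))
        prior = _make_prior(prior_mode, cols_kept, k)
        return WaveModel("probit", fit_probit(Xk, y, prior, cfg, hypers), cols_kept)
    if np.ptp(y) == 0 or Xk.shape[1] == 0:
        return ConstantModel("gaussian", float(np.mean(y)),
                             float(np.std(y)) if len(y) > 1 else 0.0)
    prior = _make_prior(prior_mode, cols_kept, k)
    return WaveModel("gaussian", fit_gaussian(Xk, y, prior, cfg, hypers), cols_kept)


def fit_sequential(cohort: CohortTable, prior_mode: str = "ldart",
                   cfg: McmcConfig | None = None,
                   hypers: BartHypers | None = None) -> SequentialModelSet:
    """Fit one model per factor of the sequential factorization.

    ``prior_mode`` selects the split prior: "uniform", "dart", "ldart"
    (history variables grouped by measurement wave), or "lastwave"
    (predictors restricted to the current wave, DART prior).
    """
    if prior_mode not in PRIOR_MODES:
        raise ValueError(f"prior_mode must be one of {PRIOR_MODES}")
    cfg = cfg or McmcConfig()
    hypers = hypers or BartHypers()
    T = cohort.T
    names, types = cohort.schema.names, cohort.schema.types
    b_names = tuple(n for n, ty in zip(names, types) if ty == "baseline")
    tv = [(n, ty) for n, ty in zip(names, types) if ty != "baseline"]
    tv_names = tuple(n for n, _ in tv)
    outcome_waves = (T,) if cohort.outcome_final_only else tuple(range(1, T + 1))

    S, R = cohort.wide("S"), cohort.wide("R")
    A, Y = cohort.wide("A"), cohort.wide("Y")
    X = {nm: cohort.wide(nm) for nm in names}
    state: dict[str, np.ndarray] = {}
    for nm in b_names:
        state[f"x0:{nm}"] = X[nm][:, 0]
    for t in range(1, T + 1):
        state[f"r{t}"] = R[:, t - 1]
        if cohort.has_treatment:
            state[f"a{t}"] = A[:, t - 1]
        if t in outcome_waves:
            state[f"y{t}"] = Y[:, t - 1]
        for nm in tv_names:
            state[f"x{t}:{nm}"] = X[nm][:, t - 1]

    ms = SequentialModelSet(
        T=T, cov_names=names, cov_types=types,
        has_treatment=cohort.has_treatment, outcome_waves=outcome_waves,
    )
    base_ok = R[:, 0] == 1
    ms.baseline = {nm: X[nm][base_ok, 0] for nm in names}

    any_death = (S == 0).any()
    any_nonresp = (R == 0).any()

    def restrict(cols):
        if prior_mode != "lastwave" or not cols:
            return cols
        maxw = max(_col_wave(c) for c in cols)
        return [c for c in cols if _col_wave(c) in (maxw, 0)]

    for k in range(1, T + 1):
        kw = dict(b_names=b_names, tv_names=tv_names,
                  has_treatment=cohort.has_treatment,
                  outcome_waves=outcome_waves)
        if k >= 2 and any_death:
            cols = restrict(_model_columns("s", k, **kw))
            rows = (S[:, k - 2] == 1) & _complete(state, cols)
            if rows.sum() == 0:
                raise ValueError(f"empty risk set for survival model at wave {k}")
            ms.survival[k] = _fit_factor(state, rows, S[:, k - 1], "probit",
                                         cols, prior_mode, k, cfg, hypers)
        if any_nonresp and (k >= 2 or np.ptp(R[:, 0]) > 0):
            cols = restrict(_model_columns("r", k, **kw)) if k >= 2 else []
            rows = (S[:, k - 1] == 1) & _complete(state, cols)
            if rows.sum() == 0:
                raise ValueError(f"empty risk set for response model at wave {k}")
            ms.response[k] = _fit_factor(state, rows, R[:, k - 1], "probit",
                                         cols, prior_mode, k, cfg, hypers)
        if k >= 2:
            for pos, (nm, ty) in enumerate(tv):
                cols = restrict(_model_columns("x", k, **kw, cov_pos=pos))
                rows = (R[:, k - 1] == 1) & _complete(state, cols)
                if rows.sum() == 0:
                    raise ValueError(f"empty risk set for covariate {nm} at wave {k}")
                kind = "probit" if ty == "binary" else "gaussian"
                ms.covariate[(k, nm)] = _fit_factor(
                    state, rows, X[nm][:, k - 1], kind, cols, prior_mode, k, cfg, hypers)
        if cohort.has_treatment:
            cols = restrict(_model_columns("a", k, **kw))
            rows = (R[:, k - 1] == 1) & _complete(state, cols)
            if rows.sum() == 0:
                raise ValueError(f"empty risk set for treatment model at wave {k}")
            ms.treatment[k] = _fit_factor(state, rows, A[:, k - 1], "gaussian",
                                          cols, prior_mode, k, cfg, hypers)
        if k in outcome_waves:
            cols = restrict(_model_columns("y", k, **kw))
            rows = (R[:, k - 1] == 1) & _complete(state, cols)
            if rows.sum() == 0:
                raise ValueError(f"empty risk set for outcome model at wave {k}")
            ms.outcome[k] = _fit_factor(state, rows, Y[:, k - 1], "gaussian",
                                        cols, prior_mode, k, cfg, hypers)

    draws = [m.fit.n_draws for d in (ms.survival, ms.response, ms.covariate,
                                     ms.treatment, ms.outcome)
             for m in d.values() if isinstance(m, WaveModel)]
    ms.n_draws = min(draws) if draws else 1
    return ms


def _complete(state, cols) -> np.ndarray:
    if not cols:
        some = next(iter(state.values()))
        return np.ones(len(some), dtype=bool)
    return ~np.isnan(np.column_stack([state[c] for c in cols])).any(axis=1)


def apply_intervention(a_star, tau: float, delta: float):
    """Incremental threshold rule: leave the natural value alone at or below
    the threshold, otherwise shift it downward by |delta| (delta <= 0)."""
    if delta > 0:
        raise ValueError("shift delta must be <= 0")
    a_star = np.asarray(a_star, dtype=float)
    out = np.where(a_star > tau, a_star + delta, a_star)
    return float(out) if out.ndim == 0 else out


@dataclass
class PseudoCohort:
    """N* simulated forward trajectories under one regime and posterior draw."""

    state: dict[str, np.ndarray]
    alive: np.ndarray          # n_star bool, alive at T
    survivor_mean: float       # Rao-Blackwellized E[Y_T | S_T = 1]
    psi: float                 # marginal survival probability at T
    regime: RegimeSpec
    draw: int
    deltas: dict[int, float]

    @property
    def n_star(self) -> int:
        return len(self.alive)


def simulate_regime(models: SequentialModelSet, regime: RegimeSpec,
                    n_star: int, draw: int, seed: int,
                    bayesian_bootstrap: bool = False) -> PseudoCohort:
    """Simulate N* pseudo-subjects forward through one posterior draw.

    The trajectory noise stream depends only on (seed, draw), never on the
    regime, and the shift draws use a separate stream, so a null
    intervention reproduces the natural course exactly under shared seeds.
    One shift delta_t is drawn per wave per posterior draw.
    """
    if n_star < 1:
        raise ValueError("n_star must be >= 1")
    ss = np.random.SeedSequence([int(seed) % (2 ** 31), int(draw)])
    traj_rng, delta_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    T = models.T
    state: dict[str, np.ndarray] = {}
    alive = np.ones(n_star, dtype=bool)
    alive_prev_final = np.ones(n_star, dtype=bool)
    p_surv_final: np.ndarray | None = None
    deltas: dict[int, float] = {}
    intervene = regime.kind == "incremental_threshold"
    survivor_mean = np.nan

    for k in range(1, T + 1):
        rows = np.flatnonzero(alive)
        if k >= 2 and k in models.survival:
            m = models.survival[k]
            p = m.mean(_design(state, m.columns, rows), draw)
            if k == T:
                alive_prev_final = alive.copy()
                p_surv_final = np.zeros(n_star)
                p_surv_final[rows] = p
            u = traj_rng.uniform(size=len(rows))
            died = rows[u >= p]
            alive[died] = False
            rows = np.flatnonzero(alive)
        elif k == T:
            alive_prev_final = alive.copy()

        rk = np.zeros(n_star)
        rk[:] = np.nan
        if k in models.response:
            m = models.response[k]
            rk[rows] = m.draw_values(_design(state, m.columns, rows), draw, traj_rng)
        else:
            rk[rows] = 1.0
        state[f"r{k}"] = rk

        if k == 1:
            base = models.baseline_sample(
                n_star, traj_rng, bayesian_bootstrap=bayesian_bootstrap)
            for nm in models.baseline_names:
                state[f"x0:{nm}"] = base[nm]
            for nm in models.tv_names:
                v = np.full(n_star, np.nan)
                v[rows] = base[nm][rows]
                state[f"x1:{nm}"] = v
        else:
            for nm in models.tv_names:
                m = models.covariate[(k, nm)]
                v = np.full(n_star, np.nan)
                v[rows] = m.draw_values(_design(state, m.columns, rows), draw, traj_rng)
                state[f"x{k}:{nm}"] = v

        if models.has_treatment:
            m = models.treatment[k]
            a_star = np.full(n_star, np.nan)
            a_star[rows] = m.draw_values(_design(state, m.columns, rows), draw, traj_rng)
            state[f"astar{k}"] = a_star
            a = a_star.copy()
            if intervene and k >= regime.start_wave and regime.tau != np.inf:
                deltas[k] = float(regime.shift_prior.sample(delta_rng))
                a[rows] = apply_intervention(a_star[rows], regime.tau, deltas[k])
            state[f"a{k}"] = a

        if k in models.outcome:
            m = models.outcome[k]
            Xd = _design(state, m.columns, rows)
            mu = m.mean(Xd, draw)
            if k == T:
                if len(rows) == 0:
                    warnings.warn(f"no survivors at wave {T}: survivor mean undefined")
                else:
                    survivor_mean = float(np.mean(mu))
            y = np.full(n_star, np.nan)
            sig = m.sigma(draw) if hasattr(m, "sigma") else 0.0
            y[rows] = mu + sig * traj_rng.standard_normal(len(rows))
            state[f"y{k}"] = y

    if p_surv_final is not None:
        psi = float(np.mean(np.where(alive_prev_final, p_surv_final, 0.0)))
    else:
        psi = float(np.mean(alive))
    return PseudoCohort(state, alive, survivor_mean, psi, regime, draw, deltas)


@dataclass(frozen=True)
class GcompDraw:
    """Per-posterior-draw G-computation summary under one regime."""

    survivor_mean: float
    psi: float
    regime: str
    draw: int


def gcomp_estimates(models: SequentialModelSet, regime: RegimeSpec,
                    n_star: int, n_draws: int, seed: int,
                    bayesian_bootstrap: bool = False) -> list[GcompDraw]:
    """Run G-computation for ``n_draws`` posterior draws (evenly spaced over
    the saved draws), excluding (with a warning) draws with no survivors."""
    total = models.n_draws
    idx = np.unique(np.linspace(0, total - 1, num=min(n_draws, total)).astype(int))
    out = []
    for d in idx:
        pc = simulate_regime(models, regime, n_star, int(d), seed,
                             bayesian_bootstrap=bayesian_bootstrap)
        if np.isnan(pc.survivor_mean):
            continue
        out.append(GcompDraw(pc.survivor_mean, pc.psi, regime.kind, int(d)))
    return out
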