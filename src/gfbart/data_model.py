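"""Longitudinal data structures for mortal-cohort G-computation.

The central container is :class:`CohortTable`, a validated long-format table
with one row per subject-wave carrying survival ``S``, response ``R``,
time-varying confounders ``X``, a continuous treatment ``A`` and a continuous
outcome ``Y``.  Within a wave the variables respect the temporal ordering
S, R, X, A, Y; death truncates everything downstream (monotone death), and a
non-response wave (``R = 0``) carries no X/A/Y.

Priors over scalar intervention parameters (the per-wave shift, and the
sensitivity parameters of the survivor-stratum analysis) are triangular and
wrapped in :class:`TriangularPrior`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TriangularPrior",
    "RegimeSpec",
    "SensitivitySpec",
    "CovariateSchema",
    "WaveRecord",
    "History",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "triangular_density",
    "triangular_sample",
]

FLAG_COLS = ("S", "R")
ID_COL = "id"
TIME_COL = "t"


class CohortValidationError(ValueError):
    """Raised when a long-format table violates the mortal-cohort invariants."""


@dataclass(frozen=True)
class TriangularPrior:
    """Triangular distribution on [lower, upper] with apex at ``mode``.

    Degenerate priors (lower == upper) are allowed and behave as point
    masses, which is how a deterministic shift or a fixed sensitivity
    parameter is expressed.
    """

    lower: float
    mode: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.mode <= self.upper):
            raise ValueError(
                f"need lower <= mode <= upper, got ({self.lower}, {self.mode}, {self.upper})"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.upper == self.lower

    def _frozen(self):
        width = self.upper - self.lower
        c = (self.mode - self.lower) / width
        return stats.triang(c, loc=self.lower, scale=width)

    def pdf(self, v: float | np.ndarray) -> float | np.ndarray:
        if self.is_degenerate:
            v = np.asarray(v, dtype=float)
            out = np.where(v == self.lower, np.inf, 0.0)
            return float(out) if out.ndim == 0 else out
        out = self._frozen().pdf(v)
        return float(out) if np.ndim(v) == 0 else out

    def mean(self) -> float:
        return (self.lower + self.mode + self.upper) / 3.0

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Inverse-CDF draw(s); reproducible for a fixed generator state."""
        if self.is_degenerate:
            if size is None:
                return self.lower
            return np.full(size, self.lower, dtype=float)
        u = rng.uniform(size=size)
        out = self._frozen().ppf(u)
        return float(out) if size is None else out


def triangular_density(p: TriangularPrior, v: float) -> float:
    """Density of the triangular prior at ``v`` (0 outside the support)."""
    return float(p.pdf(v))


def triangular_sample(p: TriangularPrior, rng: np.random.Generator | int):
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return p.sample(rng)


@dataclass(frozen=True)
class RegimeSpec:
    """A treatment regime: the natural course or an incremental threshold
    intervention that shifts the natural value of treatment downward by a
    random amount whenever it exceeds ``tau``.

    ``start_wave`` is the first wave at which the rule is applied (an
    intervention on follow-up waves only, as in a cohort whose baseline
    treatment predates the policy, uses ``start_wave=2``).
    """

    kind: str = "natural_course"  # or "incremental_threshold"
    tau: float | None = None
    shift_prior: TriangularPrior | None = None
    start_wave: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("natural_course", "incremental_threshold"):
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if self.kind == "incremental_threshold":
            if self.tau is None or self.shift_prior is None:
                raise ValueError("incremental_threshold requires tau and shift_prior")
            if self.shift_prior.upper > 0:
                raise ValueError("shift prior support must lie in (-inf, 0]")

    @property
    def is_null(self) -> bool:
        return self.kind == "natural_course" or self.tau == np.inf


@dataclass(frozen=True)
class SensitivitySpec:
    """Priors on the stochastic-monotonicity parameter λ ∈ [0, 1] and the
    cross-stratum outcome difference Δ (outcome units)."""

    lambda_prior: TriangularPrior = field(
        default_factory=lambda: TriangularPrior(0.5, 1.0, 1.0)
    )
    delta_prior: TriangularPrior = field(
        default_factory=lambda: TriangularPrior(0.0, 0.0, 0.0)
    )

    def __post_init__(self) -> None:
        if self.lambda_prior.lower < 0 or self.lambda_prior.upper > 1:
            raise ValueError("lambda prior support must lie within [0, 1]")


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered covariate names and their types ('continuous', 'binary', or
    'baseline' for time-constant covariates such as age at entry).

    The order fixes the within-wave factorization order of the sequential
    covariate models, so it is part of the model definition.  Baseline
    covariates are recorded at every wave (constant within subject), never
    get their own sequential model, and are grouped with the current-wave
    predictors by the longitudinal split prior.
    """

    names: tuple[str, ...]
    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.types):
            raise ValueError("names and types length mismatch")
        for ty in self.types:
            if ty not in ("continuous", "binary", "baseline"):
                raise ValueError(f"unknown covariate type {ty!r}")

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "CovariateSchema":
        return cls(tuple(d.keys()), tuple(d.values()))

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class WaveRecord:
    """One subject-wave observation (fields are NaN when truncated/missing)."""

    subject_id: object
    t: int
    s: int
    r: int
    x: np.ndarray
    a: float
    y: float


@dataclass(frozen=True)
class History:
    """Observed past prior to the outcome at a wave: outcomes through t-1,
    confounders and response flags through t, survival all 1 by construction.
    Treatment history is carried separately because it is conditioned on by
    the sequential models without being part of the history proper."""

    y_hist: np.ndarray
    x_hist: np.ndarray
    r_hist: np.ndarray
    a_hist: np.ndarray


class CohortTable:
    """Validated long-format cohort (one row per subject-wave).

    Parameters
    ----------
    df : DataFrame with columns ``id, t, S, R, <covariates...>, A, Y``.
    schema : covariate names/types; names must match columns.
    has_treatment : False for designs without a treatment process (the A
        column may then be absent or all-missing).
    outcome_final_only : True when the outcome is measured at the last wave
        only (Y is then required at wave T for responders, absent earlier).
    """

    def __init__(self, df: pd.DataFrame, schema: CovariateSchema,
                 has_treatment: bool = True, outcome_final_only: bool = False):
        self.schema = schema
        self.has_treatment = has_treatment
        self.outcome_final_only = outcome_final_only
        df = df.copy()
        if not has_treatment and "A" not in df.columns:
            df["A"] = np.nan
        self.df = self._validate(df, schema, has_treatment, outcome_final_only)
        self.T = int(self.df[TIME_COL].max())
        self.n = self.df[ID_COL].nunique()

    @staticmethod
    def _validate(df: pd.DataFrame, schema: CovariateSchema,
                  has_treatment: bool = True,
                  outcome_final_only: bool = False) -> pd.DataFrame:
        required = [ID_COL, TIME_COL, "S", "R", *schema.names, "A", "Y"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing columns: {missing}")
        unknown = [
            c for c in df.columns if c not in required
        ]
        if unknown:
            raise CohortValidationError(f"unknown columns (not in schema): {unknown}")
        df = df[required].sort_values([ID_COL, TIME_COL], kind="stable").reset_index(drop=True)
        for c in FLAG_COLS:
            vals = df[c].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise CohortValidationError(f"flag column {c} must be 0/1")
            df[c] = df[c].astype(np.int64)
        waves = df.groupby(ID_COL)[TIME_COL]
        tmax = int(df[TIME_COL].max())
        if not (waves.count() == tmax).all() or not (waves.min() == 1).all():
            raise CohortValidationError(
                "every subject needs a row for every wave 1..T "
                "(survival status is observed throughout follow-up)"
            )
        s = df.pivot(index=ID_COL, columns=TIME_COL, values="S").to_numpy()
        if (np.diff(s, axis=1) > 0).any():
            raise CohortValidationError("non-monotone death: S rises after a 0")
        dead = df["S"].to_numpy() == 0
        if (df.loc[dead, "R"] != 0).any():
            raise CohortValidationError("R must be 0 when S = 0")
        value_cols = list(schema.names)
        if has_treatment:
            value_cols.append("A")
        tmax_rows = df[TIME_COL].to_numpy() == tmax
        present = df[value_cols].notna().to_numpy()
        nonresp = df["R"].to_numpy() == 0
        if present[nonresp].any():
            raise CohortValidationError("X/A/Y must be absent when R = 0")
        if (~present[~nonresp]).any():
            raise CohortValidationError("X/A/Y must be present when R = 1")
        y_present = df["Y"].notna().to_numpy()
        y_req = (~nonresp) & (tmax_rows if outcome_final_only else True)
        if y_present[~y_req].any():
            raise CohortValidationError("Y present outside its measurement waves")
        if (~y_present[y_req]).any():
            raise CohortValidationError("Y must be present when R = 1")
        if not has_treatment and df["A"].notna().any():
            raise CohortValidationError("A present but has_treatment=False")
        return df

    # -- accessors ---------------------------------------------------------
    def wide(self, col: str) -> np.ndarray:
        """n × T array of one column (NaN where truncated/missing)."""
        return self.df.pivot(index=ID_COL, columns=TIME_COL, values=col).to_numpy(dtype=float)

    def records(self):
        for row in self.df.itertuples(index=False):
            yield WaveRecord(
                subject_id=getattr(row, ID_COL),
                t=int(getattr(row, TIME_COL)),
                s=int(row.S),
                r=int(row.R),
                x=np.array([getattr(row, c) for c in self.schema.names], dtype=float),
                a=float(row.A),
                y=float(row.Y),
            )

    def __len__(self) -> int:
        return len(self.df)


def read_cohort(path, schema: CovariateSchema | dict[str, str],
                has_treatment: bool = True,
                outcome_final_only: bool = False) -> CohortTable:
    """Read a long-format CSV (empty cells = missing) into a validated table."""
    if isinstance(schema, dict):
        schema = CovariateSchema.from_dict(schema)
    df = pd.read_csv(path)
    return CohortTable(df, schema, has_treatment, outcome_final_only)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.df.to_csv(path, index=False)
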