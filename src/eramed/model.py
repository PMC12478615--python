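"""Data model: problem dimensions, block structure, parameter containers.

A :class:`ModelSpec` describes the shape of one ERA-with-mediation problem:
how predictors partition into component blocks, how many covariates and
mediators there are, and which outcomes are continuous versus ordinal.  A
:class:`Dataset` carries the matching data matrices.  Parameter containers
(:class:`Weights`, :class:`MediatorParams`, :class:`ResponseParams`) mirror
the blocks of the model, and :class:`PosteriorDraws` holds retained MCMC
output.  ``validate`` checks every structural invariant and returns a
structured report instead of raising on first failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ModelSpec",
    "Dataset",
    "Weights",
    "MediatorParams",
    "ResponseParams",
    "PriorConfig",
    "PosteriorDraws",
    "ValidationError",
    "validate",
    "standardize_weights",
]


class ValidationError(ValueError):
    """Raised when a spec/data pair fails validation."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(errors))


@dataclass(frozen=True)
class ModelSpec:
    """Dimensions and block structure of the model.

    Parameters
    ----------
    n_components : int
        Number of components K.
    block_of : sequence of int
        Length-P map predictor index -> component index (0-based).
    n_covariates : int
        Number of covariates C (may be 0).
    n_mediators : int
        Number of mediators R.
    n_continuous : int
        Number of continuous outcomes T (occupying the first T positions).
    categories : sequence of int
        Category counts J_q (>= 2) for each of the Q - T ordinal outcomes.
    """

    n_components: int
    block_of: tuple[int, ...]
    n_covariates: int
    n_mediators: int
    n_continuous: int
    categories: tuple[int, ...]

    def __init__(
        self,
        n_components: int,
        block_of: Sequence[int],
        n_covariates: int,
        n_mediators: int,
        n_continuous: int,
        categories: Sequence[int] = (),
    ) -> None:
        object.__setattr__(self, "n_components", int(n_components))
        object.__setattr__(self, "block_of", tuple(int(b) for b in block_of))
        object.__setattr__(self, "n_covariates", int(n_covariates))
        object.__setattr__(self, "n_mediators", int(n_mediators))
        object.__setattr__(self, "n_continuous", int(n_continuous))
        object.__setattr__(self, "categories", tuple(int(j) for j in categories))
        errs = self._structure_errors()
        if errs:
            raise ValidationError(errs)

    def _structure_errors(self) -> list[str]:
        errs = []
        if self.n_components < 1:
            errs.append("need at least one component")
        if not self.block_of:
            errs.append("need at least one predictor")
        for p, b in enumerate(self.block_of):
            if not (0 <= b < self.n_components):
                errs.append(f"unassigned predictor: column {p} maps to block {b}")
        assigned = set(self.block_of)
        for k in range(self.n_components):
            if k not in assigned:
                errs.append(f"component {k} has no predictors")
        if self.n_covariates < 0 or self.n_mediators < 0 or self.n_continuous < 0:
            errs.append("counts must be nonnegative")
        for q, j in enumerate(self.categories):
            if j < 2:
                errs.append(f"ordinal outcome {q} has {j} categories (need >= 2)")
        return errs

    # -- derived dimensions -------------------------------------------------
    @property
    def n_predictors(self) -> int:
        return len(self.block_of)

    @property
    def n_ordinal(self) -> int:
        return len(self.categories)

    @property
    def n_outcomes(self) -> int:
        return self.n_continuous + self.n_ordinal

    @property
    def n_regressors(self) -> int:
        """Rows of A2/A3: covariates then components."""
        return self.n_covariates + self.n_components

    def block_members(self, k: int) -> np.ndarray:
        """Predictor column indices belonging to component ``k``."""
        return np.flatnonzero(np.asarray(self.block_of) == k)

    # -- config round trip --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "block_of": list(self.block_of),
            "n_covariates": self.n_covariates,
            "n_mediators": self.n_mediators,
            "n_continuous": self.n_continuous,
            "categories": list(self.categories),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            n_components=d["n_components"],
            block_of=d["block_of"],
            n_covariates=d["n_covariates"],
            n_mediators=d["n_mediators"],
            n_continuous=d["n_continuous"],
            categories=d.get("categories", []),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Dataset:
    """Observed data matrices sharing N rows.

    ``yord`` uses 1-based category codes 1..J_q.  Matrices may be empty in
    the second dimension (e.g. no covariates) but must agree on N.
    """

    x: np.ndarray
    cov: np.ndarray
    m: np.ndarray
    ycont: np.ndarray
    yord: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        n = self.x.shape[0]
        self.cov = _as_2d(self.cov, n)
        self.m = _as_2d(self.m, n)
        self.ycont = _as_2d(self.ycont, n)
        self.yord = np.asarray(
            _as_2d(self.yord, n), dtype=int
        ) if np.size(self.yord) else np.zeros((n, 0), dtype=int)

    @property
    def n(self) -> int:
        return self.x.shape[0]


def _as_2d(a, n: int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        return a.reshape(n, 0)
    return np.atleast_2d(a)


@dataclass
class Weights:
    """Block-sparse P x K component-weight matrix.

    Invariants (enforced by :func:`standardize_weights`): zero outside the
    block pattern, each component score ``X @ W[:, k]`` has unit sample
    variance, and the first weight of each block is nonnegative.
    """

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))

    def free(self, spec: ModelSpec) -> np.ndarray:
        """Length-P vector of the free (within-block) weights."""
        return self.w[np.arange(spec.n_predictors), np.asarray(spec.block_of)]

    @classmethod
    def from_free(cls, free: np.ndarray, spec: ModelSpec) -> "Weights":
        w = np.zeros((spec.n_predictors, spec.n_components))
        w[np.arange(spec.n_predictors), np.asarray(spec.block_of)] = free
        return cls(w)


def standardize_weights(
    x: np.ndarray, w: np.ndarray, spec: ModelSpec, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize components to unit sample variance with sign convention.

    Returns ``(F, W_std, scale)`` where ``F = X @ W_std`` has column sample
    variances exactly 1, ``W_std`` is the compensatingly rescaled weight
    matrix (first weight per block nonnegative), and ``scale`` is the signed
    per-component factor by which coefficient rows attached to the components
    must be *multiplied* to leave the model mean unchanged.
    """
    w = np.array(w, dtype=float)
    f = x @ w
    sd = f.std(axis=0, ddof=ddof)
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        raise ValueError("zero-variance component: degenerate weights or data")
    signs = np.ones(spec.n_components)
    for k in range(spec.n_components):
        first = spec.block_members(k)[0]
        if w[first, k] / sd[k] < 0:
            signs[k] = -1.0
    scale = sd * signs
    w_std = w / scale[np.newaxis, :]
    return x @ w_std, w_std, scale


@dataclass
class MediatorParams:
    """Parameters of the mediator regression block."""

    a1: np.ndarray          # (R,) intercepts
    a2: np.ndarray          # (C + K, R) covariate+component coefficients
    sigma_m: np.ndarray     # (R, R) residual covariance
    nu_m: float             # t degrees of freedom
    phi_m: np.ndarray       # (N,) mixture precisions


@dataclass
class ResponseParams:
    """Parameters of the mixed-outcome response block."""

    a0: np.ndarray          # (Q,) intercepts
    a3: np.ndarray          # (C + K, Q) direct effects
    a4: np.ndarray          # (R, Q) mediator -> outcome effects
    sigma_y: np.ndarray     # (Q, Q) residual covariance
    nu_c: float             # df of the continuous block
    phi1: np.ndarray        # (N,) continuous-block precisions
    phi2: np.ndarray        # (N,) ordinal-block precisions
    cutpoints: list[np.ndarray]  # per ordinal outcome, length J_q - 1, first = 0
    z: np.ndarray           # (N, Q - T) latent ordinal variables


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the flat conjugate priors and Metropolis steps.

    Coefficient priors are independent normals with common mean and (large)
    variance.  Inverse covariances get Wishart priors with ``wishart_df``
    degrees of freedom (must be >= dimension) and scale ``I / wishart_df``,
    so the prior mean of the precision matrix is the identity.  The df
    parameters get a uniform prior on 1/nu over ``df_inv_range``.
    """

    coef_mean: float = 0.0
    coef_var: float = 100.0
    weight_var: float = 100.0
    wishart_df_extra: int = 2
    df_inv_range: tuple[float, float] = (0.0, 1.0)
    step_precision: float = 0.5
    step_df_inv: float = 0.1

    def __post_init__(self) -> None:
        if self.coef_var <= 0 or self.weight_var <= 0:
            raise ValueError("prior variances must be positive")
        lo, hi = self.df_inv_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("df_inv_range must satisfy 0 <= lo < hi <= 1")
        if self.step_precision <= 0 or self.step_df_inv <= 0:
            raise ValueError("Metropolis step sizes must be positive")

    def wishart_df(self, dim: int) -> int:
        return dim + self.wishart_df_extra

    def wishart_scale(self, dim: int) -> np.ndarray:
        return np.eye(dim) / self.wishart_df(dim)


@dataclass
class PosteriorDraws:
    """Retained, thinned post-burn-in draws plus run metadata.

    Array fields are stacked along a leading draw axis.  ``gamma`` is a list
    with one ``(n_draws, J_q - 1)`` array per ordinal outcome.  Mediator
    fields are ``None`` for a fit without mediators.
    """

    spec: ModelSpec
    w: np.ndarray                    # (D, P, K)
    a0: np.ndarray                   # (D, Q)
    a3: np.ndarray                   # (D, C + K, Q)
    sigma_y: np.ndarray              # (D, Q, Q)
    nu_c: np.ndarray                 # (D,)
    gamma: list[np.ndarray]          # per ordinal outcome (D, J_q - 1)
    a1: np.ndarray | None = None     # (D, R)
    a2: np.ndarray | None = None     # (D, C + K, R)
    sigma_m: np.ndarray | None = None  # (D, R, R)
    nu_m: np.ndarray | None = None   # (D,)
    a4: np.ndarray | None = None     # (D, R, Q)
    n_iter: int = 0
    burn_in: int = 0
    thin: int = 1
    seed: int | None = None
    acceptance: dict = field(default_factory=dict)
    identified: bool = False

    @property
    def n_draws(self) -> int:
        return self.w.shape[0]

    @property
    def has_mediators(self) -> bool:
        return self.a4 is not None


def validate(spec: ModelSpec, data: Dataset) -> list[str]:
    """Check all spec/data invariants; return a list of violation messages.

    An empty list means the pair is valid.  Use :func:`require_valid` to
    raise instead.
    """
    errs = list(spec._structure_errors())
    n = data.n
    if data.x.shape[1] != spec.n_predictors:
        errs.append(
            f"dimension mismatch: X has {data.x.shape[1]} columns, "
            f"spec expects {spec.n_predictors}"
        )
    for name, mat, width in (
        ("Cov", data.cov, spec.n_covariates),
        ("M", data.m, spec.n_mediators),
        ("Ycont", data.ycont, spec.n_continuous),
        ("Yord", data.yord, spec.n_ordinal),
    ):
        if mat.shape[0] != n:
            errs.append(f"dimension mismatch: {name} has {mat.shape[0]} rows, X has {n}")
        if mat.shape[1] != width:
            errs.append(
                f"dimension mismatch: {name} has {mat.shape[1]} columns, "
                f"spec expects {width}"
            )
    for name, mat in (
        ("X", data.x), ("Cov", data.cov), ("M", data.m), ("Ycont", data.ycont)
    ):
        if mat.size and not np.all(np.isfinite(mat)):
            errs.append(f"missing values: non-finite entries in {name}")
    if data.yord.size and data.yord.shape[1] == spec.n_ordinal:
        for q, j_q in enumerate(spec.categories):
            col = data.yord[:, q]
            if np.any(col < 1):
                errs.append(f"category below 1 in ordinal outcome {q}")
            if np.any(col > j_q):
                errs.append(f"category above J={j_q} in ordinal outcome {q}")
    return errs


def require_valid(spec: ModelSpec, data: Dataset) -> None:
    errs = validate(spec, data)
    if errs:
        raise ValidationError(errs)
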