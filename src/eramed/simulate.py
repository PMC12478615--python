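"""Synthetic-data generator for the ERA mediation model.

Generates multivariate-normal predictor blocks, standardized components,
multivariate-t mediators, and mixed continuous/ordinal outcomes whose joint
error is a correlated scale mixture of normals.  The ordinal-block latents
are pushed through the t-to-logistic CDF map before discretization by
cutoffs, so each ordinal outcome follows an exact (correlated) logistic
latent model.  ``default_scenario`` emits the two-component / two-mediator /
two-continuous / two-ordinal topology used throughout the tests; the true
coefficient values are documented package defaults, all nonzero and of
moderate size so every path is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import Dataset, ModelSpec, standardize_weights
from .mvt import TApprox, t_to_logistic

__all__ = [
    "TrueParams",
    "generate_predictors",
    "make_components",
    "simulate_mediators",
    "simulate_outcomes",
    "apply_cutoffs",
    "default_scenario",
]


@dataclass
class TrueParams:
    """Ground-truth parameter values used to generate a synthetic dataset."""

    w: np.ndarray                 # (P, K) block-sparse weights (standardized post-hoc)
    sigma_x: np.ndarray           # (P, P) predictor covariance
    a1: np.ndarray                # (R,) mediator intercepts
    a2: np.ndarray                # (C + K, R)
    sigma_m: np.ndarray           # (R, R)
    nu_m: float
    a0: np.ndarray                # (Q,)
    a3: np.ndarray                # (C + K, Q)
    a4: np.ndarray                # (R, Q)
    sigma_y: np.ndarray           # (Q, Q)
    nu_c: float
    cutoffs: list[np.ndarray]     # per ordinal outcome, strictly increasing

    def __post_init__(self) -> None:
        self.cutoffs = [np.asarray(g, dtype=float) for g in self.cutoffs]
        for q, g in enumerate(self.cutoffs):
            if g.size and np.any(np.diff(g) <= 0):
                raise ValueError(f"cutoffs for ordinal outcome {q} not increasing")

    def to_dict(self) -> dict:
        d = {k: np.asarray(v).tolist() for k, v in self.__dict__.items()
             if k != "cutoffs"}
        d["cutoffs"] = [g.tolist() for g in self.cutoffs]
        return d


def generate_predictors(
    n: int, spec: ModelSpec, sigma_x: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. zero-mean multivariate-normal predictor rows."""
    sigma_x = np.asarray(sigma_x, dtype=float)
    if sigma_x.shape != (spec.n_predictors, spec.n_predictors):
        raise ValueError("sigma_x has wrong shape")
    try:
        chol = np.linalg.cholesky(sigma_x)
    except np.linalg.LinAlgError as exc:
        raise ValueError("sigma_x is not positive definite") from exc
    return rng.standard_normal((n, spec.n_predictors)) @ chol.T


def make_components(
    x: np.ndarray, w: np.ndarray, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Form component scores F = X W and rescale to unit sample variance.

    Returns ``(F, W_rescaled)``.  The rescale divides each weight block by
    the component sample standard deviation (sign-fixed), so applying the
    function twice is a no-op.
    """
    pattern = np.zeros_like(np.atleast_2d(w), dtype=bool)
    pattern[np.arange(spec.n_predictors), np.asarray(spec.block_of)] = True
    if np.any(np.asarray(w)[~pattern] != 0):
        raise ValueError("weights are not block-sparse")
    f, w_std, _ = standardize_weights(x, w, spec)
    return f, w_std


def simulate_mediators(
    f: np.ndarray,
    cov: np.ndarray,
    true: TrueParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw mediators from the normal scale mixture (marginally t, df nu_m)."""
    n = f.shape[0]
    u = np.hstack([cov, f])
    mean = true.a1 + u @ true.a2
    phi = rng.gamma(true.nu_m / 2.0, 2.0 / true.nu_m, size=n)
    chol = np.linalg.cholesky(true.sigma_m)
    eps = rng.standard_normal((n, true.sigma_m.shape[0])) @ chol.T
    return mean + eps / np.sqrt(phi)[:, None]


def simulate_outcomes(
    f: np.ndarray,
    cov: np.ndarray,
    m: np.ndarray,
    true: TrueParams,
    approx: TApprox,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw continuous outcomes, ordinal outcomes, and the latent matrix.

    The joint Q-vector error is normal with covariance
    ``D Sigma_Y D`` conditionally on the two block precisions, where
    ``D = diag(1/sqrt(phi1) * 1_T, sigma0/sqrt(phi2) * 1_{Q-T})`` with
    ``phi1 ~ Gamma(nu_c/2, nu_c/2)`` and ``phi2 ~ Gamma(nu0/2, nu0/2)``.
    Marginally the continuous block is multivariate t with df nu_c and the
    ordinal block multivariate t with df nu0 and scale ``sigma0_sq Sigma_22``;
    each ordinal latent error is mapped marginally to the logistic law before
    the mean is added and cutoffs are applied.
    """
    n = f.shape[0]
    q_total = true.sigma_y.shape[0]
    n_ord = len(true.cutoffs)
    t_cont = q_total - n_ord
    u = np.hstack([cov, f])
    mean = true.a0 + u @ true.a3 + m @ true.a4

    phi1 = rng.gamma(true.nu_c / 2.0, 2.0 / true.nu_c, size=n)
    phi2 = rng.gamma(approx.nu0 / 2.0, 2.0 / approx.nu0, size=n)
    chol = np.linalg.cholesky(true.sigma_y)
    eps = rng.standard_normal((n, q_total)) @ chol.T
    d = np.empty((n, q_total))
    d[:, :t_cont] = 1.0 / np.sqrt(phi1)[:, None]
    d[:, t_cont:] = approx.sigma0 / np.sqrt(phi2)[:, None]
    err = eps * d

    ycont = mean[:, :t_cont] + err[:, :t_cont]
    zlat = np.empty((n, n_ord))
    yord = np.empty((n, n_ord), dtype=int)
    sig_diag = np.sqrt(np.diag(true.sigma_y)[t_cont:])
    for j in range(n_ord):
        logit_err = t_to_logistic(
            err[:, t_cont + j], approx.nu0, approx.sigma0 * sig_diag[j]
        )
        zlat[:, j] = mean[:, t_cont + j] + logit_err
        yord[:, j] = apply_cutoffs(zlat[:, j], true.cutoffs[j])
    return ycont, yord, zlat


def apply_cutoffs(z, gammas: np.ndarray):
    """Discretize latent values: category j iff gamma_{j-1} < z <= gamma_j.

    ``gamma_0 = -inf`` and ``gamma_J = +inf``; categories are 1-based.  A
    value exactly at a cutpoint belongs to the category whose right endpoint
    it is.
    """
    gammas = np.asarray(gammas, dtype=float)
    if gammas.size and np.any(np.diff(gammas) <= 0):
        raise ValueError("cutoffs must be strictly increasing")
    z = np.asarray(z, dtype=float)
    cat = np.searchsorted(gammas, z, side="left") + 1
    return cat if cat.ndim else int(cat)


def _default_true(spec: ModelSpec) -> TrueParams:
    """Documented default truth for the two-component scenario (C = 0)."""
    p = spec.n_predictors
    w = np.zeros((p, spec.n_components))
    for k in range(spec.n_components):
        idx = spec.block_members(k)
        w[idx, k] = np.linspace(1.0, 0.6, idx.size)
    blk = np.asarray(spec.block_of)
    sigma_x = np.where(blk[:, None] == blk[None, :], 0.3, 0.1) + 0.7 * np.eye(p)
    sigma_m = np.array([[1.0, 0.3], [0.3, 1.0]])
    sigma_y = 0.3 + 0.7 * np.eye(4)
    return TrueParams(
        w=w,
        sigma_x=sigma_x,
        a1=np.array([0.3, -0.2]),
        a2=np.array([[0.6, 0.4], [-0.5, 0.5]]),
        sigma_m=sigma_m,
        nu_m=5.0,
        a0=np.array([0.2, -0.3, 0.25, 0.4]),
        a3=np.array([[0.5, -0.4, 0.6, -0.3], [0.4, 0.5, -0.5, 0.4]]),
        a4=np.array([[0.5, 0.3, -0.4, 0.35], [-0.3, 0.45, 0.5, -0.4]]),
        sigma_y=sigma_y,
        nu_c=8.0,
        cutoffs=[np.array([0.0]), np.array([0.0, 1.5])],
    )


def default_scenario(
    n: int,
    rng: np.random.Generator,
    true: TrueParams | None = None,
    approx: TApprox | None = None,
) -> tuple[ModelSpec, Dataset, TrueParams]:
    """Simulate the package's reference scenario.

    Two components formed from three-predictor blocks, two mediators, two
    continuous and two ordinal outcomes (binary and three-category), no
    covariates.  Pass ``true`` to override the default truth (topology must
    match).  The returned ``TrueParams`` carries the *standardized* weights
    actually used, so posterior draws compare against it directly.
    """
    if n < 20:
        raise ValueError("n must be at least 20")
    spec = ModelSpec(
        n_components=2,
        block_of=[0, 0, 0, 1, 1, 1],
        n_covariates=0,
        n_mediators=2,
        n_continuous=2,
        categories=[2, 3],
    )
    if true is None:
        true = _default_true(spec)
    if approx is None:
        approx = TApprox()

    x = generate_predictors(n, spec, true.sigma_x, rng)
    f, w_std = make_components(x, true.w, spec)
    true = replace(true, w=w_std)
    cov = np.zeros((n, 0))
    m = simulate_mediators(f, cov, true, rng)
    ycont, yord, _ = simulate_outcomes(f, cov, m, true, approx, rng)
    data = Dataset(x=x, cov=cov, m=m, ycont=ycont, yord=yord)
    return spec, data, true
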