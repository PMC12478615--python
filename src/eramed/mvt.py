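"""Student-t utilities and the logistic approximation used for ordinal outcomes.

The latent variables behind ordinal outcomes are modelled with a Student-t
error whose degrees of freedom and scale are chosen so that its marginal law
is numerically indistinguishable from the standard logistic.  Two constants
drive this: the df ``nu0`` (7.3 by default) and the variance-matching scale
``sigma0_sq``.  The same module houses the scale-mixture-of-normals helpers
(gamma precision draws) used by the Gibbs sampler, and the exact CDF-to-CDF
map that turns a variance-matched t variate into a logistic one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "LOGISTIC_VARIANCE",
    "TApprox",
    "DfParam",
    "logistic_matching_scale",
    "optimal_logistic_df",
    "sample_mixture_precision",
    "t_to_logistic",
]

#: Variance of the standard logistic distribution, pi^2 / 3.
LOGISTIC_VARIANCE = np.pi ** 2 / 3.0

#: Clamp bounds applied to CDF values before quantile inversion.
_CDF_EPS = 1e-12


def logistic_matching_scale(nu: float) -> float:
    """Scale variance making a t(nu) distribution match the logistic variance.

    Returns ``sigma_sq`` such that a Student-t with ``nu`` degrees of freedom
    and scale variance ``sigma_sq`` has total variance ``pi^2/3``, i.e.
    ``sigma_sq * nu / (nu - 2) = pi^2 / 3``.

    Parameters
    ----------
    nu : float
        Degrees of freedom; must exceed 2 for the t variance to exist.
    """
    if not np.isfinite(nu) or nu <= 2:
        raise ValueError(f"degrees of freedom must exceed 2, got {nu!r}")
    return LOGISTIC_VARIANCE * (nu - 2.0) / nu


def _squared_density_distance(nu: float, half_width: float = 40.0) -> float:
    """Integrated squared distance between the variance-matched t density
    and the standard-logistic density, by adaptive quadrature."""
    sd = np.sqrt(logistic_matching_scale(nu))

    def integrand(x: float) -> float:
        ft = stats.t.pdf(x / sd, df=nu) / sd
        fl = stats.logistic.pdf(x)
        return (ft - fl) ** 2

    # Both densities are symmetric; integrate the half line and double.
    val, _ = integrate.quad(integrand, 0.0, half_width, limit=200)
    if not np.isfinite(val):
        raise FloatingPointError("non-finite quadrature value in density distance")
    return 2.0 * val


def optimal_logistic_df(search_lo: float = 2.5, search_hi: float = 50.0) -> float:
    """Degrees of freedom minimizing the L2 distance to the standard logistic.

    For each candidate df the t scale is set by :func:`logistic_matching_scale`
    (so the variances agree), and the integrated squared difference between
    the two densities is minimized over ``(search_lo, search_hi)`` by bounded
    scalar optimization.  The minimizer is approximately 7.3.
    """
    if not (2.0 < search_lo < search_hi):
        raise ValueError("require 2 < search_lo < search_hi")
    res = optimize.minimize_scalar(
        _squared_density_distance,
        bounds=(search_lo, search_hi),
        method="bounded",
        options={"xatol": 1e-4},
    )
    if not res.success:  # pragma: no cover - bounded golden section rarely fails
        raise FloatingPointError(f"df optimization failed: {res.message}")
    return float(res.x)


@dataclass(frozen=True)
class TApprox:
    """Constants of the t approximation to the logistic latent scale.

    ``sigma0_sq`` defaults to the variance-matching value
    ``pi^2 (nu0 - 2) / (3 nu0)`` so that the scale-mixture latent marginal has
    the standard-logistic variance.
    """

    nu0: float = 7.3
    sigma0_sq: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nu0 <= 2:
            raise ValueError("nu0 must exceed 2")
        if self.sigma0_sq is None:
            object.__setattr__(self, "sigma0_sq", logistic_matching_scale(self.nu0))
        if self.sigma0_sq <= 0:
            raise ValueError("sigma0_sq must be positive")

    @property
    def sigma0(self) -> float:
        """Scale standard deviation, sqrt(sigma0_sq)."""
        return float(np.sqrt(self.sigma0_sq))


@dataclass(frozen=True)
class DfParam:
    """Unknown t degrees of freedom with a uniform prior on 1/nu.

    The prior interval on ``1/nu`` defaults to (0, 1]: 0 is the normal limit,
    1 the Cauchy.  The lower endpoint is open (nu stays finite).
    """

    nu: float
    prior_lo_inv: float = 0.0
    prior_hi_inv: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prior_lo_inv < self.prior_hi_inv <= 1.0):
            raise ValueError("require 0 <= prior_lo_inv < prior_hi_inv <= 1")
        inv = 1.0 / self.nu
        if not (self.prior_lo_inv < inv <= self.prior_hi_inv):
            raise ValueError(
                f"1/nu = {inv:.4g} outside prior support "
                f"({self.prior_lo_inv}, {self.prior_hi_inv}]"
            )


def sample_mixture_precision(
    nu: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Auxiliary precision draws of the normal scale mixture.

    phi ~ Gamma(shape=nu/2, rate=nu/2), so that N(mu, Sigma/phi) marginalizes
    to a multivariate t with ``nu`` degrees of freedom.  E(phi) = 1 and
    Var(phi) = 2/nu.
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    if n < 1:
        raise ValueError("n must be at least 1")
    return rng.gamma(shape=nu / 2.0, scale=2.0 / nu, size=n)


def t_to_logistic(z, nu: float, scale_sd: float):
    """Map a t(nu, scale_sd^2) variate to a standard-logistic one.

    Computes ``F_L^{-1}(T_nu(z / scale_sd))`` where ``T_nu`` is the Student-t
    CDF and ``F_L`` the standard-logistic CDF; strictly increasing in ``z``.
    CDF values are clamped away from {0, 1} before inversion (with a warning)
    to avoid infinite outputs in floating point.
    """
    if scale_sd <= 0:
        raise ValueError("scale_sd must be positive")
    z = np.asarray(z, dtype=float)
    # evaluate in the (floating-point accurate) lower tail and reflect, so
    # the map is exactly odd
    u = stats.t.cdf(-np.abs(z) / scale_sd, df=nu)
    if np.any(u <= _CDF_EPS):
        warnings.warn(
            "t CDF values at the floating-point boundary were clamped before "
            "logistic inversion",
            RuntimeWarning,
            stacklevel=2,
        )
        u = np.clip(u, _CDF_EPS, None)
    out = -np.sign(z) * stats.logistic.ppf(u)
    return out if out.ndim else float(out)
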