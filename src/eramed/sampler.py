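"""Gibbs-within-Metropolis sampler for ERA with mediators and mixed outcomes.

Model
-----
Component scores ``F = X W`` (block-sparse W, unit-variance columns) enter
two regressions:

* mediators:  ``m_i ~ N(a1 + A2' u_i, Sigma_M / phiM_i)`` with
  ``phiM_i ~ Gamma(nuM/2, nuM/2)`` (marginally multivariate t);
* responses:  the joint vector of continuous outcomes and ordinal latents
  ``y*_i ~ N(a0 + A3' u_i + A4' m_i, D_i Sigma_Y D_i)`` where
  ``D_i = diag(1/sqrt(phi1_i) 1_T, sigma0/sqrt(phi2_i) 1_{Q-T})``,
  ``phi1_i ~ Gamma(nuC/2, nuC/2)`` and ``phi2_i ~ Gamma(nu0/2, nu0/2)`` with
  ``nu0 = 7.3`` fixed.  Ordinal categories arise by cutting the latents at
  ordered cutpoints with the first fixed at zero.

Here ``u_i`` stacks covariates then components.  The per-subject precision
enters through the symmetric scaling ``D_i Sigma_Y D_i``, which preserves
the marginal multivariate-t law of each block.

Update cycle (one iteration)
----------------------------
1. free weights W from their joint normal conditional combining both
   likelihoods, then standardization + sign fix with compensating rescale of
   the component coefficient rows;
2. mediator block: (a1, A2) conjugate normal, Sigma_M^-1 Wishart, a
   group scale (parameter-expansion) move on (Sigma_M, phiM), phiM by
   per-subject log-scale Metropolis, nuM by Metropolis on 1/nu;
3. latent ordinal Z from univariate truncated-normal conditionals;
4. response block: (a0, A3, A4) conjugate normal, Sigma_Y^-1 Wishart,
   group scale move on (Sigma_Y, phi1, phi2), reduction of the ordinal
   latent scale to the identified sigma_qq = 1 coordinate system, free
   cutpoints from uniform conditionals, phi1/phi2 Metropolis, nuC
   Metropolis.

All randomness flows through a single ``numpy.random.Generator`` in the
fixed order above, so runs are bit-for-bit reproducible at a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import special, stats

from .model import (
    Dataset,
    MediatorParams,
    ModelSpec,
    PosteriorDraws,
    PriorConfig,
    ResponseParams,
    Weights,
    require_valid,
    standardize_weights,
)
from .mvt import TApprox

__all__ = [
    "McmcSettings",
    "SamplerState",
    "GibbsSampler",
    "fit",
    "update_covariance",
    "expand_scale",
    "metropolis_precision",
    "metropolis_df",
    "identified_rescale",
    "draw_coefficients",
]

_TRUNC_EPS = 1e-12


@dataclass(frozen=True)
class McmcSettings:
    """Chain length controls.  Defaults follow the reference analysis."""

    n_iter: int = 30_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class SamplerState:
    """All current parameter values plus bookkeeping counters."""

    weights: Weights
    f: np.ndarray                       # (N, K) standardized component scores
    med: MediatorParams | None
    resp: ResponseParams
    iteration: int = 0
    accept: dict = field(default_factory=dict)

    def count(self, name: str, accepted: float, trials: float) -> None:
        acc, tot = self.accept.get(name, (0.0, 0.0))
        self.accept[name] = (acc + accepted, tot + trials)

    def acceptance_rates(self) -> dict:
        return {k: (a / t if t else float("nan")) for k, (a, t) in self.accept.items()}


# ---------------------------------------------------------------------------
# reusable conditional-draw primitives
# ---------------------------------------------------------------------------

def _mvn_canonical(prec: np.ndarray, lin: np.ndarray, rng: np.random.Generator,
                   jitter: float = 1e-10) -> np.ndarray:
    """Draw from N(prec^-1 lin, prec^-1) via Cholesky, with jitter retry."""
    d = prec.shape[0]
    for attempt in range(4):
        try:
            chol = np.linalg.cholesky(prec + (jitter * 10 ** attempt * attempt) * np.eye(d))
        except np.linalg.LinAlgError:
            continue
        mean = sla.cho_solve((chol, True), lin)
        z = rng.standard_normal(d)
        return mean + sla.solve_triangular(chol, z, lower=True, trans="T")
    raise np.linalg.LinAlgError("singular conditional precision in coefficient draw")


def draw_coefficients(
    u: np.ndarray,
    y: np.ndarray,
    weights_qr: np.ndarray,
    sigma_inv: np.ndarray,
    prior: PriorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Joint normal draw of a multivariate-regression coefficient matrix.

    Model: rows ``y_i ~ N(B' u_i, P_i^-1)`` with per-subject precision
    ``P_i = diag(w_i) sigma_inv diag(w_i)`` where ``w_i`` is row i of
    ``weights_qr`` (sqrt precision multipliers, shape (N, Q); pass sqrt(phi)
    broadcast for an equicorrelated-precision block).  Prior: independent
    N(prior.coef_mean, prior.coef_var) on every entry of B ((U, Q)).

    With zero rows this returns a draw from the prior, which is how the
    prior-sampling tests exercise it.
    """
    n = u.shape[0]
    n_u = u.shape[1]
    n_q = sigma_inv.shape[0]
    s = weights_qr
    # Lambda[(q,u),(r,v)] = sigma_inv[q,r] * sum_i s_iq s_ir u_iu u_iv
    su = (s[:, :, None] * u[:, None, :]).reshape(n, n_q * n_u)
    m4 = (su.T @ su).reshape(n_q, n_u, n_q, n_u)
    lam = (m4 * sigma_inv[:, None, :, None]).reshape(n_q * n_u, n_q * n_u)
    lam[np.diag_indices_from(lam)] += 1.0 / prior.coef_var
    sy = (s * y) @ sigma_inv  # (N, Q): (sigma_inv (s*y)_i)_q
    lin = ((s * sy).T @ u).reshape(n_q * n_u)
    lin += prior.coef_mean / prior.coef_var
    b = _mvn_canonical(lam, lin, rng)
    return b.reshape(n_q, n_u).T  # (U, Q)


def update_covariance(
    residuals: np.ndarray,
    phi: np.ndarray | None,
    prior: PriorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a residual covariance from its Wishart full conditional.

    ``residuals`` is (N, d); ``phi`` is a per-subject precision multiplier
    (scalar column, shape (N,)) or per-subject-per-coordinate sqrt weights
    already applied (pass None).  The inverse covariance has prior
    Wishart(d + extra, I/(d + extra)); the posterior is Wishart on the
    precision-scaled residual scatter.  The draw is symmetrized and, if a
    rounding pushed it off the PD cone, jittered.
    """
    resid = np.asarray(residuals, dtype=float)
    d = resid.shape[1]
    scaled = resid if phi is None else resid * np.sqrt(np.asarray(phi))[:, None]
    df0 = prior.wishart_df(d)
    v0_inv = np.eye(d) * df0  # inverse of I/df0
    scatter = v0_inv + scaled.T @ scaled
    df_post = df0 + resid.shape[0]
    scale_post = np.linalg.inv(scatter)
    scale_post = 0.5 * (scale_post + scale_post.T)
    prec = stats.wishart.rvs(df=df_post, scale=scale_post, random_state=rng)
    prec = np.atleast_2d(prec)
    prec = 0.5 * (prec + prec.T)
    sigma = np.linalg.inv(prec)
    sigma = 0.5 * (sigma + sigma.T)
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:  # pragma: no cover - float-boundary safety
        sigma += 1e-10 * np.eye(d)
    return sigma


def expand_scale(
    sigma: np.ndarray,
    phis: list[tuple[np.ndarray, float]],
    prior: PriorConfig,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray, list[np.ndarray]]:
    """Parameter-expansion group move on the (Sigma, phi) scale orbit.

    The transformation ``Sigma -> Sigma/alpha``, ``phi -> phi/alpha`` leaves
    every likelihood term invariant, so a working scale ``alpha`` can be
    drawn from the conditional posterior along the orbit (a generalized
    inverse Gaussian under the Wishart and gamma priors) and applied.  This
    decouples the sticky total-scale direction and improves mixing.

    ``phis`` is a list of ``(phi_vector, nu)`` pairs sharing the orbit.
    Returns ``(alpha, sigma_new, [phi_new, ...])``.
    """
    d = sigma.shape[0]
    df0 = prior.wishart_df(d)
    prec = np.linalg.inv(sigma)
    # exponent of alpha in the orbit density (prior terms + Jacobians + Haar)
    a_exp = d * (df0 - d - 1) / 2.0 + d * (d + 1) / 2.0 - 1.0
    c = 0.0
    for phi, nu in phis:
        n_i = phi.shape[0]
        a_exp -= n_i * (nu / 2.0 - 1.0) + n_i
        c += (nu / 2.0) * float(np.sum(phi))
    b = 0.5 * float(np.trace((np.eye(d) * df0) @ prec))
    if c <= 0 or b <= 0:  # no phi mass on the orbit: nothing to move
        return 1.0, sigma, [phi for phi, _ in phis]
    p = a_exp + 1.0
    alpha = float(
        stats.geninvgauss.rvs(
            p, 2.0 * np.sqrt(b * c), scale=np.sqrt(c / b), random_state=rng
        )
    )
    return alpha, sigma / alpha, [phi / alpha for phi, _ in phis]


def metropolis_precision(
    phi: np.ndarray,
    log_target: "callable",
    step: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Per-subject random-walk Metropolis on log(phi).

    ``log_target(phi_vector)`` must return the per-subject log full
    conditional (up to constants).  Subjects are conditionally independent,
    so all are proposed and accepted/rejected in one vectorized sweep.  The
    log-scale proposal Jacobian is folded in via the +log(phi) term.
    Returns ``(phi_new, acceptance_fraction)``.
    """
    if step <= 0:
        raise ValueError("step size must be positive")
    prop = phi * np.exp(step * rng.standard_normal(phi.shape[0]))
    cur_lp = log_target(phi) + np.log(phi)
    new_lp = log_target(prop) + np.log(prop)
    log_u = np.log(rng.uniform(size=phi.shape[0]))
    accept = log_u < (new_lp - cur_lp)
    out = np.where(accept, prop, phi)
    return out, float(np.mean(accept)) if phi.size else 1.0


def metropolis_df(
    nu: float,
    phi: np.ndarray,
    prior: PriorConfig,
    step: float,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """Random-walk Metropolis on 1/nu with a uniform prior on its interval.

    The target is the product of the Gamma(nu/2, nu/2) densities of the
    current mixture precisions.  Proposals outside the (open-below) prior
    support are rejected outright.
    """
    lo, hi = prior.df_inv_range
    inv = 1.0 / nu
    prop_inv = inv + step * rng.standard_normal()
    # consume the uniform even on out-of-support proposals: keeps the draw
    # sequence aligned regardless of the proposal path
    log_u = np.log(rng.uniform())
    if not (lo < prop_inv <= hi):
        return nu, False
    prop_nu = 1.0 / prop_inv

    def loglik(v: float) -> float:
        h = v / 2.0
        return float(
            phi.shape[0] * (h * np.log(h) - special.gammaln(h))
            + (h - 1.0) * np.sum(np.log(phi))
            - h * np.sum(phi)
        )

    if log_u < loglik(prop_nu) - loglik(nu):
        return prop_nu, True
    return nu, False


def _truncated_normal(
    mean: np.ndarray,
    sd: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized inverse-CDF truncated-normal draws on (lo, hi]."""
    a = special.ndtr((lo - mean) / sd)
    b = special.ndtr((hi - mean) / sd)
    a = np.clip(a, 0.0, 1.0 - 2 * _TRUNC_EPS)
    b = np.clip(b, a + _TRUNC_EPS, 1.0)
    u = rng.uniform(a, b)
    u = np.clip(u, _TRUNC_EPS, 1.0 - _TRUNC_EPS)
    return mean + sd * special.ndtri(u)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class GibbsSampler:
    """One MCMC run on one dataset.  See the module docstring for the cycle.

    Parameters
    ----------
    pin : dict, optional
        Pins for oracle tests: ``{"w": array}`` fixes the (standardized)
        weights, ``{"phi": value}`` pins every mixture precision,
        ``{"sigma_y": array}``/``{"sigma_m": array}`` pin covariances,
        ``{"nu_c": v}``/``{"nu_m": v}`` pin degrees of freedom.
    include_mediators : bool
        With False, fits the response model without the mediator term (the
        comparison model); the mediator block is skipped entirely.
    """

    def __init__(
        self,
        data: Dataset,
        spec: ModelSpec,
        priors: PriorConfig | None = None,
        settings: McmcSettings | None = None,
        approx: TApprox | None = None,
        include_mediators: bool = True,
        pin: dict | None = None,
    ) -> None:
        require_valid(spec, data)
        self.data = data
        self.spec = spec
        self.priors = priors or PriorConfig()
        self.settings = settings or McmcSettings()
        self.approx = approx or TApprox()
        self.include_mediators = bool(include_mediators)
        self.pin = dict(pin or {})
        self.rng = np.random.default_rng(self.settings.seed)

        self.n = data.n
        self.n_ord = spec.n_ordinal
        self.t_cont = spec.n_continuous
        self.q_tot = spec.n_outcomes
        self._ord_slice = slice(self.t_cont, self.q_tot)

    # -- initialization -----------------------------------------------------

    def init_state(self) -> SamplerState:
        """Initial values: prior-centred draws, standardized weights, latent
        midpoints.  Coefficients start at unit-scale draws around the prior
        mean (the literal flat-prior scale would be numerically wasteful)."""
        rng, spec, pr = self.rng, self.spec, self.priors
        n, n_ord = self.n, self.n_ord

        if "w" in self.pin:
            w = np.asarray(self.pin["w"], dtype=float)
            f, w_std, _ = standardize_weights(self.data.x, w, spec)
        else:
            free = rng.standard_normal(spec.n_predictors)
            f, w_std, _ = standardize_weights(
                self.data.x, Weights.from_free(free, spec).w, spec
            )
        weights = Weights(w_std)

        cscale = min(1.0, np.sqrt(pr.coef_var))

        def coef(*shape):
            return pr.coef_mean + cscale * rng.standard_normal(shape)

        lo, hi = pr.df_inv_range

        def draw_nu() -> float:
            return 1.0 / max(rng.uniform(lo, hi), 1e-3)

        def prior_sigma(d: int) -> np.ndarray:
            prec = np.atleast_2d(
                stats.wishart.rvs(pr.wishart_df(d), pr.wishart_scale(d), random_state=rng)
            )
            return np.linalg.inv(0.5 * (prec + prec.T))

        phi_pin = float(self.pin["phi"]) if "phi" in self.pin else None

        med = None
        if self.include_mediators:
            nu_m = float(self.pin.get("nu_m", draw_nu()))
            sigma_m = np.asarray(
                self.pin.get("sigma_m", prior_sigma(spec.n_mediators)), dtype=float
            )
            phi_m = (
                np.full(n, phi_pin)
                if phi_pin is not None
                else rng.gamma(nu_m / 2.0, 2.0 / nu_m, size=n)
            )
            med = MediatorParams(
                a1=coef(spec.n_mediators),
                a2=coef(spec.n_regressors, spec.n_mediators),
                sigma_m=sigma_m,
                nu_m=nu_m,
                phi_m=phi_m,
            )

        nu_c = float(self.pin.get("nu_c", draw_nu()))
        sigma_y = np.asarray(
            self.pin.get("sigma_y", prior_sigma(self.q_tot)), dtype=float
        )
        phi1 = (
            np.full(n, phi_pin)
            if phi_pin is not None
            else rng.gamma(nu_c / 2.0, 2.0 / nu_c, size=n)
        )
        nu0 = self.approx.nu0
        phi2 = (
            np.full(n, phi_pin)
            if phi_pin is not None
            else rng.gamma(nu0 / 2.0, 2.0 / nu0, size=n)
        )
        cutpoints = [
            np.concatenate([[0.0], 0.8 * (1 + np.arange(j - 2))])
            for j in spec.categories
        ]
        z = np.zeros((n, n_ord))
        for j in range(n_ord):
            g = cutpoints[j]
            cat = self.data.yord[:, j]
            lo_b = np.where(cat >= 2, g[np.clip(cat - 2, 0, None)], -np.inf)
            hi_b = np.where(
                cat <= len(g), g[np.clip(cat - 1, 0, len(g) - 1)], np.inf
            )
            mid = np.where(
                np.isinf(lo_b),
                hi_b - 0.5,
                np.where(np.isinf(hi_b), lo_b + 0.5, 0.5 * (lo_b + hi_b)),
            )
            z[:, j] = mid
        resp = ResponseParams(
            a0=coef(self.q_tot),
            a3=coef(spec.n_regressors, self.q_tot),
            a4=(
                coef(spec.n_mediators, self.q_tot)
                if self.include_mediators
                else np.zeros((spec.n_mediators, self.q_tot))
            ),
            sigma_y=sigma_y,
            nu_c=nu_c,
            phi1=phi1,
            phi2=phi2,
            cutpoints=cutpoints,
            z=z,
        )
        if "sigma_y" not in self.pin:
            self._reduce_ordinal_scale(resp)
        return SamplerState(weights=weights, f=f, med=med, resp=resp)

    # -- shared pieces ------------------------------------------------------

    def _sqrt_lambda(self, resp: ResponseParams) -> np.ndarray:
        """(N, Q) square roots of the per-subject precision multipliers."""
        s = np.empty((self.n, self.q_tot))
        s[:, : self.t_cont] = np.sqrt(resp.phi1)[:, None]
        s[:, self._ord_slice] = np.sqrt(resp.phi2 / self.approx.sigma0_sq)[:, None]
        return s

    def _y_star(self, resp: ResponseParams) -> np.ndarray:
        return np.hstack([self.data.ycont, resp.z])

    def _u_resp(self, state: SamplerState) -> np.ndarray:
        cols = [np.ones((self.n, 1)), self.data.cov, state.f]
        if self.include_mediators:
            cols.append(self.data.m)
        return np.hstack(cols)

    def _resp_mean(self, state: SamplerState) -> np.ndarray:
        resp = state.resp
        mean = resp.a0 + self.data.cov @ resp.a3[: self.spec.n_covariates] + \
            state.f @ resp.a3[self.spec.n_covariates:]
        if self.include_mediators:
            mean = mean + self.data.m @ resp.a4
        return mean

    def _med_mean(self, state: SamplerState) -> np.ndarray:
        med = state.med
        return med.a1 + self.data.cov @ med.a2[: self.spec.n_covariates] + \
            state.f @ med.a2[self.spec.n_covariates:]

    # -- update operations --------------------------------------------------

    def update_weights(self, state: SamplerState) -> None:
        """Draw the free weights from their joint normal conditional, then
        standardize and rescale the attached coefficient rows."""
        if "w" in self.pin:
            return
        free = self._draw_free_weights(state)
        w = Weights.from_free(free, self.spec).w
        f, w_std, scale = standardize_weights(self.data.x, w, self.spec)
        c = self.spec.n_covariates
        if state.med is not None:
            state.med.a2[c:] *= scale[:, None]
        state.resp.a3[c:] *= scale[:, None]
        state.weights = Weights(w_std)
        state.f = f

    def _draw_free_weights(self, state: SamplerState) -> np.ndarray:
        """Unstandardized draw of the P free weights (prior if N = 0)."""
        spec, pr = self.spec, self.priors
        x = self.data.x
        c = spec.n_covariates
        blk = np.asarray(spec.block_of)
        p = spec.n_predictors

        lam = np.eye(p) / pr.weight_var
        lin = np.zeros(p)

        if state.med is not None:
            a2p = state.med.a2[c:][blk]          # (P, R): component rows per predictor
            sig_inv = np.linalg.inv(state.med.sigma_m)
            xw = x * state.med.phi_m[:, None]
            lam += (x.T @ xw) * (a2p @ sig_inv @ a2p.T)
            m_t = self.data.m - state.med.a1 - self.data.cov @ state.med.a2[:c]
            lin += np.sum(xw * (m_t @ sig_inv @ a2p.T), axis=0)

        resp = state.resp
        a3p = resp.a3[c:][blk]                   # (P, Q)
        sig_inv = np.linalg.inv(resp.sigma_y)
        s = self._sqrt_lambda(resp)
        y_t = self._y_star(resp) - resp.a0 - self.data.cov @ resp.a3[:c]
        if self.include_mediators:
            y_t = y_t - self.data.m @ resp.a4
        # Lambda_resp[p,P] = sum_i x_ip x_iP (a3p diag(s_i) sig_inv diag(s_i) a3p')[p,P]
        n, p_dim, q_dim = x.shape[0], x.shape[1], s.shape[1]
        xs = (x[:, :, None] * s[:, None, :]).reshape(n, p_dim * q_dim)
        t4 = (xs.T @ xs).reshape(p_dim, q_dim, p_dim, q_dim)
        lam += np.einsum("pq,Pr,qr,pqPr->pP", a3p, a3p, sig_inv, t4)
        sy = (s * y_t) @ sig_inv
        lin += np.sum(x * ((s * sy) @ a3p.T), axis=0)
        return _mvn_canonical(lam, lin, self.rng)

    def update_mediator_block(self, state: SamplerState) -> None:
        med, pr = state.med, self.priors
        u = np.hstack([np.ones((self.n, 1)), self.data.cov, state.f])
        sig_inv = np.linalg.inv(med.sigma_m)
        b = draw_coefficients(
            u, self.data.m, np.sqrt(med.phi_m)[:, None] * np.ones((1, self.spec.n_mediators)),
            sig_inv, pr, self.rng,
        )
        med.a1 = b[0]
        med.a2 = b[1:]

        resid = self.data.m - self._med_mean(state)
        if "sigma_m" not in self.pin:
            med.sigma_m = update_covariance(resid, med.phi_m, pr, self.rng)
            if "phi" not in self.pin:
                _, med.sigma_m, (med.phi_m,) = expand_scale(
                    med.sigma_m, [(med.phi_m, med.nu_m)], pr, self.rng
                )

        if "phi" not in self.pin:
            sig_inv = np.linalg.inv(med.sigma_m)
            quad = np.sum((resid @ sig_inv) * resid, axis=1)
            r_dim = self.spec.n_mediators
            nu = med.nu_m

            def log_target(phi):
                return (nu / 2.0 - 1.0 + r_dim / 2.0) * np.log(phi) - phi * (
                    nu / 2.0 + quad / 2.0
                )

            med.phi_m, rate = metropolis_precision(
                med.phi_m, log_target, pr.step_precision, self.rng
            )
            state.count("phi_m", rate * self.n, self.n)

        if "nu_m" not in self.pin and "phi" not in self.pin:
            med.nu_m, acc = metropolis_df(
                med.nu_m, med.phi_m, pr, pr.step_df_inv, self.rng
            )
            state.count("nu_m", float(acc), 1.0)

    def update_latent_ordinal(self, state: SamplerState) -> None:
        """Truncated-normal refresh of every latent ordinal variable."""
        if self.n_ord == 0:
            return
        resp = state.resp
        sig_inv = np.linalg.inv(resp.sigma_y)
        s = self._sqrt_lambda(resp)
        mean = self._resp_mean(state)
        e = self._y_star(resp) - mean
        for j in range(self.n_ord):
            qj = self.t_cont + j
            g = resp.cutpoints[j]
            cat = self.data.yord[:, j]
            lo = np.where(cat >= 2, g[np.clip(cat - 2, 0, None)], -np.inf)
            hi = np.where(cat <= len(g), g[np.clip(cat - 1, 0, len(g) - 1)], np.inf)
            cond_prec = (s[:, qj] ** 2) * sig_inv[qj, qj]
            cross = (s * e) @ sig_inv[:, qj] - (s[:, qj] * e[:, qj]) * sig_inv[qj, qj]
            cond_mean = mean[:, qj] - cross / (s[:, qj] * sig_inv[qj, qj])
            z_new = _truncated_normal(
                cond_mean, 1.0 / np.sqrt(cond_prec), lo, hi, self.rng
            )
            resp.z[:, j] = z_new
            e[:, qj] = z_new - mean[:, qj]

    def update_response_block(self, state: SamplerState) -> None:
        resp, pr = state.resp, self.priors
        u = self._u_resp(state)
        s = self._sqrt_lambda(resp)
        sig_inv = np.linalg.inv(resp.sigma_y)
        b = draw_coefficients(u, self._y_star(resp), s, sig_inv, pr, self.rng)
        c, k, r = self.spec.n_covariates, self.spec.n_components, self.spec.n_mediators
        resp.a0 = b[0]
        resp.a3 = b[1: 1 + c + k]
        if self.include_mediators:
            resp.a4 = b[1 + c + k:]

        resid = self._y_star(resp) - self._resp_mean(state)
        if "sigma_y" not in self.pin:
            resp.sigma_y = update_covariance(resid * s, None, pr, self.rng)
            if "phi" not in self.pin:
                phis = []
                if self.t_cont:
                    phis.append((resp.phi1, resp.nu_c))
                if self.n_ord:
                    phis.append((resp.phi2, self.approx.nu0))
                _, resp.sigma_y, new_phis = expand_scale(
                    resp.sigma_y, phis, pr, self.rng
                )
                idx = 0
                if self.t_cont:
                    resp.phi1 = new_phis[idx]
                    idx += 1
                if self.n_ord:
                    resp.phi2 = new_phis[idx]
            self._reduce_ordinal_scale(resp)

        self._update_cutpoints(resp)

        if "phi" not in self.pin:
            self._update_precisions(state)
        if "nu_c" not in self.pin and "phi" not in self.pin and self.t_cont:
            resp.nu_c, acc = metropolis_df(
                resp.nu_c, resp.phi1, pr, pr.step_df_inv, self.rng
            )
            state.count("nu_c", float(acc), 1.0)

    def _reduce_ordinal_scale(self, resp: ResponseParams) -> None:
        """Map back to the identified coordinate system: unit latent residual
        variance (sigma_qq = 1) for every ordinal outcome, rescaling the
        latents, cutpoints and attached coefficient columns accordingly."""
        for j in range(self.n_ord):
            qj = self.t_cont + j
            sd = np.sqrt(resp.sigma_y[qj, qj])
            if abs(sd - 1.0) < 1e-14:
                continue
            resp.z[:, j] /= sd
            resp.cutpoints[j] = resp.cutpoints[j] / sd
            resp.a0[qj] /= sd
            resp.a3[:, qj] /= sd
            resp.a4[:, qj] /= sd
            resp.sigma_y[qj, :] /= sd
            resp.sigma_y[:, qj] /= sd

    def _update_cutpoints(self, resp: ResponseParams) -> None:
        """Free cutpoints from their uniform full conditionals (first fixed
        at zero; binary outcomes have none)."""
        for j in range(self.n_ord):
            g = resp.cutpoints[j]
            if len(g) < 2:
                continue
            z = resp.z[:, j]
            cat = self.data.yord[:, j]
            for t in range(1, len(g)):
                below = z[cat == t + 1]  # category with right endpoint g[t]
                above = z[cat == t + 2] if t + 2 <= len(g) + 1 else np.empty(0)
                lo = max(g[t - 1], below.max() if below.size else -np.inf)
                hi = min(
                    g[t + 1] if t + 1 < len(g) else np.inf,
                    above.min() if above.size else np.inf,
                )
                if not np.isfinite(hi):
                    hi = lo + 2.0  # unbounded above: cap the flat conditional
                if hi > lo:
                    g[t] = self.rng.uniform(lo, hi)
            resp.cutpoints[j] = g

    def _update_precisions(self, state: SamplerState) -> None:
        resp, pr = state.resp, self.priors
        resid = self._y_star(resp) - self._resp_mean(state)
        sig_inv = np.linalg.inv(resp.sigma_y)
        t_cont, n_ord = self.t_cont, self.n_ord
        s0sq = self.approx.sigma0_sq

        def quad(phi1, phi2):
            s = np.empty((self.n, self.q_tot))
            if t_cont:
                s[:, :t_cont] = np.sqrt(phi1)[:, None]
            if n_ord:
                s[:, self._ord_slice] = np.sqrt(phi2 / s0sq)[:, None]
            sr = s * resid
            return np.sum((sr @ sig_inv) * sr, axis=1)

        if t_cont:
            nu = resp.nu_c

            def lt1(phi):
                return (
                    (nu / 2.0 - 1.0 + t_cont / 2.0) * np.log(phi)
                    - (nu / 2.0) * phi
                    - 0.5 * quad(phi, resp.phi2)
                )

            resp.phi1, rate = metropolis_precision(
                resp.phi1, lt1, pr.step_precision, self.rng
            )
            state.count("phi1", rate * self.n, self.n)

        if n_ord:
            nu0 = self.approx.nu0

            def lt2(phi):
                return (
                    (nu0 / 2.0 - 1.0 + n_ord / 2.0) * np.log(phi)
                    - (nu0 / 2.0) * phi
                    - 0.5 * quad(resp.phi1, phi)
                )

            resp.phi2, rate = metropolis_precision(
                resp.phi2, lt2, pr.step_precision, self.rng
            )
            state.count("phi2", rate * self.n, self.n)

    # -- main loop ----------------------------------------------------------

    def step(self, state: SamplerState) -> None:
        """One full update cycle in the documented order."""
        self.update_weights(state)
        if self.include_mediators:
            self.update_mediator_block(state)
        self.update_latent_ordinal(state)
        self.update_response_block(state)
        state.iteration += 1

    def run(self) -> PosteriorDraws:
        spec, st = self.spec, self.settings
        state = self.init_state()
        n_keep = st.n_retained
        keep = {
            "w": np.empty((n_keep, spec.n_predictors, spec.n_components)),
            "a0": np.empty((n_keep, self.q_tot)),
            "a3": np.empty((n_keep, spec.n_regressors, self.q_tot)),
            "sigma_y": np.empty((n_keep, self.q_tot, self.q_tot)),
            "nu_c": np.empty(n_keep),
        }
        gamma = [np.empty((n_keep, j - 1)) for j in spec.categories]
        if self.include_mediators:
            keep.update(
                a1=np.empty((n_keep, spec.n_mediators)),
                a2=np.empty((n_keep, spec.n_regressors, spec.n_mediators)),
                sigma_m=np.empty((n_keep, spec.n_mediators, spec.n_mediators)),
                nu_m=np.empty(n_keep),
                a4=np.empty((n_keep, spec.n_mediators, self.q_tot)),
            )
        pos = 0
        for it in range(st.n_iter):
            self.step(state)
            done = it + 1
            if done > st.burn_in and (done - st.burn_in) % st.thin == 0:
                keep["w"][pos] = state.weights.w
                keep["a0"][pos] = state.resp.a0
                keep["a3"][pos] = state.resp.a3
                keep["sigma_y"][pos] = state.resp.sigma_y
                keep["nu_c"][pos] = state.resp.nu_c
                for j in range(self.n_ord):
                    gamma[j][pos] = state.resp.cutpoints[j]
                if self.include_mediators:
                    keep["a1"][pos] = state.med.a1
                    keep["a2"][pos] = state.med.a2
                    keep["sigma_m"][pos] = state.med.sigma_m
                    keep["nu_m"][pos] = state.med.nu_m
                    keep["a4"][pos] = state.resp.a4
                pos += 1
                if pos % 200 == 0:
                    self._check_finite(state)
        self._check_finite(state)
        return PosteriorDraws(
            spec=spec,
            gamma=gamma,
            n_iter=st.n_iter,
            burn_in=st.burn_in,
            thin=st.thin,
            seed=st.seed,
            acceptance=state.acceptance_rates(),
            identified="sigma_y" not in self.pin,
            **keep,
        )

    def _check_finite(self, state: SamplerState) -> None:
        pieces = [state.weights.w, state.resp.a0, state.resp.a3, state.resp.sigma_y]
        if state.med is not None:
            pieces += [state.med.a2, state.med.sigma_m]
        for arr in pieces:
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(
                    f"sampler diverged at iteration {state.iteration}: "
                    f"non-finite values in state"
                )


def fit(
    data: Dataset,
    spec: ModelSpec,
    priors: PriorConfig | None = None,
    settings: McmcSettings | None = None,
    approx: TApprox | None = None,
    include_mediators: bool = True,
    pin: dict | None = None,
) -> PosteriorDraws:
    """Run the full MCMC and return retained, thinned posterior draws."""
    sampler = GibbsSampler(
        data,
        spec,
        priors=priors,
        settings=settings,
        approx=approx,
        include_mediators=include_mediators,
        pin=pin,
    )
    return sampler.run()


def identified_rescale(draws: PosteriorDraws) -> PosteriorDraws:
    """Rescale stored draws to the identified ordinal coordinate system.

    Divides ordinal-outcome intercepts, coefficient columns and cutpoints by
    the latent residual standard deviation of that outcome per draw, and
    normalizes the corresponding rows/columns of Sigma_Y to unit diagonal.
    Idempotent: draws already marked identified are returned unchanged.
    """
    if draws.identified:
        return draws
    spec = draws.spec
    t_cont = spec.n_continuous
    out = PosteriorDraws(
        spec=spec,
        w=draws.w.copy(),
        a0=draws.a0.copy(),
        a3=draws.a3.copy(),
        sigma_y=draws.sigma_y.copy(),
        nu_c=draws.nu_c.copy(),
        gamma=[g.copy() for g in draws.gamma],
        a1=None if draws.a1 is None else draws.a1.copy(),
        a2=None if draws.a2 is None else draws.a2.copy(),
        sigma_m=None if draws.sigma_m is None else draws.sigma_m.copy(),
        nu_m=None if draws.nu_m is None else draws.nu_m.copy(),
        a4=None if draws.a4 is None else draws.a4.copy(),
        n_iter=draws.n_iter,
        burn_in=draws.burn_in,
        thin=draws.thin,
        seed=draws.seed,
        acceptance=dict(draws.acceptance),
        identified=True,
    )
    for j in range(spec.n_ordinal):
        qj = t_cont + j
        sd = np.sqrt(out.sigma_y[:, qj, qj])
        out.a0[:, qj] /= sd
        out.a3[:, :, qj] /= sd[:, None]
        if out.a4 is not None:
            out.a4[:, :, qj] /= sd[:, None]
        out.gamma[j] /= sd[:, None]
        out.sigma_y[:, qj, :] /= sd[:, None]
        out.sigma_y[:, :, qj] /= sd[:, None]
    return out
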