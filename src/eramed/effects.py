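"""Mediation-effect computation and posterior summarization.

Indirect effects are the per-draw products of mediator-model coefficients
(source -> mediator) with response-model coefficients (mediator -> outcome):
no new randomness, just elementwise products over retained draws.  The
difference method contrasts the source -> outcome coefficients of a fit
without mediators against the fit with mediators.  ``summarize`` reduces
per-draw arrays to posterior means and equal-tailed credible intervals,
optionally on the odds-ratio scale (exponentiating each draw first) for
ordinal outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PosteriorDraws

__all__ = [
    "EffectSummary",
    "indirect_effects",
    "direct_effects",
    "total_effects",
    "difference_method",
    "summarize",
    "effect_table",
]


@dataclass(frozen=True)
class EffectSummary:
    """Posterior summary of one effect path."""

    label: str
    mean: float
    lo: float
    hi: float
    level: float
    scale: str = "raw"  # "raw" | "odds-ratio"

    @property
    def significant(self) -> bool:
        """CI excludes the null (0 on raw scale, 1 on odds-ratio scale)."""
        null = 1.0 if self.scale == "odds-ratio" else 0.0
        return not (self.lo <= null <= self.hi)


def indirect_effects(draws: PosteriorDraws) -> np.ndarray:
    """Per-draw indirect effects a2[s, m] * a4[m, q].

    Returns an array of shape ``(n_draws, S, R, Q)`` where S runs over the
    rows of A2 (covariates then components).  Requires a fit with mediators.
    """
    if draws.a2 is None or draws.a4 is None:
        raise ValueError("draws do not contain mediator coefficients (a2, a4)")
    if draws.a2.shape[2] != draws.a4.shape[1]:
        raise ValueError("mismatched mediator dimensions between a2 and a4")
    return draws.a2[:, :, :, None] * draws.a4[:, None, :, :]


def direct_effects(draws: PosteriorDraws) -> np.ndarray:
    """Per-draw direct effects: the A3 rows, shape (n_draws, S, Q)."""
    return draws.a3


def total_effects(draws: PosteriorDraws) -> np.ndarray:
    """Per-draw total effects: direct plus indirect summed over mediators."""
    return draws.a3 + indirect_effects(draws).sum(axis=2)


def difference_method(
    draws_full: PosteriorDraws, draws_nomed: PosteriorDraws
) -> np.ndarray:
    """Per-draw coefficient difference between the no-mediator and the
    with-mediator fits, shape (n_draws, S, Q).

    Both runs must share the model spec.  Chains are independent, so pairing
    by draw index is an approximation (documented); unequal retained counts
    are truncated to the shorter run.
    """
    if draws_full.spec != draws_nomed.spec:
        raise ValueError("fits were made under different model specs")
    d = min(draws_full.n_draws, draws_nomed.n_draws)
    return draws_nomed.a3[:d] - draws_full.a3[:d]


def summarize(
    samples: np.ndarray,
    level: float = 0.95,
    as_odds_ratio: bool = False,
    labels: list[str] | None = None,
) -> list[EffectSummary]:
    """Posterior mean and equal-tailed interval for each trailing path.

    ``samples`` has the draw axis first; remaining axes index paths.  With
    ``as_odds_ratio`` every draw is exponentiated before summarizing.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 draws to summarize")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    flat = samples.reshape(samples.shape[0], -1)
    scale = "raw"
    if as_odds_ratio:
        flat = np.exp(flat)
        scale = "odds-ratio"
    alpha = (1.0 - level) / 2.0
    mean = flat.mean(axis=0)
    lo = np.quantile(flat, alpha, axis=0)
    hi = np.quantile(flat, 1.0 - alpha, axis=0)
    if labels is None:
        labels = [
            "[" + ",".join(map(str, idx)) + "]"
            for idx in np.ndindex(samples.shape[1:])
        ]
    return [
        EffectSummary(label=l, mean=float(m), lo=float(a), hi=float(b),
                      level=level, scale=scale)
        for l, m, a, b in zip(labels, mean, lo, hi)
    ]


def effect_table(draws: PosteriorDraws, level: float = 0.95,
                 odds_ratio_ordinal: bool = True):
    """Tidy per-path summary of direct, indirect and total effects.

    Returns a pandas DataFrame with one row per path: columns ``path``,
    ``source``, ``mediator``, ``outcome``, ``mean``, ``lo``, ``hi``,
    ``scale``, ``significant``.  Ordinal-outcome paths are reported on the
    odds-ratio scale when ``odds_ratio_ordinal`` is set.
    """
    import pandas as pd

    spec = draws.spec
    t_cont = spec.n_continuous
    src_names = [f"cov{c+1}" for c in range(spec.n_covariates)] + [
        f"F{k+1}" for k in range(spec.n_components)
    ]
    out_names = [f"Y{q+1}" for q in range(spec.n_outcomes)]
    rows = []

    def add(kind, samples, s, med, q):
        as_or = odds_ratio_ordinal and q >= t_cont
        (summ,) = summarize(samples, level=level, as_odds_ratio=as_or,
                            labels=[kind])
        rows.append(
            dict(path=kind, source=src_names[s],
                 mediator=med, outcome=out_names[q],
                 mean=summ.mean, lo=summ.lo, hi=summ.hi,
                 scale=summ.scale, significant=summ.significant)
        )

    a3 = direct_effects(draws)
    for s in range(a3.shape[1]):
        for q in range(a3.shape[2]):
            add("direct", a3[:, s, q], s, "", q)
    if draws.has_mediators:
        ind = indirect_effects(draws)
        for s in range(ind.shape[1]):
            for m in range(ind.shape[2]):
                for q in range(ind.shape[3]):
                    add("indirect", ind[:, s, m, q], s, f"M{m+1}", q)
        tot = total_effects(draws)
        for s in range(tot.shape[1]):
            for q in range(tot.shape[2]):
                add("total", tot[:, s, q], s, "", q)
    return pd.DataFrame(rows)
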