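"""Convergence diagnostics on retained draws.

Parameters are addressed by name strings like ``"a3[1,0]"`` or ``"nu_c"``;
``trace`` returns the retained series in iteration order, ``ess_geweke``
computes an autocorrelation-sum effective sample size and a Geweke z score
comparing the first 10% against the last 50% of the chain.
"""

from __future__ import annotations

import re

import numpy as np

from .model import PosteriorDraws

__all__ = ["trace", "ess_geweke", "ess", "geweke_z", "parameter_names"]

_NAME_RE = re.compile(r"^([a-zA-Z0-9_]+)(?:\[([\d,\s]+)\])?$")


def _array_fields(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    fields = {
        "w": draws.w, "a0": draws.a0, "a3": draws.a3,
        "sigma_y": draws.sigma_y, "nu_c": draws.nu_c,
    }
    for name in ("a1", "a2", "sigma_m", "nu_m", "a4"):
        val = getattr(draws, name)
        if val is not None:
            fields[name] = val
    for j, g in enumerate(draws.gamma):
        fields[f"gamma{j}"] = g
    return fields


def parameter_names(draws: PosteriorDraws) -> list[str]:
    """All addressable scalar parameter names."""
    names = []
    for base, arr in _array_fields(draws).items():
        if arr.ndim == 1:
            names.append(base)
        else:
            for idx in np.ndindex(arr.shape[1:]):
                names.append(base + "[" + ",".join(map(str, idx)) + "]")
    return names


def trace(draws: PosteriorDraws, name: str) -> np.ndarray:
    """Retained-draw series of one scalar parameter, in iteration order.

    Retained index ``d`` corresponds to iteration
    ``burn_in + (d + 1) * thin`` of the original chain.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise KeyError(f"cannot parse parameter name {name!r}")
    base, idx = m.group(1), m.group(2)
    fields = _array_fields(draws)
    if base not in fields:
        raise KeyError(f"unknown parameter {base!r}")
    arr = fields[base]
    if idx is None:
        if arr.ndim != 1:
            raise KeyError(f"parameter {base!r} needs an index, e.g. {base}[0,0]")
        return np.asarray(arr)
    ix = tuple(int(t) for t in idx.split(","))
    if len(ix) != arr.ndim - 1:
        raise KeyError(f"index {idx!r} has wrong arity for {base!r}")
    return np.asarray(arr[(slice(None),) + ix])


def ess(series: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator.

    Autocorrelations are computed by FFT; the sum is truncated at the first
    lag pair whose sum of adjacent autocorrelations goes nonpositive
    (Geyer's initial positive sequence).  Returns NaN for a zero-variance
    series.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("series too short for ESS")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return float("nan")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # pair consecutive lags (1,2), (3,4), ... and stop at first nonpositive
    tau = 1.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(n / tau)


def geweke_z(series: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    Means of the first ``first`` and last ``last`` fractions are compared,
    with segment variances adjusted by each segment's ESS.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    a = x[: max(int(first * n), 4)]
    b = x[-max(int(last * n), 4):]
    va = np.var(a, ddof=1) / max(ess(a), 1.0)
    vb = np.var(b, ddof=1) / max(ess(b), 1.0)
    denom = np.sqrt(va + vb)
    if denom == 0 or not np.isfinite(denom):
        return float("nan")
    return float((a.mean() - b.mean()) / denom)


def ess_geweke(draws: PosteriorDraws, name: str) -> dict:
    """ESS and Geweke z for one parameter; NaNs for degenerate series."""
    series = trace(draws, name)
    if series.shape[0] < 100:
        raise ValueError("need at least 100 draws for diagnostics")
    return {"ess": ess(series), "geweke_z": geweke_z(series)}
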