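"""File I/O glue: headered-CSV data matrices, draw tables, run manifests.

The interchange format is plain CSV (UTF-8, '.' decimal).  Draw tables are
wide — one row per retained draw, systematic column names like ``a3[0,1]``
or ``gamma0[1]`` — so they round-trip losslessly and stay human-greppable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Dataset, ModelSpec, PosteriorDraws
from .simulate import TrueParams

__all__ = [
    "RunManifest",
    "read_dataset",
    "write_dataset",
    "write_draws",
    "read_draws",
    "write_true_params",
]

_FILES = {"x": "X.csv", "cov": "Cov.csv", "m": "M.csv",
          "ycont": "Ycont.csv", "yord": "Yord.csv"}


@dataclass
class RunManifest:
    """Settings echo and provenance for one fit, serialized beside outputs."""

    settings: dict
    seed: int | None
    wall_time_s: float
    acceptance: dict
    package_version: str
    data_checksums: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, rate in self.acceptance.items():
            if np.isfinite(rate) and not (0.0 <= rate <= 1.0):
                raise ValueError(f"acceptance rate {name}={rate} outside [0, 1]")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=float)

    @classmethod
    def from_fit(cls, draws: PosteriorDraws, wall_time_s: float,
                 data_dir=None) -> "RunManifest":
        from . import __version__

        checksums = {}
        if data_dir is not None:
            for f in sorted(Path(data_dir).glob("*.csv")):
                checksums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        return cls(
            settings={"n_iter": draws.n_iter, "burn_in": draws.burn_in,
                      "thin": draws.thin},
            seed=draws.seed,
            wall_time_s=wall_time_s,
            acceptance=draws.acceptance,
            package_version=__version__,
            data_checksums=checksums,
        )


def _read_matrix(path: Path, name: str, as_int: bool = False) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing data file for {name}: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        raise ValueError(
            f"missing value in {path.name} at row {rows[0] + 1}, "
            f"column {df.columns[cols[0]]!r}"
        )
    try:
        arr = df.to_numpy(dtype=int if as_int else float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path.name}: {exc}") from exc
    return arr


def read_dataset(data_dir, spec: ModelSpec) -> Dataset:
    """Load the five data CSVs of a directory into a :class:`Dataset`.

    Empty blocks (no covariates, etc.) may have a missing file or a
    zero-column CSV.
    """
    d = Path(data_dir)
    n = None

    def load(key, width, as_int=False):
        nonlocal n
        path = d / _FILES[key]
        if width == 0 and not path.exists():
            return np.zeros((n or 0, 0))
        arr = _read_matrix(path, key, as_int=as_int)
        if n is None:
            n = arr.shape[0]
        return arr

    x = load("x", spec.n_predictors)
    return Dataset(
        x=x,
        cov=load("cov", spec.n_covariates),
        m=load("m", spec.n_mediators),
        ycont=load("ycont", spec.n_continuous),
        yord=load("yord", spec.n_ordinal, as_int=True),
    )


def write_dataset(data: Dataset, data_dir) -> None:
    d = Path(data_dir)
    d.mkdir(parents=True, exist_ok=True)
    prefixes = {"x": "x", "cov": "c", "m": "m", "ycont": "y", "yord": "o"}
    for key, fname in _FILES.items():
        arr = getattr(data, key)
        if arr.shape[1] == 0:
            continue
        cols = [f"{prefixes[key]}{i + 1}" for i in range(arr.shape[1])]
        pd.DataFrame(arr, columns=cols).to_csv(d / fname, index=False,
                                                float_format="%.17g")


def _draw_columns(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}

    def put(base: str, arr: np.ndarray) -> None:
        if arr.ndim == 1:
            cols[base] = arr
        else:
            for idx in np.ndindex(arr.shape[1:]):
                cols[base + "[" + ",".join(map(str, idx)) + "]"] = arr[(slice(None),) + idx]

    put("w", draws.w)
    put("a0", draws.a0)
    put("a3", draws.a3)
    put("sigma_y", draws.sigma_y)
    put("nu_c", draws.nu_c)
    for j, g in enumerate(draws.gamma):
        put(f"gamma{j}", g)
    for name in ("a1", "a2", "sigma_m", "nu_m", "a4"):
        val = getattr(draws, name)
        if val is not None:
            put(name, val)
    return cols


def write_draws(draws: PosteriorDraws, path) -> None:
    """Write retained draws as a wide CSV, one row per draw."""
    pd.DataFrame(_draw_columns(draws)).to_csv(path, index=False,
                                              float_format="%.17g")


def read_draws(path, spec: ModelSpec, **meta) -> PosteriorDraws:
    """Reconstruct a :class:`PosteriorDraws` from a wide draw CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    nd = len(df)

    def take(base: str, shape: tuple) -> np.ndarray:
        if not shape:
            return df[base].to_numpy()
        out = np.empty((nd, *shape))
        for idx in np.ndindex(shape):
            out[(slice(None),) + idx] = df[
                base + "[" + ",".join(map(str, idx)) + "]"
            ].to_numpy()
        return out

    c_k, q, r = spec.n_regressors, spec.n_outcomes, spec.n_mediators
    has_med = any(c.startswith("a4[") for c in df.columns)
    return PosteriorDraws(
        spec=spec,
        w=take("w", (spec.n_predictors, spec.n_components)),
        a0=take("a0", (q,)),
        a3=take("a3", (c_k, q)),
        sigma_y=take("sigma_y", (q, q)),
        nu_c=take("nu_c", ()),
        gamma=[take(f"gamma{j}", (j_q - 1,)) for j, j_q in enumerate(spec.categories)],
        a1=take("a1", (r,)) if has_med else None,
        a2=take("a2", (c_k, r)) if has_med else None,
        sigma_m=take("sigma_m", (r, r)) if has_med else None,
        nu_m=take("nu_m", ()) if has_med else None,
        a4=take("a4", (r, q)) if has_med else None,
        **meta,
    )


def write_true_params(true: TrueParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(true.to_dict(), fh, indent=2)


class Timer:
    """Tiny wall-clock context manager for manifests."""

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.perf_counter() - self.t0
        return False
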