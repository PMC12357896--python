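"""Fully synthetic twin generation via a Gaussian copula over mixed columns.

Each numeric column is mapped to normal scores through its empirical ranks,
z = Phi^-1((rank - 0.5) / n); each categorical column through the midpoints
of its cumulative-frequency intervals (categories ordered by descending
frequency, ties lexicographic).  The latent correlation matrix is estimated
on these scores and projected to the nearest positive-definite matrix by
eigenvalue clipping.  Sampling draws latent multivariate normals and inverts
each marginal: empirical quantile interpolation for numeric columns,
interval lookup for categorical ones.

Marginals are empirical rather than parametric: the heavy-tailed wearable
energy aggregates are poorly served by named families, and the empirical
inverse is exact at the observed quantiles.

A small registry lets external synthesizers (anything exposing
``fit(table)`` / ``sample(n, seed)``) participate in the pipeline and
evaluation exactly like the built-in copula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sifter import TwinTable

__all__ = [
    "CopulaModel", "GaussianCopulaSynthesizer", "fit_copula", "sample_copula",
    "register_synthesizer", "get_synthesizer", "list_synthesizers",
]


@dataclass
class _NumericMarginal:
    sorted_values: np.ndarray       # ascending observed values
    constant: bool = False

    def to_scores(self, values: pd.Series) -> np.ndarray:
        n = len(values)
        ranks = stats.rankdata(values, method="average")
        return stats.norm.ppf((ranks - 0.5) / n)

    def inverse(self, u: np.ndarray) -> np.ndarray:
        n = len(self.sorted_values)
        if self.constant or n == 1:
            return np.full(len(u), self.sorted_values[0])
        # ECDF positions (i - 0.5)/n; linear interpolation, clamped ends
        probs = (np.arange(1, n + 1) - 0.5) / n
        return np.interp(u, probs, self.sorted_values)


@dataclass
class _CategoricalMarginal:
    categories: list                # frequency-ordered
    cum_probs: np.ndarray           # right edges of the [0,1] partition

    def to_scores(self, values: pd.Series) -> np.ndarray:
        lows = np.concatenate([[0.0], self.cum_probs[:-1]])
        mid = {c: (lo + hi) / 2.0 for c, lo, hi in
               zip(self.categories, lows, self.cum_probs)}
        u = values.map(mid).to_numpy(dtype=float)
        return stats.norm.ppf(u)

    def inverse(self, u: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.cum_probs, u, side="left")
        idx = np.clip(idx, 0, len(self.categories) - 1)
        return np.array([self.categories[i] for i in idx], dtype=object)


@dataclass
class CopulaModel:
    """Fitted Gaussian copula: per-column marginals + latent correlation."""

    columns: list[str]
    marginals: dict
    correlation: np.ndarray         # over ``corr_columns`` only
    corr_columns: list[str]
    dtypes: dict
    n: int = 0
    seed: int | None = None
    metadata: dict = field(default_factory=dict)


def _project_positive_definite(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Nearest-PD projection: clip eigenvalues at eps, renormalize diagonal."""
    vals, vecs = np.linalg.eigh((corr + corr.T) / 2.0)
    vals = np.clip(vals, eps, None)
    mat = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(mat))
    mat = mat / np.outer(d, d)
    np.fill_diagonal(mat, 1.0)
    return mat


def fit_copula(table: pd.DataFrame, id_columns: tuple[str, ...] = ("subject_id",),
               ) -> CopulaModel:
    """Fit marginals and latent correlation to a mixed-type table.

    Constant numeric columns are stored as point masses and excluded from
    correlation estimation.  Requires at least two rows and no fully missing
    column.
    """
    cols = [c for c in table.columns if c not in id_columns]
    if len(table) < 2:
        raise ValueError("need at least 2 rows to fit a copula")
    marginals: dict = {}
    scores: dict[str, np.ndarray] = {}
    corr_columns: list[str] = []
    for col in cols:
        s = table[col]
        if s.isna().all():
            raise ValueError(f"column {col!r} is entirely missing")
        s = s.dropna() if s.isna().any() else s
        if pd.api.types.is_numeric_dtype(s):
            vals = np.sort(s.to_numpy(dtype=float))
            constant = bool(vals[0] == vals[-1])
            marg = _NumericMarginal(sorted_values=vals, constant=constant)
            marginals[col] = marg
            if not constant:
                scores[col] = marg.to_scores(table[col].fillna(s.median()))
                corr_columns.append(col)
        else:
            freq = s.value_counts()
            order = sorted(freq.index, key=lambda c: (-freq[c], str(c)))
            probs = np.array([freq[c] for c in order], dtype=float)
            probs /= probs.sum()
            marg = _CategoricalMarginal(categories=list(order),
                                        cum_probs=np.cumsum(probs))
            marginals[col] = marg
            if len(order) > 1:
                filled = table[col].fillna(order[0])
                scores[col] = marg.to_scores(filled)
                corr_columns.append(col)

    if corr_columns:
        z = np.column_stack([scores[c] for c in corr_columns])
        corr = np.corrcoef(z, rowvar=False)
        corr = np.atleast_2d(corr)
        corr = _project_positive_definite(corr)
    else:
        corr = np.zeros((0, 0))
    return CopulaModel(columns=cols, marginals=marginals, correlation=corr,
                       corr_columns=corr_columns,
                       dtypes={c: table[c].dtype for c in cols}, n=len(table))


def sample_copula(model: CopulaModel, n: int, seed: int = 0) -> TwinTable:
    """Draw ``n`` synthetic rows from a fitted copula; deterministic given seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out = {}
    if n == 0:
        data = pd.DataFrame({c: pd.Series([], dtype=model.dtypes[c])
                             for c in model.columns})
        return TwinTable(data=data, method="gaussian_copula", level="synthetic",
                         seed=seed, params={"n": 0})
    k = len(model.corr_columns)
    if k:
        chol = np.linalg.cholesky(model.correlation)
        z = rng.standard_normal((n, k)) @ chol.T
        u = stats.norm.cdf(z)
    pos = {c: i for i, c in enumerate(model.corr_columns)}
    for col in model.columns:
        marg = model.marginals[col]
        if col in pos:
            ui = u[:, pos[col]]
        else:
            ui = rng.random(n)  # independent (point-mass / single-category)
        vals = marg.inverse(ui)
        s = pd.Series(vals)
        try:
            s = s.astype(model.dtypes[col])
        except (TypeError, ValueError):
            pass
        out[col] = s
    data = pd.DataFrame(out, columns=model.columns)
    return TwinTable(data=data, method="gaussian_copula", level="synthetic",
                     seed=seed, params={"n": n})


class GaussianCopulaSynthesizer:
    """fit/sample wrapper so the copula plugs into the synthesizer registry."""

    def __init__(self) -> None:
        self._model: CopulaModel | None = None

    def fit(self, table: pd.DataFrame) -> "GaussianCopulaSynthesizer":
        self._model = fit_copula(table)
        return self

    def sample(self, n: int, seed: int = 0) -> TwinTable:
        if self._model is None:
            raise RuntimeError("call fit() before sample()")
        return sample_copula(self._model, n, seed)


_REGISTRY: dict[str, type] = {}


def register_synthesizer(name: str, factory) -> str:
    """Register an external synthesizer exposing ``fit(table)``/``sample(n, seed)``."""
    if name in _REGISTRY:
        raise ValueError(f"synthesizer {name!r} already registered")
    if not callable(factory):
        raise TypeError("factory must be callable")
    _REGISTRY[name] = factory
    return name


def get_synthesizer(name: str):
    if name not in _REGISTRY:
        raise KeyError(f"unknown synthesizer {name!r}; "
                       f"registered: {sorted(_REGISTRY)}")
    return _REGISTRY[name]()


def list_synthesizers() -> list[str]:
    return sorted(_REGISTRY)


register_synthesizer("gaussian_copula", GaussianCopulaSynthesizer)
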