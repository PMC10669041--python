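"""Rank transforms, rank correlation matrices and Gaussian-copula sampling.

The dependence model throughout the package is the normal (Gaussian)
copula: by Sklar's theorem any joint distribution factors into its margins
and a copula, and the normal copula couples arbitrary margins through a
single correlation matrix R in the space of normal scores
(z = Phi^-1(F(x))).  This module provides the building blocks:

* midranks and the Spearman rank correlation (product-moment of midranks,
  identical to the classical 1 - 6*sum(d_i^2)/(n^3 - n) formula when
  values are distinct);
* the normal-scores transform z_i = Phi^-1(r_i/(n+1)) and the
  "normal rank" correlation matrix (Pearson correlation of normal scores);
* eigenvalue-clipping repair of indefinite correlation matrices;
* sampling uniforms from a Gaussian copula;
* piecewise-linear empirical margins used to move between the data scale
  and the copula scale.

All sampling takes either an integer seed or a ``numpy.random.Generator``;
an integer is expanded through ``numpy.random.default_rng`` so that a
single caller-supplied seed drives every stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .errors import ConstantColumnError, NotPositiveDefiniteError

__all__ = [
    "midranks",
    "spearman_rho",
    "normal_scores",
    "empirical_rank_corr_matrix",
    "normal_rank_corr_matrix",
    "nearest_pd",
    "is_positive_definite",
    "GaussianCopulaModel",
    "sample_gaussian_copula",
    "EmpiricalMargin",
    "empirical_quantile",
    "spearman_from_pearson",
    "pearson_from_spearman",
    "as_generator",
]

#: smallest admissible eigenvalue after positive-definiteness repair
MIN_EIGENVALUE = 1e-8


def as_generator(seed) -> np.random.Generator:
    """Coerce an int seed or Generator into a ``numpy.random.Generator``."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def midranks(x) -> np.ndarray:
    """Midranks of ``x`` (average rank over ties, 1-based)."""
    return stats.rankdata(np.asarray(x, dtype=float), method="average")


def spearman_rho(x, y, *, name_x: str | None = None, name_y: str | None = None) -> float:
    """Spearman rank correlation of two equal-length samples.

    Computed as the product-moment correlation of midranks, which reduces
    to 1 - 6*sum(d_i^2)/(n^3 - n) (d_i the rank difference of observation
    i) when all values are distinct and remains well defined under ties.

    Raises
    ------
    ConstantColumnError
        If either vector has fewer than two distinct values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 2:
        raise ValueError("need n >= 2 observations")
    for v, name in ((x, name_x), (y, name_y)):
        if np.ptp(v) == 0:
            raise ConstantColumnError(name)
    rx, ry = midranks(x), midranks(y)
    return float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))


def normal_scores(x) -> np.ndarray:
    """Normal-scores transform: Phi^-1 of midranks on the r/(n+1) grid.

    Rank-invariant: any strictly increasing transform of ``x`` yields the
    same scores.  A single observation maps to Phi^-1(1/2) = 0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    return ndtri(midranks(x) / (n + 1))


def _column_matrix(table) -> tuple[np.ndarray, list[str]]:
    """Extract (values, names) from a WetlandTable or DataFrame."""
    if hasattr(table, "data"):  # WetlandTable
        frame = table.data
    elif isinstance(table, pd.DataFrame):
        frame = table
    else:
        arr = np.asarray(table, dtype=float)
        return arr, [f"x{i}" for i in range(arr.shape[1])]
    return frame.to_numpy(dtype=float), [str(c) for c in frame.columns]


def _check_nonconstant(values: np.ndarray, names: list[str]) -> None:
    for j, name in enumerate(names):
        if np.ptp(values[:, j]) == 0:
            raise ConstantColumnError(name)


def empirical_rank_corr_matrix(table) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix of all columns.

    Accepts a :class:`~wetlandbn.traits.WetlandTable`, a DataFrame or a
    2-d array.  Symmetric with unit diagonal; a constant column raises
    :class:`ConstantColumnError` naming the variable.
    """
    values, names = _column_matrix(table)
    _check_nonconstant(values, names)
    if values.shape[1] == 1:
        return pd.DataFrame([[1.0]], index=names, columns=names)
    ranks = stats.rankdata(values, method="average", axis=0)
    R = np.corrcoef(ranks, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=names, columns=names)


def normal_rank_corr_matrix(table, repair: bool = True) -> pd.DataFrame:
    """Pearson correlation matrix of per-column normal scores.

    This is the z-space ("normal rank") correlation matrix the copula is
    parametrized by.  If the sample matrix is numerically indefinite it is
    repaired by eigenvalue clipping (see :func:`nearest_pd`) when
    ``repair`` is true.
    """
    values, names = _column_matrix(table)
    _check_nonconstant(values, names)
    if values.shape[1] == 1:
        return pd.DataFrame([[1.0]], index=names, columns=names)
    scores = np.column_stack([normal_scores(values[:, j]) for j in range(values.shape[1])])
    R = np.corrcoef(scores, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    if repair and not is_positive_definite(R):
        import logging

        logging.getLogger(__name__).info(
            "normal rank correlation matrix indefinite; applying PD repair"
        )
        R = nearest_pd(R)
    return pd.DataFrame(R, index=names, columns=names)


def is_positive_definite(R: np.ndarray, min_eig: float = MIN_EIGENVALUE) -> bool:
    """True if the symmetric matrix has all eigenvalues >= ``min_eig``."""
    R = np.asarray(R, dtype=float)
    return bool(np.linalg.eigvalsh(R).min() >= min_eig)


def nearest_pd(R, min_eig: float = MIN_EIGENVALUE) -> np.ndarray:
    """Repair a symmetric unit-diagonal matrix to positive definiteness.

    Eigenvalues below ``min_eig`` are clipped up, the matrix is rebuilt and
    rescaled back to unit diagonal; the pass repeats until the smallest
    eigenvalue clears the floor (rescaling can nudge it slightly).  Already
    positive-definite input is returned unchanged, making the repair
    idempotent.
    """
    A = np.asarray(R, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if is_positive_definite(A, min_eig):
        return A.copy()
    out = A.copy()
    for _ in range(100):
        w, V = np.linalg.eigh(out)
        # clip with headroom: the unit-diagonal rescaling below can shrink
        # the smallest eigenvalue slightly
        w = np.maximum(w, 2.0 * min_eig)
        out = (V * w) @ V.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2.0
        np.fill_diagonal(out, 1.0)
        if is_positive_definite(out, min_eig):
            return out
    raise NotPositiveDefiniteError("positive-definiteness repair did not converge")


@dataclass
class GaussianCopulaModel:
    """A normal copula: named nodes plus a z-space correlation matrix.

    ``R[i, j]`` is the correlation of the normal scores of nodes i and j;
    the copula density follows by mapping standard normals through the
    standard normal CDF Phi.
    """

    node_names: tuple[str, ...]
    R: np.ndarray

    def __post_init__(self) -> None:
        self.node_names = tuple(self.node_names)
        self.R = np.asarray(self.R, dtype=float)
        k = len(self.node_names)
        if self.R.shape != (k, k):
            raise ValueError("R shape does not match node_names")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-10):
            raise ValueError("R must have unit diagonal")
        if np.any(np.abs(self.R) > 1 + 1e-12):
            raise ValueError("R entries must lie in [-1, 1]")

    @property
    def k(self) -> int:
        return len(self.node_names)

    def index(self, name: str) -> int:
        return self.node_names.index(name)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.node_names, columns=self.node_names)


def sample_gaussian_copula(model: GaussianCopulaModel, n_samples: int, seed) -> np.ndarray:
    """Draw ``n_samples`` rows of copula uniforms (shape n_samples x k).

    Samples z ~ N(0, R) via Cholesky and maps through Phi; each column is
    marginally uniform on (0, 1).  Raises
    :class:`NotPositiveDefiniteError` for an indefinite R — repair first.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    try:
        L = np.linalg.cholesky(model.R)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(
            "copula matrix is not positive definite; apply nearest_pd first"
        ) from exc
    rng = as_generator(seed)
    z = rng.standard_normal((n_samples, model.k)) @ L.T
    return ndtr(z)


# ---------------------------------------------------------------------------
# empirical margins
# ---------------------------------------------------------------------------


@dataclass
class EmpiricalMargin:
    """Piecewise-linear empirical distribution of one variable.

    Order statistics are placed at plotting positions k/(n+1); the quantile
    function interpolates linearly between them and clamps to the observed
    minimum/maximum outside the grid, so back-transformed copula samples
    never leave the observed range.  ``evidence_u`` maps an observed (or
    interpolated) data value to a copula uniform using the midrank
    convention, the inverse operation used when conditioning on evidence.
    """

    sorted_values: np.ndarray
    plotting_positions: np.ndarray = field(default=None)  # type: ignore[assignment]
    #: distinct observed values and their midrank-based uniforms
    _levels: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _level_u: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        xs = np.sort(np.asarray(self.sorted_values, dtype=float))
        if len(xs) < 1 or np.isnan(xs).any():
            raise ValueError("margin needs at least one finite observation")
        self.sorted_values = xs
        n = len(xs)
        if self.plotting_positions is None:
            self.plotting_positions = np.arange(1, n + 1) / (n + 1)
        r = midranks(xs) / (n + 1)
        levels, first = np.unique(xs, return_index=True)
        self._levels = levels
        self._level_u = r[first]  # midrank u of each distinct level

    @classmethod
    def from_data(cls, values) -> "EmpiricalMargin":
        return cls(np.asarray(values, dtype=float))

    @property
    def n(self) -> int:
        return len(self.sorted_values)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.sorted_values[0]), float(self.sorted_values[-1])

    def quantile(self, u) -> np.ndarray | float:
        """Inverse CDF at ``u`` in (0, 1), clamped to the observed range."""
        u_arr = np.asarray(u, dtype=float)
        if np.any(u_arr <= 0) or np.any(u_arr >= 1):
            raise ValueError("u must lie strictly inside (0, 1)")
        out = np.interp(u_arr, self.plotting_positions, self.sorted_values)
        return float(out) if np.isscalar(u) else out

    def cdf(self, x) -> np.ndarray | float:
        """Piecewise-linear CDF on the plotting-position grid."""
        x_arr = np.asarray(x, dtype=float)
        xs, ps = self._collapsed_knots()
        out = np.interp(x_arr, xs, ps)
        return float(out) if np.isscalar(x) else out

    def _collapsed_knots(self) -> tuple[np.ndarray, np.ndarray]:
        # collapse tied order statistics to one knot at the mean position,
        # keeping cdf(quantile(u)) == u wherever the quantile is injective
        xs, inv = np.unique(self.sorted_values, return_inverse=True)
        ps = np.bincount(inv, weights=self.plotting_positions) / np.bincount(inv)
        return xs, ps

    def evidence_u(self, value: float) -> float:
        """Copula uniform for a data value, midrank convention.

        Observed values map to midrank/(n+1); unobserved values inside the
        observed range interpolate linearly between the neighbouring
        observed levels; values outside clamp to the nearest level.
        """
        return float(np.interp(float(value), self._levels, self._level_u))


def empirical_quantile(margin: EmpiricalMargin, u) -> np.ndarray | float:
    """Back-transform copula uniforms to the data scale of ``margin``."""
    if margin.n < 2:
        raise ValueError("margin must be built from at least two observations")
    return margin.quantile(u)


# ---------------------------------------------------------------------------
# grade-correlation conversions (cross-check mode)
# ---------------------------------------------------------------------------


def spearman_from_pearson(rho) -> np.ndarray | float:
    """Population Spearman correlation implied by a normal-copula rho."""
    return 6.0 / np.pi * np.arcsin(np.asarray(rho, dtype=float) / 2.0)


def pearson_from_spearman(rho_s) -> np.ndarray | float:
    """Inverse conversion: 2*sin(pi*rho_s/6)."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)
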