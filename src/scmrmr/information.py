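"""Discretization of continuous expression and plug-in mutual information.

Mutual information is the currency of mRMR: relevance is I(gene, label) and
redundancy is the mean I(gene, selected gene).  Continuous expression is
first discretized; two schemes are offered:

``mean_sigma``
    The classical three-level scheme from the mRMR literature: values below
    mean - alpha*sd map to bin 0, above mean + alpha*sd to bin 2, the rest
    to bin 1.  The standard deviation is the sample (n-1) estimate; a
    constant vector maps entirely to the middle bin, so constant genes have
    zero mutual information with everything by construction.

``equal_frequency``
    Near-equal bin occupancy, ties resolved by value order then original
    index.  Useful for heavy-tailed data where the mean +/- sd cutpoints
    collapse.

All mutual information values are plug-in estimates in nats:

    I(X, Y) = sum_{a,b} p(a,b) * ln[ p(a,b) / (p(a) p(b)) ],   0*ln 0 := 0

computed from the empirical joint distribution of bin indices.  The base
only rescales scores uniformly, so rankings are unaffected by the choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

MEAN_SIGMA = "mean_sigma"
EQUAL_FREQUENCY = "equal_frequency"


@dataclass(frozen=True)
class DiscretizedVector:
    """Per-cell integer bin indices in ``[0, n_bins)``."""

    bins: np.ndarray
    n_bins: int
    scheme: str

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=np.int64)
        object.__setattr__(self, "bins", b)
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        if b.size and (b.min() < 0 or b.max() >= self.n_bins):
            raise ValueError("bin index out of range")

    def __len__(self) -> int:
        return self.bins.size


def discretize(
    values: np.ndarray,
    scheme: str = MEAN_SIGMA,
    alpha: float = 0.5,
    n_bins: int = 3,
) -> DiscretizedVector:
    """Discretize a real vector into bin indices.

    Parameters
    ----------
    values : array-like of finite reals
    scheme : "mean_sigma" or "equal_frequency"
    alpha : cutpoint half-width in sample standard deviations (mean_sigma)
    n_bins : number of bins; mean_sigma is defined for exactly 3
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    if scheme == MEAN_SIGMA:
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        if n_bins != 3:
            raise ValueError("mean_sigma discretization is defined for n_bins=3")
        mean = v.mean()
        sd = v.std(ddof=1) if v.size > 1 else 0.0
        bins = np.ones(v.size, dtype=np.int64)
        if sd > 0:
            bins[v < mean - alpha * sd] = 0
            bins[v > mean + alpha * sd] = 2
        return DiscretizedVector(bins, 3, scheme)

    if scheme == EQUAL_FREQUENCY:
        if v.size and np.all(v == v[0]):
            warnings.warn("constant vector: equal_frequency yields a single bin")
            return DiscretizedVector(np.zeros(v.size, dtype=np.int64), n_bins, scheme)
        order = np.argsort(v, kind="stable")
        bins = np.empty(v.size, dtype=np.int64)
        bins[order] = (np.arange(v.size) * n_bins) // v.size
        return DiscretizedVector(bins, n_bins, scheme)

    raise ValueError(f"unknown discretization scheme {scheme!r}")


def discretize_matrix(
    values: np.ndarray, scheme: str = MEAN_SIGMA, alpha: float = 0.5, n_bins: int = 3
) -> np.ndarray:
    """Row-wise discretization of a genes x cells matrix to an int bin matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.vstack(
            [discretize(row, scheme, alpha, n_bins).bins for row in np.asarray(values, dtype=float)]
        )


def _mi_from_joint(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        raise ValueError("mutual information of empty vectors is undefined")
    pxy = counts / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log(pxy / (px * py))
    return float(terms[mask].sum())


def mutual_information(x: DiscretizedVector, y: DiscretizedVector) -> float:
    """Plug-in mutual information (nats) between two discretized vectors."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) == 0:
        raise ValueError("mutual information of empty vectors is undefined")
    joint = np.bincount(
        x.bins * y.n_bins + y.bins, minlength=x.n_bins * y.n_bins
    ).reshape(x.n_bins, y.n_bins)
    return _mi_from_joint(joint)


def entropy(x: DiscretizedVector) -> float:
    """Plug-in Shannon entropy (nats); equals mutual_information(x, x)."""
    if len(x) == 0:
        raise ValueError("entropy of an empty vector is undefined")
    p = np.bincount(x.bins, minlength=x.n_bins) / len(x)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mi_against_vector(bin_matrix: np.ndarray, n_bins: int, y: np.ndarray, y_bins: int) -> np.ndarray:
    """Mutual information of every row of a bin matrix with a fixed vector.

    Vectorized over rows; identical to per-row :func:`mutual_information`
    calls on the same bins.
    """
    X = np.asarray(bin_matrix, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n_rows, n_cells = X.shape
    if y.size != n_cells:
        raise ValueError(f"length mismatch: {n_cells} vs {y.size}")
    span = n_bins * y_bins
    codes = X * y_bins + y[None, :] + (np.arange(n_rows) * span)[:, None]
    flat = np.bincount(codes.ravel(), minlength=n_rows * span)
    joints = flat.reshape(n_rows, n_bins, y_bins)
    return np.array([_mi_from_joint(j) for j in joints])
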