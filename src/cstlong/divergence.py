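"""Kullback-Leibler and Jensen-Shannon divergences between community states.

A community state is a vector of relative abundances of all phylotypes in one
sample; dissimilarity between two states p and q is measured by the
Jensen-Shannon divergence

    JSD(p, q) = ( D_KL(p, a) + D_KL(q, a) ) / 2,   a = (p + q) / 2,

where D_KL(p, q) = sum_i p_i log(p_i / q_i) is the Kullback-Leibler
divergence.  With base-2 logarithms JSD lies in [0, 1]: 0 iff p = q, 1 iff
the supports of p and q are disjoint.  The square root of the JSD (the
Jensen-Shannon distance) is a true metric and is the default dissimilarity
used for clustering and stability analysis throughout this package.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "kl_divergence",
    "js_divergence",
    "js_distance",
    "pairwise_distances",
    "DistanceMatrix",
]

_STATE_ATOL = 1e-9


def _as_state(p, name: str = "p") -> np.ndarray:
    """Validate and return a relative-abundance vector as a float array."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector, got shape {arr.shape}")
    if np.any(arr < -_STATE_ATOL):
        raise ValueError(f"{name} has negative entries")
    total = arr.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"{name} must sum to 1 (got {total:.6g})")
    return np.clip(arr, 0.0, None)


def kl_divergence(p: Sequence[float], q: Sequence[float], log_base: float = 2.0) -> float:
    """Kullback-Leibler divergence sum_i p_i log(p_i/q_i).

    Terms with p_i = 0 contribute 0 (the 0 log 0 convention); the result is
    +inf when q_i = 0 for some i with p_i > 0.
    """
    p = _as_state(p, "p")
    q = _as_state(q, "q")
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} vs {q.shape[0]}")
    support = p > 0
    if np.any(q[support] == 0):
        return float("inf")
    terms = p[support] * (np.log(p[support]) - np.log(q[support]))
    return float(terms.sum() / np.log(log_base))


def js_divergence(p: Sequence[float], q: Sequence[float], log_base: float = 2.0) -> float:
    """Jensen-Shannon divergence: mean KL divergence of p and q to their average.

    Always finite; bounded by [0, 1] for base-2 logarithms.
    """
    p = _as_state(p, "p")
    q = _as_state(q, "q")
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} vs {q.shape[0]}")
    a = (p + q) / 2.0
    d = 0.5 * (kl_divergence(p, a, log_base) + kl_divergence(q, a, log_base))
    # guard tiny negative round-off
    return float(max(d, 0.0))


def js_distance(p: Sequence[float], q: Sequence[float], log_base: float = 2.0) -> float:
    """Jensen-Shannon distance: square root of the JS divergence (a metric)."""
    return float(np.sqrt(js_divergence(p, q, log_base)))


class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with sample ids.

    Attributes
    ----------
    values : (n, n) ndarray
        Symmetric, zero-diagonal dissimilarities.
    ids : list of str
        Sample identifiers, one per row/column.
    metric : str
        Name of the metric used to build the matrix.
    """

    def __init__(self, values: np.ndarray, ids: Sequence[str], metric: str = "js_distance"):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(ids) != values.shape[0]:
            raise ValueError("ids length does not match matrix size")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = values
        self.ids = list(map(str, ids))
        self.metric = metric

    def __len__(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, metric: str = "js_distance") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns], metric=metric)


def pairwise_distances(
    states: Sequence[Sequence[float]],
    ids: Sequence[str] | None = None,
    metric: str = "js_distance",
    log_base: float = 2.0,
) -> DistanceMatrix:
    """Pairwise JS divergence or JS distance matrix over community states.

    Parameters
    ----------
    states : sequence of relative-abundance vectors (all the same length)
    ids : optional sample ids (defaults to s0, s1, ...)
    metric : 'js_distance' (default, a metric) or 'js_divergence'
    """
    if metric not in ("js_distance", "js_divergence"):
        raise ValueError(f"unknown metric {metric!r}")
    mat = np.asarray([_as_state(s, f"states[{i}]") for i, s in enumerate(states)])
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 states")
    if ids is None:
        ids = [f"s{i}" for i in range(n)]

    # vectorised JSD over all pairs: H(a) - (H(p)+H(q))/2 in the chosen base
    log = np.log(mat, out=np.zeros_like(mat), where=mat > 0)
    ent = -(mat * log).sum(axis=1)  # nats
    out = np.zeros((n, n))
    for i in range(n):
        a = (mat[i][None, :] + mat[i:]) / 2.0
        loga = np.log(a, out=np.zeros_like(a), where=a > 0)
        ent_a = -(a * loga).sum(axis=1)
        jsd = ent_a - 0.5 * (ent[i] + ent[i:])
        out[i, i:] = np.maximum(jsd, 0.0) / np.log(log_base)
    out = out + out.T
    if metric == "js_distance":
        out = np.sqrt(out)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(out, ids, metric=metric)
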