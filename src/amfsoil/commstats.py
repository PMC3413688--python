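"""Community-ecology statistics: Bray-Curtis distance and analytic rarefaction.

Bray-Curtis dissimilarity between samples i and j over taxa k is

    BC_ij = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk)

where x is (here, usually) the proportional composition.  Expected rarefied
richness in a subsample of n reads from a sample of N total reads is

    E[S_n] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ]

computed with log-gamma to avoid overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .community import CommunityMatrix


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance structure over named samples."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        self.ids = list(self.ids)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair):
        i, j = pair
        return self.values[self.ids.index(i), self.ids.index(j)]

    def subset(self, samples) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in samples]
        return DistanceMatrix(list(samples), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.values)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity between two non-negative abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def distance_matrix(m: CommunityMatrix) -> DistanceMatrix:
    """All pairwise Bray-Curtis distances between the samples of ``m``."""
    if m.shape[0] < 2:
        raise ValueError("need at least two samples")
    X = np.asarray(m.data.values, dtype=float)
    sums = X.sum(axis=1)
    if (sums == 0).any():
        bad = m.data.index[sums == 0][0]
        raise ValueError(f"sample {bad!r} is all-zero; Bray-Curtis undefined")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = sums[:, None] + sums[None, :]
    d = num / den
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(m.sample_ids, d)


def rarefied_richness(counts, n: int) -> float:
    """Expected taxon richness of a random n-read subsample (Hurlbert)."""
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if not 1 <= n <= N:
        raise ValueError(f"subsample size {n} outside [1, {N}]")

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    terms = np.zeros(len(counts))
    feasible = (N - counts) >= n          # else the taxon is always present
    a = N - counts[feasible]
    terms[feasible] = np.exp(log_choose(a, n) - log_choose(N, n))
    return float(np.sum(1.0 - terms))


def rarefaction_curve(m: CommunityMatrix, samples=None, depths=None):
    """Mean expected VT richness across a sample group at each depth.

    At each depth only samples whose total read count reaches the depth
    contribute to the mean; a depth reachable by no sample is an error.
    Returns a DataFrame with columns ``depth``, ``mean_richness``,
    ``n_samples``.
    """
    if m.mode != "counts":
        raise ValueError("rarefaction requires a counts-mode matrix")
    sub = m.subset(samples) if samples is not None else m
    if sub.shape[0] == 0:
        raise ValueError("empty sample group")
    totals = sub.row_totals()
    if depths is None:
        hi = int(totals.max())
        depths = sorted({1, *range(10, hi + 1, max(1, hi // 25)), hi})
    rows = []
    for depth in depths:
        usable = totals.index[totals >= depth]
        if len(usable) == 0:
            raise ValueError(f"no sample has >= {depth} reads")
        vals = [rarefied_richness(sub.data.loc[s].values, depth) for s in usable]
        rows.append((depth, float(np.mean(vals)), len(usable)))
    return pd.DataFrame(rows, columns=["depth", "mean_richness", "n_samples"])
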