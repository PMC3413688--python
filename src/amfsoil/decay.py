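"""Distance decay of community similarity.

Pairwise similarity (1 - Bray-Curtis) between all sample pairs is
logit-transformed and regressed on spatial distance (metres) or temporal
distance (days) by ordinary least squares.  Because pairwise observations
are not independent, no analytic p-value is attached to the slope; its
significance comes from permuting sample labels (rows/columns of the
similarity matrix) and recomputing the slope, one-sided toward decay by
default.  AICs of the untransformed- and log-distance models are reported
for the transform comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .commstats import DistanceMatrix

__all__ = ["PairSet", "build_pairs", "logit", "DistanceDecay", "DecayFit",
           "DecayPermutationResult", "fit_decay", "permutation_test_slope"]


@dataclass
class PairSet:
    """All unordered sample pairs with similarity and distance.

    ``similarity_matrix`` (n x n) retains the sample-level structure needed
    for label permutation; ``idx_i``/``idx_j`` index the upper triangle.
    """

    sample_ids: list
    similarity_matrix: np.ndarray
    distance: np.ndarray
    idx_i: np.ndarray
    idx_j: np.ndarray
    kind: str = "spatial"

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.distance)

    @property
    def similarity(self) -> np.ndarray:
        return self.similarity_matrix[self.idx_i, self.idx_j]

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.sample_ids)
        return pd.DataFrame({"sample_i": ids[self.idx_i], "sample_j": ids[self.idx_j],
                             "similarity": self.similarity, "distance": self.distance})


def build_pairs(dm: DistanceMatrix, positions=None, dates=None) -> PairSet:
    """Pair similarities (1 - Bray-Curtis) with spatial or temporal distances.

    Exactly one of ``positions`` (sample -> (x, y) in metres; a DataFrame
    with ``x_m``/``y_m`` columns also works) or ``dates`` (sample ->
    date-like) must be given.  Temporal distance is the absolute difference
    in whole days.
    """
    if (positions is None) == (dates is None):
        raise ValueError("give exactly one of positions= or dates=")
    n = dm.n
    iu = np.triu_indices(n, k=1)
    sim = 1.0 - dm.values
    if positions is not None:
        if isinstance(positions, pd.DataFrame):
            missing = set(dm.ids) - set(positions.index)
            if missing:
                raise KeyError(f"no position for samples: {sorted(missing)[:5]}")
            xy = positions.loc[dm.ids, ["x_m", "y_m"]].values.astype(float)
        else:
            try:
                xy = np.array([positions[s] for s in dm.ids], dtype=float)
            except KeyError as exc:
                raise KeyError(f"no position for sample {exc.args[0]!r}") from exc
        diff = xy[:, None, :] - xy[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))[iu]
        kind = "spatial"
    else:
        if isinstance(dates, pd.Series):
            missing = set(dm.ids) - set(dates.index)
            if missing:
                raise KeyError(f"no date for samples: {sorted(missing)[:5]}")
            dser = pd.to_datetime(dates.loc[dm.ids])
        else:
            try:
                dser = pd.to_datetime(pd.Series([dates[s] for s in dm.ids], index=dm.ids))
            except KeyError as exc:
                raise KeyError(f"no date for sample {exc.args[0]!r}") from exc
        days = dser.values.astype("datetime64[D]").astype(np.int64)
        dist = np.abs(days[:, None] - days[None, :])[iu].astype(float)
        kind = "temporal"
    return PairSet(list(dm.ids), sim, dist, iu[0], iu[1], kind=kind)


def logit(s, eps: float = 1e-3):
    """Logit with clamping into [eps, 1-eps]; returns ``(values, n_clamped)``.

    Similarity is bounded in [0, 1]; exact 0 or 1 (and anything beyond the
    clamp) is pulled to the nearest representable value and counted.
    """
    s = np.asarray(s, dtype=float)
    if not 0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    clamped = np.clip(s, eps, 1.0 - eps)
    n_clamped = int(np.sum((s < eps) | (s > 1.0 - eps)))
    vals = np.log(clamped / (1.0 - clamped))
    if vals.ndim == 0:
        return float(vals), n_clamped
    return vals, n_clamped


@dataclass
class DecayFit:
    slope_logit: float
    intercept: float
    slope_se: float
    aic_untransformed: float
    aic_logdistance: float
    n_pairs: int
    n_clamped: int
    distance_transform: str
    kind: str

    def ci95(self) -> tuple[float, float]:
        from scipy.stats import t
        half = t.ppf(0.975, self.n_pairs - 2) * self.slope_se
        return self.slope_logit - half, self.slope_logit + half

    def summary(self) -> str:
        lo, hi = self.ci95()
        return (f"{self.kind} distance decay ({self.distance_transform} distance, "
                f"{self.n_pairs} pairs, {self.n_clamped} clamped):\n"
                f"  slope (logit scale) = {self.slope_logit:.5g} [{lo:.5g}, {hi:.5g}]\n"
                f"  intercept = {self.intercept:.5g}\n"
                f"  AIC untransformed = {self.aic_untransformed:.2f}, "
                f"log-distance = {self.aic_logdistance:.2f}")

    def to_dict(self) -> dict:
        return {"slope_logit": self.slope_logit, "intercept": self.intercept,
                "slope_se": self.slope_se, "aic_untransformed": self.aic_untransformed,
                "aic_logdistance": self.aic_logdistance, "n_pairs": self.n_pairs,
                "n_clamped": self.n_clamped, "kind": self.kind}


@dataclass
class DecayPermutationResult:
    p_perm: float
    n_perm: int
    slope_obs: float
    null_slopes: np.ndarray
    alternative: str
    seed: object

    def summary(self) -> str:
        return (f"permutation test ({self.n_perm} label permutations, "
                f"alternative={self.alternative}): slope = {self.slope_obs:.5g}, "
                f"P = {self.p_perm:.4g}")


def _ols(x: np.ndarray, y: np.ndarray):
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx <= 0:
        raise ValueError("all distances identical; slope undefined")
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    rss = float((resid ** 2).sum())
    # Gaussian AIC with sigma estimated: k = 3 parameters
    aic = n * np.log(2 * np.pi * rss / n) + n + 2 * 3
    se = np.sqrt(rss / (n - 2) / sxx) if n > 2 else np.nan
    return slope, intercept, se, rss, aic


def _transform_distance(d: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return d
    if transform == "log":
        # natural log; falls back to log1p when zero distances are present
        # (repeat samples collected on the same date have distance 0)
        if (d <= 0).any():
            return np.log1p(d)
        return np.log(d)
    raise ValueError(f"unknown distance transform {transform!r}")


class DistanceDecay:
    """Logit-linear model of pairwise similarity against distance."""

    def __init__(self, pairs: PairSet, eps: float = 1e-3):
        if pairs.n_pairs < 3:
            raise ValueError("need at least 3 pairs")
        if len(np.unique(pairs.distance)) < 2:
            raise ValueError("need at least 2 distinct distances")
        self.pairs = pairs
        self.eps = eps

    def fit(self, distance_transform: str = "none") -> DecayFit:
        y, n_clamped = logit(self.pairs.similarity, self.eps)
        x = _transform_distance(self.pairs.distance, distance_transform)
        slope, intercept, se, _, aic = _ols(x, y)
        x_alt = _transform_distance(self.pairs.distance,
                                    "log" if distance_transform == "none" else "none")
        try:
            *_, aic_alt = _ols(x_alt, y)
        except ValueError:
            aic_alt = np.nan
        aic_none, aic_log = (aic, aic_alt) if distance_transform == "none" else (aic_alt, aic)
        return DecayFit(slope_logit=slope, intercept=intercept, slope_se=se,
                        aic_untransformed=aic_none, aic_logdistance=aic_log,
                        n_pairs=self.pairs.n_pairs, n_clamped=n_clamped,
                        distance_transform=distance_transform, kind=self.pairs.kind)

    def permutation_test(self, n_perm: int = 999, seed=None,
                         alternative: str = "less",
                         distance_transform: str = "none") -> DecayPermutationResult:
        """Permute sample labels of the similarity matrix, refit the slope.

        ``alternative='less'`` is the one-sided test toward decay (more
        negative slope than the null); ``'two-sided'`` is available.  The
        full null-slope distribution is retained.
        """
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if alternative not in ("less", "greater", "two-sided"):
            raise ValueError(f"unknown alternative {alternative!r}")
        x = _transform_distance(self.pairs.distance, distance_transform)
        xc = x - x.mean()
        sxx = float((xc ** 2).sum())
        logit_matrix, _ = logit(self.pairs.similarity_matrix, self.eps)
        ii, jj = self.pairs.idx_i, self.pairs.idx_j
        y_obs = logit_matrix[ii, jj]
        slope_obs = float((xc * (y_obs - y_obs.mean())).sum() / sxx)

        rng = np.random.default_rng(seed)
        n = self.pairs.n_samples
        null = np.empty(n_perm)
        for b in range(n_perm):
            p = rng.permutation(n)
            y = logit_matrix[p[ii], p[jj]]
            null[b] = (xc * (y - y.mean())).sum() / sxx
        if alternative == "less":
            exceed = int(np.sum(null <= slope_obs + 1e-15))
        elif alternative == "greater":
            exceed = int(np.sum(null >= slope_obs - 1e-15))
        else:
            exceed = int(np.sum(np.abs(null) >= abs(slope_obs) - 1e-15))
        p_val = (1.0 + exceed) / (1.0 + n_perm)
        return DecayPermutationResult(p_perm=p_val, n_perm=n_perm,
                                      slope_obs=slope_obs, null_slopes=null,
                                      alternative=alternative, seed=seed)


def fit_decay(pairs: PairSet, distance_transform: str = "none",
              eps: float = 1e-3) -> DecayFit:
    """Functional wrapper around :class:`DistanceDecay`."""
    return DistanceDecay(pairs, eps=eps).fit(distance_transform)


def permutation_test_slope(pairs: PairSet, n_perm: int = 999, seed=None,
                           alternative: str = "less", eps: float = 1e-3):
    """Functional wrapper around :meth:`DistanceDecay.permutation_test`."""
    return DistanceDecay(pairs, eps=eps).permutation_test(
        n_perm=n_perm, seed=seed, alternative=alternative)
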