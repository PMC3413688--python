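"""Distance-based and count-based inference models.

All three models follow the fit-then-results pattern: construct the model
from data, call :meth:`fit`, read estimates and permutation/analytic
p-values off the results object.

* :class:`Permanova` — permutational multivariate ANOVA on a distance
  matrix with sequential (Type I) sums of squares and free permutation of
  sample labels.  With Gower's centred matrix G (from -d^2/2, double
  centred), the total sum of squares is tr(G) and the sum of squares of a
  term is the increment tr(H_m G) - tr(H_{m-1} G) of the hat matrices of
  the nested dummy-coded designs.  The pseudo-F of each term is its mean
  square over the residual mean square; p-values use the (1+b)/(1+B)
  convention so they are never zero.
* :class:`BetaDispersion` — homogeneity of multivariate dispersions:
  samples are embedded by principal coordinates, distances to the group
  centroid are corrected for negative eigenvalues (d^2 = d_real^2 -
  d_imag^2, clipped at zero), and a one-way ANOVA F with (k-1, n-k)
  degrees of freedom is reported.
* :class:`PoissonRichness` — log-link Poisson GLM of per-sample VT
  richness on a grouping factor, fitted by iteratively reweighted least
  squares; the group effect is tested by the deviance difference against
  the intercept-only model on a chi-square with k-1 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .commstats import DistanceMatrix

__all__ = ["Permanova", "PermanovaResults", "BetaDispersion",
           "BetaDispersionResults", "PoissonRichness", "PoissonRichnessResults",
           "permanova", "dispersion_test", "poisson_richness_test"]


def _gower_centre(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummy(levels: pd.Series) -> np.ndarray:
    """Full-rank dummy coding (drop first level), observations x (k-1)."""
    cats = pd.Categorical(levels)
    if len(cats.categories) < 2:
        raise ValueError(f"factor has a single level: {cats.categories.tolist()}")
    return pd.get_dummies(cats, drop_first=True, dtype=float).values


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


class Permanova:
    """PERMANOVA of a distance matrix on one or more factors.

    Parameters
    ----------
    dm :
        :class:`~amfsoil.commstats.DistanceMatrix` over the samples.
    factors :
        DataFrame indexed by sample id containing the factor columns.
    terms :
        Ordered factor names; sums of squares are sequential in this order.
    """

    def __init__(self, dm: DistanceMatrix, factors: pd.DataFrame, terms):
        self.dm = dm
        self.terms = list(terms)
        missing = set(dm.ids) - set(factors.index)
        if missing:
            raise KeyError(f"samples missing factor levels: {sorted(missing)[:5]}")
        self.factors = factors.loc[dm.ids, self.terms]
        if dm.n < 3:
            raise ValueError("PERMANOVA needs at least 3 samples")

    def fit(self, n_permutations: int = 999, seed=None) -> "PermanovaResults":
        d = self.dm.values
        n = self.dm.n
        g = _gower_centre(d)
        ss_total = float(np.trace(g))
        if ss_total <= 1e-12:
            raise ValueError("all samples identical: total sum of squares is zero")

        # nested hat matrices: intercept, +term1, +term1+term2, ...
        ones = np.ones((n, 1))
        designs, dfs = [ones], []
        for t in self.terms:
            designs.append(np.hstack([designs[-1], _dummy(self.factors[t])]))
        hats = [_hat(x) for x in designs]
        ranks = [int(round(np.trace(h))) for h in hats]
        dfs = [ranks[i + 1] - ranks[i] for i in range(len(self.terms))]
        df_resid = n - ranks[-1]
        if df_resid <= 0:
            raise ValueError("residual degrees of freedom <= 0")
        # increment matrices let each permuted statistic be a single
        # elementwise product: SS_term = tr(H_m G) - tr(H_{m-1} G)
        increments = [hats[i + 1] - hats[i] for i in range(len(self.terms))]
        resid_proj = np.eye(n) - hats[-1]

        def term_stats(gmat):
            ss = np.array([float(np.sum(inc * gmat)) for inc in increments])
            ss_res = float(np.sum(resid_proj * gmat))
            ms = ss / np.array(dfs)
            ms_res = ss_res / df_resid
            return ss, ss_res, ms / ms_res

        ss_terms, ss_resid, f_obs = term_stats(g)

        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(self.terms))
        for _ in range(n_permutations):
            p = rng.permutation(n)
            gp = g[np.ix_(p, p)]
            _, _, f_perm = term_stats(gp)
            exceed += f_perm >= f_obs - 1e-12
        p_perm = (1.0 + exceed) / (1.0 + n_permutations)

        rows = []
        for i, t in enumerate(self.terms):
            rows.append([t, dfs[i], ss_terms[i], ss_terms[i] / dfs[i],
                         f_obs[i], ss_terms[i] / ss_total, p_perm[i]])
        rows.append(["Residuals", df_resid, ss_resid, ss_resid / df_resid,
                     np.nan, ss_resid / ss_total, np.nan])
        rows.append(["Total", n - 1, ss_total, np.nan, np.nan, np.nan, np.nan])
        table = pd.DataFrame(rows, columns=["term", "df", "SS", "MS",
                                            "pseudo_F", "R2", "p_perm"]).set_index("term")
        return PermanovaResults(table=table, n_permutations=n_permutations,
                                seed=seed, terms=self.terms)


@dataclass
class PermanovaResults:
    table: pd.DataFrame
    n_permutations: int
    seed: object
    terms: list

    @property
    def pseudo_F(self) -> pd.Series:
        return self.table.loc[self.terms, "pseudo_F"]

    @property
    def p_perm(self) -> pd.Series:
        return self.table.loc[self.terms, "p_perm"]

    @property
    def r2(self) -> pd.Series:
        return self.table.loc[self.terms, "R2"]

    def summary(self) -> str:
        with pd.option_context("display.float_format", "{:0.4g}".format):
            body = self.table.to_string()
        return (f"PERMANOVA (sequential SS, {self.n_permutations} permutations, "
                f"seed={self.seed})\n{body}")

    def to_dict(self) -> dict:
        out = {"n_permutations": self.n_permutations, "terms": list(self.terms)}
        for t in self.terms:
            r = self.table.loc[t]
            out[t] = {"df": int(r["df"]), "SS": float(r["SS"]), "MS": float(r["MS"]),
                      "pseudo_F": float(r["pseudo_F"]), "R2": float(r["R2"]),
                      "p_perm": float(r["p_perm"])}
        out["residual_SS"] = float(self.table.loc["Residuals", "SS"])
        out["total_SS"] = float(self.table.loc["Total", "SS"])
        return out


def permanova(dm: DistanceMatrix, factors: pd.DataFrame, terms,
              n_perm: int = 999, seed=None) -> PermanovaResults:
    """Functional wrapper around :class:`Permanova`."""
    return Permanova(dm, factors, terms).fit(n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------


def pcoa_embedding(d: np.ndarray):
    """Principal-coordinates embedding of a distance matrix.

    Returns ``(coords_real, coords_imag)``: axes with positive eigenvalues
    scaled by sqrt(lambda), and 'imaginary' axes from negative eigenvalues
    scaled by sqrt(-lambda).  Squared distances in the embedding are
    d_real^2 - d_imag^2.
    """
    g = _gower_centre(d)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-9 * max(1.0, np.abs(vals).max())
    pos, neg = vals > tol, vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


class BetaDispersion:
    """Homogeneity of multivariate dispersions across groups.

    ``centre`` is ``"centroid"`` (group mean in PCoA space, default) or
    ``"spatial_median"`` (coordinate-wise minimiser of summed embedding
    distance, computed by Weiszfeld iteration on the real axes with the
    imaginary correction applied at distance evaluation).
    """

    def __init__(self, dm: DistanceMatrix, groups: pd.Series, centre: str = "centroid"):
        if centre not in ("centroid", "spatial_median"):
            raise ValueError(f"unknown centre {centre!r}")
        self.dm = dm
        self.groups = pd.Series(groups).loc[dm.ids]
        sizes = self.groups.value_counts()
        if (sizes < 2).any():
            small = sizes[sizes < 2].index.tolist()
            raise ValueError(f"groups with fewer than 2 samples: {small}")
        self.centre = centre

    def fit(self) -> "BetaDispersionResults":
        real, imag = pcoa_embedding(self.dm.values)
        n = self.dm.n
        z = np.zeros(n)
        n_clipped = 0
        for level in self.groups.unique():
            idx = np.where(self.groups.values == level)[0]
            cr = self._centre_of(real[idx])
            ci = self._centre_of(imag[idx]) if imag.shape[1] else np.zeros(0)
            d2 = ((real[idx] - cr) ** 2).sum(axis=1)
            if imag.shape[1]:
                d2 = d2 - ((imag[idx] - ci) ** 2).sum(axis=1)
            n_clipped += int((d2 < 0).sum())
            z[idx] = np.sqrt(np.clip(d2, 0.0, None))
        k = self.groups.nunique()
        df1, df2 = k - 1, n - k
        grand = z.mean()
        means = pd.Series({lv: z[self.groups.values == lv].mean()
                           for lv in self.groups.unique()})
        ss_between = sum(((self.groups.values == lv).sum()) * (means[lv] - grand) ** 2
                         for lv in means.index)
        ss_within = sum(((z[self.groups.values == lv] - means[lv]) ** 2).sum()
                        for lv in means.index)
        if ss_within <= 0:
            f = np.inf if ss_between > 0 else 0.0
        else:
            f = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        dist = pd.Series(z, index=self.dm.ids, name="distance_to_centre")
        return BetaDispersionResults(distances=dist, group_means=means,
                                     F=float(f), df1=df1, df2=df2, p=p,
                                     centre=self.centre, n_clipped=n_clipped)

    def _centre_of(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] == 0:
            return np.zeros(0)
        if self.centre == "centroid":
            return x.mean(axis=0)
        c = x.mean(axis=0)
        for _ in range(500):
            d = np.sqrt(((x - c) ** 2).sum(axis=1))
            d = np.where(d < 1e-12, 1e-12, d)
            new = (x / d[:, None]).sum(axis=0) / (1.0 / d).sum()
            if np.allclose(new, c, atol=1e-10):
                return new
            c = new
        return c


@dataclass
class BetaDispersionResults:
    distances: pd.Series
    group_means: pd.Series
    F: float
    df1: int
    df2: int
    p: float
    centre: str
    n_clipped: int = 0

    def summary(self) -> str:
        means = ", ".join(f"{k}={v:.4g}" for k, v in self.group_means.items())
        return (f"Multivariate dispersion ({self.centre}): "
                f"F_{self.df1},{self.df2} = {self.F:.4g}, P = {self.p:.4g}\n"
                f"group mean distances to centre: {means}")

    def to_dict(self) -> dict:
        return {"F": self.F, "df1": self.df1, "df2": self.df2, "p": self.p,
                "centre": self.centre,
                "group_means": {str(k): float(v) for k, v in self.group_means.items()}}


def dispersion_test(dm: DistanceMatrix, groups, centre: str = "centroid"):
    """Functional wrapper around :class:`BetaDispersion`."""
    return BetaDispersion(dm, groups, centre=centre).fit()


# ---------------------------------------------------------------------------


class PoissonRichness:
    """Poisson log-link GLM of per-sample richness on one grouping factor."""

    def __init__(self, richness: pd.Series, groups: pd.Series):
        richness = pd.Series(richness)
        self.y = richness.astype(float)
        self.groups = pd.Series(groups).loc[richness.index]
        if (self.y < 0).any():
            raise ValueError("richness must be non-negative")
        if self.groups.nunique() < 2:
            raise ValueError("need at least two groups")

    @staticmethod
    def _deviance(y, mu):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(term - (y - mu)))

    @staticmethod
    def _irls(y, x, max_iter=100, tol=1e-10):
        beta = np.zeros(x.shape[1])
        mean = max(y.mean(), 1e-8)
        beta[0] = np.log(mean)
        for _ in range(max_iter):
            eta = x @ beta
            mu = np.exp(np.clip(eta, -30, 30))
            w = mu
            z = eta + (y - mu) / mu
            wx = x * w[:, None]
            beta_new = np.linalg.solve(x.T @ wx, wx.T @ z)
            if np.max(np.abs(beta_new - beta)) < tol:
                return beta_new, np.exp(x @ beta_new)
            beta = beta_new
        raise RuntimeError("IRLS did not converge after "
                           f"{max_iter} iterations (beta={beta})")

    def fit(self) -> "PoissonRichnessResults":
        y = self.y.values
        n = len(y)
        x_null = np.ones((n, 1))
        x_grp = np.hstack([x_null, _dummy(self.groups)])
        _, mu_null = self._irls(y, x_null)
        _, mu_grp = self._irls(y, x_grp)
        dev_null = self._deviance(y, mu_null)
        dev_grp = self._deviance(y, mu_grp)
        chi2 = max(dev_null - dev_grp, 0.0)
        k = self.groups.nunique()
        p = float(sps.chi2.sf(chi2, k - 1))
        means = self.y.groupby(self.groups).mean()
        ses = self.y.groupby(self.groups).sem()
        return PoissonRichnessResults(group_means=means, group_se=ses,
                                      chi2=float(chi2), df=k - 1, p=p,
                                      deviance_null=dev_null, deviance_model=dev_grp)


@dataclass
class PoissonRichnessResults:
    group_means: pd.Series
    group_se: pd.Series
    chi2: float
    df: int
    p: float
    deviance_null: float
    deviance_model: float

    def summary(self) -> str:
        lines = [f"{k}: mean = {self.group_means[k]:.2f}, s.e. = {self.group_se[k]:.2f}"
                 for k in self.group_means.index]
        lines.append(f"Poisson GLM chi2 = {self.chi2:.2f} (df={self.df}), P = {self.p:.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p,
                "group_means": {str(k): float(v) for k, v in self.group_means.items()}}


def poisson_richness_test(richness, groups) -> PoissonRichnessResults:
    """Functional wrapper around :class:`PoissonRichness`."""
    return PoissonRichness(richness, groups).fit()
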