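"""Robustness experiments: depth equalisation and read trimming.

Depth equalisation repeatedly thins the count matrix so every sample is
represented by the same number of reads (the minimum row total by default)
and re-runs the main analyses — spatial and seasonal PERMANOVA and the two
distance-decay fits — recording per-matrix p-values and slope signs.  To
keep 1000 repetitions desk-scale, permutation inference is not re-run for
the decay fits; their slope signs are tallied instead, and the PERMANOVAs
use a reduced permutation count.

Read trimming compares taxonomic assignments of the same reads at a
reference length against a 3'-trimmed length: fraction of identical hits
(with and without reads unassigned in either set), VT richness, and mean
per-sample Bray-Curtis distance and Pearson correlation between the matched
community profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .commstats import bray_curtis, distance_matrix
from .community import CommunityMatrix
from .decay import DistanceDecay, build_pairs
from .models import Permanova


class ThinningError(ValueError):
    pass


def thin_matrix(m: CommunityMatrix, depth: int, seed=None) -> CommunityMatrix:
    """Subsample every row without replacement to exactly ``depth`` reads.

    Each row is a multivariate-hypergeometric draw from its own counts, so
    zero cells can never gain reads.  A row with fewer than ``depth`` reads
    is an error naming the sample.
    """
    if m.mode != "counts":
        raise ValueError("thinning requires a counts-mode matrix")
    rng = np.random.default_rng(seed)
    rows = []
    for sid, row in m.data.iterrows():
        total = int(row.sum())
        if total < depth:
            raise ThinningError(f"sample {sid!r} has {total} reads < depth {depth}")
        if total == depth:
            rows.append(row.values.astype(np.int64))
        else:
            rows.append(rng.multivariate_hypergeometric(row.values.astype(np.int64),
                                                        depth))
    data = pd.DataFrame(np.vstack(rows), index=m.data.index, columns=m.data.columns)
    return CommunityMatrix(data, mode="counts", meta=m.meta)


@dataclass
class ThinningSummary:
    n_matrices: int
    depth: int
    alpha: float
    frac_spatial_significant: float
    frac_seasonal_significant: float
    frac_spatial_slope_negative: float       # similarity decays = dissimilarity grows
    frac_temporal_slope_negative: float
    frac_temporal_slope_positive: float
    per_matrix: pd.DataFrame = field(repr=False, default=None)
    # "<" vs "<=" threshold reading, both tallied
    frac_spatial_significant_le: float = None
    frac_seasonal_significant_le: float = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "per_matrix"}
        return d


def _default_subsets(meta: pd.DataFrame):
    """Infer the spatial and seasonal analysis subsets from the design.

    Spatial subset: samples collected on the date observed in the largest
    number of plots (ties broken toward the latest date).  Seasonal subset:
    samples of the plot with the most distinct collection dates.
    """
    meta = meta.copy()
    by_date = meta.groupby("date")["plot"].nunique()
    best = by_date[by_date == by_date.max()].index.max()
    spatial = meta.index[meta["date"] == best]
    by_plot = meta.groupby("plot")["date"].nunique()
    plot = by_plot.sort_values(kind="mergesort").index[-1]
    seasonal = meta.index[meta["plot"] == plot]
    return list(spatial), list(seasonal)


def run_main_analyses(m: CommunityMatrix, n_perm: int = 999, seed=None,
                      decay_perm: int | None = 999, alpha: float = 0.05) -> dict:
    """Spatial/seasonal PERMANOVA and decay fits on one count matrix.

    ``decay_perm=None`` skips permutation inference for the decay slopes
    (the thinning study records only their signs).
    """
    meta = m.meta
    if meta is None:
        raise ValueError("matrix has no metadata")
    spatial_ids, seasonal_ids = _default_subsets(meta)
    rng = np.random.default_rng(seed)
    out: dict = {}

    sub = m.subset(spatial_ids).normalise()
    dm = distance_matrix(sub)
    fac = meta.loc[spatial_ids, ["plot"]].astype(str)
    res = Permanova(dm, fac, ["plot"]).fit(n_permutations=n_perm,
                                           seed=int(rng.integers(2 ** 31)))
    out["spatial_permanova"] = res
    pairs = build_pairs(dm, positions=meta.loc[spatial_ids])
    model = DistanceDecay(pairs)
    out["spatial_decay"] = model.fit()
    if decay_perm:
        out["spatial_decay_perm"] = model.permutation_test(
            n_perm=decay_perm, seed=int(rng.integers(2 ** 31)))

    sub = m.subset(seasonal_ids).normalise()
    dm = distance_matrix(sub)
    fac = meta.loc[seasonal_ids].copy()
    fac["season"] = fac["date"].dt.strftime("%Y-%m-%d")
    fac["sample_point"] = fac["grid_point"].astype(str)
    res = Permanova(dm, fac, ["season", "sample_point"]).fit(
        n_permutations=n_perm, seed=int(rng.integers(2 ** 31)))
    out["seasonal_permanova"] = res
    if decay_perm:
        # sequential SS depend on term order; both orders are reported
        out["seasonal_permanova_reversed"] = Permanova(
            dm, fac, ["sample_point", "season"]).fit(
            n_permutations=n_perm, seed=int(rng.integers(2 ** 31)))
    pairs = build_pairs(dm, dates=meta.loc[seasonal_ids, "date"])
    model = DistanceDecay(pairs)
    out["temporal_decay"] = model.fit()
    if decay_perm:
        out["temporal_decay_perm"] = model.permutation_test(
            n_perm=decay_perm, seed=int(rng.integers(2 ** 31)))
    return out


def thinning_study(m: CommunityMatrix, n_matrices: int = 1000,
                   depth: int | None = None, alpha: float = 0.05,
                   n_perm: int = 199, seed=None) -> ThinningSummary:
    """Thin ``n_matrices`` times to a common depth and re-run the analyses.

    ``depth`` defaults to the minimum row total.  Per matrix, the spatial
    and seasonal PERMANOVA p-values (``n_perm`` label permutations each)
    and the spatial/temporal decay slopes (no permutation inference) are
    recorded; the summary reports the fractions significant at ``alpha``
    (both ``<`` and ``<=`` readings) and the slope-sign fractions.
    """
    if m.mode != "counts":
        raise ValueError("thinning study requires a counts-mode matrix")
    if depth is None:
        depth = int(m.row_totals().min())
    rng = np.random.default_rng(seed)
    records = []
    for b in range(n_matrices):
        s = int(rng.integers(2 ** 31))
        thinned = thin_matrix(m, depth, seed=s)
        res = run_main_analyses(thinned, n_perm=n_perm,
                                seed=int(rng.integers(2 ** 31)), decay_perm=None)
        records.append({
            "matrix": b, "seed": s,
            "spatial_p": float(res["spatial_permanova"].p_perm.iloc[0]),
            "seasonal_p_season": float(res["seasonal_permanova"].p_perm.loc["season"]),
            "seasonal_p_sample": float(res["seasonal_permanova"].p_perm.loc["sample_point"]),
            "spatial_slope": res["spatial_decay"].slope_logit,
            "temporal_slope": res["temporal_decay"].slope_logit,
        })
    per = pd.DataFrame(records).set_index("matrix")
    seas_sig = (per["seasonal_p_season"] < alpha) | (per["seasonal_p_sample"] < alpha)
    seas_sig_le = (per["seasonal_p_season"] <= alpha) | (per["seasonal_p_sample"] <= alpha)
    return ThinningSummary(
        n_matrices=n_matrices, depth=depth, alpha=alpha,
        frac_spatial_significant=float((per["spatial_p"] < alpha).mean()),
        frac_seasonal_significant=float(seas_sig.mean()),
        frac_spatial_slope_negative=float((per["spatial_slope"] < 0).mean()),
        frac_temporal_slope_negative=float((per["temporal_slope"] < 0).mean()),
        frac_temporal_slope_positive=float((per["temporal_slope"] > 0).mean()),
        per_matrix=per,
        frac_spatial_significant_le=float((per["spatial_p"] <= alpha).mean()),
        frac_seasonal_significant_le=float(seas_sig_le.mean()),
    )


# ---------------------------------------------------------------------------
# read-trimming comparison


@dataclass
class TrimComparison:
    trimmed_length: int
    n_reads_compared: int
    identical_hit_pct: float
    identical_hit_pct_no_nohits: float
    richness: int
    richness_pct_of_reference: float
    mean_bc_to_reference: float
    mean_pearson_r_to_reference: float
    n_samples_compared: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _profiles(assignments: dict, sample_of: dict) -> pd.DataFrame:
    rows = [(sample_of[r], v) for r, v in assignments.items() if v is not None]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["sample", "vt"])
    return pd.crosstab(df["sample"], df["vt"])


def trim_compare(reference_assignments: dict, trimmed_assignments: dict,
                 sample_of: dict, trimmed_length: int = 0,
                 min_sample_reads: int = 10) -> TrimComparison:
    """Compare per-read VT assignments between two read lengths.

    Both maps must cover exactly the same reads (value ``None`` for an
    unassigned read).  The first identity metric counts ``None == None`` as
    identical; the second omits any read unassigned in either set.
    Community profiles are built per sample from assigned reads, samples
    with fewer than ``min_sample_reads`` assigned reads in either set are
    dropped, profiles are normalised to proportions over the union VT set,
    and mean Bray-Curtis distance and mean Pearson correlation across the
    matched samples are reported.
    """
    ref_reads, trim_reads_ = set(reference_assignments), set(trimmed_assignments)
    if ref_reads != trim_reads_:
        diff = sorted(ref_reads ^ trim_reads_)
        raise ValueError(f"read sets differ; symmetric difference (first 5): {diff[:5]}")
    reads = sorted(ref_reads)
    n = len(reads)
    ident = sum(reference_assignments[r] == trimmed_assignments[r] for r in reads)
    both = [r for r in reads
            if reference_assignments[r] is not None and trimmed_assignments[r] is not None]
    ident_both = sum(reference_assignments[r] == trimmed_assignments[r] for r in both)

    ref_rich = len({v for v in reference_assignments.values() if v is not None})
    trim_rich = len({v for v in trimmed_assignments.values() if v is not None})

    prof_ref = _profiles(reference_assignments, sample_of)
    prof_trim = _profiles(trimmed_assignments, sample_of)
    samples = sorted(set(prof_ref.index) & set(prof_trim.index))
    keep = [s for s in samples
            if prof_ref.loc[s].sum() >= min_sample_reads
            and prof_trim.loc[s].sum() >= min_sample_reads]
    vt_union = sorted(set(prof_ref.columns) | set(prof_trim.columns))
    bcs, rs = [], []
    for s in keep:
        a = prof_ref.reindex(columns=vt_union, fill_value=0).loc[s].values.astype(float)
        b = prof_trim.reindex(columns=vt_union, fill_value=0).loc[s].values.astype(float)
        a, b = a / a.sum(), b / b.sum()
        bcs.append(bray_curtis(a, b))
        if np.std(a) > 0 and np.std(b) > 0:
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    return TrimComparison(
        trimmed_length=trimmed_length,
        n_reads_compared=n,
        identical_hit_pct=100.0 * ident / n if n else float("nan"),
        identical_hit_pct_no_nohits=(100.0 * ident_both / len(both)
                                     if both else float("nan")),
        richness=trim_rich,
        richness_pct_of_reference=(100.0 * trim_rich / ref_rich
                                   if ref_rich else float("nan")),
        mean_bc_to_reference=float(np.mean(bcs)) if bcs else float("nan"),
        mean_pearson_r_to_reference=float(np.mean(rs)) if rs else float("nan"),
        n_samples_compared=len(keep),
    )
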