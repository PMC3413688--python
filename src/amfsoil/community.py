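"""Sample-by-virtual-taxon community matrices.

A :class:`CommunityMatrix` wraps a pandas DataFrame whose rows are soil
samples and whose columns are virtual taxa (VT), together with optional
per-sample metadata (plot, grid point, collection date, coordinates in
metres).  Matrices are either in ``counts`` mode (non-negative integers,
read counts) or ``proportions`` mode (rows summing to one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("plot", "grid_point", "date", "x_m", "y_m")


class EmptyMatrixError(ValueError):
    """All samples were removed during filtering."""


@dataclass
class FilterLog:
    """Record of what :func:`filter_matrix` removed and why."""

    samples_low_count: list[str] = field(default_factory=list)
    vt_singleton: list[str] = field(default_factory=list)
    vt_empty: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "samples_low_count": list(self.samples_low_count),
            "vt_singleton": list(self.vt_singleton),
            "vt_empty": list(self.vt_empty),
        }


class CommunityMatrix:
    """Sample x VT abundance table with sample metadata.

    Parameters
    ----------
    data :
        DataFrame indexed by sample id with one column per VT.
    mode :
        ``"counts"`` (integer read counts) or ``"proportions"`` (row sums 1).
    meta :
        Optional DataFrame indexed by sample id.  Recognised columns are
        ``plot``, ``grid_point``, ``date``, ``x_m``, ``y_m``; extra columns
        are carried along untouched.
    """

    def __init__(self, data: pd.DataFrame, mode: str = "counts",
                 meta: pd.DataFrame | None = None):
        if mode not in ("counts", "proportions"):
            raise ValueError(f"unknown mode {mode!r}")
        if (np.asarray(data.values, dtype=float) < 0).any():
            raise ValueError("abundances must be non-negative")
        if mode == "counts":
            vals = np.asarray(data.values, dtype=float)
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts mode requires integer values")
            data = data.astype(np.int64)
        else:
            data = data.astype(float)
            sums = data.values.sum(axis=1)
            nonzero = sums > 0
            if not np.allclose(sums[nonzero], 1.0, atol=1e-9):
                raise ValueError("proportions mode requires non-empty rows to sum to 1")
        if data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if data.columns.has_duplicates:
            raise ValueError("duplicate VT ids")
        if meta is not None:
            missing = set(data.index) - set(meta.index)
            if missing:
                raise KeyError(f"samples missing from metadata: {sorted(missing)}")
            meta = meta.loc[data.index].copy()
        self.data = data
        self.mode = mode
        self.meta = meta

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def vt_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def richness(self) -> pd.Series:
        """Observed VT richness per sample (number of non-zero cells)."""
        return (self.data > 0).sum(axis=1)

    def subset(self, samples) -> "CommunityMatrix":
        samples = list(samples)
        meta = self.meta.loc[samples] if self.meta is not None else None
        return CommunityMatrix(self.data.loc[samples], mode=self.mode, meta=meta)

    def copy(self) -> "CommunityMatrix":
        meta = self.meta.copy() if self.meta is not None else None
        return CommunityMatrix(self.data.copy(), mode=self.mode, meta=meta)

    # -- transformations -------------------------------------------------
    def normalise(self) -> "CommunityMatrix":
        """Divide each row by its total (proportional composition).

        Raises ``ValueError`` naming the first offending sample if any row
        sums to zero.  Already-normalised matrices pass through unchanged
        (idempotent).
        """
        sums = self.data.sum(axis=1)
        zero = sums[sums == 0]
        if len(zero):
            raise ValueError(f"sample {zero.index[0]!r} has zero total; cannot normalise")
        props = self.data.div(sums, axis=0)
        return CommunityMatrix(props, mode="proportions", meta=self.meta)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, mode: str = "counts",
                 meta: pd.DataFrame | None = None) -> "CommunityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, mode=mode, meta=meta)


def read_design(path) -> pd.DataFrame:
    """Read a sampling-design TSV (sample_id, plot, grid_point, date, x_m, y_m)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "plot": str})
    meta = meta.set_index("sample_id")
    if "date" in meta.columns:
        meta["date"] = pd.to_datetime(meta["date"])
    return meta


def write_design(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    if "date" in out.columns:
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index_label="sample_id")


def filter_matrix(m: CommunityMatrix, min_sample_hits: int = 10,
                  drop_singleton_vt: bool = True,
                  singleton_rule: str = "reads") -> tuple[CommunityMatrix, FilterLog]:
    """Apply the study's sample and singleton-VT filters.

    Samples whose row total is below ``min_sample_hits`` are removed, then
    VT that are singletons across the whole retained matrix, and the two
    checks are iterated to a fixed point so the result does not depend on
    the order in which they are stated.  ``singleton_rule`` is ``"reads"``
    (a VT with exactly one read in total, the default reading) or
    ``"samples"`` (a VT present in exactly one sample).  VT left with zero
    reads after sample removal are dropped and logged separately.

    Returns the filtered matrix and a :class:`FilterLog` partitioning the
    removed entities by reason.
    """
    if m.mode != "counts":
        raise ValueError("filter_matrix requires a counts-mode matrix")
    if singleton_rule not in ("reads", "samples"):
        raise ValueError(f"unknown singleton_rule {singleton_rule!r}")
    data = m.data.copy()
    log = FilterLog()
    while True:
        changed = False
        totals = data.sum(axis=1)
        low = totals[totals < min_sample_hits].index
        if len(low):
            log.samples_low_count.extend(low)
            data = data.drop(index=low)
            changed = True
        if data.shape[0] == 0:
            raise EmptyMatrixError("all samples removed by the <{} hits filter"
                                   .format(min_sample_hits))
        col_tot = data.sum(axis=0)
        empty = col_tot[col_tot == 0].index
        if len(empty):
            log.vt_empty.extend(empty)
            data = data.drop(columns=empty)
            changed = True
        if drop_singleton_vt:
            if singleton_rule == "reads":
                single = data.columns[data.sum(axis=0) == 1]
            else:
                single = data.columns[(data > 0).sum(axis=0) == 1]
            if len(single):
                log.vt_singleton.extend(single)
                data = data.drop(columns=single)
                changed = True
        if not changed:
            break
    meta = m.meta.loc[data.index] if m.meta is not None else None
    return CommunityMatrix(data, mode="counts", meta=meta), log
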