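"""End-to-end orchestration: demux -> assign -> filter -> normalise -> stats.

:func:`run_study` executes the whole workflow on in-memory inputs (or a
precomputed count matrix) and returns a report dict mirroring the survey's
summary tables: preprocessing statistics, matrix dimensions before and
after filtering, a per-plot/season summary, PERMANOVA tables, dispersion
and richness tests, decay fits with permutation p-values, and optionally a
thinning summary.  Every random stage takes a seed derived from a single
run seed, recorded in the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assign import MatchCriteria, assign_reads, build_matrix
from .commstats import distance_matrix, rarefaction_curve
from .community import CommunityMatrix, filter_matrix
from .models import BetaDispersion, PoissonRichness
from .preprocess import NS31, BarcodeMap, demultiplex, length_summary
from .robustness import _default_subsets, run_main_analyses, thinning_study

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Paths and parameters for a full CLI run (all stages skippable by
    supplying the downstream artifact directly)."""

    reads_fasta: str | None = None
    barcodes_tsv: str | None = None
    reference_fasta: str | None = None
    hits_tsv: str | None = None
    matrix_tsv: str | None = None
    design_tsv: str | None = None
    fwd_primer: str = NS31
    min_length: int = 170
    min_identity: float = 97.0
    max_len_diff: int = 10
    max_evalue: float = 1e-50
    min_sample_hits: int = 10
    n_permutations: int = 999
    thinning_matrices: int = 0
    seed: int = 0
    extra: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra = extra
        return cfg


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def summarise_by_group(m: CommunityMatrix) -> pd.DataFrame:
    """Per plot x season summary: n samples, mean reads (range), total VT.

    VT totals are unions over the group's samples, not sums of per-sample
    richness.
    """
    if m.meta is None:
        raise ValueError("matrix has no metadata")
    meta = m.meta
    rows = []
    for (plot, date), idx in meta.groupby(["plot", "date"], sort=True).groups.items():
        sub = m.data.loc[list(idx)]
        totals = sub.sum(axis=1)
        n_vt = int((sub.sum(axis=0) > 0).sum())
        rows.append({
            "plot": plot, "date": pd.Timestamp(date).strftime("%Y-%m-%d"),
            "n_samples": len(idx),
            "mean_reads": float(totals.mean()) if len(idx) else float("nan"),
            "min_reads": int(totals.min()) if len(idx) else 0,
            "max_reads": int(totals.max()) if len(idx) else 0,
            "n_vt": n_vt,
        })
    return pd.DataFrame(rows)


def run_study(matrix: CommunityMatrix, n_permutations: int = 999,
              thinning_matrices: int = 0, thinning_perm: int = 199,
              alpha: float = 0.05, seed: int = 0,
              preprocess_stats=None) -> dict:
    """All statistical analyses on a filtered count matrix; returns the report."""
    rng = np.random.default_rng(seed)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software": {"package": "amfsoil", "version": __version__},
        "seed": seed,
        "matrix": {"n_samples": matrix.shape[0], "n_vt": matrix.shape[1],
                   "total_reads": int(matrix.row_totals().sum()),
                   "min_sample_reads": int(matrix.row_totals().min()),
                   "max_sample_reads": int(matrix.row_totals().max())},
    }
    if preprocess_stats is not None:
        report["preprocess"] = {k: v for k, v in preprocess_stats.__dict__.items()
                                if not k.startswith("_")}
    report["group_summary"] = summarise_by_group(matrix).to_dict(orient="records")

    analyses = run_main_analyses(matrix, n_perm=n_permutations,
                                 seed=int(rng.integers(2 ** 31)),
                                 decay_perm=n_permutations, alpha=alpha)
    report["spatial_permanova"] = analyses["spatial_permanova"].to_dict()
    report["seasonal_permanova"] = analyses["seasonal_permanova"].to_dict()
    report["seasonal_permanova_reversed"] = (
        analyses["seasonal_permanova_reversed"].to_dict())
    report["spatial_decay"] = analyses["spatial_decay"].to_dict()
    report["spatial_decay"]["p_perm"] = analyses["spatial_decay_perm"].p_perm
    report["temporal_decay"] = analyses["temporal_decay"].to_dict()
    report["temporal_decay"]["p_perm"] = analyses["temporal_decay_perm"].p_perm

    spatial_ids, seasonal_ids = _default_subsets(matrix.meta)
    sub = matrix.subset(spatial_ids)
    dm = distance_matrix(sub.normalise())
    disp = BetaDispersion(dm, matrix.meta.loc[spatial_ids, "plot"]).fit()
    report["spatial_dispersion"] = disp.to_dict()
    rich = PoissonRichness(sub.richness(), matrix.meta.loc[spatial_ids, "plot"]).fit()
    report["spatial_richness"] = rich.to_dict()

    seas = matrix.subset(seasonal_ids)
    season_label = matrix.meta.loc[seasonal_ids, "date"].dt.strftime("%Y-%m-%d")
    rich_s = PoissonRichness(seas.richness(), season_label).fit()
    report["seasonal_richness"] = rich_s.to_dict()
    dm_s = distance_matrix(seas.normalise())
    disp_s = BetaDispersion(dm_s, season_label).fit()
    report["seasonal_dispersion"] = disp_s.to_dict()

    depths = [1] + list(range(10, int(matrix.row_totals().min()) + 1, 3))
    curve = rarefaction_curve(matrix, depths=sorted(set(depths)))
    report["rarefaction"] = curve.to_dict(orient="records")

    if thinning_matrices:
        summary = thinning_study(matrix, n_matrices=thinning_matrices,
                                 alpha=alpha, n_perm=thinning_perm,
                                 seed=int(rng.integers(2 ** 31)))
        report["thinning"] = summary.to_dict()
    return report


def run(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Either start from reads (+barcodes, +hits, +reference lengths) or from
    a precomputed count-matrix TSV with a design TSV.  Intermediate-file
    checksums are recorded when paths are given.
    """
    from .community import read_design
    from .preprocess import read_fasta

    report_inputs = {}
    for label in ("reads_fasta", "barcodes_tsv", "reference_fasta",
                  "hits_tsv", "matrix_tsv", "design_tsv"):
        p = getattr(config, label)
        if p:
            if not Path(p).exists():
                raise FileNotFoundError(f"{label}: {p}")
            report_inputs[label] = {"path": str(p), "sha256": file_checksum(p)}

    if config.design_tsv is None:
        raise ValueError("a design TSV is required")
    design = read_design(config.design_tsv)

    stats = None
    if config.matrix_tsv:
        matrix = CommunityMatrix.from_tsv(config.matrix_tsv, mode="counts",
                                          meta=design)
    else:
        if not (config.reads_fasta and config.barcodes_tsv and config.hits_tsv
                and config.reference_fasta):
            raise ValueError("need reads, barcodes, hits and reference "
                             "(or a matrix TSV)")
        barcodes = BarcodeMap.from_tsv(config.barcodes_tsv)
        reads, stats = demultiplex(read_fasta(config.reads_fasta), barcodes,
                                   fwd_primer=config.fwd_primer,
                                   min_length=config.min_length)
        qlen = {r.read_id: r.length for r in reads}
        slen = {rid: len(seq) for rid, seq in read_fasta(config.reference_fasta)}
        criteria = MatchCriteria(config.min_identity, config.max_len_diff,
                                 config.max_evalue)
        assigned = assign_reads(config.hits_tsv, qlen, slen, criteria)
        sample_of = {r.read_id: r.sample_id for r in reads}
        matrix = build_matrix(((rid, sample_of[rid], vt)
                               for rid, vt in assigned.items()), design)
    shape_before = matrix.shape
    filtered, flog = filter_matrix(matrix, min_sample_hits=config.min_sample_hits)
    report = run_study(filtered, n_permutations=config.n_permutations,
                       thinning_matrices=config.thinning_matrices,
                       seed=config.seed, preprocess_stats=stats)
    report["inputs"] = report_inputs
    report["filtering"] = {"shape_before": list(shape_before),
                           "shape_after": list(filtered.shape),
                           "removed": flog.as_dict()}
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
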