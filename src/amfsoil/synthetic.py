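"""Synthetic study generator: reference sequences, sampling design, true
communities, barcoded reads and tabular alignment hits.

The generator emulates the structure of a barcoded 454 soil survey of
arbuscular mycorrhizal fungi: three 10x10 m forest plots with a 3x3
sampling grid at 5 m spacing, one plot revisited four times across a
growing season (late May to early September), 37 virtual taxa, reads of
170-557 nt (median ~382), a small fraction (~5.8%) of reads assignable to
AMF, per-sample assigned-read counts spanning 13-1986, plot-level
compositional differences with no seasonal effect, and a weak logit-scale
decay of community similarity with distance.

Communities follow a Dirichlet-compositional model: per-sample VT
proportions are Dirichlet draws around softmax-transformed log-abundance
fields that combine a common VT abundance profile, per-plot shifts, optional
per-season shifts, and a spatially autocorrelated Gaussian field (Gaussian
kernel) whose standard deviation is calibrated by simulation so the fitted
logit decay slope approximates ``spatial_decay_beta``.  Everything is a
pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .preprocess import NS31, BarcodeMap, RawRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Empirically calibrated: fitted September logit decay slope ~ -c * sigma_f^2
#: for the default kernel range and plot effect (see docs/methods.md).
DECAY_SLOPE_CALIBRATION = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator (defaults = the survey)."""

    n_vt: int = 37
    plots: tuple = ("A", "B", "C")
    repeated_plot: str = "A"          # sampled at every date; others last date only
    grid_side: int = 3
    grid_spacing_m: float = 5.0
    plot_centres: tuple = ((0.0, 0.0), (40.0, 0.0), (20.0, 34.641))
    dates: tuple = ("2009-05-25", "2009-06-30", "2009-07-22", "2009-09-03")
    plot_effect_size: float = 0.4     # sd of per-plot log-abundance shifts
    season_effect_size: float = 0.0   # sd of per-date shifts (none observed)
    spatial_decay_beta: float = -0.011   # target logit slope per metre
    spatial_range_m: float = 25.0     # Gaussian-kernel range of the field
    base_log_sd: float = 2.0          # sd of the common VT log-abundance profile
    concentration: float = 30.0       # Dirichlet concentration (overdispersion)
    depth_range: tuple = (13, 1986)   # per-sample AMF-assigned read counts
    amf_read_fraction: float = 0.058  # fraction of reads that are AMF
    read_length: tuple = (170, 557)
    length_beta: tuple = (2.35, 2.0)  # Beta shape giving median length ~382
    error_rate: float = 0.0025        # per-base substitution rate
    ref_length: int = 557
    divergence: float = 10.0          # min pairwise reference dissimilarity, %
    decoy_hit_fraction: float = 0.05  # AMF reads also hit a wrong reference
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.amf_read_fraction <= 1:
            raise ValueError("amf_read_fraction must be in [0, 1]")
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise ValueError("invalid depth_range")
        if self.read_length[0] > self.read_length[1]:
            raise ValueError("invalid read_length range")
        if self.read_length[1] > self.ref_length:
            raise ValueError("read_length max exceeds reference length")
        if len(self.plot_centres) != len(self.plots):
            raise ValueError("plot_centres must match plots")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# sampling design


def make_design(cfg: SimulationConfig) -> pd.DataFrame:
    """Sampling-design table: sample_id, plot, grid_point, date, x_m, y_m."""
    rows = []
    half = (cfg.grid_side - 1) * cfg.grid_spacing_m / 2.0
    for plot, (cx, cy) in zip(cfg.plots, cfg.plot_centres):
        dates = cfg.dates if plot == cfg.repeated_plot else cfg.dates[-1:]
        for date in dates:
            mmdd = date[5:7] + date[8:10]
            for g in range(1, cfg.grid_side ** 2 + 1):
                gx = ((g - 1) % cfg.grid_side) * cfg.grid_spacing_m - half + cx
                gy = ((g - 1) // cfg.grid_side) * cfg.grid_spacing_m - half + cy
                rows.append((f"{plot}{g}-{mmdd}", plot, g, date, gx, gy))
    df = pd.DataFrame(rows, columns=["sample_id", "plot", "grid_point",
                                     "date", "x_m", "y_m"]).set_index("sample_id")
    df["date"] = pd.to_datetime(df["date"])
    return df


# ---------------------------------------------------------------------------
# reference database and barcodes


def _random_seq(rng, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    n = min(len(a), len(b))
    return float((a[:n] == b[:n]).mean()) * 100.0


def make_reference(n_vt: int, seq_length: int = 557, divergence: float = 10.0,
                   seed=0) -> dict:
    """``{vt_id: sequence}`` with all pairwise identities <= 100 - divergence.

    Identity is positional over the shared prefix (the alignment model used
    throughout the simulator).  Offending sequences are re-drawn; if the
    requested divergence cannot be achieved the construction errors out.
    """
    rng = np.random.default_rng(seed)
    seqs: list[np.ndarray] = []
    limit = 100.0 - divergence
    for _ in range(n_vt):
        for attempt in range(200):
            cand = _random_seq(rng, seq_length)
            if all(_identity(cand, s) <= limit for s in seqs):
                seqs.append(cand)
                break
        else:
            raise ValueError(f"cannot achieve {divergence}% divergence for "
                             f"{n_vt} sequences of {seq_length} nt")
    return {f"VT{i + 1:05d}": bytes(s).decode() for i, s in enumerate(seqs)}


def make_barcodes(sample_ids, seed=0, length: int = 8, min_hamming: int = 3) -> BarcodeMap:
    """One unique random barcode per sample, pairwise Hamming >= ``min_hamming``."""
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for _ in sample_ids:
        for attempt in range(5000):
            cand = _BASES[rng.integers(0, 4, size=length)]
            if all(int((cand != c).sum()) >= min_hamming for c in chosen):
                chosen.append(cand)
                break
        else:
            raise ValueError("could not generate enough distinct barcodes")
    return BarcodeMap([(bytes(c).decode(), s) for c, s in zip(chosen, sample_ids)])


# ---------------------------------------------------------------------------
# true communities


def simulate_communities(cfg: SimulationConfig, seed=None):
    """True per-sample VT proportions plus the design table.

    Returns ``(CommunityMatrix in proportions mode, design DataFrame)``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    design = make_design(cfg)
    n_s = len(design)
    v = cfg.n_vt

    base = rng.normal(0.0, cfg.base_log_sd, size=v)
    plot_shift = {p: rng.normal(0.0, cfg.plot_effect_size, size=v) for p in cfg.plots}
    season_shift = {d: (rng.normal(0.0, cfg.season_effect_size, size=v)
                        if cfg.season_effect_size > 0 else np.zeros(v))
                    for d in cfg.dates}

    # spatially autocorrelated log-abundance field, constant in time:
    # one Gaussian-process draw per VT over the distinct grid locations
    locs = design[["x_m", "y_m"]].drop_duplicates()
    coords = locs.values
    h2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    if cfg.spatial_decay_beta != 0.0:
        sigma_f = math.sqrt(abs(cfg.spatial_decay_beta) / DECAY_SLOPE_CALIBRATION)
        k = np.exp(-h2 / (2.0 * cfg.spatial_range_m ** 2))
        chol = np.linalg.cholesky(k + 1e-8 * np.eye(len(coords)))
        fields = sigma_f * (chol @ rng.standard_normal((len(coords), v)))
    else:
        fields = np.zeros((len(coords), v))
    loc_index = {tuple(c): i for i, c in enumerate(coords)}

    eta = np.empty((n_s, v))
    for i, (sid, row) in enumerate(design.iterrows()):
        li = loc_index[(row["x_m"], row["y_m"])]
        eta[i] = (base + plot_shift[row["plot"]]
                  + season_shift[row["date"].strftime("%Y-%m-%d")] + fields[li])
    centred = eta - eta.max(axis=1, keepdims=True)
    p = np.exp(centred)
    p /= p.sum(axis=1, keepdims=True)
    props = np.vstack([rng.dirichlet(cfg.concentration * p[i] + 1e-9)
                       for i in range(n_s)])
    vt_ids = [f"VT{i + 1:05d}" for i in range(v)]
    data = pd.DataFrame(props, index=design.index, columns=vt_ids)
    return CommunityMatrix(data, mode="proportions", meta=design), design


def draw_depths(cfg: SimulationConfig, n: int, rng) -> np.ndarray:
    """Per-sample AMF-assigned read depths, log-uniform over depth_range."""
    lo, hi = cfg.depth_range
    return np.round(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))).astype(int)


def simulate_counts(truth: CommunityMatrix, cfg: SimulationConfig, seed=None,
                    depths=None) -> CommunityMatrix:
    """Multinomial read-count matrix drawn from true proportions.

    A fast path for statistics-level experiments that do not need reads.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    p = truth.data.values
    if depths is None:
        depths = draw_depths(cfg, p.shape[0], rng)
    counts = np.vstack([rng.multinomial(int(depths[i]), p[i] / p[i].sum())
                        for i in range(p.shape[0])])
    data = pd.DataFrame(counts, index=truth.data.index, columns=truth.data.columns)
    return CommunityMatrix(data, mode="counts", meta=truth.meta)


# ---------------------------------------------------------------------------
# reads and hits


def _draw_lengths(cfg: SimulationConfig, n: int, rng) -> np.ndarray:
    lo, hi = cfg.read_length
    a, b = cfg.length_beta
    return (lo + np.floor(rng.beta(a, b, size=n) * (hi - lo + 1))).astype(int).clip(lo, hi)


def _mutate(template: np.ndarray, length: int, error_rate: float, rng) -> tuple[np.ndarray, int]:
    read = template[:length].copy()
    if error_rate <= 0:
        return read, 0
    n_err = rng.binomial(length, error_rate)
    if n_err:
        pos = rng.choice(length, size=n_err, replace=False)
        # substitute with a different base: shift by 1..3 in base index
        cur = np.searchsorted(_BASES, read[pos])
        read[pos] = _BASES[(cur + rng.integers(1, 4, size=n_err)) % 4]
    return read, int(n_err)


def simulate_reads(truth: CommunityMatrix, cfg: SimulationConfig,
                   barcodes: BarcodeMap, reference: dict, seed=None):
    """Barcoded raw reads plus a truth table.

    Per sample, the AMF-assigned depth is drawn log-uniformly within
    ``depth_range``; AMF reads are drawn from the sample's true VT
    proportions, the remainder (sized so AMF reads are
    ``amf_read_fraction`` of the total) from a decoy pool of shuffled
    reference sequences.  Every read is ``barcode + NS31 + template
    prefix`` with independent per-base substitution errors.

    Returns ``(list of RawRead, truth DataFrame indexed by read_id with
    sample_id / true_vt (NA for non-target) / payload_length)``.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    sample_to_barcode = {s: bc for bc, s in barcodes.items()}
    vt_ids = truth.vt_ids
    templates = {v: np.frombuffer(reference[v].encode(), dtype=np.uint8) for v in vt_ids}
    decoys = [np.array(rng.permutation(t)) for t in templates.values()]

    reads: list[RawRead] = []
    truth_rows = []
    counter = 0
    f = cfg.amf_read_fraction
    for sid in truth.sample_ids:
        bc = sample_to_barcode[sid]
        prefix = bc + NS31
        props = truth.data.loc[sid].values
        n_amf = int(draw_depths(cfg, 1, rng)[0])
        n_non = int(round(n_amf * (1.0 - f) / f)) if f < 1 else 0
        vt_counts = rng.multinomial(n_amf, props / props.sum())
        jobs = [(vt_ids[k], templates[vt_ids[k]], int(c))
                for k, c in enumerate(vt_counts) if c > 0]
        jobs.append((None, None, n_non))
        for vt, template, count in jobs:
            if count == 0:
                continue
            lengths = _draw_lengths(cfg, count, rng)
            for ln in lengths:
                if vt is None:
                    template_i = decoys[rng.integers(len(decoys))]
                else:
                    template_i = template
                ln = min(int(ln), len(template_i))
                payload, _ = _mutate(template_i, ln, cfg.error_rate, rng)
                counter += 1
                rid = f"read{counter:08d}"
                reads.append(RawRead(rid, prefix + bytes(payload).decode()))
                truth_rows.append((rid, sid, vt if vt is not None else pd.NA, ln))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth_df = pd.DataFrame([truth_rows[i] for i in order],
                            columns=["read_id", "sample_id", "true_vt",
                                     "payload_length"]).set_index("read_id")
    return reads, truth_df


def _surrogate_scores(length: int, mismatches: int):
    """Deterministic, monotone bitscore/e-value surrogate.

    bitscore = 2*(matches) - 3*(mismatches); e-value = L * 3191 * 2^-bitscore
    (computed in log10, floored at 1e-180).  Tests depend only on the
    criteria thresholds, never on this scale.
    """
    bitscore = 2.0 * (length - mismatches) - 3.0 * mismatches
    log10e = math.log10(length * 3191.0) - bitscore * math.log10(2.0)
    if log10e < -180:
        evalue = 1e-180
    elif log10e > 200:
        evalue = 1e200
    else:
        evalue = 10.0 ** log10e
    return bitscore, evalue


def simulate_hits(reads, truth_df: pd.DataFrame, reference: dict,
                  cfg: SimulationConfig, seed=None) -> pd.DataFrame:
    """Tabular (12-column) hits for AMF reads against their true reference.

    Identity is recomputed by positional comparison of the stripped read
    payload with its template prefix, so it reflects the errors actually
    introduced.  Non-target reads get no rows; a ``decoy_hit_fraction`` of
    AMF reads also receive a (failing) hit against a random wrong
    reference.
    """
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    templates = {v: np.frombuffer(s.encode(), dtype=np.uint8)
                 for v, s in reference.items()}
    strip = 8 + len(NS31)
    vt_list = list(reference)
    rows = []
    for r in reads:
        info = truth_df.loc[r.read_id]
        vt = info["true_vt"]
        if pd.isna(vt):
            continue
        payload = np.frombuffer(r.sequence[strip:].encode(), dtype=np.uint8)
        ln = len(payload)
        tmpl = templates[vt]
        mism = int((payload != tmpl[:ln]).sum())
        ident = 100.0 * (ln - mism) / ln
        bit, ev = _surrogate_scores(ln, mism)
        rows.append((r.read_id, vt, round(ident, 2), ln, mism, 0,
                     1, ln, 1, ln, ev, round(bit, 1)))
        if rng.random() < cfg.decoy_hit_fraction:
            other = vt_list[rng.integers(len(vt_list))]
            if other != vt:
                t2 = templates[other]
                m2 = int((payload != t2[:ln]).sum())
                id2 = 100.0 * (ln - m2) / ln
                b2, e2 = _surrogate_scores(ln, m2)
                rows.append((r.read_id, other, round(id2, 2), ln, m2, 0,
                             1, ln, 1, ln, e2, round(b2, 1)))
    from .assign import HIT_COLUMNS
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_dataset(cfg: SimulationConfig, seed=None):
    """Generate the full linked dataset in memory.

    Returns a dict with keys ``truth`` (proportions CommunityMatrix),
    ``design``, ``barcodes``, ``reference``, ``reads``, ``truth_table``,
    ``hits``.
    """
    seed = cfg.seed if seed is None else seed
    truth, design = simulate_communities(cfg, seed=seed)
    barcodes = make_barcodes(truth.sample_ids, seed=seed + 10)
    reference = make_reference(cfg.n_vt, cfg.ref_length, cfg.divergence,
                               seed=seed + 20)
    reads, truth_table = simulate_reads(truth, cfg, barcodes, reference,
                                        seed=seed + 30)
    hits = simulate_hits(reads, truth_table, reference, cfg, seed=seed + 40)
    return {"truth": truth, "design": design, "barcodes": barcodes,
            "reference": reference, "reads": reads,
            "truth_table": truth_table, "hits": hits}
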