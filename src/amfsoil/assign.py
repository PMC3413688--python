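"""Closed-reference virtual-taxon assignment from tabular alignment hits.

Reads are assigned to MaarjAM-style virtual taxa (VT) by filtering 12-column
tabular alignment hits (qseqid sseqid pident length mismatch gapopen qstart
qend sstart send evalue bitscore) with the study's match criteria —
identity >= 97%, alignment length within 10 nt of the shorter of query and
subject, e-value < 1e-50 — and keeping, per read, the passing hit with the
highest bitscore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CommunityMatrix

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


class HitParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"identity {self.pct_identity} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")


@dataclass(frozen=True)
class MatchCriteria:
    """The study's closed-reference match thresholds."""

    min_identity: float = 97.0
    max_len_diff: int = 10
    max_evalue: float = 1e-50

    def __post_init__(self):
        if self.min_identity <= 0 or self.max_len_diff <= 0 or self.max_evalue <= 0:
            raise ValueError("all thresholds must be positive")


def parse_hits(hit_file, query_lengths: dict | None = None,
               subject_lengths: dict | None = None):
    """Yield :class:`AlignmentHit` per non-comment row of a tabular hit file.

    When length maps are supplied, every id in the file must be known;
    an unknown id raises ``HitParseError`` naming it.  Malformed rows raise
    with their 1-based line number.
    """
    with open(hit_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise HitParseError(f"line {lineno}: expected 12 columns, got {len(fields)}")
            q, s = fields[0], fields[1]
            if query_lengths is not None and q not in query_lengths:
                raise HitParseError(f"line {lineno}: unknown query id {q!r}")
            if subject_lengths is not None and s not in subject_lengths:
                raise HitParseError(f"line {lineno}: unknown subject id {s!r}")
            try:
                yield AlignmentHit(q, s, float(fields[2]), int(fields[3]),
                                   float(fields[10]), float(fields[11]))
            except ValueError as exc:
                raise HitParseError(f"line {lineno}: {exc}") from exc


def passes_criteria(hit: AlignmentHit, qlen: int, slen: int,
                    criteria: MatchCriteria = MatchCriteria()) -> bool:
    """True iff the hit satisfies identity, length-difference and e-value
    thresholds.  The length rule compares the alignment length with the
    shorter of query and subject; the e-value bound is strict."""
    if qlen < 1 or slen < 1:
        raise ValueError("sequence lengths must be >= 1")
    return (hit.pct_identity >= criteria.min_identity
            and abs(hit.aln_length - min(qlen, slen)) <= criteria.max_len_diff
            and hit.evalue < criteria.max_evalue)


def best_hit(hits, qlen: int, subject_lengths: dict,
             criteria: MatchCriteria = MatchCriteria()) -> str | None:
    """VT id of the best passing hit for one query, or None.

    Best = maximal bitscore; ties broken by lower e-value, then
    lexicographically smallest subject id, so the result is independent of
    input order.
    """
    hits = list(hits)
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    passing = [h for h in hits
               if passes_criteria(h, qlen, subject_lengths[h.subject_id], criteria)]
    if not passing:
        return None
    return min(passing, key=lambda h: (-h.bitscore, h.evalue, h.subject_id)).subject_id


def assign_reads(hit_file, query_lengths: dict, subject_lengths: dict,
                 criteria: MatchCriteria = MatchCriteria()) -> dict:
    """Best passing VT per read for a whole hit file (vectorised).

    Returns ``{read_id: vt_id}`` for reads with a passing hit; reads absent
    from the map received no passing hit.  Semantics match :func:`best_hit`
    applied per query.
    """
    df = pd.read_csv(hit_file, sep="\t", comment="#", header=None,
                     names=HIT_COLUMNS,
                     dtype={"qseqid": str, "sseqid": str})
    if df.empty:
        return {}
    unknown_q = set(df["qseqid"]) - set(query_lengths)
    if unknown_q:
        raise HitParseError(f"unknown query ids: {sorted(unknown_q)[:5]}")
    unknown_s = set(df["sseqid"]) - set(subject_lengths)
    if unknown_s:
        raise HitParseError(f"unknown subject ids: {sorted(unknown_s)[:5]}")
    qlen = df["qseqid"].map(query_lengths)
    slen = df["sseqid"].map(subject_lengths)
    shorter = pd.concat([qlen, slen], axis=1).min(axis=1)
    ok = ((df["pident"] >= criteria.min_identity)
          & ((df["length"] - shorter).abs() <= criteria.max_len_diff)
          & (df["evalue"] < criteria.max_evalue))
    df = df[ok]
    if df.empty:
        return {}
    df = df.sort_values(["qseqid", "bitscore", "evalue", "sseqid"],
                        ascending=[True, False, True, True], kind="mergesort")
    best = df.drop_duplicates("qseqid", keep="first")
    return dict(zip(best["qseqid"], best["sseqid"]))


def run_blastn(query_fasta, reference_fasta, out_tsv, evalue: float = 1e-10,
               blastn: str = "blastn") -> None:
    """Optional hook: produce a 12-column hit file with a local blastn.

    Plumbing only — the package never requires an aligner; soft masking
    (DUST) is left on, matching the study's search settings.  Raises if the
    binary is missing or exits non-zero.
    """
    import subprocess
    cmd = [blastn, "-query", str(query_fasta), "-subject", str(reference_fasta),
           "-outfmt", "6", "-evalue", str(evalue), "-soft_masking", "true",
           "-out", str(out_tsv)]
    subprocess.run(cmd, check=True)


def build_matrix(assignments, design: pd.DataFrame) -> CommunityMatrix:
    """Count matrix from an iterable of ``(read_id, sample_id, vt_id)``.

    Every sample in ``design`` gets a row (zero rows are retained at this
    stage; the <10-hit filter removes them later).  An assignment naming a
    sample absent from the design is an error.
    """
    rows = list(assignments)
    samples = list(design.index)
    sample_set = set(samples)
    counts: dict[tuple[str, str], int] = {}
    vt_seen: set[str] = set()
    for read_id, sample_id, vt_id in rows:
        if sample_id not in sample_set:
            raise KeyError(f"read {read_id!r}: sample {sample_id!r} not in design")
        counts[(sample_id, vt_id)] = counts.get((sample_id, vt_id), 0) + 1
        vt_seen.add(vt_id)
    vt_ids = sorted(vt_seen)
    data = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                        columns=vt_ids, dtype=np.int64)
    for (s, v), n in counts.items():
        data.loc[s, v] = n
    return CommunityMatrix(data, mode="counts", meta=design)
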