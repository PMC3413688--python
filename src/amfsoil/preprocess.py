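"""Demultiplexing and length handling for barcoded amplicon reads.

Raw 454-style reads have the structure ``[8-nt barcode][forward primer]
[amplicon payload]``.  A read is kept only if its barcode matches one used
in the study, it carries the correct forward primer immediately after the
barcode, and the remaining payload is at least ``min_length`` nucleotides
(170 by default).  Checks are applied in that order and every rejection is
counted, so the counters always partition the input.
"""

from __future__ import annotations

import gzip
import json
import statistics
from dataclasses import dataclass, field

from Bio.SeqIO.FastaIO import SimpleFastaParser

#: NS31 forward primer delimiting the Glomeromycota SSU amplicon (5' end).
NS31 = "TTGGAGGGCAAGTCTGGTGCC"
#: AML2 reverse primer (3' end); not required for read acceptance.
AML2 = "GAACCCAAACACTTTGGTTTCC"

_DNA = frozenset("ACGTN")


class BarcodeError(ValueError):
    """Invalid barcode map configuration."""


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str


@dataclass(frozen=True)
class Read:
    """A demultiplexed read: barcode and primer already stripped."""

    read_id: str
    sample_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PreprocessStats:
    n_input: int = 0
    n_pass: int = 0
    n_bad_barcode: int = 0
    n_bad_primer: int = 0
    n_too_short: int = 0
    length_min: int | None = None
    length_max: int | None = None
    length_median: float | None = None
    _lengths: list = field(default_factory=list, repr=False)

    def finalise(self) -> None:
        if self._lengths:
            self.length_min, self.length_max, self.length_median = length_summary_values(
                self._lengths)
        self._lengths = []

    def check_partition(self) -> bool:
        return self.n_input == (self.n_pass + self.n_bad_barcode
                                + self.n_bad_primer + self.n_too_short)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if not k.startswith("_")}
        return json.dumps(d, indent=2)


class BarcodeMap:
    """Barcode -> sample assignment; all barcodes the same length and unique."""

    def __init__(self, entries):
        entries = list(entries)
        if not entries:
            raise BarcodeError("barcode map is empty")
        lengths = {len(bc) for bc, _ in entries}
        if len(lengths) != 1:
            raise BarcodeError(f"barcodes have mixed lengths: {sorted(lengths)}")
        barcodes = [bc for bc, _ in entries]
        samples = [s for _, s in entries]
        if len(set(barcodes)) != len(barcodes):
            raise BarcodeError("duplicate barcodes")
        if len(set(samples)) != len(samples):
            raise BarcodeError("duplicate sample ids")
        for bc in barcodes:
            if not set(bc) <= frozenset("ACGT"):
                raise BarcodeError(f"barcode {bc!r} contains non-ACGT characters")
        self.barcode_length = lengths.pop()
        self._map = dict(zip(barcodes, samples))

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    def lookup(self, barcode: str, max_mismatches: int = 0) -> str | None:
        """Sample for ``barcode``, or None.

        With a non-zero Hamming budget the nearest barcode wins; ties (two
        barcodes equally near) are treated as unresolvable and rejected.
        """
        hit = self._map.get(barcode)
        if hit is not None or max_mismatches == 0:
            return hit
        best, best_d, tied = None, max_mismatches + 1, False
        for bc, sample in self._map.items():
            d = sum(a != b for a, b in zip(bc, barcode))
            if d < best_d:
                best, best_d, tied = sample, d, False
            elif d == best_d:
                tied = True
        if tied or best_d > max_mismatches:
            return None
        return best

    @classmethod
    def from_tsv(cls, path) -> "BarcodeMap":
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                bc, sample = line.split("\t")[:2]
                entries.append((bc, sample))
        return cls(entries)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for bc, sample in self._map.items():
                fh.write(f"{bc}\t{sample}\n")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(reads, barcodes: BarcodeMap, fwd_primer: str = NS31,
                min_length: int = 170, max_primer_mismatches: int = 0,
                max_barcode_mismatches: int = 0):
    """Demultiplex raw reads; returns ``(list of Read, PreprocessStats)``.

    ``reads`` is an iterable of :class:`RawRead` (or ``(id, sequence)``
    pairs).  Checks run in order barcode -> primer -> length; each read
    increments exactly one counter.  Reads with characters outside A/C/G/T/N
    are rejected at the barcode stage.  Output order follows input order.
    """
    if not fwd_primer:
        raise ValueError("forward primer must be non-empty")
    bl = barcodes.barcode_length
    pl = len(fwd_primer)
    stats = PreprocessStats()
    out: list[Read] = []
    for r in reads:
        if not isinstance(r, RawRead):
            r = RawRead(*r)
        stats.n_input += 1
        seq = r.sequence.upper()
        if not set(seq) <= _DNA:
            stats.n_bad_barcode += 1
            continue
        sample = barcodes.lookup(seq[:bl], max_barcode_mismatches)
        if sample is None or len(seq) < bl:
            stats.n_bad_barcode += 1
            continue
        primer_region = seq[bl:bl + pl]
        if len(primer_region) < pl or _hamming(primer_region, fwd_primer) > max_primer_mismatches:
            stats.n_bad_primer += 1
            continue
        payload = seq[bl + pl:]
        if len(payload) < min_length:
            stats.n_too_short += 1
            continue
        stats.n_pass += 1
        stats._lengths.append(len(payload))
        out.append(Read(r.read_id, sample, payload))
    stats.finalise()
    return out, stats


def trim_reads(reads, target_length: int, select_longer_than: int | None = None):
    """Trim reads at the 3' end to exactly ``target_length`` nucleotides.

    When ``select_longer_than`` is given, only reads strictly longer than
    that length enter the experiment (the robustness analysis first selects
    reads of >400 nt).  Reads shorter than ``target_length`` are dropped;
    kept reads keep their 5' end.
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    out = []
    for r in reads:
        if select_longer_than is not None and r.length <= select_longer_than:
            continue
        if r.length < target_length:
            continue
        out.append(Read(r.read_id, r.sample_id, r.sequence[:target_length]))
    return out


def length_summary_values(lengths) -> tuple[int, int, float]:
    lengths = list(lengths)
    if not lengths:
        raise ValueError("no reads")
    # even-n median: mean of the central pair
    return min(lengths), max(lengths), float(statistics.median(lengths))


def length_summary(reads) -> tuple[int, int, float]:
    """(min, max, median) read length; median of an even count is the mean
    of the central pair."""
    return length_summary_values(r.length for r in reads)


def read_fasta(path):
    """Yield ``(read_id, sequence)`` from a FASTA file (gzipped ok)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for title, seq in SimpleFastaParser(fh):
            yield title.split()[0], seq


def write_fasta(records, path, sample_annotation: bool = True) -> None:
    """Write :class:`Read` records (or ``(id, seq)`` pairs) as FASTA.

    Demultiplexed reads carry a ``sample=`` annotation in the header.
    """
    with open(path, "w") as fh:
        for r in records:
            if isinstance(r, Read):
                header = f"{r.read_id} sample={r.sample_id}" if sample_annotation else r.read_id
                fh.write(f">{header}\n{r.sequence}\n")
            else:
                rid, seq = r
                fh.write(f">{rid}\n{seq}\n")
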