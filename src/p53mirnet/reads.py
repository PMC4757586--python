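"""Small RNA read cleaning, characterization and miRNA counting.

The cleaning stage mirrors the classic single-end small-RNA protocol: 50-nt
tags are screened for low quality, 5' adapter contamination, a missing 3'
adapter, empty inserts, poly(A) artifacts and out-of-bounds insert lengths —
in that fixed order, so every raw read is attributed to exactly one class.
Counting assigns each clean insert to mature miRNAs by full-length matching
with at most one substitution (a deliberately simple stand-in for a
genome-mapper + reference-database alignment step).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import ReadRecord

DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_LENGTH_BOUNDS = (18, 30)

#: fixed filter order; FilterReport counts must sum to the raw input count
FILTER_CLASSES = (
    "low_quality",
    "adapter5_contaminant",
    "no_adapter3",
    "no_insert",
    "polyA",
    "length_out_of_bounds",
)


@dataclass
class FilterReport:
    """Per-class read counts from one cleaning pass."""

    raw: int = 0
    low_quality: int = 0
    adapter5_contaminant: int = 0
    no_adapter3: int = 0
    no_insert: int = 0
    polyA: int = 0
    length_out_of_bounds: int = 0
    clean: int = 0

    def fractions(self) -> dict[str, float]:
        if self.raw == 0:
            raise ValueError("empty report: no raw reads")
        classes = (*FILTER_CLASSES, "clean")
        return {c: getattr(self, c) / self.raw for c in classes}

    def check_conservation(self) -> bool:
        return self.raw == self.clean + sum(getattr(self, c) for c in FILTER_CLASSES)


@dataclass
class CountTable:
    """miRNA x library read counts plus per-library clean-read totals."""

    counts: pd.DataFrame  # index: miRNA names; columns: library names
    totals: pd.Series  # clean reads per library (assigned + unassigned)

    def __post_init__(self) -> None:
        self.totals = self.totals.reindex(self.counts.columns)
        if self.totals.isna().any():
            raise ValueError("totals missing for some libraries")
        if (self.totals <= 0).any():
            raise ValueError("library totals must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) > self.totals).any():
            # multi-assigned reads can push column sums past totals; per-miRNA
            # counts may still never exceed the library size
            if (self.counts.gt(self.totals, axis=1)).any().any():
                raise ValueError("a count exceeds its library total")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def mirnas(self) -> list[str]:
        return list(self.counts.index)


class Alignment(NamedTuple):
    """A substitution-only hit of a read on the forward coordinates of a reference."""

    read_id: str
    chrom: str
    start: int  # 0-based, half-open interval [start, start + read length)
    strand: str  # '+' or '-'
    mismatches: int


def _mean_quality(q: Sequence[int]) -> float:
    return float(np.mean(q)) if len(q) else 0.0


def clean_reads(
    reads: Iterable[ReadRecord],
    adapter5: str = DEFAULT_ADAPTER5,
    adapter3: str = DEFAULT_ADAPTER3,
    quality_threshold: float = 20.0,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
    adapter_seed: int = 8,
    max_n_fraction: float = 0.10,
    polya_fraction: float = 0.80,
) -> tuple[list[ReadRecord], FilterReport]:
    """Screen raw tags and return adapter-trimmed inserts plus a FilterReport.

    Filter definitions (applied in FILTER_CLASSES order, first hit wins):

    * low quality — mean Phred < ``quality_threshold`` or > ``max_n_fraction`` N bases;
    * 5' adapter contaminant — read begins with the first ``adapter_seed`` bases
      of the 5' adapter (the insert was skipped during ligation);
    * no 3' adapter — no exact occurrence of the first ``adapter_seed`` bases of
      the 3' adapter anywhere in the read;
    * no insert — the trimmed insert is empty (adapter-dimer);
    * polyA — >= ``polya_fraction`` of the insert is adenine;
    * length out of bounds — insert length outside ``length_bounds`` (inclusive).

    Adapter matching is exact, which keeps the classification deterministic.
    """
    if not adapter5 or not adapter3:
        raise ValueError("adapters must be non-empty")
    lo, hi = length_bounds
    if lo > hi:
        raise ValueError(f"invalid length bounds {length_bounds}")
    a5 = adapter5[:adapter_seed].upper()
    a3 = adapter3[:adapter_seed].upper()

    report = FilterReport()
    clean: list[ReadRecord] = []
    for rec in reads:
        if len(rec.sequence) != len(rec.quality):
            raise ValueError(f"read {rec.id}: sequence/quality length mismatch")
        report.raw += 1
        seq = rec.sequence
        if (
            _mean_quality(rec.quality) < quality_threshold
            or seq.count("N") > max_n_fraction * max(len(seq), 1)
        ):
            report.low_quality += 1
            continue
        if seq.startswith(a5):
            report.adapter5_contaminant += 1
            continue
        pos = seq.find(a3)
        if pos < 0:
            report.no_adapter3 += 1
            continue
        insert, qual = seq[:pos], rec.quality[:pos]
        if len(insert) == 0:
            report.no_insert += 1
            continue
        if insert.count("A") >= polya_fraction * len(insert):
            report.polyA += 1
            continue
        if not (lo <= len(insert) <= hi):
            report.length_out_of_bounds += 1
            continue
        report.clean += 1
        clean.append(ReadRecord(rec.id, insert, qual))
    return clean, report


def length_distribution(reads: Iterable[ReadRecord | str]) -> dict[int, float]:
    """Fraction of clean inserts at each observed length; fractions sum to 1."""
    lengths = Counter(len(r if isinstance(r, str) else r.sequence) for r in reads)
    total = sum(lengths.values())
    if total == 0:
        raise ValueError("no reads")
    return {length: n / total for length, n in sorted(lengths.items())}


def nucleotide_bias(reads: Iterable[ReadRecord | str]) -> pd.DataFrame:
    """Per-position A/U/C/G composition of miRNA-assigned reads.

    Positions are 1-based; each row is normalized over the reads long enough to
    cover that position, so row sums are 1.  T is reported as U (RNA alphabet).
    """
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    if not seqs:
        raise ValueError("no reads")
    max_len = max(len(s) for s in seqs)
    counts = np.zeros((max_len, 4), dtype=float)
    order = {"A": 0, "U": 1, "C": 2, "G": 3, "T": 1}
    covered = np.zeros(max_len, dtype=float)
    for s in seqs:
        for i, base in enumerate(s.upper()):
            if base in order:
                counts[i, order[base]] += 1
                covered[i] += 1
    with np.errstate(invalid="ignore"):
        frac = counts / covered[:, None]
    return pd.DataFrame(frac, index=pd.RangeIndex(1, max_len + 1, name="position"),
                        columns=["A", "U", "C", "G"])


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def map_reads(
    reads: Iterable[ReadRecord],
    reference: dict[str, str],
    max_mismatch: int = 1,
) -> tuple[list[Alignment], list[str]]:
    """Substitution-only alignment of each read against both strands.

    Every window of every chromosome with at most ``max_mismatch`` mismatches
    is reported (no indels, ties all kept).  Reverse-strand hits compare the
    reverse complement of the read; reported coordinates are forward-strand,
    0-based.  Returns (alignments, unmapped read ids).
    """
    if not reference:
        raise ValueError("empty reference")
    enc_ref = {name: _encode(seq.upper()) for name, seq in reference.items()}
    alignments: list[Alignment] = []
    unmapped: list[str] = []
    cache: dict[tuple[str, str], list[tuple[str, int, int]]] = {}
    for rec in reads:
        hits = []
        for strand in "+-":
            query = rec.sequence if strand == "+" else reverse_complement(rec.sequence)
            key = (query, strand)
            if key not in cache:
                found: list[tuple[str, int, int]] = []
                q = _encode(query)
                m = len(q)
                for chrom, ref in enc_ref.items():
                    n = len(ref)
                    if m > n:
                        continue
                    # mismatch count per offset via a strided window comparison
                    windows = np.lib.stride_tricks.sliding_window_view(ref, m)
                    mm = (windows != q).sum(axis=1)
                    for start in np.flatnonzero(mm <= max_mismatch):
                        found.append((chrom, int(start), int(mm[start])))
                cache[key] = found
            hits.extend(
                Alignment(rec.id, chrom, start, strand, mm) for chrom, start, mm in cache[key]
            )
        if hits:
            alignments.extend(hits)
        else:
            unmapped.append(rec.id)
    return alignments, unmapped


def chromosome_strand_counts(alignments: Iterable[Alignment]) -> pd.DataFrame:
    """Read counts per chromosome and strand (the genome-distribution summary)."""
    rows = Counter((a.chrom, a.strand) for a in alignments)
    df = pd.DataFrame(
        [(chrom, strand, n) for (chrom, strand), n in sorted(rows.items())],
        columns=["chrom", "strand", "reads"],
    )
    return df


def _matches_mature(insert: str, mature: str, max_mismatch: int) -> bool:
    """Full-insert match: some window of the mature sequence (or the insert,
    when the insert is longer) aligns with <= max_mismatch substitutions."""
    a, b = (insert, mature) if len(insert) <= len(mature) else (mature, insert)
    qa = _encode(a)
    qb = _encode(b)
    if len(qa) == 0:
        return False
    windows = np.lib.stride_tricks.sliding_window_view(qb, len(qa))
    return bool(((windows != qa).sum(axis=1) <= max_mismatch).any())


def count_mirnas(
    clean_reads: Iterable[ReadRecord | str],
    mature: dict[str, str],
    max_mismatch: int = 1,
    multi: Literal["all", "best"] = "all",
) -> tuple[pd.Series, int]:
    """Count clean inserts per mature miRNA for one library.

    A read increments every mature miRNA it matches with at most
    ``max_mismatch`` substitutions over its full length (``multi='all'``), or
    only the fewest-mismatch hit with a deterministic name tie-break
    (``multi='best'``).  Returns (counts indexed by miRNA name, library total
    = number of clean reads, matched or not).
    """
    names = list(mature)
    if len(names) != len(set(names)):
        raise ValueError("duplicate miRNA names")
    mature_up = {name: seq.upper().replace("U", "T") for name, seq in mature.items()}

    seq_counter = Counter(
        (r if isinstance(r, str) else r.sequence).upper().replace("U", "T")
        for r in clean_reads
    )
    counts = pd.Series(0, index=pd.Index(names, name="mirna"), dtype=int)
    total = sum(seq_counter.values())
    for seq, n in seq_counter.items():
        if multi == "all":
            for name, mseq in mature_up.items():
                if _matches_mature(seq, mseq, max_mismatch):
                    counts[name] += n
        else:
            best: tuple[int, str] | None = None
            for name, mseq in mature_up.items():
                for mm in range(max_mismatch + 1):
                    if _matches_mature(seq, mseq, mm):
                        if best is None or (mm, name) < best:
                            best = (mm, name)
                        break
            if best is not None:
                counts[best[1]] += n
    return counts, total


def build_count_table(
    libraries: dict[str, Iterable[ReadRecord | str]],
    mature: dict[str, str],
    max_mismatch: int = 1,
    multi: Literal["all", "best"] = "all",
) -> CountTable:
    """Assemble the miRNA x library CountTable from per-library clean reads."""
    cols = {}
    totals = {}
    for lib, reads in libraries.items():
        counts, total = count_mirnas(reads, mature, max_mismatch=max_mismatch, multi=multi)
        cols[lib] = counts
        totals[lib] = total
    return CountTable(counts=pd.DataFrame(cols), totals=pd.Series(totals))
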