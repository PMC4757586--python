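"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTQ/FASTA go through Biopython; BED, GMT and the various TSV tables are
small enough that pandas / plain parsing is the natural fit.  All genomic
intervals are 0-based half-open in memory, matching BED's native convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ReadRecord(NamedTuple):
    """One sequencing read: id, base string (may contain N), per-base Phred scores."""

    id: str
    sequence: str
    quality: tuple[int, ...]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


class Peak(NamedTuple):
    """A ChIP-seq peak interval, 0-based half-open, tagged by source study."""

    chrom: str
    start: int
    end: int
    study: str = "."


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream Phred+33 FASTQ records, validating length consistency."""
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        seq = str(rec.seq).upper()
        qual = tuple(rec.letter_annotations["phred_quality"])
        if len(seq) != len(qual):  # Biopython enforces this, but keep the contract explicit
            raise ValueError(f"record {i} ({rec.id}): sequence/quality length mismatch")
        yield ReadRecord(rec.id, seq, qual)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    def as_records():
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.quality]
            yield rec

    SeqIO.write(as_records(), str(path), "fastq")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA as an ordered name -> sequence mapping (uppercased)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record name: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> list[Peak]:
    """BED3+name; the name column carries the source-study tag."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line (need >=3 fields)")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else "."
            peaks.append(Peak(fields[0], start, end, name))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.study}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one gene set per line -- name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, set):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
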