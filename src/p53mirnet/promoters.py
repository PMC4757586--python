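"""miRNA TSS assignment, promoter windows and transcription-factor peak overlap.

A transcription start site is assigned to each miRNA by a three-step
priority: a curated TSS resource when the miRNA is listed there; otherwise
the transcription initiation of the host-gene transcript for intragenic
miRNAs; otherwise the genomic first nucleotide of the precursor hairpin.
The putative promoter is 10 kb upstream to 1 kb downstream of the TSS,
strand-aware and clipped at chromosome edges.  Any >= 1 bp overlap between a
peak and a promoter window is reported as a candidate binding site, with its
position signed in transcription orientation (negative = upstream of TSS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, NamedTuple

import pandas as pd

from .io import Peak

UPSTREAM_BP = 10_000
DOWNSTREAM_BP = 1_000


class TSSRecord(NamedTuple):
    mirna: str
    chrom: str
    pos: int  # 0-based coordinate of the first transcribed base
    strand: str
    source: Literal["curated", "host_gene", "premirna_start"]


class PromoterWindow(NamedTuple):
    mirna: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str


@dataclass(frozen=True)
class BindingSite:
    """One peak <-> promoter overlap."""

    mirna: str
    peak: Peak
    signed_distance: float  # TSS -> peak midpoint, bp, negative = upstream
    upstream: bool
    within_5kb_upstream: bool


def assign_tss(
    annotations: pd.DataFrame,
    curated_tss: pd.DataFrame | None = None,
    host_transcripts: pd.DataFrame | None = None,
    curated_one_based: bool = False,
) -> list[TSSRecord]:
    """Assign a TSS to every annotated miRNA by the three-step priority rule.

    ``annotations`` needs columns mirna, chrom, strand, precursor_start,
    precursor_end and (optionally) host_gene; ``curated_tss`` columns mirna,
    chrom, pos, strand (set ``curated_one_based`` if pos is 1-based);
    ``host_transcripts`` columns host_gene, chrom, tx_start, tx_end, strand
    (0-based half-open).  On the minus strand the first transcribed base is
    the highest coordinate of the interval.
    """
    required = {"mirna", "chrom", "strand", "precursor_start", "precursor_end"}
    if missing := required - set(annotations.columns):
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    curated: Mapping[str, tuple[str, int, str]] = {}
    if curated_tss is not None and len(curated_tss):
        offset = 1 if curated_one_based else 0
        curated = {
            r.mirna: (r.chrom, int(r.pos) - offset, r.strand)
            for r in curated_tss.itertuples()
        }
    hosts: Mapping[str, tuple[str, int, int, str]] = {}
    if host_transcripts is not None and len(host_transcripts):
        hosts = {
            r.host_gene: (r.chrom, int(r.tx_start), int(r.tx_end), r.strand)
            for r in host_transcripts.itertuples()
        }

    records: list[TSSRecord] = []
    for row in annotations.itertuples():
        if row.mirna in curated:
            chrom, pos, strand = curated[row.mirna]
            records.append(TSSRecord(row.mirna, chrom, pos, strand, "curated"))
            continue
        host = getattr(row, "host_gene", None)
        if host and not pd.isna(host) and host in hosts:
            chrom, tx_start, tx_end, strand = hosts[host]
            pos = tx_start if strand == "+" else tx_end - 1
            records.append(TSSRecord(row.mirna, chrom, pos, strand, "host_gene"))
            continue
        pos = int(row.precursor_start) if row.strand == "+" else int(row.precursor_end) - 1
        records.append(TSSRecord(row.mirna, row.chrom, pos, row.strand, "premirna_start"))
    return records


def promoter_window(
    tss: TSSRecord,
    upstream: int = UPSTREAM_BP,
    downstream: int = DOWNSTREAM_BP,
    chrom_length: int | None = None,
) -> PromoterWindow:
    """Strand-aware promoter interval around a TSS, clipped to the chromosome.

    Plus strand: [pos - upstream, pos + downstream); minus strand the mirror
    image [pos - downstream + 1, pos + upstream + 1), so the window always has
    length upstream + downstream absent clipping.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window extents must be non-negative")
    if tss.strand == "+":
        start, end = tss.pos - upstream, tss.pos + downstream
    elif tss.strand == "-":
        start, end = tss.pos - downstream + 1, tss.pos + upstream + 1
    else:
        raise ValueError(f"unknown strand {tss.strand!r}")
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start >= end:
        raise ValueError(
            f"promoter window for {tss.mirna} is empty after clipping "
            f"(TSS {tss.pos} on {tss.chrom})"
        )
    return PromoterWindow(tss.mirna, tss.chrom, start, end, tss.strand)


def find_binding_sites(
    promoters: Iterable[PromoterWindow],
    peaks: Iterable[Peak],
    tss_by_mirna: Mapping[str, TSSRecord] | None = None,
    min_overlap: int = 1,
) -> list[BindingSite]:
    """Intersect peaks with promoter windows (any >= ``min_overlap`` bp).

    Signed distance runs from the TSS to the peak midpoint in transcription
    orientation.  When ``tss_by_mirna`` is omitted the TSS position is
    recovered from the window geometry.  Duplicate peaks carried by different
    study tags are retained separately.
    """
    promoters = list(promoters)
    sites: list[BindingSite] = []
    for peak in peaks:
        for win in promoters:
            if peak.chrom != win.chrom:
                continue
            overlap = min(peak.end, win.end) - max(peak.start, win.start)
            if overlap < min_overlap:
                continue
            if tss_by_mirna and win.mirna in tss_by_mirna:
                pos = tss_by_mirna[win.mirna].pos
            else:
                pos = win.start + UPSTREAM_BP if win.strand == "+" else win.end - 1 - UPSTREAM_BP
            mid = (peak.start + peak.end) / 2
            dist = mid - pos if win.strand == "+" else pos - mid
            sites.append(
                BindingSite(
                    mirna=win.mirna,
                    peak=peak,
                    signed_distance=dist,
                    upstream=dist < 0,
                    within_5kb_upstream=-5000 <= dist < 0,
                )
            )
    return sites


def merged_unique_sites(sites: Iterable[BindingSite]) -> list[BindingSite]:
    """Collapse sites sharing (miRNA, peak interval), ignoring the study tag."""
    seen: dict[tuple, BindingSite] = {}
    for s in sites:
        key = (s.mirna, s.peak.chrom, s.peak.start, s.peak.end)
        seen.setdefault(key, s)
    return list(seen.values())


def summarize_sites(sites: list[BindingSite], dems) -> dict:
    """Binding-site placement summary over a DEM set.

    Reports how many selected miRNAs carry >= 1 site, their up/down split, how
    many carry multiple distinct peaks, and the fraction of all sites upstream
    of the TSS / within 5 kb upstream.  Fractions are ``None`` when there are
    no sites.
    """
    if dems is None or len(dems.table) == 0:
        raise ValueError("empty DEM set")
    known = set(dems.table.index)
    for s in sites:
        if s.mirna not in known:
            raise ValueError(f"binding site for unknown miRNA {s.mirna!r}")
    per_mirna: dict[str, set[tuple]] = {}
    for s in sites:
        per_mirna.setdefault(s.mirna, set()).add((s.peak.chrom, s.peak.start, s.peak.end))
    directions = dems.table["direction"]
    n_sites = len(sites)
    n_up = sum(1 for m in per_mirna if directions.get(m) == "up")
    summary = {
        "n_mirnas_with_sites": len(per_mirna),
        "n_up": n_up,
        "n_down": len(per_mirna) - n_up,
        "n_with_multiple_sites": sum(1 for peaks in per_mirna.values() if len(peaks) >= 2),
        "n_sites": n_sites,
        "upstream_fraction": (sum(s.upstream for s in sites) / n_sites) if n_sites else None,
        "within_5kb_upstream_fraction": (
            sum(s.within_5kb_upstream for s in sites) / n_sites
        ) if n_sites else None,
        "bound_mirnas": sorted(per_mirna),
    }
    return summary
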