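"""Synthetic inputs with recorded planted truth for every pipeline stage.

The generators emulate the shape of a two-condition, two-replicate small
RNA-seq study of a transcription factor's miRNA program: a toy genome
carrying miRNA precursors, FASTQ libraries whose mature-miRNA abundances obey
planted log2 fold changes, promoter peaks planted for a chosen miRNA subset,
target-prediction tables with controlled inter-source overlap, annotation
sets with planted enriched categories, and a sparse PPI graph.  Every
generator is bit-reproducible under a fixed seed and the truth is written
alongside the data, so downstream stages can be scored against it.

Read abundances follow a log-normal base profile (the typical heavy skew of
small-RNA libraries) with the condition effect applied multiplicatively.
Contamination classes are injected mutually exclusively per read, matching
the cleaning stage's filter order, so report fractions compare directly to
the planted rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Peak, ReadRecord, write_bed, write_fasta, write_fastq, write_json, write_tsv
from .promoters import TSSRecord, promoter_window
from .reads import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: read-library geometry of the emulated protocol
READ_LENGTH = 50
MATURE_LENGTH = 22
PRECURSOR_RANGE = (60, 110)

#: contamination classes the injector understands (= cleaning filter classes)
CONTAMINATION_CLASSES = (
    "low_quality",
    "adapter5_contaminant",
    "no_adapter3",
    "no_insert",
    "polyA",
    "length_out_of_bounds",
)

#: defaults for the stated world: modest contamination (~2% of raw tags lost
#: to quality, a few percent to adapter artifacts), as in a clean run where
#: ~98% of raw reads survive filtering
DEFAULT_CONTAMINATION = {
    "low_quality": 0.02,
    "adapter5_contaminant": 0.005,
    "no_adapter3": 0.03,
    "no_insert": 0.005,
    "polyA": 0.01,
    "length_out_of_bounds": 0.005,
}

LIBRARIES = ("control_rep1", "treated_rep1", "control_rep2", "treated_rep2")


@dataclass(frozen=True)
class ToyGenome:
    """A small stand-in genome: named chromosomes with random base sequences."""

    chromosomes: tuple[tuple[str, int], ...]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length")
            seq = self.sequences[name]
            if len(seq) != length:
                raise ValueError(f"chromosome {name}: sequence/length mismatch")
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name}: non-ACGT characters")

    def length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]


@dataclass
class SyntheticTruth:
    """What was planted, for downstream recovery scoring."""

    planted_log2fc: dict[str, float] = field(default_factory=dict)
    bound_mirnas: set[str] = field(default_factory=set)
    multi_site_mirnas: set[str] = field(default_factory=set)
    enriched_pairs: list[tuple[str, str]] = field(default_factory=list)
    contamination_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, rate in self.contamination_rates.items():
            if cls not in CONTAMINATION_CLASSES:
                raise ValueError(f"unknown contamination class {cls!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"contamination rate for {cls} outside [0, 1]")
        if sum(self.contamination_rates.values()) > 1:
            raise ValueError("contamination rates sum past 1")
        if not self.multi_site_mirnas <= self.bound_mirnas:
            raise ValueError("multi-site miRNAs must be bound")

    def validate_against(self, mirnas: Iterable[str]) -> None:
        known = set(mirnas)
        for m in self.planted_log2fc:
            if m not in known:
                raise ValueError(f"planted miRNA {m!r} not in reference")
        if unknown := self.bound_mirnas - known:
            raise ValueError(f"bound miRNAs not in reference: {sorted(unknown)}")

    def to_json_dict(self) -> dict:
        return {
            "planted_log2fc": self.planted_log2fc,
            "bound_mirnas": sorted(self.bound_mirnas),
            "multi_site_mirnas": sorted(self.multi_site_mirnas),
            "enriched_pairs": [list(p) for p in self.enriched_pairs],
            "contamination_rates": self.contamination_rates,
            "seed": self.seed,
        }


@dataclass
class MirnaReference:
    """Mature + precursor sequences with genomic locations and host genes."""

    genome: ToyGenome
    mature: dict[str, str]
    precursor: dict[str, str]
    annotations: pd.DataFrame  # mirna, chrom, strand, precursor_start/end, mature_start/end, host_gene
    host_transcripts: pd.DataFrame  # host_gene, chrom, tx_start, tx_end, strand

    @property
    def mirnas(self) -> list[str]:
        return list(self.mature)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome_fasta": outdir / "genome.fa",
            "mature_fasta": outdir / "mature.fa",
            "precursor_fasta": outdir / "precursor.fa",
            "annotations_tsv": outdir / "mirna_annotations.tsv",
            "host_transcripts_tsv": outdir / "host_transcripts.tsv",
        }
        write_fasta(self.genome.sequences, paths["genome_fasta"])
        write_fasta(self.mature, paths["mature_fasta"])
        write_fasta(self.precursor, paths["precursor_fasta"])
        write_tsv(self.annotations, paths["annotations_tsv"])
        write_tsv(self.host_transcripts, paths["host_transcripts_tsv"])
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _forbidden_kmers(adapter_seed: int = 8) -> tuple[str, ...]:
    return (DEFAULT_ADAPTER5[:adapter_seed], DEFAULT_ADAPTER3[:adapter_seed])


def generate_mirna_reference(
    n_mirnas: int = 50,
    genome_spec: Sequence[tuple[str, int]] = (("chr1", 2_000_000), ("chr2", 2_000_000)),
    intragenic_fraction: float = 0.5,
    min_spacing: int = 32_000,
    seed: int = 0,
) -> MirnaReference:
    """Place miRNA precursors on a random toy genome, without overlaps.

    Each miRNA gets a 60–110 nt precursor on a random strand with a 22-nt
    mature subsequence; ``intragenic_fraction`` of them receive a host-gene
    transcript spanning the precursor.  ``min_spacing`` keeps precursors far
    enough apart that default promoter windows of distinct miRNAs are
    disjoint, which makes planted promoter peaks identifiable (set it to 0
    for dense placement).  Mature sequences are re-drawn if they happen to
    contain an adapter seed k-mer (adapters are designed to be absent from
    real inserts; keeping them out keeps trimming exact).  Deterministic
    given ``seed``.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    rng = np.random.default_rng(seed)
    sequences = {name: _random_seq(rng, length) for name, length in genome_spec}
    genome = ToyGenome(chromosomes=tuple(genome_spec), sequences=sequences)

    forbidden = _forbidden_kmers()
    chrom_names = [c for c, _ in genome_spec]
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    mature: dict[str, str] = {}
    precursor: dict[str, str] = {}
    rows = []
    host_rows = []
    max_attempts = 500 * n_mirnas
    attempts = 0
    i = 0
    while i < n_mirnas:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n_mirnas} non-overlapping precursors on a "
                f"genome of {sum(l for _, l in genome_spec)} bp: density too high"
            )
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        chrom_len = genome.length(chrom)
        pre_len = int(rng.integers(PRECURSOR_RANGE[0], PRECURSOR_RANGE[1] + 1))
        if chrom_len < pre_len:
            continue
        start = int(rng.integers(0, chrom_len - pre_len + 1))
        end = start + pre_len
        if any(s < end + min_spacing and start - min_spacing < e for s, e in placed[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        m_off = int(rng.integers(0, pre_len - MATURE_LENGTH + 1))
        m_start, m_end = start + m_off, start + m_off + MATURE_LENGTH
        g = sequences[chrom]
        pre_seq = g[start:end] if strand == "+" else reverse_complement(g[start:end])
        mat_seq = g[m_start:m_end] if strand == "+" else reverse_complement(g[m_start:m_end])
        if any(k in mat_seq for k in forbidden):
            continue
        name = f"syn-miR-{i + 1}"
        placed[chrom].append((start, end))
        mature[name] = mat_seq
        precursor[name] = pre_seq
        intragenic = rng.random() < intragenic_fraction
        host_gene = ""
        if intragenic:
            host_gene = f"HOSTG{i + 1}"
            tx_start = max(0, start - int(rng.integers(1_000, 5_000)))
            tx_end = min(chrom_len, end + int(rng.integers(500, 5_000)))
            host_rows.append((host_gene, chrom, tx_start, tx_end, strand))
        rows.append((name, chrom, strand, start, end, m_start, m_end, host_gene))
        i += 1

    annotations = pd.DataFrame(
        rows,
        columns=["mirna", "chrom", "strand", "precursor_start", "precursor_end",
                 "mature_start", "mature_end", "host_gene"],
    )
    host_transcripts = pd.DataFrame(
        host_rows, columns=["host_gene", "chrom", "tx_start", "tx_end", "strand"]
    )
    return MirnaReference(
        genome=genome, mature=mature, precursor=precursor,
        annotations=annotations, host_transcripts=host_transcripts,
    )


def make_study_like_truth(
    reference: MirnaReference,
    seed: int = 0,
    n_up: int = 12,
    n_down: int = 21,
    n_bound: int = 18,
    n_multi: int = 7,
    effect_range: tuple[float, float] = (2.0, 8.0),
    contamination: Mapping[str, float] | None = None,
) -> SyntheticTruth:
    """A truth mirroring the study's structure: 12 up + 21 down DEMs, 18 of
    them with promoter binding sites, 7 of those with multiple sites."""
    rng = np.random.default_rng(seed)
    mirnas = list(reference.mirnas)
    if n_up + n_down > len(mirnas):
        raise ValueError("more planted DEMs than miRNAs in the reference")
    dems = list(rng.choice(mirnas, size=n_up + n_down, replace=False))
    lo, hi = effect_range
    planted = {}
    for m in dems[:n_up]:
        planted[m] = float(np.round(rng.uniform(lo, hi), 2))
    for m in dems[n_up:]:
        planted[m] = float(-np.round(rng.uniform(lo, hi), 2))
    bound = list(rng.choice(dems, size=min(n_bound, len(dems)), replace=False))
    multi = set(rng.choice(bound, size=min(n_multi, len(bound)), replace=False))
    return SyntheticTruth(
        planted_log2fc=planted,
        bound_mirnas=set(bound),
        multi_site_mirnas=multi,
        contamination_rates=dict(contamination if contamination is not None
                                 else DEFAULT_CONTAMINATION),
        seed=seed,
    )


def _contaminated_read(
    rng: np.random.Generator,
    cls: str,
    insert: str,
    adapter5: str,
    adapter3: str,
) -> tuple[str, np.ndarray]:
    """Build a 50-nt tag of the given contamination class (or 'clean')."""
    def pad_to(seq: str) -> str:
        while len(seq) < READ_LENGTH:
            chunk = _random_seq(rng, READ_LENGTH - len(seq))
            seq = seq + chunk
        return seq[:READ_LENGTH]

    qual = rng.integers(30, 41, size=READ_LENGTH, dtype=np.uint8)
    if cls == "clean":
        seq = pad_to(insert + adapter3)
    elif cls == "low_quality":
        seq = pad_to(insert + adapter3)
        qual = rng.integers(2, 15, size=READ_LENGTH, dtype=np.uint8)
    elif cls == "adapter5_contaminant":
        seq = pad_to(adapter5 + adapter3)
    elif cls == "no_adapter3":
        a3_seed = adapter3[:8]
        for _ in range(100):
            seq = pad_to(insert + "")  # insert then random tail, no adapter
            if a3_seed not in seq:
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not synthesize adapter-free read")
    elif cls == "no_insert":
        seq = pad_to(adapter3)
    elif cls == "polyA":
        seq = pad_to("A" * MATURE_LENGTH + adapter3)
    elif cls == "length_out_of_bounds":
        seq = pad_to(insert[:10] + adapter3)
    else:
        raise ValueError(f"unknown contamination class {cls!r}")
    return seq, qual


def generate_read_libraries(
    reference: MirnaReference,
    truth: SyntheticTruth,
    n_reads: int = 100_000,
    seed: int = 0,
    outdir: str | Path | None = None,
    adapter5: str = DEFAULT_ADAPTER5,
    adapter3: str = DEFAULT_ADAPTER3,
    abundance_sigma: float = 1.0,
) -> dict[str, list[ReadRecord]]:
    """Four FASTQ libraries (control/treated x two replicates).

    Mature-miRNA abundances follow one log-normal base profile per miRNA
    (sigma ``abundance_sigma``); the treated condition multiplies each planted
    miRNA's abundance by 2**planted_log2fc.  Because library proportions are
    compositional, the base weights of the planted-up and planted-down groups
    are rescaled against each other so the planted mass gained equals the mass
    lost — null miRNAs then keep their exact relative abundance and each
    planted miRNA's RPM ratio equals its planted fold change in expectation.
    Contamination classes are drawn mutually exclusively per read at the
    planted rates.  With ``outdir`` set, FASTQ files and a truth JSON are
    written alongside.
    """
    if n_reads < 1000:
        raise ValueError("n_reads >= 1000 required for stable fractions")
    truth.validate_against(reference.mirnas)
    rng = np.random.default_rng(seed)
    mirnas = reference.mirnas
    base = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=len(mirnas))
    fc = np.array([2.0 ** truth.planted_log2fc.get(m, 0.0) for m in mirnas])
    up, down = fc > 1, fc < 1
    gained = float((base[up] * (fc[up] - 1)).sum())
    lost = float((base[down] * (1 - fc[down])).sum())
    if gained > 0 and lost > 0:
        base[up] *= lost / gained

    classes = list(CONTAMINATION_CLASSES)
    rates = np.array([truth.contamination_rates.get(c, 0.0) for c in classes])
    probs = np.concatenate([[1.0 - rates.sum()], rates])
    class_names = ["clean"] + classes

    libraries: dict[str, list[ReadRecord]] = {}
    for lib in LIBRARIES:
        weights = base * (fc if lib.startswith("treated") else 1.0)
        p = weights / weights.sum()
        per_mirna = rng.multinomial(n_reads, p)
        cls_draw = rng.choice(len(class_names), size=n_reads, p=probs)
        mirna_of_read = np.repeat(np.arange(len(mirnas)), per_mirna)
        rng.shuffle(mirna_of_read)
        reads = []
        for j in range(n_reads):
            insert = reference.mature[mirnas[mirna_of_read[j]]]
            seq, qual = _contaminated_read(rng, class_names[cls_draw[j]], insert,
                                           adapter5, adapter3)
            reads.append(ReadRecord(f"{lib}:{j}", seq, qual))
        libraries[lib] = reads

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lib, reads in libraries.items():
            write_fastq(reads, outdir / f"{lib}.fastq")
        write_json(truth.to_json_dict(), outdir / "truth.json")
    return libraries


def generate_chip_peaks(
    tss_records: Sequence[TSSRecord],
    truth: SyntheticTruth,
    genome: ToyGenome,
    decoy_count: int = 50,
    peak_width: int = 200,
    seed: int = 0,
    study_tags: Sequence[str] = ("studyA", "studyB", "studyC", "studyD"),
    upstream: int = 10_000,
    downstream: int = 1_000,
    out_bed: str | Path | None = None,
) -> list[Peak]:
    """Plant promoter peaks for the bound miRNAs plus decoys outside all promoters.

    Every bound miRNA receives one peak fully inside its promoter window (two
    for the multi-site subset, at distinct positions); decoys are rejection-
    sampled to avoid every promoter window.  BED output is 0-based half-open.
    """
    by_mirna = {t.mirna: t for t in tss_records}
    if unknown := truth.bound_mirnas - set(by_mirna):
        raise ValueError(f"bound miRNAs missing from the TSS table: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    windows = []
    for t in tss_records:
        windows.append(promoter_window(t, upstream, downstream,
                                       chrom_length=genome.length(t.chrom)))
    win_by_mirna = {w.mirna: w for w in windows}

    peaks: list[Peak] = []
    for m in sorted(truth.bound_mirnas):
        win = win_by_mirna[m]
        n_here = 2 if m in truth.multi_site_mirnas else 1
        span = win.end - win.start
        if span < peak_width:
            raise ValueError(f"promoter window of {m} shorter than peak width")
        starts: set[int] = set()
        while len(starts) < n_here:
            starts.add(int(rng.integers(win.start, win.end - peak_width + 1)))
        for k, s in enumerate(sorted(starts)):
            tag = study_tags[int(rng.integers(len(study_tags)))]
            peaks.append(Peak(win.chrom, s, s + peak_width, tag))

    chrom_names = [c for c, _ in genome.chromosomes]
    placed = 0
    attempts = 0
    while placed < decoy_count:
        attempts += 1
        if attempts > 1000 * max(decoy_count, 1):
            raise ValueError("cannot place decoy peaks outside all promoter windows")
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        limit = genome.length(chrom) - peak_width
        if limit <= 0:
            continue
        s = int(rng.integers(0, limit + 1))
        e = s + peak_width
        if any(w.chrom == chrom and s < w.end and w.start < e for w in windows):
            continue
        tag = study_tags[int(rng.integers(len(study_tags)))]
        peaks.append(Peak(chrom, s, e, tag))
        placed += 1

    if out_bed is not None:
        write_bed(peaks, out_bed)
    return peaks


def generate_target_data(
    mirnas: Sequence[str],
    n_genes: int = 2_000,
    targets_per_mirna: int = 200,
    overlap_fraction: float = 0.5,
    validated_per_mirna: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Two prediction tables with controlled Jaccard overlap, plus validated pairs.

    Per miRNA both sources predict ``targets_per_mirna`` genes with
    |A ∩ B| / |A ∪ B| ~= ``overlap_fraction``; validated genes are drawn
    independently.  Returns (predA, predB, validated, gene universe).
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    s = targets_per_mirna
    shared = int(round(2 * s * overlap_fraction / (1 + overlap_fraction)))
    union_size = 2 * s - shared
    if union_size > n_genes or validated_per_mirna > n_genes:
        raise ValueError(
            f"n_genes={n_genes} too small for {s} targets per source at "
            f"overlap {overlap_fraction} (needs {union_size})"
        )
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1}" for i in range(n_genes)]
    rows_a, rows_b, rows_v = [], [], []
    for m in mirnas:
        pool = rng.choice(genes, size=union_size, replace=False)
        both = pool[:shared]
        only_a = pool[shared : shared + (s - shared)]
        only_b = pool[shared + (s - shared) :]
        rows_a.extend((m, str(g)) for g in np.concatenate([both, only_a]))
        rows_b.extend((m, str(g)) for g in np.concatenate([both, only_b]))
        val = rng.choice(genes, size=validated_per_mirna, replace=False)
        rows_v.extend((m, str(g)) for g in val)
    pred_a = pd.DataFrame(rows_a, columns=["mirna", "gene"])
    pred_b = pd.DataFrame(rows_b, columns=["mirna", "gene"])
    validated = pd.DataFrame(rows_v, columns=["mirna", "gene"])
    return pred_a, pred_b, validated, genes


def generate_annotation_sets(
    genes: Sequence[str],
    target_sets: Mapping[str, set[str]],
    planted_pairs: Sequence[tuple[str, str]] = (),
    n_background: int = 50,
    category_size: int = 50,
    enrichment_factor: float = 5.0,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Flat category -> gene sets with planted over-represented pairs.

    Background categories sample genes uniformly.  A planted (miRNA,
    category) pair over-samples that miRNA's targets so their share of the
    category is ``enrichment_factor`` times the null expectation.
    """
    genes = list(genes)
    if category_size > len(genes):
        raise ValueError("category size exceeds the gene universe")
    for m, _ in planted_pairs:
        if m not in target_sets:
            raise ValueError(f"planted category references unknown miRNA {m!r}")
    rng = np.random.default_rng(seed)
    categories: dict[str, set[str]] = {}
    for m, cat_name in planted_pairs:
        targets = sorted(set(target_sets[m]) & set(genes))
        if not targets:
            raise ValueError(f"miRNA {m!r} has no targets inside the universe")
        null_share = len(targets) / len(genes)
        n_from_targets = min(
            int(round(enrichment_factor * null_share * category_size)),
            category_size, len(targets),
        )
        chosen = set(rng.choice(targets, size=n_from_targets, replace=False))
        others = [g for g in genes if g not in chosen]
        chosen |= set(rng.choice(others, size=category_size - n_from_targets, replace=False))
        categories[cat_name] = chosen
    for i in range(n_background):
        categories[f"BG_{i + 1:04d}"] = set(
            rng.choice(genes, size=category_size, replace=False)
        )
    return categories


def generate_ppi_and_p53_targets(
    genes: Sequence[str],
    edge_density: float = 0.01,
    n_p53_targets: int = 100,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[str]]:
    """A simple undirected PPI edge list plus a direct-target gene list.

    Each unordered gene pair is an edge independently with probability
    ``edge_density`` (no self-loops); direct targets are sampled uniformly.
    """
    if not 0 < edge_density <= 1:
        raise ValueError("edge density must be in (0, 1]")
    if n_p53_targets > len(genes):
        raise ValueError("more direct targets requested than genes available")
    rng = np.random.default_rng(seed)
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < edge_density
    edges = [(genes[i], genes[j]) for i, j in zip(iu[keep], ju[keep])]
    p53_targets = sorted(str(g) for g in rng.choice(list(genes), size=n_p53_targets, replace=False))
    return edges, p53_targets


def expected_ffl_count(
    bound_mirnas: Iterable[str],
    targets,  # IntegratedTargets
    p53_targets: Iterable[str],
    tf: str = "TP53",
) -> int:
    """Planted FFL count given perfect DEM and binding-site detection."""
    direct = set(p53_targets) - {tf}
    return sum(len((targets.genes(m) - {tf}) & direct) for m in bound_mirnas)
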