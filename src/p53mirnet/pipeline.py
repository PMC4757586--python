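"""End-to-end orchestration: simulate -> clean/count -> DE -> promoters ->
targets/enrichment -> network/FFL, with a checksummed output manifest.

The pipeline is a plain Python function over a :class:`PipelineConfig`; each
stage writes its tabular outputs under ``outdir`` and the manifest records a
SHA-256 per file, so a rerun with the same config and seed is bit-identical.
All randomness is funnelled through child seeds derived from the one config
seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, network, promoters, reads, synthetic, targets
from .io import Peak, write_bed, write_json, write_tsv

logger = logging.getLogger(__name__)

STAGES = ("simulate", "process_reads", "diffexpr", "promoter_chip",
          "targets_enrich", "network")


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; defaults give the study-like world."""

    outdir: str | Path = "p53mirnet_run"
    seed: int = 0
    # simulation
    n_mirnas: int = 50
    n_reads: int = 100_000
    n_up: int = 12
    n_down: int = 21
    n_bound: int = 18
    n_multi: int = 7
    decoy_peaks: int = 50
    n_genes: int = 2_000
    targets_per_mirna: int = 200
    overlap_fraction: float = 0.5
    validated_per_mirna: int = 20
    n_categories: int = 50
    n_planted_categories: int = 5
    edge_density: float = 0.01
    n_p53_targets: int = 150
    contamination: dict | None = None
    # analysis thresholds
    criteria: diffexpr.SelectionCriteria = field(default_factory=diffexpr.SelectionCriteria)
    promoter_upstream: int = 10_000
    promoter_downstream: int = 1_000
    alpha: float = 0.05
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if unknown := set(self.stages) - set(STAGES):
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; return the output manifest.

    The manifest maps every written file to its SHA-256 and carries the
    headline numbers of each stage (DEM counts, bound-miRNA count, FFL count,
    planted-truth values) so callers can score recovery directly.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 6)
    manifest: dict = {"seed": config.seed, "outputs": {}, "summary": {}}
    outputs: dict[str, Path] = {}

    def record(name: str, path: Path) -> None:
        outputs[name] = path
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    last_stage = max(STAGES.index(s) for s in config.stages)

    def stop_after(stage: str) -> bool:
        return STAGES.index(stage) >= last_stage

    def finalize() -> dict:
        write_json(manifest, outdir / "manifest.json")
        return manifest

    current = None
    try:
        # --- simulate -------------------------------------------------------
        current = "simulate"
        reference = synthetic.generate_mirna_reference(
            n_mirnas=config.n_mirnas, seed=seeds[0]
        )
        truth = synthetic.make_study_like_truth(
            reference, seed=seeds[1], n_up=config.n_up, n_down=config.n_down,
            n_bound=config.n_bound, n_multi=config.n_multi,
            contamination=config.contamination,
        )
        libraries = synthetic.generate_read_libraries(
            reference, truth, n_reads=config.n_reads, seed=seeds[2],
            outdir=outdir / "reads",
        )
        for name, path in reference.write(outdir / "reference").items():
            record(name, path)
        for lib in synthetic.LIBRARIES:
            record(f"fastq_{lib}", outdir / "reads" / f"{lib}.fastq")
        record("truth_json", outdir / "reads" / "truth.json")
        manifest["summary"]["planted"] = truth.to_json_dict()

        if stop_after("simulate"):
            return finalize()

        # --- process reads --------------------------------------------------
        current = "process_reads"
        clean_by_lib: dict[str, list] = {}
        reports = {}
        for lib, raw in libraries.items():
            clean, report = reads.clean_reads(raw)
            clean_by_lib[lib] = clean
            reports[lib] = report
        report_df = pd.DataFrame(
            {lib: {**{c: getattr(r, c) for c in ("raw", *reads.FILTER_CLASSES, "clean")}}
             for lib, r in reports.items()}
        ).T.rename_axis("library").reset_index()
        write_tsv(report_df, outdir / "filter_report.tsv")
        record("filter_report", outdir / "filter_report.tsv")

        lengths = reads.length_distribution(
            [r for lib in clean_by_lib.values() for r in lib]
        )
        write_tsv(pd.DataFrame(lengths.items(), columns=["length", "fraction"]),
                  outdir / "length_distribution.tsv")
        record("length_distribution", outdir / "length_distribution.tsv")

        count_table = reads.build_count_table(clean_by_lib, reference.mature)
        counts_df = count_table.counts.rename_axis("mirna").reset_index()
        write_tsv(counts_df, outdir / "count_table.tsv")
        record("count_table", outdir / "count_table.tsv")
        manifest["summary"]["clean_fraction"] = {
            lib: r.clean / r.raw for lib, r in reports.items()
        }

        if stop_after("process_reads"):
            return finalize()

        # --- differential expression ---------------------------------------
        current = "diffexpr"
        rep1 = diffexpr.differential_table(count_table, "control_rep1", "treated_rep1")
        rep2 = diffexpr.differential_table(count_table, "control_rep2", "treated_rep2")
        write_tsv(rep1, outdir / "de_rep1.tsv")
        write_tsv(rep2, outdir / "de_rep2.tsv")
        record("de_rep1", outdir / "de_rep1.tsv")
        record("de_rep2", outdir / "de_rep2.tsv")
        dems = diffexpr.apply_selection_criteria(rep1, rep2, config.criteria)
        if len(dems.table) >= 2:
            dems = diffexpr.cluster_dems(dems)
        write_tsv(dems.table.reset_index(), outdir / "dems.tsv")
        record("dems", outdir / "dems.tsv")
        manifest["summary"]["dems"] = {
            "n_selected": len(dems.table), "n_up": dems.n_up, "n_down": dems.n_down,
        }

        if stop_after("diffexpr"):
            return finalize()

        # --- promoters and ChIP peaks ---------------------------------------
        current = "promoter_chip"
        tss = promoters.assign_tss(
            reference.annotations, curated_tss=None,
            host_transcripts=reference.host_transcripts,
        )
        tss_df = pd.DataFrame(tss)
        write_tsv(tss_df, outdir / "tss.tsv")
        record("tss", outdir / "tss.tsv")
        peaks = synthetic.generate_chip_peaks(
            tss, truth, reference.genome, decoy_count=config.decoy_peaks,
            seed=seeds[3], upstream=config.promoter_upstream,
            downstream=config.promoter_downstream,
            out_bed=outdir / "peaks.bed",
        )
        record("peaks_bed", outdir / "peaks.bed")
        windows = [
            promoters.promoter_window(
                t, config.promoter_upstream, config.promoter_downstream,
                chrom_length=reference.genome.length(t.chrom),
            )
            for t in tss if t.mirna in dems.table.index
        ]
        write_bed([Peak(w.chrom, w.start, w.end, w.mirna) for w in windows],
                  outdir / "promoters.bed")
        record("promoters_bed", outdir / "promoters.bed")
        sites = promoters.find_binding_sites(
            windows, peaks, tss_by_mirna={t.mirna: t for t in tss}
        )
        site_summary = promoters.summarize_sites(sites, dems)
        write_json(site_summary, outdir / "site_summary.json")
        record("site_summary", outdir / "site_summary.json")
        manifest["summary"]["binding_sites"] = site_summary

        if stop_after("promoter_chip"):
            return finalize()

        # --- targets and enrichment -----------------------------------------
        current = "targets_enrich"
        dem_names = list(dems.table.index)
        pred_a, pred_b, validated, genes = synthetic.generate_target_data(
            dem_names, n_genes=config.n_genes,
            targets_per_mirna=config.targets_per_mirna,
            overlap_fraction=config.overlap_fraction,
            validated_per_mirna=config.validated_per_mirna, seed=seeds[4],
        )
        integrated = targets.integrate_targets(pred_a, pred_b, validated,
                                               mirnas=dem_names)
        write_tsv(integrated.to_frame(), outdir / "integrated_targets.tsv")
        record("integrated_targets", outdir / "integrated_targets.tsv")
        planted_pairs = [
            (m, f"PLANTED_{i + 1}")
            for i, m in enumerate(dem_names[: config.n_planted_categories])
        ]
        categories = synthetic.generate_annotation_sets(
            genes, {m: integrated.genes(m) for m in dem_names},
            planted_pairs=planted_pairs, n_background=config.n_categories,
            seed=seeds[5],
        )
        results = targets.enrich_per_mirna(integrated, categories, genes,
                                           alpha=config.alpha)
        matrix = targets.enrichment_matrix(results)
        write_tsv(matrix.reset_index(), outdir / "enrichment_matrix.tsv")
        record("enrichment_matrix", outdir / "enrichment_matrix.tsv")
        manifest["summary"]["enrichment"] = {
            "planted_pairs": [list(p) for p in planted_pairs],
            "recovered_pairs": [
                [m, c] for m, c in planted_pairs
                if m in results and bool(
                    results[m].set_index("category").loc[c, "significant"]
                )
            ],
        }

        if stop_after("targets_enrich"):
            return finalize()

        # --- network and FFLs -----------------------------------------------
        current = "network"
        ppi_edges, p53_target_genes = synthetic.generate_ppi_and_p53_targets(
            genes, edge_density=config.edge_density,
            n_p53_targets=config.n_p53_targets, seed=seeds[3] ^ 0x5F5F,
        )
        bound_detected = [m for m in site_summary["bound_mirnas"]]
        net = network.build_network(dems, bound_detected, integrated,
                                    p53_target_genes, ppi_edges)
        loops = network.enumerate_ffls(net)
        write_tsv(network.ffl_table(loops), outdir / "ffls.tsv")
        record("ffls", outdir / "ffls.tsv")
        for path in network.export_network(net, outdir / "network", fmt="sif"):
            record(f"network_{path.name}", path)
        manifest["summary"]["network"] = {
            "n_tf_mirna_edges": len(net.edges_of_type("tf_mirna")),
            "n_mirna_gene_edges": len(net.edges_of_type("mirna_gene")),
            "n_tf_gene_edges": len(net.edges_of_type("tf_gene")),
            "n_ppi_edges": net.ppi.number_of_edges(),
            "n_ffls": len(loops),
            "expected_ffls": synthetic.expected_ffl_count(
                truth.bound_mirnas & set(dems.table.index), integrated,
                p53_target_genes,
            ),
        }
    except Exception:
        logger.exception("pipeline failed in stage %r; partial outputs kept in %s",
                         current, outdir)
        raise

    return finalize()
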