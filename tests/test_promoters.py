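"""TSS assignment priority, strand-aware windows, peak overlap vs an all-pairs
oracle, and site summaries (including a synthetic stand-in for the published
site-table structure: 18 bound miRNAs, 7 multi-site, 33/36 upstream, 25/36
within 5 kb)."""

from __future__ import annotations

import pandas as pd
import pytest

from p53mirnet import (
    BindingSite,
    DEMSet,
    Peak,
    TSSRecord,
    assign_tss,
    find_binding_sites,
    promoter_window,
    summarize_sites,
)
from p53mirnet.promoters import PromoterWindow, merged_unique_sites


def _annotations(rows):
    return pd.DataFrame(
        rows,
        columns=["mirna", "chrom", "strand", "precursor_start", "precursor_end", "host_gene"],
    )


class TestAssignTSS:
    CURATED = pd.DataFrame([("mA", "chr1", 500, "+")],
                           columns=["mirna", "chrom", "pos", "strand"])
    HOSTS = pd.DataFrame([("HG1", "chr1", 2_000, 9_000, "+")],
                         columns=["host_gene", "chrom", "tx_start", "tx_end", "strand"])

    def test_curated_wins(self):
        ann = _annotations([("mA", "chr1", "+", 3_000, 3_080, "HG1")])
        rec, = assign_tss(ann, self.CURATED, self.HOSTS)
        assert rec.pos == 500 and rec.source == "curated"

    def test_host_gene_second(self):
        ann = _annotations([("mB", "chr1", "+", 3_000, 3_080, "HG1")])
        rec, = assign_tss(ann, self.CURATED, self.HOSTS)
        assert rec.pos == 2_000 and rec.source == "host_gene"

    def test_precursor_start_fallback_minus_strand(self):
        ann = _annotations([("mC", "chr2", "-", 1_000, 1_080, "")])
        rec, = assign_tss(ann, self.CURATED, self.HOSTS)
        assert rec.pos == 1_079 and rec.source == "premirna_start"

    def test_minus_strand_host(self):
        hosts = pd.DataFrame([("HG2", "chr1", 2_000, 9_000, "-")],
                             columns=["host_gene", "chrom", "tx_start", "tx_end", "strand"])
        ann = _annotations([("mD", "chr1", "-", 3_000, 3_080, "HG2")])
        rec, = assign_tss(ann, None, hosts)
        assert rec.pos == 8_999 and rec.source == "host_gene"

    def test_curated_one_based_flag(self):
        cur = pd.DataFrame([("mA", "chr1", 501, "+")],
                           columns=["mirna", "chrom", "pos", "strand"])
        ann = _annotations([("mA", "chr1", "+", 3_000, 3_080, "")])
        rec, = assign_tss(ann, cur, None, curated_one_based=True)
        assert rec.pos == 500


class TestPromoterWindow:
    def test_plus_strand(self):
        w = promoter_window(TSSRecord("m", "chr1", 100_000, "+", "curated"))
        assert (w.start, w.end) == (90_000, 101_000)

    def test_minus_strand_mirror(self):
        w = promoter_window(TSSRecord("m", "chr1", 100_000, "-", "curated"))
        assert (w.start, w.end) == (99_001, 110_001)

    def test_clipping_and_empty(self):
        w = promoter_window(TSSRecord("m", "chr1", 5_000, "+", "curated"))
        assert (w.start, w.end) == (0, 6_000)
        with pytest.raises(ValueError, match="empty"):
            promoter_window(TSSRecord("m", "chr1", 0, "+", "curated"), downstream=0)

    def test_length_invariant_both_strands(self):
        for strand in "+-":
            w = promoter_window(TSSRecord("m", "chr1", 500_000, strand, "curated"))
            assert w.end - w.start == 11_000


class TestFindBindingSites:
    def test_one_bp_overlap_reported(self):
        win = PromoterWindow("m", "chr1", 1_000, 2_000, "+")
        assert len(find_binding_sites([win], [Peak("chr1", 1_999, 2_100, "s")])) == 1
        assert len(find_binding_sites([win], [Peak("chr1", 2_000, 2_100, "s")])) == 0

    def test_signed_distance_orientation(self):
        tss = TSSRecord("m", "chr1", 100_000, "-", "curated")
        win = promoter_window(tss)
        # peak at higher coordinate than a minus-strand TSS is upstream
        site, = find_binding_sites([win], [Peak("chr1", 104_900, 105_100, "s")],
                                   tss_by_mirna={"m": tss})
        assert site.signed_distance == -5_000 and site.upstream and site.within_5kb_upstream

    def test_equals_all_pairs_oracle(self, rng):
        """500 random peaks x 40 windows == quadratic brute-force overlap set."""
        windows = []
        for i in range(40):
            start = int(rng.integers(0, 500_000))
            windows.append(PromoterWindow(f"m{i}", f"chr{int(rng.integers(1, 4))}",
                                          start, start + 11_000, "+" if rng.random() < 0.5 else "-"))
        peaks = []
        for j in range(500):
            s = int(rng.integers(0, 520_000))
            peaks.append(Peak(f"chr{int(rng.integers(1, 4))}", s, s + int(rng.integers(50, 800)),
                              f"study{j % 4}"))
        got = {(s.mirna, s.peak) for s in find_binding_sites(windows, peaks)}
        want = {
            (w.mirna, p)
            for w in windows for p in peaks
            if p.chrom == w.chrom and min(p.end, w.end) - max(p.start, w.start) >= 1
        }
        assert got == want

    def test_concatenation_order_invariance(self, rng):
        windows = [PromoterWindow("m", "chr1", 0, 11_000, "+")]
        peaks = [Peak("chr1", int(rng.integers(0, 12_000)), int(rng.integers(0, 12_000)) + 100,
                      f"s{i % 3}") for i in range(50)]
        a = find_binding_sites(windows, peaks)
        b = find_binding_sites(windows, list(reversed(peaks)))
        assert sorted((s.mirna, s.peak) for s in a) == sorted((s.mirna, s.peak) for s in b)

    def test_study_tags_retained_and_merged_view(self):
        win = PromoterWindow("m", "chr1", 0, 11_000, "+")
        dup = [Peak("chr1", 100, 300, "studyA"), Peak("chr1", 100, 300, "studyB")]
        sites = find_binding_sites([win], dup)
        assert len(sites) == 2
        assert len(merged_unique_sites(sites)) == 1


def _dems(names_up, names_down):
    rows = [(m, 2.0, 2.0, 1e-5, 1e-5, "up") for m in names_up]
    rows += [(m, -2.0, -2.0, 1e-5, 1e-5, "down") for m in names_down]
    t = pd.DataFrame(rows, columns=["mirna", "rep1_log2fc", "rep2_log2fc",
                                    "rep1_p", "rep2_p", "direction"]).set_index("mirna")
    return DEMSet(table=t)


class TestSummarizeSites:
    def test_no_sites(self):
        s = summarize_sites([], _dems(["m1"], ["m2"]))
        assert s["n_mirnas_with_sites"] == 0 and s["upstream_fraction"] is None

    def test_empty_dems_rejected(self):
        with pytest.raises(ValueError):
            summarize_sites([], DEMSet(table=pd.DataFrame(
                columns=["direction"], index=pd.Index([], name="mirna"))))

    def test_published_structure_stand_in(self):
        """A synthetic stand-in shaped like the published site table: 36 sites
        over 18 of 33 DEMs (5 up / 13 down), 7 miRNAs multi-site, 33/36 sites
        upstream (91.67%) and 25/36 within 5 kb upstream (69.44%)."""
        ups = [f"u{i}" for i in range(12)]
        downs = [f"d{i}" for i in range(21)]
        dems = _dems(ups, downs)
        bound = ups[:5] + downs[:13]  # 18 bound: 5 up, 13 down
        multi = bound[:7]
        sites = []
        # distances: 25 within 5 kb upstream, 8 upstream beyond 5 kb, 3 downstream
        distances = [-2_000.0] * 25 + [-8_000.0] * 8 + [500.0] * 3
        peaks_made = 0
        for m in bound:
            n_here = 2 if m in multi else 1
            for j in range(n_here):
                d = distances[peaks_made]
                peaks_made += 1
                sites.append(
                    BindingSite(
                        mirna=m, peak=Peak("chr1", 1_000 * peaks_made, 1_000 * peaks_made + 200, "s"),
                        signed_distance=d, upstream=d < 0,
                        within_5kb_upstream=-5_000 <= d < 0,
                    )
                )
        # pad to 36 total sites with extra singles on multi-site miRNAs
        while peaks_made < 36:
            d = distances[peaks_made]
            peaks_made += 1
            sites.append(BindingSite(
                mirna=multi[peaks_made % 7],
                peak=Peak("chr1", 1_000 * peaks_made, 1_000 * peaks_made + 200, "s"),
                signed_distance=d, upstream=d < 0, within_5kb_upstream=-5_000 <= d < 0))
        s = summarize_sites(sites, dems)
        assert s["n_mirnas_with_sites"] == 18
        assert (s["n_up"], s["n_down"]) == (5, 13)
        assert s["n_with_multiple_sites"] == 7
        assert s["n_sites"] == 36
        assert s["upstream_fraction"] * 100 == pytest.approx(91.67, abs=0.005)
        assert s["within_5kb_upstream_fraction"] * 100 == pytest.approx(69.44, abs=0.005)

    def test_planted_truth_recovery(self, study_reference, study_truth):
        """18 of 33 planted-bound miRNAs, 7 with multiple peaks, recovered exactly."""
        from p53mirnet import generate_chip_peaks
        from p53mirnet.promoters import promoter_window as pw
        tss = assign_tss(study_reference.annotations,
                         host_transcripts=study_reference.host_transcripts)
        peaks = generate_chip_peaks(tss, study_truth, study_reference.genome,
                                    decoy_count=40, seed=5)
        dem_names = sorted(study_truth.planted_log2fc)
        dems = _dems([m for m in dem_names if study_truth.planted_log2fc[m] > 0],
                     [m for m in dem_names if study_truth.planted_log2fc[m] < 0])
        windows = [
            pw(t, chrom_length=study_reference.genome.length(t.chrom))
            for t in tss if t.mirna in dems.table.index
        ]
        sites = find_binding_sites(windows, peaks, tss_by_mirna={t.mirna: t for t in tss})
        s = summarize_sites(sites, dems)
        assert s["n_mirnas_with_sites"] == 18
        assert s["n_with_multiple_sites"] == 7
        assert set(s["bound_mirnas"]) == study_truth.bound_mirnas
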