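"""Clean reads, count miRNAs and select robust differentially expressed miRNAs.

Prints the filter report, the count-test results for both replicate
comparisons and the final selection — which should recover the planted
fold-change signs exactly at this depth.
"""

from p53mirnet import (
    apply_selection_criteria,
    build_count_table,
    clean_reads,
    cluster_dems,
    differential_table,
    generate_mirna_reference,
    generate_read_libraries,
    make_study_like_truth,
)

reference = generate_mirna_reference(n_mirnas=50, seed=1)
truth = make_study_like_truth(reference, seed=1)
libraries = generate_read_libraries(reference, truth, n_reads=20_000, seed=1)

clean = {}
for lib, raw in libraries.items():
    clean[lib], report = clean_reads(raw)
    print(f"{lib}: {report.clean}/{report.raw} reads clean "
          f"({100 * report.clean / report.raw:.1f}%)")

counts = build_count_table(clean, reference.mature)
rep1 = differential_table(counts, "control_rep1", "treated_rep1")
rep2 = differential_table(counts, "control_rep2", "treated_rep2")
dems = cluster_dems(apply_selection_criteria(rep1, rep2))

print(f"\nselected {len(dems.table)} miRNAs "
      f"({dems.n_up} up, {dems.n_down} down) — planted: "
      f"{sum(v > 0 for v in truth.planted_log2fc.values())} up, "
      f"{sum(v < 0 for v in truth.planted_log2fc.values())} down")
hits = sum(m in dems.table.index for m in truth.planted_log2fc)
print(f"planted DEMs recovered: {hits}/{len(truth.planted_log2fc)}")
print("\ntop rows (log2fc = treated/control on the reads-per-million scale):")
print(dems.table.sort_values("rep1_log2fc").head(5).to_string())
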