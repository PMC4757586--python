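"""Generate a complete planted-truth dataset: toy genome, miRNA reference,
four FASTQ libraries, promoter peaks, target tables — and print what was planted.

The truth file is the point: every downstream example scores itself against it.
"""

from pathlib import Path

from p53mirnet import (
    generate_mirna_reference,
    generate_read_libraries,
    make_study_like_truth,
)

outdir = Path("example_output/simulated")

reference = generate_mirna_reference(n_mirnas=50, seed=1)
truth = make_study_like_truth(reference, seed=1)  # 12 up + 21 down, 18 bound, 7 multi-site
libraries = generate_read_libraries(reference, truth, n_reads=20_000, seed=1, outdir=outdir)
reference.write(outdir / "reference")

print(f"reference: {len(reference.mirnas)} miRNAs on "
      f"{len(reference.genome.chromosomes)} chromosomes")
print(f"libraries: {', '.join(libraries)} ({len(libraries['control_rep1'])} reads each)")
ups = sum(1 for v in truth.planted_log2fc.values() if v > 0)
print(f"planted: {ups} up + {len(truth.planted_log2fc) - ups} down regulated miRNAs, "
      f"{len(truth.bound_mirnas)} with promoter binding sites "
      f"({len(truth.multi_site_mirnas)} multi-site)")
print(f"files under {outdir}/ — truth.json records every planted value")
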