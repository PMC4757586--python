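"""Apply the robust-selection filter to the packaged published DEM table.

The packaged table lists 33 miRNAs with per-replicate log2 fold changes and
p-values.  The filter (|log2fc| > 1 both replicates with consistent sign,
p < 0.01 in at least one) keeps all 33: 12 up- and 21 down-regulated, and
Ward clustering of the fold-change profiles splits exactly along direction.
"""

from p53mirnet import apply_selection_criteria, cluster_dems, load_published_dem_table

fixture = load_published_dem_table()
rep1, rep2 = fixture.replicate_frames()
dems = cluster_dems(apply_selection_criteria(rep1, rep2))

print(f"selected {len(dems.table)} of {len(fixture.table)} miRNAs: "
      f"{dems.n_up} up, {dems.n_down} down")
agree = (dems.table["cluster"] == 1) == (dems.table["direction"] == "up")
print(f"cluster/direction agreement: {agree.sum()}/{len(dems.table)}")
print("\nstrongest responders per direction:")
t = dems.table
print(t.loc[[t.rep1_log2fc.idxmax(), t.rep1_log2fc.idxmin()]].to_string())
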