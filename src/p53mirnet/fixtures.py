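"""Packaged reference table of the 33 doxorubicin-responsive miRNAs.

The fixture ships the published per-replicate log2 fold changes and p-values
(with their significance tiers), the genomic locus type of each miRNA and the
host gene of the intragenic ones.  It is the desk-scale anchor for the
selection-criteria filter: 12 up-regulated and 21 down-regulated miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

_EXPECTED_ROWS = 33
_LOCUS_TYPES = {"Intergenic", "Intron", "Intron/Exon"}


@dataclass(frozen=True)
class PublishedDemTable:
    """The published DEM table: one row per miRNA, two replicate comparisons."""

    table: pd.DataFrame

    def replicate_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Split into per-replicate frames shaped like ``differential_table`` output.

        No read counts are printed in the source table, so the frames carry only
        mirna/log2fc/p columns; the selection filter treats the count criterion
        as satisfied when counts are absent.
        """
        rep1 = self.table[["mirna", "rep1_log2fc", "rep1_p"]].rename(
            columns={"rep1_log2fc": "log2fc", "rep1_p": "p"}
        )
        rep2 = self.table[["mirna", "rep2_log2fc", "rep2_p"]].rename(
            columns={"rep2_log2fc": "log2fc", "rep2_p": "p"}
        )
        return rep1.copy(), rep2.copy()


def load_published_dem_table() -> PublishedDemTable:
    """Load and validate the packaged 33-row DEM fixture."""
    ref = resources.files("p53mirnet").joinpath("data/published_dems.tsv")
    try:
        with ref.open("r") as fh:
            df = pd.read_csv(fh, sep="\t", keep_default_na=False)
    except FileNotFoundError as exc:  # pragma: no cover - packaging failure
        raise FileNotFoundError("packaged DEM fixture is missing") from exc

    required = {
        "mirna", "rep1_log2fc", "rep1_p", "rep1_sig",
        "rep2_log2fc", "rep2_p", "rep2_sig", "locus_type", "host_gene",
    }
    if missing := required - set(df.columns):
        raise ValueError(f"DEM fixture corrupt: missing columns {sorted(missing)}")
    if len(df) != _EXPECTED_ROWS:
        raise ValueError(f"DEM fixture corrupt: {len(df)} rows, expected {_EXPECTED_ROWS}")
    if df["mirna"].duplicated().any():
        raise ValueError("DEM fixture corrupt: duplicate miRNA names")
    if not set(df["locus_type"]) <= _LOCUS_TYPES:
        raise ValueError("DEM fixture corrupt: unknown locus type")
    for col in ("rep1_log2fc", "rep1_p", "rep2_log2fc", "rep2_p"):
        df[col] = df[col].astype(float)
    return PublishedDemTable(table=df)
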