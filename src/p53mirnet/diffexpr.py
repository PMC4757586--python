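"""Differential miRNA expression between two count libraries.

Normalization is reads-per-million of clean reads.  Significance uses the
Audic–Claverie statistic for comparing a count ``x`` in a library of size
``N1`` with a count ``y`` in a library of size ``N2``:

    p(y | x) = (N2/N1)^y * (x + y)! / ( x! * y! * (1 + N2/N1)^(x + y + 1) )

i.e. the posterior predictive of ``y`` given ``x`` under a flat prior on the
common Poisson rate.  The two-sided p-value doubles the smaller of the two
tails P(Y <= y) and P(Y >= y), capped at 1.  Multiple testing is controlled
with Benjamini–Hochberg.

Selection of robust differentially expressed miRNAs (DEMs) across two
replicate comparisons requires |log2 fold change| > 1 with a consistent sign
in both replicates, a raw count above 10 in at least one of the four
libraries, and p < 0.01 in at least one replicate comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .reads import CountTable

logger = logging.getLogger(__name__)

#: RPM stand-in for a zero count when forming fold-change ratios.  Small enough
#: to keep extreme published fold changes (|log2fc| ~ 10) representable.
PSEUDO_RPM = 0.01


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the robust-DEM filter (defaults as published)."""

    min_abs_log2fc: float = 1.0
    min_reads: int = 10
    max_p: float = 0.01

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0 or self.min_reads <= 0 or not (0 < self.max_p <= 1):
            raise ValueError("selection thresholds must be positive (max_p in (0,1])")


@dataclass
class DEMSet:
    """Selected miRNAs with per-replicate statistics, direction and cluster id."""

    table: pd.DataFrame  # index mirna; rep{1,2}_log2fc, rep{1,2}_p, direction[, cluster]
    excluded_conflicts: list[str] = field(default_factory=list)

    @property
    def mirnas(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())


def normalize(counts: CountTable) -> pd.DataFrame:
    """Reads-per-million matrix: count / library clean-read total * 1e6.

    Zeros stay zero here; the PSEUDO_RPM substitution applies only when
    fold-change ratios are formed.
    """
    if (counts.totals <= 0).any():
        raise ValueError("library totals must be positive")
    return counts.counts.div(counts.totals, axis=1) * 1e6


def audic_claverie_pvalue(x: int, y: int, N1: int, N2: int) -> float:
    """Two-sided Audic–Claverie p-value for counts x (library N1) vs y (library N2).

    The lower tail P(Y <= y) is the finite sum of the posterior predictive
    mass evaluated in log-gamma space.  When y sits in the upper tail the
    complement of the lower sum would cancel catastrophically, so
    P(Y >= y) is then summed directly from y upward until the geometric
    remainder bound is negligible.  Always in (0, 1]; values below the
    smallest normal float are floored at it rather than underflowing to 0.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    log_r = np.log(N2) - np.log(N1)
    log_1pr = np.logaddexp(0.0, log_r)

    def log_terms(ks: np.ndarray) -> np.ndarray:
        return (
            ks * log_r
            + gammaln(x + ks + 1)
            - gammaln(x + 1)
            - gammaln(ks + 1)
            - (x + ks + 1) * log_1pr
        )

    tiny = float(np.finfo(float).tiny)
    lower = float(np.exp(logsumexp(log_terms(np.arange(y + 1)))))  # P(Y <= y)
    if lower <= 0.5:
        # lower + upper = 1 + p(y|x) >= 1, so the lower tail is the smaller one
        return float(min(1.0, max(2.0 * lower, tiny)))

    # direct upper-tail summation, chunked; term ratio tends to r/(1+r) < 1
    ratio_inf = np.exp(log_r - log_1pr)
    log_upper = -np.inf
    k0 = y
    chunk = 512
    while True:
        ks = np.arange(k0, k0 + chunk)
        log_upper = np.logaddexp(log_upper, logsumexp(log_terms(ks)))
        k_last = k0 + chunk - 1
        ratio = (x + k_last + 2) / (k_last + 2) * ratio_inf
        last = float(log_terms(np.array([k_last + 1]))[0])
        if ratio < 1 and last - np.log1p(-ratio) < log_upper + np.log(1e-17):
            break
        k0 += chunk
    upper = float(np.exp(log_upper))  # P(Y >= y)
    return float(min(1.0, max(2.0 * min(lower, upper), tiny)))


def differential_table(
    counts: CountTable,
    control: str,
    treated: str,
    pseudo_rpm: float = PSEUDO_RPM,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-miRNA expression comparison of one control/treated library pair.

    Returns one row per miRNA with raw counts, RPM, log2 fold change
    (treated/control, zeros replaced by ``pseudo_rpm`` in the ratio only),
    the Audic–Claverie p-value and its multiplicity-adjusted version.  The
    (log2fc, -log10 p) columns are the scatter-plot axes of the comparison.
    """
    for lib in (control, treated):
        if lib not in counts.libraries:
            raise KeyError(f"library {lib!r} not in count table")
    x = counts.counts[control].to_numpy()
    y = counts.counts[treated].to_numpy()
    N1 = int(counts.totals[control])
    N2 = int(counts.totals[treated])
    rpm_c = x / N1 * 1e6
    rpm_t = y / N2 * 1e6
    log2fc = np.log2(np.where(rpm_t > 0, rpm_t, pseudo_rpm) / np.where(rpm_c > 0, rpm_c, pseudo_rpm))
    p = np.array([audic_claverie_pvalue(int(xi), int(yi), N1, N2) for xi, yi in zip(x, y)])
    p_adj = multipletests(p, method=method)[1]
    df = pd.DataFrame(
        {
            "mirna": counts.mirnas,
            "count_control": x,
            "count_treated": y,
            "total_control": N1,
            "total_treated": N2,
            "rpm_control": rpm_c,
            "rpm_treated": rpm_t,
            "log2fc": log2fc,
            "p": p,
            "p_adjusted": np.maximum(p_adj, p),
        }
    )
    return df


def apply_selection_criteria(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    criteria: SelectionCriteria | None = None,
) -> DEMSet:
    """Select robust DEMs across two replicate comparisons.

    ``rep1``/``rep2`` are ``differential_table`` outputs (or any frame with
    ``mirna``, ``log2fc`` and ``p``; count columns, when present, feed the
    read-count criterion, otherwise that criterion is treated as satisfied —
    as for published tables that omit raw counts).

    Membership: |log2fc| > min_abs_log2fc with the same sign in both
    replicates, AND raw count > min_reads in at least one of the four
    libraries, AND raw p < max_p in at least one replicate.  Rows with
    conflicting strong fold changes are excluded and logged, not errors.
    """
    criteria = criteria or SelectionCriteria()
    r1 = rep1.set_index("mirna")
    r2 = rep2.set_index("mirna")
    if set(r1.index) != set(r2.index):
        raise ValueError("replicate comparisons cover different miRNA universes")
    r2 = r2.reindex(r1.index)

    l1, l2 = r1["log2fc"], r2["log2fc"]
    strong = (l1.abs() > criteria.min_abs_log2fc) & (l2.abs() > criteria.min_abs_log2fc)
    consistent = np.sign(l1) == np.sign(l2)
    conflicts = strong & ~consistent
    for name in r1.index[conflicts]:
        logger.warning("miRNA %s has strong but opposite fold changes; excluded", name)

    count_cols = [c for c in ("count_control", "count_treated") if c in r1.columns and c in r2.columns]
    if count_cols:
        max_count = pd.concat([r1[count_cols], r2[count_cols]], axis=1).max(axis=1)
        counted = max_count > criteria.min_reads
    else:
        counted = pd.Series(True, index=r1.index)

    significant = (r1["p"] < criteria.max_p) | (r2["p"] < criteria.max_p)
    selected = strong & consistent & counted & significant

    table = pd.DataFrame(
        {
            "rep1_log2fc": l1[selected],
            "rep2_log2fc": l2[selected],
            "rep1_p": r1.loc[selected, "p"],
            "rep2_p": r2.loc[selected, "p"],
            "direction": np.where(l1[selected] > 0, "up", "down"),
        }
    )
    table.index.name = "mirna"
    return DEMSet(table=table, excluded_conflicts=sorted(r1.index[conflicts]))


def cluster_dems(dems: DEMSet, k: int = 2, method: str = "ward") -> DEMSet:
    """Hierarchically cluster the selected miRNAs on their per-replicate log2fc.

    Ward linkage with Euclidean distance, cut at ``k`` clusters; cluster ids
    are relabelled deterministically by decreasing mean fold change so that
    cluster 1 is the up-regulated one when the partition splits by direction.
    A ``cluster`` column and a ``leaf_order`` attribute are added; only the
    partition (not the leaf order) is contractual.
    """
    X = dems.table[["rep1_log2fc", "rep2_log2fc"]].to_numpy(dtype=float)
    if len(X) < 2:
        logger.warning("fewer than 2 miRNAs; degenerate single cluster")
        out = dems.table.copy()
        out["cluster"] = 1
        return DEMSet(table=out, excluded_conflicts=list(dems.excluded_conflicts))
    Z = linkage(X, method=method, metric="euclidean")
    raw = fcluster(Z, k, criterion="maxclust")
    order = np.argsort(
        [-X[raw == c].mean() for c in sorted(set(raw))]
    )
    relabel = {c: int(np.flatnonzero(order == i)[0]) + 1 for i, c in enumerate(sorted(set(raw)))}
    out = dems.table.copy()
    out["cluster"] = [relabel[c] for c in raw]
    result = DEMSet(table=out, excluded_conflicts=list(dems.excluded_conflicts))
    result.leaf_order = [dems.table.index[i] for i in leaves_list(Z)]
    return result
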