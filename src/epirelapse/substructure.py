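"""Epigenomic-substructure methylation status and hypo/hyper fractions.

Probes are stratified by their relation to CpG islands: the island itself,
shores (up to 2 kb flanking the island, N = upstream, S = downstream) and
shelves (the next 2 kb beyond the shores). Undefined/unmapped (open sea)
probes are excluded from substructure-level analyses.

Two analyses live here:

* ``substructure_status`` — compare per-probe mean betas between the
  primary and relapse groups within each substructure (two-sided t over
  probes, paired by default).
* ``fraction_analysis`` — among probes significant at an uncorrected
  threshold, classify each as hypomethylated (logFC < 0) or
  hypermethylated (logFC > 0) and report per-substructure percent
  breakdowns of all changes, of hypo, and of hyper probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import DmpTable
from .errors import ValidationError
from .io_model import MAPPED_SUBSTRUCTURES, SUBSTRUCTURES, ProbeAnnotation
from .preprocess import GroupMeanBeta

logger = logging.getLogger(__name__)

HYPO, HYPER, NONE = "HYPO", "HYPER", "NONE"

TEST_MODES = ("paired_over_probes", "welch_over_probes")


@dataclass
class SubstructurePartition:
    """Total, disjoint assignment of probes to substructure categories."""

    mapping: pd.Series  # probe_id -> substructure
    counts: dict[str, int]
    n_undefined: int

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def mapped_probes(self, category: str) -> pd.Index:
        return self.mapping.index[self.mapping == category]


def partition_probes(annotation: ProbeAnnotation) -> SubstructurePartition:
    """Partition probes by substructure, reporting all six category counts."""
    mapping = annotation.table["substructure"]
    counts = {cat: int((mapping == cat).sum()) for cat in SUBSTRUCTURES}
    return SubstructurePartition(
        mapping=mapping, counts=counts, n_undefined=counts["UNDEFINED"]
    )


def substructure_status(
    gm: GroupMeanBeta,
    partition: SubstructurePartition,
    test_mode: str = "paired_over_probes",
) -> pd.DataFrame:
    """Compare per-probe group-mean betas between groups, per substructure.

    For each non-UNDEFINED substructure the vectors of per-probe primary
    means and relapse means are compared with a two-sided t-test: paired
    over probes (default; each probe supplies a matched pair of means) or
    unpaired Welch. Rows carry mean-of-means for both groups, t, p and the
    probe count; substructures with < 2 usable probes are flagged with
    missing statistics.
    """
    if test_mode not in TEST_MODES:
        raise ValueError(f"unknown test_mode {test_mode!r}")
    if all(partition.counts[c] == 0 for c in MAPPED_SUBSTRUCTURES):
        raise ValidationError("no mapped probes: every probe is UNDEFINED")
    rows = []
    for cat in MAPPED_SUBSTRUCTURES:
        probes = partition.mapped_probes(cat)
        prim = gm.primary_mean.reindex(probes)
        rel = gm.relapse_mean.reindex(probes)
        complete = prim.notna() & rel.notna()
        prim, rel = prim[complete], rel[complete]
        n = int(complete.sum())
        if n < 2:
            rows.append(
                dict(substructure=cat, mean_primary=float(prim.mean()) if n else np.nan,
                     mean_relapse=float(rel.mean()) if n else np.nan,
                     t_stat=np.nan, p_value=np.nan, n_probes=n, flagged=True)
            )
            continue
        if test_mode == "paired_over_probes":
            res = stats.ttest_rel(rel, prim)
        else:
            res = stats.ttest_ind(rel, prim, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        if np.isnan(t):  # zero variance with equal means
            t, p = 0.0, 1.0
        rows.append(
            dict(substructure=cat, mean_primary=float(prim.mean()),
                 mean_relapse=float(rel.mean()), t_stat=t, p_value=p,
                 n_probes=n, flagged=False)
        )
    return pd.DataFrame(rows)


def classify_probe(logfc):
    """Sign rule: logFC < 0 -> HYPO, > 0 -> HYPER, exactly 0 -> NONE.

    Vectorized; non-finite input raises.
    """
    arr = np.asarray(logfc, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("logFC must be finite")
    out = np.where(arr < 0, HYPO, np.where(arr > 0, HYPER, NONE))
    if np.isscalar(logfc):
        return str(out)
    return out


@dataclass
class FractionTable:
    """Per-substructure percent breakdown of significant probes.

    ``table`` has one row per mapped substructure with counts
    (count_all, count_hypo, count_hyper) and percents (pct_all, pct_hypo,
    pct_hyper); each percent panel sums to 100 over the substructures when
    its total count is nonzero. Probes with logFC exactly 0 are counted in
    ``n_unclassified`` and excluded from all denominators.
    """

    table: pd.DataFrame
    n_selected: int
    n_hypo: int
    n_hyper: int
    n_unclassified: int
    alpha: float
    use_adjusted: bool

    @property
    def empty(self) -> bool:
        return self.n_selected == 0


def fraction_analysis(
    dmp: DmpTable,
    partition: SubstructurePartition,
    alpha: float = 0.05,
    use_adjusted: bool = False,
    include_undefined: bool = False,
) -> FractionTable:
    """Decompose significant probes into hypo/hyper fractions per substructure.

    Probes with p below ``alpha`` (raw by default — the selection is a
    marginal screen, not a ranking, so no correction is applied) are kept,
    UNDEFINED probes dropped, and each remaining probe classified by the
    sign of its logFC.
    """
    sig = dmp.significant(alpha, use_adjusted)
    cats = list(SUBSTRUCTURES) if include_undefined else list(MAPPED_SUBSTRUCTURES)
    sub = partition.mapping.reindex(sig.index)
    keep = sub.isin(cats)
    sig = sig[keep]
    sub = sub[keep]
    if len(sig) == 0:
        logger.warning("fraction_analysis: zero selected probes")
        empty = pd.DataFrame(
            {c: [] for c in
             ["substructure", "count_all", "count_hypo", "count_hyper",
              "pct_all", "pct_hypo", "pct_hyper"]}
        )
        return FractionTable(empty, 0, 0, 0, 0, alpha, use_adjusted)
    cls = pd.Series(classify_probe(sig["logFC"].to_numpy()), index=sig.index)
    n_unclassified = int((cls == NONE).sum())
    classified = cls != NONE
    sub_c = sub[classified]
    cls_c = cls[classified]
    rows = []
    n_all = int(classified.sum())
    n_hypo = int((cls_c == HYPO).sum())
    n_hyper = int((cls_c == HYPER).sum())
    for cat in cats:
        in_cat = sub_c == cat
        c_all = int(in_cat.sum())
        c_hypo = int((in_cat & (cls_c == HYPO)).sum())
        c_hyper = int((in_cat & (cls_c == HYPER)).sum())
        rows.append(
            dict(
                substructure=cat,
                count_all=c_all,
                count_hypo=c_hypo,
                count_hyper=c_hyper,
                pct_all=100.0 * c_all / n_all if n_all else np.nan,
                pct_hypo=100.0 * c_hypo / n_hypo if n_hypo else np.nan,
                pct_hyper=100.0 * c_hyper / n_hyper if n_hyper else np.nan,
            )
        )
    return FractionTable(
        pd.DataFrame(rows), n_all + n_unclassified, n_hypo, n_hyper,
        n_unclassified, alpha, use_adjusted,
    )
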