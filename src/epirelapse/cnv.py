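"""Copy-number comparison from array intensities.

The total fluorescence intensity of a probe (methylated + unmethylated
channel) scales with local DNA copy number, so the log2 ratio of total
intensity between a patient's relapse and primary sample is a per-locus
copy-number log-fold change. Per-patient median-centering (on by default)
removes array-wide intensity scale differences so that the genome-wide
median logFC is 0. A cohort view selects the top-k most variable loci
across patients and renders them, genome-ordered, as a heatmap with
patients grouped by molecular subgroup.

No segmentation is performed; output is locus-level.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diffmeth import Pair
from .errors import ValidationError
from .io_model import IntensityMatrices, ProbeAnnotation, SampleSheet

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0
TOP_K_CRITERIA = ("variance_across_patients", "max_abs")


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    m = re.fullmatch(r"chr(\d+)", str(chrom))
    if m:
        return (int(m.group(1)), "")
    order = {"chrX": 23, "chrY": 24, "chrM": 25}
    return (order.get(str(chrom), 99), str(chrom))


@dataclass
class CnvMatrix:
    """Loci x patients log2 intensity fold changes (relapse vs primary).

    ``loci`` carries chromosome and 1-based position per probe, sorted in
    genome order; ``values`` has one column per patient with a complete
    pair.
    """

    loci: pd.DataFrame  # index probe_id; columns chromosome, position
    values: pd.DataFrame  # index probe_id; columns patient_id
    centered: bool = True

    def __post_init__(self) -> None:
        if not self.loci.index.equals(self.values.index):
            raise ValidationError("loci and values must share probe index")

    def sorted_genome_order(self) -> "CnvMatrix":
        key = self.loci.assign(
            _k=[_chrom_sort_key(c)[0] for c in self.loci["chromosome"]]
        ).sort_values(["_k", "position"]).index
        return CnvMatrix(self.loci.loc[key], self.values.loc[key], self.centered)


def total_intensity(intensities: IntensityMatrices) -> pd.DataFrame:
    """Per-cell total intensity (methylated + unmethylated)."""
    total = intensities.total
    if (total.to_numpy() < 0).any():
        raise ValueError("negative intensities")
    return total


def patient_logfc(
    totals: pd.DataFrame,
    pairs: list[Pair],
    annotation: ProbeAnnotation,
    *,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    center: bool = True,
) -> CnvMatrix:
    """Per-locus, per-patient log2((relapse + c)/(primary + c)).

    Loci whose total intensity is zero in every sample of every pair are
    dropped (logged). With ``center`` (default) each patient column is
    shifted so its genome-wide median is exactly 0.
    """
    if not pairs:
        raise ValidationError("patient_logfc needs >= 1 complete pair")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    cols = {}
    used = []
    for p in pairs:
        prim = totals[p.primary_sample]
        rel = totals[list(p.relapse_samples)].mean(axis=1)
        cols[p.patient_id] = np.log2((rel + pseudocount) / (prim + pseudocount))
        used.append((prim, rel))
    values = pd.DataFrame(cols, index=totals.index)
    all_zero = pd.concat([prim + rel for prim, rel in used], axis=1).sum(axis=1) == 0
    if all_zero.any():
        logger.info("patient_logfc: dropping %d zero-intensity loci", int(all_zero.sum()))
        values = values[~all_zero]
    if center:
        values = values - values.median(axis=0)
    loci = annotation.table.loc[values.index, ["chromosome", "position"]]
    return CnvMatrix(loci, values, centered=center).sorted_genome_order()


def top_k_loci(
    matrix: CnvMatrix, k: int, criterion: str = "variance_across_patients"
) -> CnvMatrix:
    """Select the k loci ranking highest on the criterion.

    ``variance_across_patients`` ranks by the variance of logFC over
    patients (recurrent change); ``max_abs`` by the largest |logFC| in any
    patient. Ties break deterministically by (chromosome, position); the
    returned matrix is in genome order. k larger than the locus count
    returns everything with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if criterion not in TOP_K_CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    v = matrix.values
    if criterion == "variance_across_patients":
        score = v.var(axis=1, ddof=1) if v.shape[1] > 1 else v.abs().iloc[:, 0]
    else:
        score = v.abs().max(axis=1)
    if k >= len(v):
        if k > len(v):
            logger.warning("top_k_loci: k=%d exceeds %d available loci", k, len(v))
        return matrix.sorted_genome_order()
    order = pd.DataFrame(
        {
            "score": -score,
            "_chrom": [_chrom_sort_key(c)[0] for c in matrix.loci["chromosome"]],
            "position": matrix.loci["position"],
        },
        index=v.index,
    ).sort_values(["score", "_chrom", "position"], kind="mergesort")
    keep = order.index[:k]
    return CnvMatrix(matrix.loci.loc[keep], v.loc[keep], matrix.centered).sorted_genome_order()


def subgroup_summary(matrix: CnvMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-subgroup mean |logFC| over loci and that subgroup's patients."""
    patient_subgroup = (
        sheet.table.drop_duplicates("patient_id").set_index("patient_id")["subgroup"]
    )
    rows = []
    for label in sorted(patient_subgroup.unique()):
        patients = [
            p for p in matrix.values.columns if patient_subgroup.get(p) == label
        ]
        if not patients:
            continue
        sub = matrix.values[patients]
        rows.append(
            dict(
                subgroup=label,
                n_patients=len(patients),
                mean_abs_logfc=float(sub.abs().to_numpy().mean()),
                mean_logfc=float(sub.to_numpy().mean()),
            )
        )
    return pd.DataFrame(rows)


def cnv_report(
    matrix: CnvMatrix,
    sheet: SampleSheet,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, Path | None]:
    """Cohort heatmap (patients grouped by subgroup, loci genome-ordered)
    plus a per-subgroup mean-|logFC| summary table.

    Returns ``(summary, figure_path)``; the figure is written only when
    ``out_dir`` is given.
    """
    if matrix.values.empty:
        raise ValidationError("cnv_report needs a non-empty matrix")
    summary = subgroup_summary(matrix, sheet)
    fig_path = None
    if out_dir is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        m = matrix.sorted_genome_order()
        patient_subgroup = (
            sheet.table.drop_duplicates("patient_id").set_index("patient_id")["subgroup"]
        )
        col_order = sorted(
            m.values.columns, key=lambda p: (str(patient_subgroup.get(p, "")), p)
        )
        data = m.values[col_order].to_numpy().T
        fig, ax = plt.subplots(figsize=(10, max(2, 0.25 * len(col_order))))
        vmax = max(0.5, np.nanpercentile(np.abs(data), 99))
        im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_yticks(range(len(col_order)))
        ax.set_yticklabels(
            [f"{p} ({patient_subgroup.get(p, '?')})" for p in col_order], fontsize=6
        )
        ax.set_xlabel("loci (genome order)")
        fig.colorbar(im, ax=ax, label="log2 intensity FC (relapse/primary)")
        fig.tight_layout()
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fig_path = out_dir / "cnv_heatmap.png"
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
    return summary, fig_path
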