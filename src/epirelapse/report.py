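"""One-shot orchestration of the full comparison pipeline.

``run_all`` chains the stages — optional simulation, beta/M preprocessing,
paired probe-level differential methylation, substructure status and
hypo/hyper fractions, intensity-based CNV, and (when scores are supplied)
morphology — and writes a single machine-readable JSON report. A pydantic
model doubles as the report's versioned schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel

from . import __version__
from .cnv import patient_logfc, top_k_loci, cnv_report, total_intensity
from .diffmeth import make_pairs, run_dmp
from .errors import ConfigError, ValidationError
from .io_model import (
    AlignedDataset,
    align_inputs,
    read_beta_matrix,
    read_intensity_matrices,
    read_probe_annotation,
    read_sample_sheet,
)
from .morphology import read_scores, summarize, unpaired_t
from .preprocess import group_means
from .substructure import fraction_analysis, partition_probes, substructure_status
from .synthetic import SimulationConfig, config_from_dict, simulate_dataset

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


@dataclass
class RunConfig:
    """Inputs and knobs for a full pipeline run."""

    # either file inputs ...
    annotation_path: str | None = None
    beta_path: str | None = None
    sheet_path: str | None = None
    methylated_path: str | None = None
    unmethylated_path: str | None = None
    scores_path: str | None = None
    # ... or a simulation
    simulate: dict | None = None
    seed: int = 0

    pairing_policy: str = "first_relapse"
    alpha: float = 0.05
    use_adjusted: bool = False
    substructure_test: str = "paired_over_probes"
    morphology_mode: str = "student_pooled"
    moderation: bool = False
    top_k: int = 1000
    per_subgroup: bool = True
    out_dir: str = "results"
    write_figures: bool = False

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if self.simulate is None and not (
            self.annotation_path and self.beta_path and self.sheet_path
        ):
            raise ConfigError("need either simulate config or annotation/beta/sheet paths")


# --- report schema ---------------------------------------------------------


class SubstructureRow(BaseModel):
    substructure: str
    mean_primary: float | None
    mean_relapse: float | None
    t_stat: float | None
    p_value: float | None
    n_probes: int


class FractionRow(BaseModel):
    substructure: str
    count_all: int
    count_hypo: int
    count_hyper: int
    pct_all: float | None
    pct_hypo: float | None
    pct_hyper: float | None


class DmpSummary(BaseModel):
    scope: str
    n_probes_tested: int
    n_pairs: int
    n_sig_raw: int
    n_sig_adjusted: int


class CnvSubgroupRow(BaseModel):
    subgroup: str
    n_patients: int
    mean_abs_logfc: float
    mean_logfc: float


class MorphologyRow(BaseModel):
    variable: str
    mean_primary: float
    mean_relapse: float
    t_stat: float
    p_value: float


class Report(BaseModel):
    schema_version: str
    package_version: str
    seed: int
    config_hash: str
    partition_counts: dict[str, int]
    partition_total: int
    dmp: list[DmpSummary]
    substructure_status: dict[str, list[SubstructureRow]]
    fractions: dict[str, list[FractionRow]]
    cnv: list[CnvSubgroupRow] | str
    morphology: list[MorphologyRow] | str


def _nan_to_none(x):
    return None if x is None or (isinstance(x, float) and x != x) else x


def _load_dataset(config: RunConfig) -> AlignedDataset:
    if config.simulate is not None:
        sim_cfg = config.simulate
        if isinstance(sim_cfg, SimulationConfig):
            sim = sim_cfg
        else:
            sim = config_from_dict({**sim_cfg, "seed": sim_cfg.get("seed", config.seed)})
        ds = simulate_dataset(sim)
        return align_inputs(ds.annotation, ds.beta, ds.sheet, ds.intensities)
    annotation = read_probe_annotation(config.annotation_path)
    beta = read_beta_matrix(config.beta_path)
    sheet = read_sample_sheet(config.sheet_path)
    intensities = None
    if config.methylated_path and config.unmethylated_path:
        intensities = read_intensity_matrices(config.methylated_path, config.unmethylated_path)
    return align_inputs(annotation, beta, sheet, intensities)


def run_all(config: RunConfig) -> Report:
    """Execute every applicable stage and return the aggregated report.

    Also writes ``report.json`` (and stage TSVs) under ``config.out_dir``.
    """
    config.validate()
    # hash covers the analysis-relevant config only, not output locations
    cfg_repr = json.dumps(
        {k: v for k, v in asdict(config).items() if k not in ("out_dir", "write_figures")},
        sort_keys=True,
        default=str,
    )
    config_hash = hashlib.sha256(cfg_repr.encode()).hexdigest()[:16]
    logger.info("run_all: seed=%d config=%s", config.seed, config_hash)

    dataset = _load_dataset(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    partition = partition_probes(dataset.annotation)

    # --- differential methylation -----------------------------------------
    dmp_cohort = run_dmp(dataset, "cohort", moderation=config.moderation,
                         policy=config.pairing_policy)
    dmp_tables = {"cohort": dmp_cohort}
    if config.per_subgroup:
        dmp_tables.update(run_dmp(dataset, "per_subgroup", moderation=config.moderation,
                                  policy=config.pairing_policy))
    dmp_summaries = []
    for scope, tab in dmp_tables.items():
        t = tab.table
        dmp_summaries.append(
            DmpSummary(
                scope=scope,
                n_probes_tested=int(t["p_raw"].notna().sum()) if len(t) else 0,
                n_pairs=int(t["n_pairs"].max()) if len(t) else 0,
                n_sig_raw=int((t["p_raw"] < config.alpha).sum()) if len(t) else 0,
                n_sig_adjusted=int((t["p_adj"] < config.alpha).sum()) if len(t) else 0,
            )
        )
    dmp_cohort.table.to_csv(out_dir / "dmp_cohort.tsv", sep="\t", float_format="%.6g")

    # --- substructure status + fractions ----------------------------------
    status: dict[str, list[SubstructureRow]] = {}
    fractions: dict[str, list[FractionRow]] = {}
    gm_cohort = group_means(dataset.beta, dataset.sheet)
    gms = {"cohort": gm_cohort}
    if config.per_subgroup:
        gms.update(group_means(dataset.beta, dataset.sheet, stratify_by_subgroup=True))
    for scope, gm in gms.items():
        st = substructure_status(gm, partition, config.substructure_test)
        status[scope] = [
            SubstructureRow(**{k: _nan_to_none(v) for k, v in row.items() if k != "flagged"})
            for row in st.to_dict("records")
        ]
    for scope, tab in dmp_tables.items():
        if len(tab.table) == 0:
            fractions[scope] = []
            continue
        ft = fraction_analysis(tab, partition, config.alpha, config.use_adjusted)
        fractions[scope] = [
            FractionRow(**{k: _nan_to_none(v) for k, v in row.items()})
            for row in ft.table.to_dict("records")
        ]

    # --- CNV ----------------------------------------------------------------
    if dataset.intensities is not None:
        pairs = make_pairs(dataset.sheet, config.pairing_policy)
        totals = total_intensity(dataset.intensities)
        cnv_matrix = top_k_loci(
            patient_logfc(totals, pairs, dataset.annotation), config.top_k
        )
        summary, _ = cnv_report(
            cnv_matrix, dataset.sheet, out_dir if config.write_figures else None
        )
        cnv_field: list[CnvSubgroupRow] | str = [
            CnvSubgroupRow(**row) for row in summary.to_dict("records")
        ]
        cnv_matrix.values.to_csv(out_dir / "cnv_top_loci.tsv", sep="\t", float_format="%.6g")
    else:
        logger.info("run_all: no intensity matrices; CNV stage skipped")
        cnv_field = "skipped"

    # --- morphology ----------------------------------------------------------
    if config.scores_path:
        scores = read_scores(config.scores_path)
        summ = summarize(scores)
        morph_rows = []
        for var in sorted(scores.table["variable"].unique()):
            x = scores.values(var, "PRIMARY")
            y = scores.values(var, "RELAPSE")
            if len(x) < 2 or len(y) < 2:
                continue
            t, _, p = unpaired_t(y, x, config.morphology_mode)
            s = summ[summ["variable"] == var].set_index("group")
            morph_rows.append(
                MorphologyRow(
                    variable=var,
                    mean_primary=float(s.loc["PRIMARY", "mean"]),
                    mean_relapse=float(s.loc["RELAPSE", "mean"]),
                    t_stat=t,
                    p_value=p,
                )
            )
        morph_field: list[MorphologyRow] | str = morph_rows
    else:
        morph_field = "skipped"

    report = Report(
        schema_version=REPORT_SCHEMA_VERSION,
        package_version=__version__,
        seed=config.seed,
        config_hash=config_hash,
        partition_counts=partition.counts,
        partition_total=partition.total,
        dmp=dmp_summaries,
        substructure_status=status,
        fractions=fractions,
        cnv=cnv_field,
        morphology=morph_field,
    )
    (out_dir / "report.json").write_text(
        json.dumps(report.model_dump(), indent=2, sort_keys=True) + "\n"
    )
    return report
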