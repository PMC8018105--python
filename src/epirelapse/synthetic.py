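"""Seeded generator of paired primary/relapse methylation-array datasets.

The generator emulates the structure of a paired tumor cohort profiled on a
450K-style array: per-patient primary and relapse samples, five molecular
subgroups of unequal size, probes stratified over CpG-island substructures
with a bimodal beta baseline (island probes mostly unmethylated, open-sea
probes mostly methylated), subgroup-specific planted relapse effects
(island hypermethylation, shelf hypomethylation) on the beta scale,
patient- and sample-level noise on the M scale, and lognormal total
intensities with optional chromosome-window copy-number events in relapse
samples. A ground-truth table records every planted effect.

Everything is driven by a single integer seed; identical config + seed
gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from . import io_model
from .io_model import (
    PRIMARY,
    RELAPSE,
    SUBSTRUCTURES,
    BetaMatrix,
    IntensityMatrices,
    ProbeAnnotation,
    SampleSheet,
)
from .preprocess import beta_to_m, m_to_beta

#: Substructure proportions of a 485,577-probe 450K annotation
#: (island 150254, N shelf 24844, N shore 62870, S shelf 22300,
#: S shore 49197, undefined 176112), normalized.
DEFAULT_PROPORTIONS = {
    "ISLAND": 150254 / 485577,
    "N_SHORE": 62870 / 485577,
    "S_SHORE": 49197 / 485577,
    "N_SHELF": 24844 / 485577,
    "S_SHELF": 22300 / 485577,
    "UNDEFINED": 176112 / 485577,
}

#: Cohort composition mirroring a 45-patient paired ependymoma series.
DEFAULT_SUBGROUPS = (
    ("ST-EPN-RELA", 11),
    ("PF-SE", 2),
    ("PF-EPN-A", 23),
    ("PF-EPN-B", 7),
    ("SP-MPE", 2),
)

#: Relapse island hypermethylation / shelf hypomethylation, planted only in
#: the subgroups where such shifts are expected.
DEFAULT_DELTA_ISLAND = {"ST-EPN-RELA": 0.05, "PF-SE": 0.05, "PF-EPN-A": 0.05}
DEFAULT_DELTA_SHELF = {"ST-EPN-RELA": -0.03, "PF-SE": -0.03}


@dataclass(frozen=True)
class CnaEvent:
    """A multiplicative intensity event in relapse samples of one subgroup."""

    subgroup: str
    chromosome: str
    start: int
    end: int
    intensity_factor: float


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults describe the emulated cohort."""

    n_probes: int = 20_000
    substructure_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    subgroups: Sequence[tuple[str, int]] = DEFAULT_SUBGROUPS
    delta_island: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DELTA_ISLAND)
    )
    delta_shelf: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DELTA_SHELF)
    )
    patient_sd: float = 0.5  # between-patient SD, M scale
    residual_sd: float = 0.3  # within-pair SD, M scale
    cna_events: Sequence[CnaEvent] = ()
    relapses_per_patient: int = 1
    n_chromosomes: int = 22
    chromosome_length: int = 100_000_000
    island_low_fraction: float = 0.8  # islands drawn from the low mixture mode
    nonisland_high_fraction: float = 0.8
    mean_total_intensity: float = 2000.0  # lognormal median, fluorescence units
    # per-(probe, sample) lognormal sigma (natural log); 0.1 puts the
    # relapse/primary log2-ratio SD near 0.2, the scale seen for paired
    # array total intensities once probe affinity cancels in the ratio
    intensity_sigma: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes <= 0:
            raise ConfigError("n_probes must be positive")
        if not self.subgroups or any(n <= 0 for _, n in self.subgroups):
            raise ConfigError("subgroups must be non-empty with positive sizes")
        props = {k: float(v) for k, v in self.substructure_proportions.items()}
        if set(props) != set(SUBSTRUCTURES):
            raise ConfigError(f"proportions must cover exactly {SUBSTRUCTURES}")
        if any(v < 0 for v in props.values()):
            raise ConfigError("proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigError("proportions must sum to 1")
        if self.residual_sd <= 0:
            raise ConfigError("residual_sd must be positive")
        if self.patient_sd < 0:
            raise ConfigError("patient_sd must be >= 0")
        for ev in self.cna_events:
            if ev.intensity_factor <= 0:
                raise ConfigError("intensity_factor must be positive")
        if self.relapses_per_patient < 1:
            raise ConfigError("relapses_per_patient must be >= 1")


@dataclass
class TruthTable:
    """Planted effects: per-probe beta shifts and per-locus intensity
    log2 factors, one column per subgroup."""

    beta_shift: pd.DataFrame  # probes x subgroups, beta-scale shift
    intensity_log2_factor: pd.DataFrame  # probes x subgroups, log2 factor


@dataclass
class SimulatedDataset:
    annotation: ProbeAnnotation
    beta: BetaMatrix
    intensities: IntensityMatrices
    sheet: SampleSheet
    truth: TruthTable
    config: SimulationConfig


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw a complete paired-cohort dataset from the generative model.

    Per probe: a baseline beta from a two-component Beta mixture conditioned
    on substructure; per patient: a Normal(0, patient_sd^2) M-scale offset
    shared by the pair; per sample: Normal(0, residual_sd^2) M-scale noise.
    Relapse samples add the planted beta-scale shift of the probe's
    substructure in the patient's subgroup after mapping back to the beta
    scale, so the expected relapse-primary beta difference equals the
    planted shift. Total intensity is lognormal, multiplied by the event
    factor at loci inside a copy-number event of the sample's subgroup
    (relapse samples only).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_probes

    # --- probes -----------------------------------------------------------
    cats = list(SUBSTRUCTURES)
    probs = np.array([config.substructure_proportions[c] for c in cats], float)
    probs = probs / probs.sum()
    sub_idx = rng.choice(len(cats), size=n, p=probs)
    substructure = np.array(cats, dtype=object)[sub_idx]
    chrom_num = rng.integers(1, config.n_chromosomes + 1, size=n)
    position = rng.integers(1, config.chromosome_length + 1, size=n)
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": [f"chr{c}" for c in chrom_num],
                "position": position,
                "substructure": substructure,
            },
            index=probe_ids,
        )
    )

    # --- baseline betas: bimodal mixture ----------------------------------
    is_island = substructure == "ISLAND"
    u = rng.random(n)
    low_mode = np.where(is_island, u < config.island_low_fraction,
                        u >= config.nonisland_high_fraction)
    low = rng.beta(2.0, 18.0, size=n)  # concentrated near 0.1
    high = rng.beta(18.0, 2.0, size=n)  # concentrated near 0.9
    baseline_beta = np.where(low_mode, low, high)
    m0 = beta_to_m(baseline_beta)

    # --- samples ----------------------------------------------------------
    sheet_rows = []
    patient_labels: list[tuple[str, str]] = []  # (patient_id, subgroup)
    idx = 0
    for label, n_pat in config.subgroups:
        for _ in range(n_pat):
            idx += 1
            pid = f"P{idx:02d}"
            patient_labels.append((pid, label))
            sheet_rows.append((f"{pid}-P0", pid, PRIMARY, 0, label))
            for r in range(1, config.relapses_per_patient + 1):
                sheet_rows.append((f"{pid}-R{r}", pid, RELAPSE, r, label))
    sheet = SampleSheet(
        pd.DataFrame(
            sheet_rows,
            columns=["sample_id", "patient_id", "status", "relapse_index", "subgroup"],
        ).set_index("sample_id")
    )

    # --- planted effects per subgroup -------------------------------------
    subgroup_labels = [label for label, _ in config.subgroups]
    shift = pd.DataFrame(0.0, index=probe_ids, columns=subgroup_labels)
    is_shelf = np.isin(substructure, ("N_SHELF", "S_SHELF"))
    for g in subgroup_labels:
        d_isl = float(config.delta_island.get(g, 0.0))
        d_shf = float(config.delta_shelf.get(g, 0.0))
        shift[g] = np.where(is_island, d_isl, np.where(is_shelf, d_shf, 0.0))

    log2_factor = pd.DataFrame(0.0, index=probe_ids, columns=subgroup_labels)
    in_event_by_group: dict[str, np.ndarray] = {g: np.zeros(n, bool) for g in subgroup_labels}
    for ev in config.cna_events:
        if ev.subgroup not in in_event_by_group:
            raise ConfigError(f"cna_event subgroup {ev.subgroup!r} not in cohort")
        mask = (
            (annotation.table["chromosome"].to_numpy() == ev.chromosome)
            & (position >= ev.start)
            & (position <= ev.end)
        )
        in_event_by_group[ev.subgroup] |= mask
        log2_factor.loc[mask, ev.subgroup] += np.log2(ev.intensity_factor)

    # --- betas and intensities --------------------------------------------
    beta_cols: dict[str, np.ndarray] = {}
    meth_cols: dict[str, np.ndarray] = {}
    unmeth_cols: dict[str, np.ndarray] = {}
    mu_log = np.log(config.mean_total_intensity)
    for pid, g in patient_labels:
        patient_eff = rng.normal(0.0, config.patient_sd, size=n) if config.patient_sd else 0.0
        d = shift[g].to_numpy()
        factor = np.exp2(log2_factor[g].to_numpy())
        for sid, status in [(f"{pid}-P0", PRIMARY)] + [
            (f"{pid}-R{r}", RELAPSE) for r in range(1, config.relapses_per_patient + 1)
        ]:
            noise = rng.normal(0.0, config.residual_sd, size=n)
            beta = m_to_beta(m0 + patient_eff + noise)
            if status == RELAPSE:
                beta = beta + d
            beta = np.clip(beta, 0.001, 0.999)
            total = rng.lognormal(mu_log, config.intensity_sigma, size=n)
            if status == RELAPSE:
                total = total * factor
            beta_cols[sid] = beta
            meth_cols[sid] = total * beta
            unmeth_cols[sid] = total * (1.0 - beta)

    sample_ids = list(sheet.sample_ids)
    beta_df = pd.DataFrame(beta_cols, index=probe_ids)[sample_ids]
    intensities = IntensityMatrices(
        pd.DataFrame(meth_cols, index=probe_ids)[sample_ids],
        pd.DataFrame(unmeth_cols, index=probe_ids)[sample_ids],
    )
    return SimulatedDataset(
        annotation=annotation,
        beta=BetaMatrix(beta_df),
        intensities=intensities,
        sheet=sheet,
        truth=TruthTable(shift, log2_factor),
        config=config,
    )


def write_fixture(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the package's plain-text formats plus truth CSVs.

    File contents are deterministic for a fixed dataset.
    """
    if len(dataset.sheet.sample_ids) == 0:
        raise ValidationError("cannot write a 0-sample dataset")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": io_model.write_probe_annotation(dataset.annotation, out / "annotation.csv"),
        "beta": io_model.write_matrix(dataset.beta.values, out / "beta.tsv"),
        "methylated": io_model.write_matrix(dataset.intensities.methylated, out / "intensity_methylated.tsv"),
        "unmethylated": io_model.write_matrix(dataset.intensities.unmethylated, out / "intensity_unmethylated.tsv"),
        "samples": io_model.write_sample_sheet(dataset.sheet, out / "samples.csv"),
    }
    t = dataset.truth
    t.beta_shift.rename_axis("probe_id").to_csv(out / "truth_beta_shift.csv", float_format="%.6g")
    t.intensity_log2_factor.rename_axis("probe_id").to_csv(
        out / "truth_intensity_log2_factor.csv", float_format="%.6g"
    )
    paths["truth_beta_shift"] = out / "truth_beta_shift.csv"
    paths["truth_intensity_log2_factor"] = out / "truth_intensity_log2_factor.csv"
    return paths


def annotation_from_counts(
    counts: Mapping[str, int], n_chromosomes: int = 22, chromosome_length: int = 100_000_000
) -> ProbeAnnotation:
    """Deterministic annotation with exactly the given per-category counts.

    Probes are laid out round-robin over synthetic chromosomes; useful for
    partition accounting against a known category composition.
    """
    cats = np.repeat(
        np.array(list(counts.keys()), dtype=object),
        np.array(list(counts.values()), dtype=int),
    )
    n = len(cats)
    if n == 0:
        raise ConfigError("counts must describe at least one probe")
    chrom = 1 + (np.arange(n) % n_chromosomes)
    position = 1 + (np.arange(n) // n_chromosomes) % chromosome_length
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": [f"chr{c}" for c in chrom],
                "position": position,
                "substructure": cats,
            },
            index=pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id"),
        )
    )


def config_from_dict(d: Mapping) -> SimulationConfig:
    """Build a config from a YAML/JSON-style mapping."""
    d = dict(d)
    if "cna_events" in d:
        d["cna_events"] = tuple(
            CnaEvent(**ev) if isinstance(ev, Mapping) else CnaEvent(*ev)
            for ev in d["cna_events"]
        )
    if "subgroups" in d:
        d["subgroups"] = tuple((str(g), int(k)) for g, k in d["subgroups"])
    return SimulationConfig(**d)
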