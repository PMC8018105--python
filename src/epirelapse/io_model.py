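"""Domain types and plain-text readers/writers for 450K-style array data.

The in-memory containers are thin dataclasses around pandas objects:

* :class:`ProbeAnnotation` — one row per probe: chromosome, 1-based
  position, and its relation to the nearest CpG island (island, shore,
  shelf, or undefined/open sea).
* :class:`BetaMatrix` — probes x samples methylation fractions in [0, 1].
* :class:`IntensityMatrices` — methylated and unmethylated channel
  intensities of the same shape (arbitrary fluorescence units).
* :class:`SampleSheet` — patient pairing (primary vs relapse, relapse
  index) and molecular subgroup labels.

Files are plain CSV/TSV; raw scanner (IDAT) formats are out of scope —
matrices are assumed to arrive preprocessed, as they do from public
repositories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical epigenomic substructure categories (total, disjoint partition).
SUBSTRUCTURES = ("ISLAND", "N_SHORE", "S_SHORE", "N_SHELF", "S_SHELF", "UNDEFINED")

#: Categories carried into substructure-level analyses (UNDEFINED excluded).
MAPPED_SUBSTRUCTURES = ("ISLAND", "N_SHORE", "S_SHORE", "N_SHELF", "S_SHELF")

#: Per-substructure probe counts of the HumanMethylation450 annotation
#: (485,577 probes in total); used as the reference composition for
#: synthetic annotations and partition accounting.
HM450_SUBSTRUCTURE_COUNTS = {
    "ISLAND": 150_254,
    "N_SHORE": 62_870,
    "S_SHORE": 49_197,
    "N_SHELF": 24_844,
    "S_SHELF": 22_300,
    "UNDEFINED": 176_112,
}

# Accepts Illumina-manifest dialects ("Island", "N_Shore", "OpenSea") and
# the "Shelve" spelling used in some reports.
_SUBSTRUCTURE_SYNONYMS = {
    "ISLAND": "ISLAND",
    "CPG ISLAND": "ISLAND",
    "CPG_ISLAND": "ISLAND",
    "N_SHORE": "N_SHORE",
    "N SHORE": "N_SHORE",
    "S_SHORE": "S_SHORE",
    "S SHORE": "S_SHORE",
    "N_SHELF": "N_SHELF",
    "N SHELF": "N_SHELF",
    "N_SHELVE": "N_SHELF",
    "N SHELVE": "N_SHELF",
    "S_SHELF": "S_SHELF",
    "S SHELF": "S_SHELF",
    "S_SHELVE": "S_SHELF",
    "S SHELVE": "S_SHELF",
    "OPENSEA": "UNDEFINED",
    "OPEN SEA": "UNDEFINED",
    "OPEN_SEA": "UNDEFINED",
    "UNDEFINED": "UNDEFINED",
    "UNMAPPED": "UNDEFINED",
    "UNDEFINED/UNMAPPED": "UNDEFINED",
    "NONE": "UNDEFINED",
    "": "UNDEFINED",
}

PRIMARY = "PRIMARY"
RELAPSE = "RELAPSE"


def normalize_substructure(label: str) -> tuple[str, bool]:
    """Map a substructure string to the canonical vocabulary.

    Returns ``(category, recognized)``; unrecognized strings map to
    ``UNDEFINED`` with ``recognized=False`` so callers can count them.
    """
    key = str(label).strip().upper()
    if key in _SUBSTRUCTURE_SYNONYMS:
        return _SUBSTRUCTURE_SYNONYMS[key], True
    return "UNDEFINED", False


@dataclass
class ProbeAnnotation:
    """Genomic position and substructure class for every array probe.

    ``table`` is indexed by probe_id with columns ``chromosome``,
    ``position`` (1-based) and ``substructure`` (one of
    :data:`SUBSTRUCTURES`).
    """

    table: pd.DataFrame
    n_unrecognized_substructure: int = 0

    def __post_init__(self) -> None:
        t = self.table
        required = {"chromosome", "position", "substructure"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        if not t.index.is_unique:
            dups = t.index[t.index.duplicated()].unique()[:5].tolist()
            raise ValidationError(f"duplicate probe_id(s): {dups}")
        if len(t) and (t["position"] < 1).any():
            raise ValidationError("positions must be >= 1")
        bad = set(t["substructure"].unique()) - set(SUBSTRUCTURES)
        if bad:
            raise ValidationError(f"unknown substructure categories: {sorted(bad)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions; NaN marks missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not v.index.is_unique or not v.columns.is_unique:
            raise ValidationError("beta matrix labels must be unique")
        arr = v.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(arr, initial=0.0) < 0 or np.nanmax(arr, initial=1.0) > 1:
                raise ValidationError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class IntensityMatrices:
    """Methylated/unmethylated channel intensities (same shape, >= 0)."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame

    def __post_init__(self) -> None:
        m, u = self.methylated, self.unmethylated
        if m.shape != u.shape or not m.index.equals(u.index) or not m.columns.equals(u.columns):
            raise ValidationError("methylated/unmethylated matrices must share labels")
        if (m.to_numpy() < 0).any() or (u.to_numpy() < 0).any():
            raise ValidationError("intensities must be non-negative")

    @property
    def total(self) -> pd.DataFrame:
        return self.methylated + self.unmethylated


@dataclass
class SampleSheet:
    """Sample metadata: patient pairing and molecular subgroup.

    ``table`` is indexed by sample_id with columns ``patient_id``,
    ``status`` (PRIMARY/RELAPSE), ``relapse_index`` (0 for primary,
    1..k for successive relapses) and ``subgroup``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"patient_id", "status", "relapse_index", "subgroup"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if not t.index.is_unique:
            raise ValidationError("duplicate sample_id in sample sheet")
        bad = set(t["status"].unique()) - {PRIMARY, RELAPSE}
        if bad:
            raise ValidationError(f"unknown status values: {sorted(bad)}")
        if t.duplicated(subset=["patient_id", "relapse_index"]).any():
            raise ValidationError("(patient_id, relapse_index) must be unique")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_of(self, status: str) -> pd.Index:
        return self.table.index[self.table["status"] == status]

    def unpaired_patients(self) -> list[str]:
        """Patients lacking a PRIMARY sample (excluded from paired analyses)."""
        has_primary = self.table.groupby("patient_id")["status"].apply(
            lambda s: (s == PRIMARY).any()
        )
        return sorted(has_primary.index[~has_primary])


@dataclass
class AlignedDataset:
    """Probe/sample-consistent bundle produced by :func:`align_inputs`."""

    annotation: ProbeAnnotation
    beta: BetaMatrix
    sheet: SampleSheet
    intensities: IntensityMatrices | None = None
    n_probes_dropped: int = 0
    n_samples_dropped: int = 0


# ---------------------------------------------------------------------------
# readers / writers


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a probe annotation CSV (probe_id,chromosome,position,substructure).

    Unrecognized substructure strings are mapped to UNDEFINED; their count
    is logged and recorded on the returned object.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"probe_id": str, "chromosome": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty annotation file") from exc
    required = ["probe_id", "chromosome", "position", "substructure"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    mapped, recognized = zip(*(normalize_substructure(s) for s in df["substructure"]))
    n_bad = int(len(recognized) - sum(recognized))
    if n_bad:
        logger.warning("%s: %d unrecognized substructure labels mapped to UNDEFINED", path, n_bad)
    df = df.assign(substructure=list(mapped)).set_index("probe_id")
    df["position"] = pd.to_numeric(df["position"], errors="raise").astype(np.int64)
    return ProbeAnnotation(df[["chromosome", "position", "substructure"]], n_bad)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> Path:
    path = Path(path)
    annotation.table.rename_axis("probe_id").to_csv(path)
    return path


def read_matrix(
    path: str | Path,
    kind: str = "beta",
    *,
    missing_token: str = "NA",
    beta_tolerance: float = 1e-3,
) -> pd.DataFrame:
    """Read a probes x samples TSV (first column probe_id).

    ``kind="beta"`` validates the [0, 1] range: values outside it by at most
    ``beta_tolerance`` are clipped with a logged warning; larger excursions
    raise. ``kind="intensity"`` requires non-negative values.
    """
    if kind not in ("beta", "intensity"):
        raise ValueError(f"kind must be 'beta' or 'intensity', got {kind!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[missing_token])
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty matrix file") from exc
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
    if df.isna().to_numpy().all() and df.size:
        logger.warning("%s: matrix is entirely missing", path)
    arr = df.to_numpy()
    if kind == "beta":
        low, high = np.nanmin(arr, initial=0.0), np.nanmax(arr, initial=1.0)
        if low < -beta_tolerance or high > 1 + beta_tolerance:
            raise ValidationError(
                f"{path}: beta values outside [0,1] beyond tolerance "
                f"{beta_tolerance} (range [{low:.6g}, {high:.6g}])"
            )
        n_clip = int(((arr < 0) | (arr > 1)).sum())
        if n_clip:
            logger.warning("%s: clipped %d beta values into [0,1]", path, n_clip)
            df = df.clip(0.0, 1.0)
    else:
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError(f"{path}: negative intensity values")
    return df


def read_beta_matrix(path: str | Path, **kw) -> BetaMatrix:
    return BetaMatrix(read_matrix(path, "beta", **kw))


def read_intensity_matrices(
    methylated_path: str | Path, unmethylated_path: str | Path, **kw
) -> IntensityMatrices:
    return IntensityMatrices(
        read_matrix(methylated_path, "intensity", **kw),
        read_matrix(unmethylated_path, "intensity", **kw),
    )


def write_matrix(
    values: pd.DataFrame, path: str | Path, *, missing_token: str = "NA", precision: int = 6
) -> Path:
    path = Path(path)
    values.rename_axis("probe_id").to_csv(
        path, sep="\t", na_rep=missing_token, float_format=f"%.{precision}g"
    )
    return path


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet CSV (sample_id,patient_id,status,relapse_index,subgroup)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty sample sheet") from exc
    required = ["sample_id", "patient_id", "status", "relapse_index", "subgroup"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.set_index("sample_id")
    df["status"] = df["status"].str.upper()
    df["relapse_index"] = pd.to_numeric(df["relapse_index"], errors="raise").astype(int)
    return SampleSheet(df[required[1:]])


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> Path:
    path = Path(path)
    sheet.table.rename_axis("sample_id").to_csv(path)
    return path


# ---------------------------------------------------------------------------
# alignment


def align_inputs(
    annotation: ProbeAnnotation,
    beta: BetaMatrix,
    sheet: SampleSheet,
    intensities: IntensityMatrices | None = None,
) -> AlignedDataset:
    """Intersect probes (annotation ∩ matrix) and samples (matrix ∩ sheet).

    Matrix order is preserved; dropped counts are recorded. An empty
    intersection on either axis raises :class:`ValidationError`. The
    operation is idempotent.
    """
    probes = beta.probe_ids.intersection(annotation.probe_ids, sort=False)
    samples = beta.sample_ids.intersection(sheet.sample_ids, sort=False)
    if len(probes) == 0:
        raise ValidationError("no probes shared between annotation and matrix")
    if len(samples) == 0:
        raise ValidationError("no samples shared between matrix and sample sheet")
    n_probes_dropped = (len(annotation) - len(probes)) + (len(beta.probe_ids) - len(probes))
    n_samples_dropped = (len(beta.sample_ids) - len(samples)) + (
        len(sheet.sample_ids) - len(samples)
    )
    aligned_int = None
    if intensities is not None:
        aligned_int = IntensityMatrices(
            intensities.methylated.loc[probes, samples],
            intensities.unmethylated.loc[probes, samples],
        )
    return AlignedDataset(
        annotation=ProbeAnnotation(annotation.table.loc[probes], annotation.n_unrecognized_substructure),
        beta=BetaMatrix(beta.values.loc[probes, samples]),
        sheet=SampleSheet(sheet.table.loc[samples]),
        intensities=aligned_int,
        n_probes_dropped=int(n_probes_dropped),
        n_samples_dropped=int(n_samples_dropped),
    )
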