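"""Group comparison of histomorphology scores and Ki67 indexes.

Ordinal scores (cell density 1-3, necrosis 0-3, vessel proliferation 0-3)
and Ki67 percentages (0-100) are summarized as mean ± SEM per group and
compared between primary and relapse samples with an unpaired two-sided
t-test (pooled-variance Student by default; Welch and a rank-based
Mann-Whitney alternative are available). Scores are treated as interval
data for the t-test; they arrive as inputs — no image analysis here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

#: Allowed value range per score variable.
SCALES = {
    "cell_density": (1, 3),
    "necrosis": (0, 3),
    "vessel_proliferation": (0, 3),
    "ki67": (0, 100),
}

T_MODES = ("student_pooled", "welch")


@dataclass
class ScoreSet:
    """Long-format per-sample scores with a PRIMARY/RELAPSE group label."""

    table: pd.DataFrame  # columns: sample_id, group, variable, value

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "variable", "value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"scores missing columns: {sorted(missing)}")
        for var, (lo, hi) in SCALES.items():
            vals = self.table.loc[self.table["variable"] == var, "value"]
            if len(vals) and ((vals < lo) | (vals > hi)).any():
                raise ValidationError(f"{var} values outside [{lo}, {hi}]")

    def values(self, variable: str, group: str) -> np.ndarray:
        m = (self.table["variable"] == variable) & (self.table["group"] == group)
        return self.table.loc[m, "value"].to_numpy(dtype=float)


def read_scores(path) -> ScoreSet:
    df = pd.read_csv(path)
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    return ScoreSet(df)


def summarize(scores: ScoreSet) -> pd.DataFrame:
    """Per-(variable, group) mean, SEM = sd/sqrt(n), and n.

    Singleton groups get SEM = NaN and are flagged.
    """
    rows = []
    for (var, grp), sub in scores.table.groupby(["variable", "group"], sort=True):
        vals = sub["value"].to_numpy(dtype=float)
        n = len(vals)
        if n == 0:
            raise ValidationError(f"empty group {grp} for {var}")
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(
            dict(variable=var, group=grp, mean=float(vals.mean()), sem=sem,
                 n=n, flagged=n < 2)
        )
    return pd.DataFrame(rows)


def unpaired_t(x, y, mode: str = "student_pooled") -> tuple[float, float, float]:
    """Two-sided unpaired t-test; returns (t, df, p).

    Both groups constant and equal gives t = 0, p = 1 rather than NaN.
    """
    if mode not in T_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("unpaired t needs >= 2 values per group")
    res = stats.ttest_ind(x, y, equal_var=(mode == "student_pooled"))
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if np.isnan(t):
        if np.isclose(x.mean(), y.mean()):
            t, p = 0.0, 1.0
        else:  # zero variance, distinct means: evidence is unbounded
            t, p = np.inf if x.mean() > y.mean() else -np.inf, 0.0
        df = len(x) + len(y) - 2 if mode == "student_pooled" else np.nan
    return t, df, p


def mann_whitney(x, y) -> tuple[float, float]:
    """Rank-based alternative; returns (U, p), two-sided."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def t_from_summary(
    mean1: float, sem1: float, n1: int,
    mean2: float, sem2: float, n2: int,
    mode: str = "student_pooled",
) -> tuple[float, float, float]:
    """Unpaired t-test reconstructed from per-group mean, SEM and n.

    Group standard deviations are recovered as sd = sem * sqrt(n). Returns
    (t, df, p) two-sided. Zero pooled variance with distinct means reports
    p = 0 (below any printable threshold).
    """
    if mode not in T_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if n1 < 2 or n2 < 2:
        raise ValidationError("t_from_summary needs n >= 2 per group")
    if sem1 < 0 or sem2 < 0:
        raise ValidationError("SEMs must be >= 0")
    sd1 = sem1 * np.sqrt(n1)
    sd2 = sem2 * np.sqrt(n2)
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(mode == "student_pooled")
    )
    t, p = float(res.statistic), float(res.pvalue)
    if mode == "student_pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = float((v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))) if v1 + v2 > 0 else np.nan
    if np.isnan(t):
        if np.isclose(mean1, mean2):
            t, p = 0.0, 1.0
        else:
            t, p = (np.inf if mean1 > mean2 else -np.inf), 0.0
    return t, df, p
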