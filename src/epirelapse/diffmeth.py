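"""Per-probe paired differential methylation on the M scale.

Each patient contributes one (primary, relapse) pair; the per-probe test is
a one-sample t on the paired M-value differences (relapse - primary), the
form a paired linear model reduces to. Optional empirical-Bayes variance
moderation borrows strength across probes by shrinking each probe's
variance toward a common prior, with the prior degrees of freedom and scale
estimated by moment matching on log variances. Multiple testing is
controlled with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_model import PRIMARY, RELAPSE, AlignedDataset, SampleSheet
from .preprocess import DEFAULT_EPSILON, beta_to_m

logger = logging.getLogger(__name__)

DEFAULT_VARIANCE_FLOOR = 1e-8

PAIR_POLICIES = ("first_relapse", "all_relapses_averaged")


@dataclass(frozen=True)
class Pair:
    """One patient's matched primary sample and relapse sample(s)."""

    patient_id: str
    primary_sample: str
    relapse_samples: tuple[str, ...]
    subgroup: str


def make_pairs(sheet: SampleSheet, policy: str = "first_relapse") -> list[Pair]:
    """Form one (primary, relapse) pair per patient.

    ``first_relapse`` keeps the relapse with the lowest relapse_index;
    ``all_relapses_averaged`` keeps all of a patient's relapses — downstream
    their values are averaged into one pseudo-sample. Patients lacking a
    primary or a relapse are dropped with a logged count.
    """
    if policy not in PAIR_POLICIES:
        raise ValueError(f"unknown pairing policy {policy!r}")
    pairs: list[Pair] = []
    n_dropped = 0
    for patient, sub in sheet.table.groupby("patient_id", sort=True):
        prim = sub.index[sub["status"] == PRIMARY]
        rel = sub[sub["status"] == RELAPSE].sort_values("relapse_index")
        if len(prim) == 0 or len(rel) == 0:
            n_dropped += 1
            continue
        relapse_samples = (
            (rel.index[0],) if policy == "first_relapse" else tuple(rel.index)
        )
        pairs.append(
            Pair(str(patient), prim[0], relapse_samples, str(sub["subgroup"].iloc[0]))
        )
    if n_dropped:
        logger.info("make_pairs: dropped %d unpaired patient(s)", n_dropped)
    if not pairs:
        raise ValidationError("no complete primary/relapse pairs")
    return pairs


def paired_differences(values: pd.DataFrame, pairs: list[Pair]) -> pd.DataFrame:
    """Probes x patients matrix of per-pair differences (relapse - primary).

    Under the averaged policy a patient's relapse value is the mean over
    that patient's relapse samples (pairwise-complete).
    """
    cols = {}
    for p in pairs:
        relapse = values[list(p.relapse_samples)].mean(axis=1)
        cols[p.patient_id] = relapse - values[p.primary_sample]
    return pd.DataFrame(cols, index=values.index)


def paired_t(differences, variance_floor: float = DEFAULT_VARIANCE_FLOOR):
    """One-sample two-sided t on paired differences.

    For a 1-D vector returns ``(logFC, t, df, p)`` scalars; for a 2-D array
    (probes in rows) returns arrays, with NaN entries treated as missing
    pairwise. Rows with fewer than 2 non-missing differences get NaN
    statistics. A degenerate all-zero row yields t = 0, p = 1.
    """
    arr = np.asarray(differences, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    n = np.sum(~np.isnan(arr), axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(arr, axis=1) / np.maximum(n, 1), np.nan)
        # ddof=1 sample variance over non-missing entries
        ss = np.nansum((arr - mean[:, None]) ** 2, axis=1)
    ok = n >= 2
    var = np.full_like(mean, np.nan)
    var[ok] = ss[ok] / (n[ok] - 1)
    var = np.maximum(var, variance_floor)
    df = n - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(var / n)
    t = np.where(ok, t, np.nan)
    # exact-zero rows: mean 0 with floored variance already gives t = 0
    p = np.full_like(t, np.nan)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    mean = np.where(ok, mean, np.nan)
    df = np.where(ok, df, np.nan)
    if squeeze:
        if not ok[0]:
            raise ValidationError("paired_t needs >= 2 non-missing differences")
        return float(mean[0]), float(t[0]), float(df[0]), float(p[0])
    return mean, t, df, p


def moderate_variances(variances, dfs):
    """Empirical-Bayes shrinkage of per-probe variances.

    Assuming s_g^2 | sigma_g^2 ~ sigma_g^2 * chi^2_df / df with an inverse
    chi-square prior (d0, s0^2) on sigma_g^2, the posterior variance is
    ``(d0*s0^2 + df*s^2) / (d0 + df)``. (d0, s0^2) are estimated by moment
    matching on log variances (the marginal of s^2/s0^2 is F(df, d0)).
    Returns ``(d0, s0sq, posterior)``; d0 may be ``inf`` when the observed
    log-variance dispersion is no larger than expected under equal true
    variances, in which case all posteriors equal s0^2.
    """
    s2 = np.asarray(variances, dtype=float)
    df = np.asarray(dfs, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df >= 1)
    if ok.sum() < 10:
        raise ValidationError("moderation needs >= 10 probes with positive variance and df >= 1")
    if not (s2[np.isfinite(s2)] > 0).any():
        raise ValidationError("all variances zero; raise variance_floor")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df[ok] / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
    else:
        d0 = np.inf
    if not np.isfinite(d0):
        if not np.isinf(d0):  # NaN from a failed inversion
            logger.warning("moment matching failed; falling back to d0 = inf")
        d0 = np.inf
        # no excess dispersion: common variance, estimated without log bias
        s0sq = float(np.mean(s2[ok]))
        posterior = np.full_like(s2, s0sq)
        return d0, s0sq, posterior
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    posterior = (d0 * s0sq + df * s2) / (d0 + df)
    return float(d0), s0sq, posterior


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    # trigamma(y) ~ 1/y + 1/(2y^2); start from the 1/y approximation
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def adjust_pvalues(p_raw, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through."""
    if method != "bh":
        raise ValueError(f"unsupported adjustment method {method!r}")
    p = np.asarray(p_raw, dtype=float)
    finite = ~np.isnan(p)
    if finite.any() and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


@dataclass
class DmpTable:
    """Per-probe paired differential-methylation results.

    ``table`` is indexed by probe_id with columns logFC (mean paired M
    difference, relapse - primary), t_stat, df, p_raw, p_adj, n_pairs.
    """

    table: pd.DataFrame
    scope: str = "cohort"
    n_excluded: int = 0

    def significant(self, alpha: float = 0.05, use_adjusted: bool = False) -> pd.DataFrame:
        col = "p_adj" if use_adjusted else "p_raw"
        return self.table[self.table[col] < alpha]


def dmp_from_differences(
    diffs: pd.DataFrame,
    *,
    moderation: bool = False,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    scope: str = "cohort",
) -> DmpTable:
    """Build a :class:`DmpTable` from a probes x patients difference matrix."""
    logfc, t, df, p = paired_t(diffs.to_numpy(), variance_floor)
    n_pairs = diffs.notna().sum(axis=1).to_numpy()
    if moderation:
        ok = ~np.isnan(df)
        s2 = np.full(len(diffs), np.nan)
        arr = diffs.to_numpy(dtype=float)
        mean = np.nanmean(arr, axis=1)
        ss = np.nansum((arr - mean[:, None]) ** 2, axis=1)
        s2[ok] = np.maximum(ss[ok] / (n_pairs[ok] - 1), variance_floor)
        d0, s0sq, post = moderate_variances(s2[ok], df[ok])
        df_mod = df.copy()
        t_mod = np.full_like(t, np.nan)
        t_mod[ok] = logfc[ok] / np.sqrt(post / n_pairs[ok])
        if np.isinf(d0):
            df_mod[ok] = np.inf
            p = np.full_like(t, np.nan)
            p[ok] = 2.0 * stats.norm.sf(np.abs(t_mod[ok]))
        else:
            df_mod[ok] = df[ok] + d0
            p = np.full_like(t, np.nan)
            p[ok] = 2.0 * stats.t.sf(np.abs(t_mod[ok]), df_mod[ok])
        t, df = t_mod, df_mod
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t_stat": t,
            "df": df,
            "p_raw": p,
            "p_adj": adjust_pvalues(p),
            "n_pairs": n_pairs,
        },
        index=diffs.index,
    )
    n_excluded = int(np.isnan(p).sum())
    if n_excluded:
        logger.info("dmp: %d probe(s) with < 2 complete pairs flagged NaN", n_excluded)
    return DmpTable(table, scope=scope, n_excluded=n_excluded)


def run_dmp(
    dataset: AlignedDataset,
    scope: str = "cohort",
    *,
    moderation: bool = False,
    policy: str = "first_relapse",
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    epsilon: float = DEFAULT_EPSILON,
) -> DmpTable | dict[str, DmpTable]:
    """Paired DMP analysis for the whole cohort or per molecular subgroup.

    Subgroups with fewer than 2 complete pairs yield an empty table with a
    logged warning rather than an error.
    """
    if scope not in ("cohort", "per_subgroup"):
        raise ValueError(f"unknown scope {scope!r}")
    mvals = beta_to_m(dataset.beta.values, epsilon)
    if scope == "cohort":
        pairs = make_pairs(dataset.sheet, policy)
        return dmp_from_differences(
            paired_differences(mvals, pairs),
            moderation=moderation,
            variance_floor=variance_floor,
        )
    out: dict[str, DmpTable] = {}
    for label, sub in dataset.sheet.table.groupby("subgroup", sort=True):
        try:
            pairs = make_pairs(SampleSheet(sub), policy)
        except ValidationError:
            pairs = []
        if len(pairs) < 2:
            logger.warning("subgroup %s: < 2 complete pairs; empty DMP table", label)
            empty = pd.DataFrame(
                columns=["logFC", "t_stat", "df", "p_raw", "p_adj", "n_pairs"]
            )
            out[str(label)] = DmpTable(empty, scope=str(label))
            continue
        out[str(label)] = dmp_from_differences(
            paired_differences(mvals, pairs),
            moderation=moderation,
            variance_floor=variance_floor,
            scope=str(label),
        )
    return out
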