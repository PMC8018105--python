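"""Beta/M-value conversion and per-group per-probe means.

Methylation arrays report a beta value per probe, the fraction
``methylated / (methylated + unmethylated)``. Statistical testing is more
reliable on the M scale, ``M = log2(beta / (1 - beta))``, whose variance is
approximately constant across the methylation range. Substructure summaries
use the beta scale directly; the two scales are never mixed within one
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_model import PRIMARY, RELAPSE, BetaMatrix, SampleSheet

#: Default clip bound before the logit; keeps M finite for beta in {0, 1}.
DEFAULT_EPSILON = 1e-3


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """Convert beta (fraction in [0,1]) to M = log2(b'/(1-b')), b' clipped to [eps, 1-eps].

    Accepts scalars or arrays; NaN passes through. Values outside [0, 1]
    raise ``ValueError``.
    """
    arr = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(arr, initial=0.0) < 0 or np.nanmax(arr, initial=1.0) > 1:
            raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, epsilon, 1.0 - epsilon)
    out = np.log2(clipped / (1.0 - clipped))
    out = np.where(np.isnan(arr), np.nan, out)
    if np.isscalar(beta):
        return float(out)
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` away from clipping: 2^m / (1 + 2^m)."""
    arr = np.asarray(m, dtype=float)
    # expit formulation avoids overflow for large |m|
    out = 1.0 / (1.0 + np.exp2(-arr))
    if np.isscalar(m):
        return float(out)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(out, index=m.index)
    return out


@dataclass
class GroupMeanBeta:
    """Per-probe mean beta across PRIMARY and across RELAPSE samples.

    Means are over non-missing values; ``n_primary``/``n_relapse`` record
    the effective per-probe sample counts (0 means the mean is missing).
    """

    primary_mean: pd.Series
    relapse_mean: pd.Series
    n_primary: pd.Series
    n_relapse: pd.Series


def group_means(
    beta: BetaMatrix,
    sheet: SampleSheet,
    stratify_by_subgroup: bool = False,
) -> GroupMeanBeta | dict[str, GroupMeanBeta]:
    """Arithmetic per-probe mean beta for each status group.

    With ``stratify_by_subgroup`` a mapping subgroup label -> GroupMeanBeta
    is returned (subgroups with an empty status group are skipped with a
    ``ValidationError`` only when the whole cohort is degenerate).
    """
    if stratify_by_subgroup:
        out: dict[str, GroupMeanBeta] = {}
        for label, sub in sheet.table.groupby("subgroup", sort=True):
            subsheet = SampleSheet(sub)
            if (sub["status"] == PRIMARY).sum() == 0 or (sub["status"] == RELAPSE).sum() == 0:
                continue
            out[str(label)] = group_means(
                BetaMatrix(beta.values[subsheet.sample_ids]), subsheet
            )
        return out

    prim = sheet.samples_of(PRIMARY)
    rel = sheet.samples_of(RELAPSE)
    if len(prim) == 0 or len(rel) == 0:
        raise ValidationError("both PRIMARY and RELAPSE groups need >= 1 sample")
    pv = beta.values[prim]
    rv = beta.values[rel]
    return GroupMeanBeta(
        primary_mean=pv.mean(axis=1),
        relapse_mean=rv.mean(axis=1),
        n_primary=pv.notna().sum(axis=1),
        n_relapse=rv.notna().sum(axis=1),
    )
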