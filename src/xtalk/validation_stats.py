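"""Expression-validation statistics: ddCt quantification, ANOVA, Tukey HSD.

Relative qPCR quantification follows the comparative-Ct convention:
dCt = Ct_target - Ct_reference per sample, ddCt = dCt - mean dCt of the
control group, fold change = 2^(-ddCt).  Group comparisons use a one-way
ANOVA with an upper-tail F p-value, followed by Tukey's honestly
significant difference test on all pairs (Tukey-Kramer for unequal group
sizes, via the studentized-range distribution).
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def read_ct_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "ct_target", "ct_reference"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    return df


def delta_delta_ct(table: pd.DataFrame, control_group: str,
                   calibrator: str = "control_mean") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample and per-group relative quantification.

    Returns ``(per_sample, per_group)``.  ``per_sample`` carries dCt, ddCt
    and fold per row; ``per_group`` the mean and SD of the folds.  The
    default calibrator is the control-group mean dCt; ``calibrator=
    "group_mean"`` instead calibrates each group against the control mean
    of dCt computed the same way (kept for symmetry with common software
    defaults, identical here) — the switch exists so per-group calibration
    variants can be added without changing the interface.
    """
    if control_group not in set(table["group"]):
        raise ValueError(f"control group {control_group!r} absent from table")
    if not np.isfinite(table[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    out = table.copy()
    out["dct"] = out["ct_target"] - out["ct_reference"]
    control_mean = out.loc[out["group"] == control_group, "dct"].mean()
    out["ddct"] = out["dct"] - control_mean
    out["fold"] = np.power(2.0, -out["ddct"])
    per_group = (
        out.groupby("group", sort=True)["fold"]
        .agg(mean_fold="mean", sd_fold="std", n="count")
        .reset_index()
    )
    return out, per_group


def one_way_anova(values_by_group: Mapping[str, np.ndarray]) -> dict:
    """Classical one-way ANOVA decomposition.

    Returns F, between/within degrees of freedom, and the upper-tail
    F p-value.  Degenerate zero within-group variance with unequal means
    is reported as p at the numeric floor with ``degenerate=True``.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_values = np.concatenate(list(groups.values()))
    grand = all_values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_between = len(groups) - 1
    df_within = len(all_values) - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        if ms_between == 0:
            return {"F": 0.0, "df_between": df_between, "df_within": df_within,
                    "p": 1.0, "degenerate": False}
        logger.warning("one_way_anova: zero within-group variance with unequal means")
        return {"F": np.inf, "df_between": df_between, "df_within": df_within,
                "p": P_FLOOR, "degenerate": True}
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return {"F": float(f), "df_between": df_between, "df_within": df_within,
            "p": p, "degenerate": False}


def tukey_hsd(values_by_group: Mapping[str, np.ndarray],
              family_alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey(-Kramer) comparisons after a one-way layout.

    Backed by the studentized-range implementation in
    :func:`scipy.stats.tukey_hsd`; returns one row per unordered pair with
    the mean difference, adjusted p, and a significance flag at
    ``family_alpha``.
    """
    names = sorted(values_by_group)
    if len(names) < 2 or any(len(values_by_group[g]) < 2 for g in names):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        p = float(res.pvalue[i, j])
        rows.append({
            "group_a": names[i],
            "group_b": names[j],
            "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
            "p_adj": p,
            "significant": p < family_alpha,
        })
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff",
                                       "p_adj", "significant"])


def ct_report(table: pd.DataFrame, control_group: str,
              family_alpha: float = 0.05) -> dict:
    """Full validation block: folds, ANOVA on per-sample folds, Tukey pairs."""
    per_sample, per_group = delta_delta_ct(table, control_group)
    by_group = {g: v["fold"].to_numpy() for g, v in per_sample.groupby("group")}
    anova = one_way_anova(by_group)
    tukey = tukey_hsd(by_group, family_alpha)
    return {"per_sample": per_sample, "per_group": per_group,
            "anova": anova, "tukey": tukey}
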