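"""Cross-study differential expression with Fisher-combined p-values.

Each study is a two-group (case vs. control) expression matrix on a
log2-like scale.  Per study and per gene, a pooled-variance two-sample t
contrast (the linear-model contrast for a two-group design) yields a
two-sided p-value; per gene, the study p-values are combined with Fisher's
combined-probability statistic X^2 = -2 sum(ln p_i) ~ chi^2 with 2k degrees
of freedom under the joint null.  Genes with combined p below alpha are
flagged as differentially expressed (DEGs), and DEGs are mapped onto
detected complexes to nominate disease-associated ("PD") clusters.

An optional variance-moderation switch shrinks per-gene variances toward a
common prior, a simplified analogue of empirical-Bayes moderation for
small-sample stability; it is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_VAR_EPS = 1e-12


@dataclass
class ExpressionStudy:
    """genes x samples matrix plus sample -> {case, control} labels."""

    matrix: pd.DataFrame
    groups: pd.Series  # index = sample, values in {"case", "control"}
    study_id: str

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = set(self.matrix.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)[:5]}")
        bad = set(self.groups.loc[list(self.matrix.columns)]) - {"case", "control"}
        if bad:
            raise ValueError(f"group labels must be case/control, got {sorted(bad)}")

    def samples_in(self, group: str) -> list:
        labels = self.groups.loc[list(self.matrix.columns)]
        return [s for s in self.matrix.columns if labels[s] == group]


def differential_expression(
    study: ExpressionStudy,
    moderate_variance: bool = False,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-gene two-group contrast for one study.

    Returns a frame indexed by gene with columns ``statistic`` and ``p``
    (two-sided), from a pooled-variance t with n1 + n0 - 2 degrees of
    freedom.  Zero pooled variance is floored at a small epsilon so exact
    separation yields an extreme finite statistic.  With
    ``moderate_variance`` the pooled variances are shrunk toward their
    median with ``prior_df`` pseudo-degrees of freedom and the t degrees of
    freedom increase accordingly.
    """
    case = study.samples_in("case")
    ctrl = study.samples_in("control")
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"study {study.study_id!r}: both groups need >= 2 samples "
            f"(case={len(case)}, control={len(ctrl)})"
        )
    x1 = study.matrix[case].to_numpy(dtype=float)
    x0 = study.matrix[ctrl].to_numpy(dtype=float)
    n1, n0 = x1.shape[1], x0.shape[1]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    s1 = x1.var(axis=1, ddof=1)
    s0 = x0.var(axis=1, ddof=1)
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * s1 + (n0 - 1) * s0) / df
    if moderate_variance:
        s02 = float(np.median(sp2))
        sp2 = (prior_df * s02 + df * sp2) / (prior_df + df)
        df = df + prior_df
    sp2 = np.maximum(sp2, _VAR_EPS)
    t = (m1 - m0) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"statistic": t, "p": p}, index=study.matrix.index)


def fisher_combine(p_list, floor: float = 1e-300) -> tuple[float, int, float]:
    """Fisher's combined-probability method.

    Returns (X^2, df, combined p) with X^2 = -2 sum(ln p_i) and df = 2k.
    Zero p-values are clamped to ``floor`` with a warning; values outside
    [0, 1] are rejected.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise ValueError("p_list must be non-empty")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("fisher_combine: clamping %d zero p-value(s) to %g",
                       int((p == 0).sum()), floor)
        p = np.maximum(p, floor)
    x2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    combined = float(stats.chi2.sf(x2, df))
    return x2, df, combined


def combine_studies(
    per_study: dict,
    alpha: float = 0.05,
    floor: float = 1e-300,
) -> pd.DataFrame:
    """Combine per-study results into one meta table.

    ``per_study`` maps study_id -> frame from :func:`differential_expression`.
    Genes missing from some studies (NaN p) are combined over the studies
    that measured them, with df = 2 x (number available).  Returns a frame
    indexed by gene with per-study p columns, ``x2``, ``df``, ``combined_p``
    and ``deg`` (combined_p < alpha, strict).
    """
    if not per_study:
        raise ValueError("no studies to combine")
    p_cols = pd.DataFrame(
        {f"p_{sid}": res["p"] for sid, res in per_study.items()}
    ).sort_index()
    p = p_cols.to_numpy(dtype=float)
    measured = ~np.isnan(p)
    if not measured.any(axis=1).all():
        bad = p_cols.index[~measured.any(axis=1)]
        raise ValueError(f"genes measured in no study: {list(bad[:5])}")
    n_zero = int((p[measured] == 0).sum())
    if n_zero:
        logger.warning("combine_studies: clamping %d zero p-value(s) to %g", n_zero, floor)
    clamped = np.clip(p, floor, 1.0)
    logs = np.where(measured, np.log(clamped), 0.0)
    x2 = -2.0 * logs.sum(axis=1)
    df = 2 * measured.sum(axis=1)
    combined = stats.chi2.sf(x2, df)
    out = p_cols.copy()
    out["x2"] = x2
    out["df"] = df
    out["combined_p"] = combined
    out["deg"] = combined < alpha
    return out


def call_degs(meta: pd.DataFrame, alpha: float = 0.05, adjust: str = "none") -> set:
    """Genes with combined p < alpha (strict).

    ``adjust="bh"`` applies Benjamini-Hochberg FDR control before
    thresholding; the default mirrors an unadjusted per-gene cutoff.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = meta["combined_p"]
    if adjust == "none":
        keep = p < alpha
    elif adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        keep = pd.Series(
            multipletests(p.to_numpy(), alpha=alpha, method="fdr_bh")[0],
            index=p.index,
        )
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return set(meta.index[keep])


def map_degs_to_clusters(clusters, degs: set, min_hits: int = 1) -> list:
    """Annotate complexes with DEG hits; those with >= min_hits are PD clusters.

    Returns, in the input (rank) order, a list of dicts with the complex,
    its DEG hits, and the PD flag.
    """
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    out = []
    for c in clusters:
        hits = set(c.members) & set(degs)
        out.append({"complex": c, "hits": hits, "n_hits": len(hits),
                    "is_pd": len(hits) >= min_hits})
    logger.info("map_degs_to_clusters: %d/%d clusters flagged PD (min_hits=%d)",
                sum(r["is_pd"] for r in out), len(out), min_hits)
    return out


def pd_clusters(mapped: list) -> list:
    """The complexes flagged PD, in rank order."""
    return [r["complex"] for r in mapped if r["is_pd"]]


def meta_to_tsv(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("gene").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_expression_tsv(expr_path, meta_path) -> list:
    """Load studies from a genes x samples TSV plus (sample, group, study) metadata."""
    matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"sample", "group", "study"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    studies = []
    for sid, block in meta.groupby("study", sort=True):
        cols = [s for s in block["sample"] if s in matrix.columns]
        groups = pd.Series(block.set_index("sample")["group"])
        studies.append(ExpressionStudy(matrix[cols], groups, str(sid)))
    return studies
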