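"""Two-group differential expression with pre-filter conventions and BH correction.

The test is a Welch two-sample t on log2(normalized + 1), where "normalized"
means counts divided by the per-sample size factor.  This is a deliberately
simple replicate-aware engine; the TSV interface (see :mod:`gliakit.io`)
also accepts differential tables computed by any external engine, so a full
negative-binomial analysis can be substituted without touching the
downstream attribution machinery.

Conventions for genes failing the expression pre-filter: p-value 1, log2
fold change 0, and exclusion from the Benjamini-Hochberg correction (the BH
denominator counts only pre-filter-passing genes; failing genes carry a
missing adjusted p).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["test_two_groups", "adjust_bh", "assemble_de_table"]

#: Column order of a differential table (the TSV interchange schema).
DE_COLUMNS = [
    "log2_fc",
    "p_value",
    "adj_p",
    "prefilter_pass",
    "mean_ctrl",
    "mean_trt",
]


def test_two_groups(
    expr: pd.DataFrame,
    group_labels: pd.Series | dict,
    control: str | None = None,
    treatment: str | None = None,
    size_factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 fold change and Welch-t p-value between two groups.

    Parameters
    ----------
    expr
        Genes x samples matrix of counts or normalized expression.  If
        ``size_factors`` is given, columns are divided by it first.
    group_labels
        Sample -> group label mapping covering every column of ``expr``.
        Exactly two distinct labels are required.
    control, treatment
        Which label is the baseline.  Default: first two labels in sorted
        order, ``control`` the lexicographically smaller.
    pseudocount
        Added before the log2 transform to bound fold changes at low counts.

    Returns
    -------
    DataFrame indexed by gene with columns ``log2_fc`` (treatment minus
    control on the log2 scale), ``p_value``, ``mean_ctrl``, ``mean_trt``
    (group means of the normalized values, linear scale).
    """
    labels = pd.Series(group_labels).reindex(expr.columns)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()][:3])
        raise ValueError(f"samples without group label: {missing}")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    if control is None and treatment is None:
        control, treatment = groups
    elif control is None:
        control = next(g for g in groups if g != treatment)
    elif treatment is None:
        treatment = next(g for g in groups if g != control)
    for name, grp in (("control", control), ("treatment", treatment)):
        n = int((labels == grp).sum())
        if n < 2:
            raise ValueError(f"{name} group {grp!r} has {n} samples; >=2 required")

    vals = expr.to_numpy(dtype=float)
    if size_factors is not None:
        sf = pd.Series(size_factors).reindex(expr.columns)
        if sf.isna().any() or (sf <= 0).any():
            raise ValueError("size_factors must be positive and cover all samples")
        vals = vals / sf.to_numpy()[None, :]
    logv = np.log2(vals + pseudocount)

    ctrl_mask = (labels == control).to_numpy()
    trt_mask = (labels == treatment).to_numpy()
    log_ctrl, log_trt = logv[:, ctrl_mask], logv[:, trt_mask]
    log2_fc = log_trt.mean(axis=1) - log_ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(log_trt, log_ctrl, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups -> no evidence
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_value": p,
            "mean_ctrl": vals[:, ctrl_mask].mean(axis=1),
            "mean_trt": vals[:, trt_mask].mean(axis=1),
        },
        index=expr.index,
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("p-values must not contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assemble_de_table(stats_table: pd.DataFrame, prefilter_flags: pd.Series) -> pd.DataFrame:
    """Combine raw test statistics with pre-filter flags into a differential table.

    BH correction runs only across pre-filter-passing genes; failing genes
    get p = 1, log2 fold change 0 and adjusted p = NaN (written as an empty
    field in TSV output).
    """
    flags = prefilter_flags.reindex(stats_table.index)
    if flags.isna().any():
        raise ValueError("prefilter flags must cover every gene in the stats table")
    flags = flags.astype(bool)
    out = stats_table.copy()
    out["prefilter_pass"] = flags
    out.loc[~flags, "log2_fc"] = 0.0
    out.loc[~flags, "p_value"] = 1.0
    out["adj_p"] = np.nan
    if flags.any():
        out.loc[flags, "adj_p"] = adjust_bh(out.loc[flags, "p_value"].to_numpy())
    for col in ("mean_ctrl", "mean_trt"):
        if col not in out.columns:
            out[col] = np.nan
    return out[DE_COLUMNS]
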