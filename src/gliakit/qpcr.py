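"""qPCR Ct processing: replicate averaging, imputation, -dCt, ddCt and testing.

A plate is a long table of technical-replicate Ct measurements with
pass/fail calls, one row per (sample, assay, replicate).  Processing steps:

1. technical replicates are averaged, omitting fail calls; assays failing
   on all replicates of a sample are imputed at Ct^max + 1, one cycle past
   the worst passing Ct that assay achieved in any sample (below-detection
   abundance), and flagged;
2. -dCt = -(Ct_target - mean Ct of the housekeeping assays) per sample;
3. splicing ddCt = (-dCt of the inclusion assay) - (-dCt of the skipping
   assay); lower values indicate more exon skipping;
4. per-cell-type two-sample t between conditions (imputed values included),
   BH-corrected across events within each cell type.

Amplification efficiency is assumed to be exactly 2, so a ddCt difference
of 1 corresponds to a two-fold abundance ratio.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from gliakit.differential_expression import adjust_bh

__all__ = ["summarize_ct", "delta_ct", "ddct_splicing", "test_ddct", "ddct_treatment"]

PLATE_COLUMNS = [
    "sample_id",
    "cell_type",
    "condition",
    "assay_id",
    "assay_role",
    "replicate_idx",
    "ct",
    "pass",
]


def summarize_ct(plate: pd.DataFrame) -> pd.DataFrame:
    """Mean passing Ct per (sample, assay), with Ct^max+1 imputation.

    Returns one row per (sample, assay) with columns ``ct`` and ``imputed``
    plus the sample/assay metadata.  Raises if an assay has no passing
    replicate in any sample (no Ct^max exists to impute from).
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    ok = plate["pass"].astype(bool)
    if (plate.loc[ok, "ct"] <= 0).any() or not np.isfinite(plate.loc[ok, "ct"]).all():
        raise ValueError("passing Ct values must be finite and positive")
    ct_max = plate[ok].groupby("assay_id")["ct"].max()

    meta_cols = ["sample_id", "cell_type", "condition", "assay_id", "assay_role"]
    rows = []
    for keys, grp in plate.groupby(meta_cols, sort=False):
        rec = dict(zip(meta_cols, keys))
        passing = grp.loc[grp["pass"].astype(bool), "ct"]
        if len(passing):
            rec["ct"] = float(passing.mean())
            rec["imputed"] = False
        else:
            assay = rec["assay_id"]
            if assay not in ct_max.index:
                raise ValueError(
                    f"assay {assay!r} failed on all replicates of every sample; "
                    "no Ct^max available for imputation"
                )
            rec["ct"] = float(ct_max[assay]) + 1.0
            rec["imputed"] = True
        rows.append(rec)
    return pd.DataFrame(rows)


def delta_ct(
    ct_table: pd.DataFrame, housekeeping_assays: list[str] | set[str]
) -> pd.DataFrame:
    """-dCt per (sample, target assay): -(Ct_target - mean housekeeping Ct).

    ``housekeeping_assays`` is configurable; samples lacking any of the
    housekeeping assays are excluded with a warning.  The ``imputed`` flag
    propagates from either the target or a housekeeping measurement.
    """
    hk = set(housekeeping_assays)
    if not hk:
        raise ValueError("at least one housekeeping assay required")
    rows = []
    for sample, grp in ct_table.groupby("sample_id", sort=False):
        hk_rows = grp[grp["assay_id"].isin(hk)]
        if set(hk_rows["assay_id"]) != hk:
            warnings.warn(
                f"sample {sample!r}: missing housekeeping assay(s) "
                f"{sorted(hk - set(hk_rows['assay_id']))}; sample excluded",
                stacklevel=2,
            )
            continue
        hk_mean = float(hk_rows["ct"].mean())
        hk_imputed = bool(hk_rows["imputed"].any())
        for _, row in grp[~grp["assay_id"].isin(hk)].iterrows():
            rows.append(
                {
                    "sample_id": sample,
                    "cell_type": row["cell_type"],
                    "condition": row["condition"],
                    "assay_id": row["assay_id"],
                    "assay_role": row["assay_role"],
                    "minus_delta_ct": -(float(row["ct"]) - hk_mean),
                    "imputed": bool(row["imputed"]) or hk_imputed,
                }
            )
    return pd.DataFrame(rows)


def ddct_splicing(
    minus_dct: pd.DataFrame,
    inclusion_role: str = "inclusion",
    skipping_role: str = "skipping",
    event_of_assay: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Per-sample splicing ddCt: (-dCt of inclusion) - (-dCt of skipping).

    Lower ddCt means more skipping.  Assays pair within a sample by event:
    ``event_of_assay`` maps assay_id -> event_id; when omitted, each sample
    is expected to carry exactly one inclusion and one skipping assay.
    Samples with either isoform assay missing are excluded with a warning;
    the ``imputed`` flag propagates from either assay.
    """
    if event_of_assay is not None:
        events = pd.Series(event_of_assay)
        minus_dct = minus_dct.copy()
        minus_dct["event_id"] = minus_dct["assay_id"].map(events)
        group_cols = ["sample_id", "event_id"]
    else:
        minus_dct = minus_dct.copy()
        minus_dct["event_id"] = "event"
        group_cols = ["sample_id", "event_id"]
    rows = []
    for (sample, event), grp in minus_dct.groupby(group_cols, sort=False):
        inc = grp[grp["assay_role"] == inclusion_role]
        skp = grp[grp["assay_role"] == skipping_role]
        if len(inc) != 1 or len(skp) != 1:
            warnings.warn(
                f"sample {sample!r}, event {event!r}: needs exactly one "
                "inclusion and one skipping assay; excluded",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "sample_id": sample,
                "event_id": event,
                "cell_type": grp["cell_type"].iloc[0],
                "condition": grp["condition"].iloc[0],
                "ddct": float(inc["minus_delta_ct"].iloc[0])
                - float(skp["minus_delta_ct"].iloc[0]),
                "imputed": bool(inc["imputed"].iloc[0]) or bool(skp["imputed"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)


def test_ddct(
    ddct: pd.DataFrame,
    control: str | None = None,
    treatment: str | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-cell-type t-test of ddCt between conditions, BH across events.

    The default is the classical equal-variance Student's t (Welch available
    via ``equal_var=False``); imputed values are included.  Cell types with
    fewer than two samples in a condition for an event are skipped with a
    warning.  BH correction is applied across events within each cell type.
    """
    conds = sorted(ddct["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"exactly two conditions required, got {conds}")
    if control is None:
        control = conds[0]
    if treatment is None:
        treatment = next(c for c in conds if c != control)
    rows = []
    for (ct_label, event), grp in ddct.groupby(["cell_type", "event_id"], sort=False):
        a = grp.loc[grp["condition"] == control, "ddct"].to_numpy(dtype=float)
        b = grp.loc[grp["condition"] == treatment, "ddct"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"cell type {ct_label!r}, event {event!r}: fewer than two "
                "samples per condition; skipped",
                stacklevel=2,
            )
            continue
        if np.var(a) == 0 and np.var(b) == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = float(stats.ttest_ind(b, a, equal_var=equal_var).pvalue)
        rows.append(
            {
                "cell_type": ct_label,
                "event_id": event,
                "mean_ctrl": float(a.mean()),
                "mean_trt": float(b.mean()),
                "delta_ddct": float(b.mean() - a.mean()),
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["cell_type", "event_id", "mean_ctrl", "mean_trt", "delta_ddct", "p"],
    )
    out["adj_p"] = np.nan
    for ct_label in out["cell_type"].unique():
        m = out["cell_type"] == ct_label
        out.loc[m, "adj_p"] = adjust_bh(out.loc[m, "p"].to_numpy())
    return out


def ddct_treatment(
    minus_dct: pd.DataFrame,
    control: str | None = None,
    treatment: str | None = None,
) -> pd.DataFrame:
    """Gene-level treatment ddCt: mean -dCt(treated) minus mean -dCt(control).

    Computed per (assay, cell type); positive values indicate induction by
    treatment (a value of 1 is a two-fold induction under perfect
    amplification efficiency).  Groupings missing a condition are excluded
    with a warning.
    """
    conds = sorted(minus_dct["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"exactly two conditions required, got {conds}")
    if control is None:
        control = conds[0]
    if treatment is None:
        treatment = next(c for c in conds if c != control)
    rows = []
    for (assay, ct_label), grp in minus_dct.groupby(["assay_id", "cell_type"], sort=False):
        a = grp.loc[grp["condition"] == control, "minus_delta_ct"]
        b = grp.loc[grp["condition"] == treatment, "minus_delta_ct"]
        if a.empty or b.empty:
            warnings.warn(
                f"assay {assay!r}, cell type {ct_label!r}: a condition is "
                "missing; excluded",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "assay_id": assay,
                "cell_type": ct_label,
                "ddct": float(b.mean()) - float(a.mean()),
                "imputed": bool(grp["imputed"].any()),
            }
        )
    return pd.DataFrame(rows, columns=["assay_id", "cell_type", "ddct", "imputed"])
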