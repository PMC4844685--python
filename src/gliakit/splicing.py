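"""Splice-variant counting, variant frequency (vFreq) and differential usage.

Splicing events are groups of (usually two) splice variants; a classical
cassette exon is one event whose inclusion and skipping isoforms are its
variants.  Each variant carries a 5' and a 3' count per sample.  vFreq is a
variant's share of its event's summarized counts in a sample, from 0 (fully
skipped) to 1 (fully included).

The testable-variant cascade, in order: (1) drop variants lacking the
minimum counts; (2) drop events left with a single variant — effectively
constitutive; (3) drop retained-intron events; (4) within each surviving
event, exclude the first variant (input order, generally a skipping
variant) from testing and from the multiple-testing family.

Differential usage is tested per testable variant by Welch t on
logit(vFreq) with vFreq clamped to [0.01, 0.99]; BH correction runs across
the testable variants.  The results TSV format also accepts externally
computed per-variant p-values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit

from gliakit.differential_expression import adjust_bh

__all__ = [
    "summarize_variant_counts",
    "compute_variant_freq",
    "filter_splicing_variants",
    "test_differential_usage",
]

EVENT_COLUMNS = [
    "event_id",
    "variant_id",
    "role",
    "retained_intron",
    "same_features",
    "sample_id",
    "count5p",
    "count3p",
]


def _check_event_table(events: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    for col in ("count5p", "count3p"):
        if (events[col] < 0).any():
            raise ValueError(f"{col} must be nonnegative")


def summarize_variant_counts(events: pd.DataFrame) -> pd.DataFrame:
    """Single count per variant and sample from the 5' and 3' counts.

    5' and 3' counts measuring distinct features are added; when they
    measure the same features (``same_features``) the single unique value is
    taken, and unequal counts are a contract violation.

    Returns a variant x sample count matrix whose row index is
    ``(event_id, variant_id)`` in input order, with variant metadata
    (``role``, ``retained_intron``) in ``.attrs["variant_info"]``.
    """
    _check_event_table(events)
    same = events["same_features"].astype(bool)
    bad = same & (events["count5p"] != events["count3p"])
    if bad.any():
        row = events[bad].iloc[0]
        raise ValueError(
            "same_features=True but 5' and 3' counts differ for variant "
            f"{row['variant_id']!r} in sample {row['sample_id']!r} "
            f"({row['count5p']} vs {row['count3p']})"
        )
    counts = np.where(same, events["count5p"], events["count5p"] + events["count3p"])
    long = events[["event_id", "variant_id", "sample_id"]].copy()
    long["count"] = counts
    # preserve input order of events and variants (the first-variant rule
    # depends on it)
    variant_order = list(
        dict.fromkeys(zip(events["event_id"], events["variant_id"]))
    )
    wide = long.pivot_table(
        index=["event_id", "variant_id"],
        columns="sample_id",
        values="count",
        aggfunc="first",
    )
    sample_order = list(dict.fromkeys(events["sample_id"]))
    wide = wide.reindex(pd.MultiIndex.from_tuples(variant_order), fill_value=0)
    wide = wide[sample_order]
    wide.index.names = ["event_id", "variant_id"]
    info = (
        events.drop_duplicates(["event_id", "variant_id"])
        .set_index(["event_id", "variant_id"])[["role", "retained_intron"]]
        .reindex(wide.index)
    )
    wide.attrs["variant_info"] = info
    return wide


def compute_variant_freq(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-variant, per-sample vFreq: variant count over event total.

    Undefined (NaN) wherever the event total is zero; within an event and
    sample the defined values sum to 1.
    """
    totals = counts.groupby(level="event_id", sort=False).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        vfreq = counts.to_numpy(dtype=float) / totals.to_numpy(dtype=float)
    out = pd.DataFrame(vfreq, index=counts.index, columns=counts.columns)
    out.attrs.update(counts.attrs)
    return out


def filter_splicing_variants(
    counts: pd.DataFrame,
    min_count: int = 5,
    min_samples: int = 3,
    variant_info: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the testability cascade; return counts with a ``testable`` marker.

    Steps, in order: (1) drop variants with fewer than ``min_samples``
    samples at >= ``min_count`` counts (any condition); (2) drop events with
    at most one remaining variant; (3) drop retained-intron events; (4) mark
    each event's first remaining variant (input order) as not testable.

    ``variant_info`` defaults to the metadata attached by
    :func:`summarize_variant_counts`.  The cascade is idempotent.

    Returns the surviving variant count matrix with a boolean ``testable``
    column appended via ``.attrs["testable"]`` (a Series on the surviving
    index).
    """
    if variant_info is None:
        variant_info = counts.attrs.get("variant_info")
    if variant_info is None:
        raise ValueError("variant_info required (role, retained_intron per variant)")
    # (1) count filter
    enough = (counts.to_numpy() >= min_count).sum(axis=1) >= min_samples
    kept = counts[enough]
    # (2) events reduced to a single variant are effectively constitutive
    sizes = kept.groupby(level="event_id", sort=False).size()
    multi = sizes[sizes >= 2].index
    kept = kept[kept.index.get_level_values("event_id").isin(multi)]
    # (3) retained-intron events
    info = variant_info.reindex(kept.index)
    ri_events = set(
        info.index.get_level_values("event_id")[info["retained_intron"].astype(bool)]
    )
    kept = kept[~kept.index.get_level_values("event_id").isin(ri_events)]
    # (4) first remaining variant of each event is excluded from testing
    first = kept.groupby(level="event_id", sort=False).cumcount() == 0
    testable = pd.Series(~first.to_numpy(), index=kept.index, name="testable")
    out = kept.copy()
    out.attrs["variant_info"] = variant_info.reindex(kept.index)
    out.attrs["testable"] = testable
    return out


def test_differential_usage(
    vfreq: pd.DataFrame,
    condition_labels: pd.Series | dict,
    testable: pd.Series | None = None,
    control: str | None = None,
    treatment: str | None = None,
    clamp: tuple[float, float] = (0.01, 0.99),
) -> pd.DataFrame:
    """Differential variant usage between two conditions.

    For each testable variant: samples with undefined vFreq are dropped;
    vFreq is clamped to ``clamp`` and logit-transformed; a Welch two-sample
    t compares conditions.  BH correction runs across all tested variants.

    Returns a DataFrame indexed by (event_id, variant_id) with columns
    ``mean_vfreq_ctrl, mean_vfreq_trt, delta, p, adj_p`` where ``delta`` is
    the treatment-minus-control difference of mean vFreq.
    """
    if testable is None:
        testable = vfreq.attrs.get("testable")
    if testable is None:
        testable = pd.Series(True, index=vfreq.index)
    labels = pd.Series(condition_labels).reindex(vfreq.columns)
    if labels.isna().any():
        raise ValueError("condition_labels must cover every sample")
    conds = sorted(labels.unique())
    if len(conds) != 2:
        raise ValueError(f"exactly two conditions required, got {conds}")
    if control is None:
        control = conds[0]
    if treatment is None:
        treatment = next(c for c in conds if c != control)
    ctrl_mask = (labels == control).to_numpy()
    trt_mask = (labels == treatment).to_numpy()

    lo, hi = clamp
    rows = []
    for key in vfreq.index[testable.reindex(vfreq.index).fillna(False)]:
        v = vfreq.loc[key].to_numpy(dtype=float)
        vc, vt = v[ctrl_mask], v[trt_mask]
        vc, vt = vc[~np.isnan(vc)], vt[~np.isnan(vt)]
        if len(vc) < 2 or len(vt) < 2:
            warnings.warn(
                f"variant {key}: fewer than two defined vFreq values in a "
                "condition; skipped",
                stacklevel=2,
            )
            continue
        lc = logit(np.clip(vc, lo, hi))
        lt = logit(np.clip(vt, lo, hi))
        if np.var(lc) == 0 and np.var(lt) == 0:
            # degenerate t: constant groups give p=1 when equal, p=0 when not
            p = 1.0 if lc.mean() == lt.mean() else 0.0
        else:
            p = float(stats.ttest_ind(lt, lc, equal_var=False).pvalue)
        rows.append(
            {
                "event_id": key[0],
                "variant_id": key[1],
                "mean_vfreq_ctrl": float(vc.mean()),
                "mean_vfreq_trt": float(vt.mean()),
                "delta": float(vt.mean() - vc.mean()),
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["event_id", "variant_id", "mean_vfreq_ctrl",
                       "mean_vfreq_trt", "delta", "p"]
    )
    if len(out):
        out = out.set_index(["event_id", "variant_id"])
        out["adj_p"] = adjust_bh(out["p"].to_numpy())
    else:
        out = out.set_index(pd.MultiIndex.from_tuples([], names=["event_id", "variant_id"]))
        out["adj_p"] = []
    return out
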