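"""Attribution of bulk-tissue expression changes to CNS cell types.

Core procedure: build per-gene mean nRPKM profiles across the three sorted
cell types (microglia, astrocytes, neurons), place each gene on the
two-dimensional simplex ("triangle plot") whose corners represent exclusive
expression in one type, select highly type-specific marker genes, attribute
each bulk differential gene to the cell type dominating its reference
expression, and classify whether the bulk change reflects within-cell-type
regulation, altered cellular composition, or both.

Simplex geometry: a profile vector is normalized to composition fractions
(f1, f2, f3) summing to 1 (the plane x+y+z=1), then projected to the plane
by the matrix ``[[-1, 1, 0], [0, 0, sqrt(3)]]``.  The pure unit vectors map
to the corners (-1, 0), (1, 0) and (0, sqrt(3)) of an equilateral triangle
of side 2, in the recorded profile column order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PROJECTION_MATRIX",
    "build_reference_profiles",
    "project_to_simplex",
    "select_markers",
    "attribute_bulk_changes",
    "classify_change_mode",
    "marker_shift_diagnostic",
    "heatmap_zscore_matrix",
    "select_variable_genes",
    "collapse_probes_by_iqr",
    "prepare_fourway",
]

#: Maps composition fractions (f1, f2, f3) on the plane x+y+z=1 to the
#: triangle with corners (-1,0), (1,0), (0, sqrt(3)), row by row.
PROJECTION_MATRIX = np.array([[-1.0, 1.0, 0.0], [0.0, 0.0, np.sqrt(3.0)]])


def build_reference_profiles(expr: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean normalized expression in each of exactly three cell types.

    ``sample_sheet`` needs columns ``sample_id`` and ``cell_type``; samples
    with cell type ``bulk`` are ignored.  The output column order follows
    first appearance in the sample sheet and is the corner order of the
    simplex projection.
    """
    sheet = sample_sheet[sample_sheet["cell_type"] != "bulk"]
    cell_types = list(dict.fromkeys(sheet["cell_type"]))
    if len(cell_types) != 3:
        raise ValueError(
            f"exactly three cell types required, found {cell_types or 'none'}"
        )
    cols = {}
    for ct in cell_types:
        samples = sheet.loc[sheet["cell_type"] == ct, "sample_id"].tolist()
        missing = [s for s in samples if s not in expr.columns]
        if missing:
            raise ValueError(f"cell type {ct!r}: samples missing from matrix: {missing}")
        if not samples:
            raise ValueError(f"cell type {ct!r} has no samples")
        cols[ct] = expr[samples].mean(axis=1)
    return pd.DataFrame(cols, index=expr.index)[cell_types]


def project_to_simplex(profile: pd.DataFrame) -> pd.DataFrame:
    """Composition fractions and triangle-plot coordinates per gene.

    Genes whose profile sums to zero cannot be placed on the simplex and are
    excluded; their ids are recorded in ``.attrs["excluded"]``.

    Returns a DataFrame with columns ``f1, f2, f3, x, y``.
    """
    if profile.shape[1] != 3:
        raise ValueError("profile must have exactly three cell-type columns")
    vals = profile.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("profile values must be nonnegative")
    totals = vals.sum(axis=1)
    keep = totals > 0
    fracs = vals[keep] / totals[keep, None]
    xy = fracs @ PROJECTION_MATRIX.T
    out = pd.DataFrame(
        np.column_stack([fracs, xy]),
        index=profile.index[keep],
        columns=["f1", "f2", "f3", "x", "y"],
    )
    out.attrs["excluded"] = profile.index[~keep].tolist()
    out.attrs["cell_type_order"] = list(profile.columns)
    return out


def select_markers(
    profile: pd.DataFrame, fold: float = 20.0, pseudocount: float = 0.1
) -> dict[str, list]:
    """Marker genes per cell type: >= ``fold`` enrichment over both other types.

    A gene is a marker of type *c* iff
    ``(expr_c + pseudocount) / (expr_other + pseudocount) >= fold`` for each
    of the other two types.  With ``fold > 1`` the three sets are disjoint.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    vals = profile.to_numpy(dtype=float) + pseudocount
    markers: dict[str, list] = {}
    for i, ct in enumerate(profile.columns):
        others = [j for j in range(profile.shape[1]) if j != i]
        ok = np.ones(len(profile), dtype=bool)
        for j in others:
            ok &= vals[:, i] / vals[:, j] >= fold
        markers[ct] = profile.index[ok].tolist()
    return markers


def attribute_bulk_changes(
    bulk_de: pd.DataFrame,
    profile: pd.DataFrame,
    fc_cut: float = 2.0,
    p_cut: float = 0.05,
    share_cut: float = 0.5,
) -> pd.DataFrame:
    """Attribute each significant bulk gene to the cell type dominating its profile.

    Significance: ``|log2_fc| >= log2(fc_cut)`` and ``adj_p <= p_cut`` in the
    bulk differential table.  Shares are the gene's simplex composition
    fractions; the gene is assigned to the max-share type when that share
    reaches ``share_cut``, to ``"mixed"`` otherwise.  Because shares are
    proportional to absolute reference expression, a gene induced in two
    types is assigned to the one with the higher absolute expression level.
    Genes absent from (or zero in) the reference profile are ``"unassigned"``.

    Returns a DataFrame indexed by significant gene with columns
    ``log2_fc_bulk, adj_p_bulk, share_<type1..3>, assigned``.
    """
    sig = bulk_de[
        (bulk_de["log2_fc"].abs() >= np.log2(fc_cut)) & (bulk_de["adj_p"] <= p_cut)
    ]
    coords = project_to_simplex(profile)
    cell_types = list(profile.columns)
    rows = []
    for gene in sig.index:
        rec = {
            "log2_fc_bulk": sig.at[gene, "log2_fc"],
            "adj_p_bulk": sig.at[gene, "adj_p"],
        }
        if gene in coords.index:
            shares = coords.loc[gene, ["f1", "f2", "f3"]].to_numpy(dtype=float)
            top = int(np.argmax(shares))
            rec.update({f"share_{ct}": s for ct, s in zip(cell_types, shares)})
            rec["assigned"] = cell_types[top] if shares[top] >= share_cut else "mixed"
        else:
            rec.update({f"share_{ct}": np.nan for ct in cell_types})
            rec["assigned"] = "unassigned"
        rows.append(rec)
    columns = ["log2_fc_bulk", "adj_p_bulk"] + [
        f"share_{ct}" for ct in cell_types
    ] + ["assigned"]
    out = pd.DataFrame(rows, index=sig.index, columns=columns)
    out.attrs["cell_type_order"] = cell_types
    return out


def classify_change_mode(
    calls: pd.DataFrame,
    sorted_de: dict[str, pd.DataFrame],
    composition_changed: dict[str, bool] | None = None,
    fc_cut: float = 2.0,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Label each attributed bulk change as regulation, composition, both or unassigned.

    For a gene assigned to cell type *c* with sorted-cell differential table
    ``sorted_de[c]``:

    - **regulation** — the sorted profile shows a significant same-direction
      change and *c* has no composition prior;
    - **both** — significant same-direction sorted change and *c*'s abundance
      is flagged as differing between conditions (``composition_changed``,
      supplied by the caller or by synthetic ground truth);
    - **composition** — no significant sorted change, but *c*'s abundance is
      flagged as changed (the bulk change is explained by cell content);
    - **unassigned** — anything else, including mixed/unassigned attribution
      and a missing sorted table (warned).
    """
    composition_changed = composition_changed or {}
    modes = []
    for gene in calls.index:
        assigned = calls.at[gene, "assigned"]
        if assigned in ("mixed", "unassigned"):
            modes.append("unassigned")
            continue
        if assigned not in sorted_de:
            warnings.warn(
                f"no sorted-cell differential table for {assigned!r}; "
                f"gene {gene} left unassigned",
                stacklevel=2,
            )
            modes.append("unassigned")
            continue
        table = sorted_de[assigned]
        comp = bool(composition_changed.get(assigned, False))
        if gene not in table.index:
            modes.append("composition" if comp else "unassigned")
            continue
        lfc = table.at[gene, "log2_fc"]
        adj = table.at[gene, "adj_p"]
        bulk_lfc = calls.at[gene, "log2_fc_bulk"]
        sig_same = (
            not pd.isna(adj)
            and adj <= p_cut
            and abs(lfc) >= np.log2(fc_cut)
            and np.sign(lfc) == np.sign(bulk_lfc)
        )
        if sig_same:
            modes.append("both" if comp else "regulation")
        elif comp:
            modes.append("composition")
        else:
            modes.append("unassigned")
    out = calls.copy()
    out["change_mode"] = modes
    return out


def marker_shift_diagnostic(
    markers: dict[str, list], bulk_de: pd.DataFrame, min_markers: int = 5
) -> pd.DataFrame:
    """Fold-change distribution shift of each marker set against the background.

    For each cell type, compares the bulk log2 fold changes of its marker
    genes with those of all non-marker genes: a rightward marker shift is
    consistent with higher content of that cell type in the affected tissue,
    a leftward shift with depletion.  Location shift is summarized by group
    medians and tested two-sided by Wilcoxon rank-sum.

    Returns a DataFrame indexed by cell type with columns
    ``n_markers, median_marker_lfc, median_background_lfc, shift, p_value``.
    """
    all_markers = {g for genes in markers.values() for g in genes}
    rows = {}
    for ct, genes in markers.items():
        present = [g for g in genes if g in bulk_de.index]
        if not present:
            warnings.warn(f"marker set for {ct!r} is empty; skipped", stacklevel=2)
            continue
        if len(present) < min_markers:
            warnings.warn(
                f"marker set for {ct!r} has only {len(present)} genes", stacklevel=2
            )
        marker_lfc = bulk_de.loc[present, "log2_fc"].to_numpy()
        bg_idx = bulk_de.index.difference(all_markers)
        bg_lfc = bulk_de.loc[bg_idx, "log2_fc"].to_numpy()
        res = stats.ranksums(marker_lfc, bg_lfc)
        rows[ct] = {
            "n_markers": len(present),
            "median_marker_lfc": float(np.median(marker_lfc)),
            "median_background_lfc": float(np.median(bg_lfc)),
            "shift": float(np.median(marker_lfc) - np.median(bg_lfc)),
            "p_value": float(res.pvalue),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def heatmap_zscore_matrix(
    expr: pd.DataFrame,
    dataset_labels: pd.Series | dict | None = None,
    floor: float = -4.0,
    cap: float = 4.0,
) -> pd.DataFrame:
    """log2 -> floor -> per-dataset gene-wise Z -> cap, for heat-map display.

    Each entry is log2-transformed; log2 values below ``floor`` (including
    -inf from zeros) are set to ``floor``.  Z-scores are computed per gene
    separately within each dataset label (population standard deviation;
    zero-variance rows give Z = 0), and Z-scores above ``cap`` are set to
    ``cap``.
    """
    if floor >= cap:
        raise ValueError("floor must be < cap")
    if dataset_labels is None:
        labels = pd.Series("all", index=expr.columns)
    else:
        labels = pd.Series(dataset_labels).reindex(expr.columns)
        if labels.isna().any():
            raise ValueError("dataset_labels must cover every sample")
    with np.errstate(divide="ignore"):
        logv = np.log2(expr.to_numpy(dtype=float))
    logv = np.where(logv < floor, floor, logv)
    z = np.empty_like(logv)
    cols = np.asarray(labels)
    for ds in pd.unique(cols):
        m = cols == ds
        block = logv[:, m]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=0, keepdims=True)
        zb = np.where(sd > 0, (block - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        z[:, m] = zb
    z = np.where(z > cap, cap, z)
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def select_variable_genes(transformed_expr: pd.DataFrame, fraction: float = 0.025) -> list:
    """Top ``ceil(fraction * n_genes)`` genes by per-gene standard deviation.

    Sample metadata is never consulted.  Ties at the cutoff break by
    lexicographic gene id, making the selection deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = int(np.ceil(fraction * len(transformed_expr)))
    sd = transformed_expr.std(axis=1, ddof=0)
    order = sorted(transformed_expr.index, key=lambda g: (-sd[g], str(g)))
    return order[:n]


def collapse_probes_by_iqr(
    probe_matrix: pd.DataFrame, probe_to_gene: pd.Series | dict
) -> pd.DataFrame:
    """Keep, per gene, the probe row with the largest interquartile range.

    IQR = Q3 - Q1 with linear-interpolation quantiles, computed across all
    samples without regard to metadata.  Ties break by lexicographically
    smallest probe id; unmapped probes are dropped, genes with no probes are
    absent from the output.
    """
    mapping = pd.Series(probe_to_gene)
    mapping = mapping.reindex(probe_matrix.index).dropna()
    vals = probe_matrix.loc[mapping.index]
    q1 = vals.quantile(0.25, axis=1, interpolation="linear")
    q3 = vals.quantile(0.75, axis=1, interpolation="linear")
    iqr = q3 - q1
    best: dict = {}
    for probe in sorted(mapping.index, key=str):
        gene = mapping[probe]
        if gene not in best or iqr[probe] > iqr[best[gene]]:
            best[gene] = probe
    genes = sorted(best, key=str)
    out = probe_matrix.loc[[best[g] for g in genes]].copy()
    out.index = pd.Index(genes, name=probe_matrix.index.name or "gene_id")
    return out


def prepare_fourway(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    expr_threshold: float = 1.0,
    fc_cut: float = 2.0,
    p_cut: float = 0.05,
    name_a: str = "a",
    name_b: str = "b",
) -> pd.DataFrame:
    """Paired fold changes for a four-way comparison of two differential tables.

    A gene whose mean normalized expression is below ``expr_threshold`` in
    both conditions of one comparison is plotted as fold change 1 (log2 fc 0)
    for that comparison.  Each gene meeting ``fc_cut``/``p_cut`` in one or
    both comparisons (after thresholding) is categorized ``<name_a>-only``,
    ``<name_b>-only`` or ``both``; all other genes get an empty category.
    """
    common = de_a.index.intersection(de_b.index)
    out = pd.DataFrame(index=common)
    for name, de in ((name_a, de_a), (name_b, de_b)):
        lfc = de.loc[common, "log2_fc"].astype(float).copy()
        low = (de.loc[common, "mean_ctrl"] < expr_threshold) & (
            de.loc[common, "mean_trt"] < expr_threshold
        )
        lfc[low] = 0.0
        sig = (lfc.abs() >= np.log2(fc_cut)) & (de.loc[common, "adj_p"] <= p_cut)
        sig &= ~low
        out[f"log2_fc_{name}"] = lfc
        out[f"sig_{name}"] = sig.fillna(False)
    cat = np.select(
        [
            out[f"sig_{name_a}"] & out[f"sig_{name_b}"],
            out[f"sig_{name_a}"],
            out[f"sig_{name_b}"],
        ],
        ["both", f"{name_a}-only", f"{name_b}-only"],
        default="",
    )
    out["category"] = cat
    return out
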