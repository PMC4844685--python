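"""TSV readers/writers and GTF gene-length derivation.

All on-disk formats are UTF-8 TSV with header rows; undefined numeric
values are written as ``NA``; numeric output keeps full precision (round
trips are stable).  GTF coordinates are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from gliakit.normalization import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_lengths",
    "write_gene_lengths",
    "load_count_matrix",
    "compute_gene_lengths",
    "read_de_table",
    "write_de_table",
    "read_event_table",
    "write_event_table",
    "read_plate",
    "write_plate",
    "write_markers",
    "write_attribution",
    "write_simplex",
]

VALID_CELL_TYPES = {"microglia", "astrocyte", "neuron", "bulk"}
_FLOAT_FMT = "%.10g"


def _float_format(x: float) -> str:
    return _FLOAT_FMT % x


def read_counts(path: str | Path) -> pd.DataFrame:
    """Count matrix TSV: first column ``gene_id``, one integer column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        line = int(dup.index[0]) + 2  # header is line 1
        raise ValueError(f"{path}: duplicate gene id {dup.iloc[0]!r} at line {line}")
    df = df.set_index("gene_id")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            frac = vals.astype(float) % 1 != 0
            if frac.any():
                line = int(np.nonzero(frac.to_numpy())[0][0]) + 2
                raise ValueError(
                    f"{path}: non-integer count in column {col!r} at line {line}"
                )
            df[col] = vals.astype(np.int64)
        if (df[col] < 0).any():
            line = int(np.nonzero((df[col] < 0).to_numpy())[0][0]) + 2
            raise ValueError(f"{path}: negative count in column {col!r} at line {line}")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, condition, cell_type, total_uniq_reads."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "condition", "cell_type", "total_uniq_reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        line = int(dup.index[0]) + 2
        raise ValueError(f"{path}: duplicate sample id {dup.iloc[0]!r} at line {line}")
    bad = ~df["cell_type"].isin(VALID_CELL_TYPES)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
        raise ValueError(
            f"{path}: unknown cell_type {df.loc[bad, 'cell_type'].iloc[0]!r} "
            f"at line {line} (expected one of {sorted(VALID_CELL_TYPES)})"
        )
    df["total_uniq_reads"] = df["total_uniq_reads"].astype(float)
    if (df["total_uniq_reads"] <= 0).any():
        raise ValueError(f"{path}: total_uniq_reads must be > 0")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Gene length TSV: gene_id <TAB> length_bp."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "length_bp"):
        if col not in df.columns:
            raise ValueError(f"{path}: gene length table missing column {col!r}")
    if (df["length_bp"] <= 0).any():
        raise ValueError(f"{path}: gene lengths must be > 0")
    return df.set_index("gene_id")["length_bp"]


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length_bp").to_csv(path, sep="\t", index_label="gene_id")


def load_count_matrix(
    counts_path: str | Path,
    sample_sheet_path: str | Path,
    gene_lengths_path: str | Path,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Assemble a validated CountMatrix from its three TSV components."""
    counts = read_counts(counts_path)
    sheet = read_sample_sheet(sample_sheet_path)
    lengths = read_gene_lengths(gene_lengths_path)
    totals = sheet.set_index("sample_id")["total_uniq_reads"]
    return CountMatrix(counts, lengths, totals), sheet


def compute_gene_lengths(gtf_path: str | Path) -> pd.Series:
    """Union-exon gene length (bp) from a GTF file.

    Overlapping or duplicated exon intervals of a gene are merged before
    summing; strand is ignored.  Coordinates are 1-based inclusive, so an
    exon [s, e] contributes e - s + 1 bases.  Genes without exon features
    are absent from the output (warned).
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    seen_genes: set[str] = set()
    with open(gtf_path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            attrs = fields[8]
            gene = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene = part.split(None, 1)[1].strip().strip('"')
                    break
            if gene is None:
                continue
            seen_genes.add(gene)
            if fields[2] != "exon":
                continue
            start, end = int(fields[3]), int(fields[4])
            if start > end:
                raise ValueError(f"{gtf_path}: exon with start > end for gene {gene!r}")
            exons.setdefault(gene, []).append((start, end))
    no_exons = seen_genes - set(exons)
    if no_exons:
        warnings.warn(
            f"genes without exon features omitted: {sorted(no_exons)[:5]}",
            stacklevel=2,
        )
    lengths = {}
    for gene, ivals in exons.items():
        ivals.sort()
        total, cur_s, cur_e = 0, *ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
        lengths[gene] = total
    return pd.Series(lengths, name="length_bp").sort_index()


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Differential table TSV (also the input format for external DE engines)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = ["gene_id", "log2_fc", "p_value", "adj_p", "prefilter_pass"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: differential table missing columns {missing}")
    df = df.set_index("gene_id")
    df["prefilter_pass"] = df["prefilter_pass"].astype(bool)
    return df


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT, na_rep="NA")


def read_event_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "variant_id": str})
    from gliakit.splicing import EVENT_COLUMNS

    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: event table missing columns {missing}")
    return df


def write_event_table(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_plate(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "assay_id": str})
    from gliakit.qpcr import PLATE_COLUMNS

    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: plate table missing columns {missing}")
    df["pass"] = df["pass"].astype(bool)
    return df


def write_plate(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


def write_markers(markers: dict[str, list], fold: float, path: str | Path) -> None:
    rows = [
        {"cell_type": ct, "gene_id": g, "fold_min": fold}
        for ct, genes in markers.items()
        for g in genes
    ]
    pd.DataFrame(rows, columns=["cell_type", "gene_id", "fold_min"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_attribution(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT, na_rep="NA")


def write_simplex(coords: pd.DataFrame, path: str | Path) -> None:
    coords.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)
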