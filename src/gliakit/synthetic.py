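"""Negative-binomial mixture simulator for sorted-cell and bulk CNS RNA-seq.

Emulates the design of a sorted-cell neuroinflammation study: three cell
types (microglia, astrocytes, neurons) FACS-sorted from n=5 animals per
condition, plus bulk cortex samples modeled as proportion-weighted mixtures
of the cell-type expression profiles.  Condition effects act through two
separable channels:

- **composition**: the bulk mixing proportions differ between conditions
  (the default scenario doubles the microglial fraction 0.10 -> 0.20 at the
  expense of neurons, mimicking microgliosis with neuronal loss);
- **regulation**: a chosen gene set changes fold within one cell type
  (the alternative scenario applies a 4-fold microglial induction at fixed
  proportions).

Counts are negative binomial with Var = mu + phi * mu^2.  The simulator
also produces splice-event tables (binomial read splits with a logit shift
on inclusion frequency under treatment) and qPCR plates
(Ct = a - log2(abundance) + noise, with failure calls past a detection
threshold), each with ground truth, so every pipeline stage is testable
end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from gliakit.normalization import CountMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "generate_reference_truth",
    "generate_sorted_counts",
    "generate_bulk_counts",
    "generate_splicing_counts",
    "generate_qpcr_plate",
    "simulate_study",
    "composition_config",
    "regulation_config",
]

CELL_TYPES = ("microglia", "astrocyte", "neuron")


@dataclass
class SimulationConfig:
    """All knobs of the simulator; the defaults are the study conditions.

    Expression profiles: non-marker genes share a log-normal base abundance
    with mild per-type jitter; marker genes draw a well-expressed target
    abundance and have the other two types floored at target/specificity
    fold.  Library sizes are log-uniform to exercise the size-factor
    machinery; totals exceed exonic sums to mimic intronic read excess.
    """

    seed: int
    n_genes: int = 2000
    cell_types: tuple[str, ...] = CELL_TYPES
    n_markers: dict = field(
        default_factory=lambda: {"microglia": 200, "astrocyte": 200, "neuron": 200}
    )
    specificity_fold: float = 1000.0  # markers effectively exclusive
    base_logmean: float = 1.5  # natural-log mean of shared base abundance
    base_logsd: float = 1.5
    type_jitter_sd: float = 0.3  # per-type log-normal jitter, non-marker genes
    marker_logmean: float = 3.0  # markers are well-expressed genes
    marker_logsd: float = 1.0
    phi: float = 0.1  # NB dispersion, Var = mu + phi mu^2
    n_reps: int = 5  # animals per condition
    lib_size_range: tuple[float, float] = (5e5, 2e6)
    intronic_factor_range: tuple[float, float] = (1.3, 1.7)
    # bulk mixing proportions per condition (order = cell_types)
    proportions: dict = field(
        default_factory=lambda: {
            "control": (0.10, 0.30, 0.60),
            "treated": (0.20, 0.30, 0.50),
        }
    )
    # regulation: number of genes induced `regulation_fold`-fold in
    # `regulation_cell_type` under treatment (0 = composition-only)
    n_regulated: int = 0
    regulation_cell_type: str = "microglia"
    regulation_fold: float = 4.0
    # splicing
    n_events: int = 100
    read_depth: int = 60
    baseline_vfreq_range: tuple[float, float] = (0.2, 0.8)
    logit_shift: float = 0.0
    # qPCR
    qpcr_intercept: float = 20.0
    qpcr_sigma: float = 0.15
    qpcr_fail_ct: float = 35.0
    qpcr_n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.phi <= 0:
            raise ValueError("dispersion phi must be > 0")
        for cond, pi in self.proportions.items():
            if abs(sum(pi) - 1.0) > 1e-9:
                raise ValueError(f"proportions for {cond!r} must sum to 1")
        if sum(self.n_markers.values()) > self.n_genes:
            raise ValueError("marker gene counts exceed n_genes")
        if self.n_regulated > self.n_markers.get(self.regulation_cell_type, 0):
            raise ValueError(
                "regulated genes are drawn from the target type's markers; "
                f"n_regulated={self.n_regulated} exceeds "
                f"n_markers[{self.regulation_cell_type!r}]"
            )


def composition_config(seed: int, **overrides) -> SimulationConfig:
    """Composition-only scenario: microglia 0.10 -> 0.20, no regulation."""
    return SimulationConfig(seed=seed, n_regulated=0, **overrides)


def regulation_config(seed: int, **overrides) -> SimulationConfig:
    """Regulation-only scenario: fixed proportions, 100 genes x4 in microglia."""
    return SimulationConfig(
        seed=seed,
        n_regulated=100,
        regulation_fold=4.0,
        regulation_cell_type="microglia",
        proportions={
            "control": (0.10, 0.30, 0.60),
            "treated": (0.10, 0.30, 0.60),
        },
        **overrides,
    )


@dataclass
class GroundTruth:
    """True per-gene cell-type abundances and effect labels."""

    theta: pd.DataFrame  # genes x cell types, true relative abundance
    marker_of: pd.Series  # gene -> cell type or ""
    regulated: pd.Series  # gene -> bool (true regulation targets)
    gene_length_bp: pd.Series
    config: SimulationConfig

    @property
    def marker_sets(self) -> dict[str, list]:
        return {
            ct: self.marker_of.index[self.marker_of == ct].tolist()
            for ct in self.config.cell_types
        }


@dataclass
class SimulatedStudy:
    """Sorted + bulk count matrices with sample sheets and ground truth."""

    sorted_counts: CountMatrix
    sorted_sheet: pd.DataFrame
    bulk_counts: CountMatrix
    bulk_sheet: pd.DataFrame
    truth: GroundTruth


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent child streams per data product so adding one product
    # never perturbs another
    return np.random.default_rng([config.seed, stream])


def generate_reference_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the true cell-type expression profile theta and effect labels."""
    rng = _rng(config, 1)
    n, types = config.n_genes, list(config.cell_types)
    genes = pd.Index([f"gene{i:05d}" for i in range(n)], name="gene_id")

    base = rng.lognormal(config.base_logmean, config.base_logsd, size=n)
    jitter = rng.lognormal(0.0, config.type_jitter_sd, size=(n, len(types)))
    theta = base[:, None] * jitter

    marker_of = pd.Series("", index=genes, name="marker_of")
    pool = rng.permutation(n)
    start = 0
    marker_idx: dict[str, np.ndarray] = {}
    for ct in types:
        k = config.n_markers.get(ct, 0)
        idx = pool[start : start + k]
        start += k
        target = rng.lognormal(config.marker_logmean, config.marker_logsd, size=k)
        c = types.index(ct)
        for j in range(len(types)):
            theta[idx, j] = target / (1.0 if j == c else config.specificity_fold)
        marker_of.iloc[idx] = ct
        marker_idx[ct] = idx

    # regulation targets are genes enriched in the target cell type, as
    # real inflammatory/disease response genes are: a fold change confined
    # to one cell type is only visible in bulk for genes that type dominates
    regulated = pd.Series(False, index=genes, name="regulated")
    if config.n_regulated:
        idx = marker_idx[config.regulation_cell_type][: config.n_regulated]
        regulated.iloc[idx] = True

    lengths = np.exp(rng.uniform(np.log(500), np.log(10000), size=n)).astype(int)
    return GroundTruth(
        theta=pd.DataFrame(theta, index=genes, columns=types),
        marker_of=marker_of,
        regulated=regulated,
        gene_length_bp=pd.Series(lengths, index=genes, name="length_bp"),
        config=config,
    )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _theta_under(
    truth: GroundTruth, cell_type: str, condition: str
) -> np.ndarray:
    cfg = truth.config
    th = truth.theta[cell_type].to_numpy(dtype=float).copy()
    if condition != "control" and cell_type == cfg.regulation_cell_type:
        th[truth.regulated.to_numpy()] *= cfg.regulation_fold
    return th


def generate_sorted_counts(truth: GroundTruth) -> tuple[CountMatrix, pd.DataFrame]:
    """Sorted-cell counts: every cell type x condition x replicate.

    Per sample, count ~ NB(mean = lib_size * theta / sum(theta), phi), with
    regulation folds applied in the treated condition's target cell type.
    Returns the combined count matrix and its sample sheet.
    """
    cfg = truth.config
    rng = _rng(cfg, 2)
    cols, sheet_rows = {}, []
    for ct in cfg.cell_types:
        for cond in cfg.proportions:
            th = _theta_under(truth, ct, cond)
            rel = th / th.sum()
            for rep in range(1, cfg.n_reps + 1):
                lib = np.exp(rng.uniform(*np.log(cfg.lib_size_range)))
                counts = _nb_sample(rng, lib * rel, cfg.phi)
                sid = f"{ct}_{cond}_{rep}"
                cols[sid] = counts
                total = counts.sum() * rng.uniform(*cfg.intronic_factor_range)
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "condition": cond,
                        "cell_type": ct,
                        "total_uniq_reads": float(total),
                    }
                )
    mat = pd.DataFrame(cols, index=truth.theta.index)
    sheet = pd.DataFrame(sheet_rows)
    cm = CountMatrix(
        counts=mat,
        gene_length_bp=truth.gene_length_bp,
        total_uniq_reads=sheet.set_index("sample_id")["total_uniq_reads"],
    )
    return cm, sheet


def generate_bulk_counts(truth: GroundTruth) -> tuple[CountMatrix, pd.DataFrame]:
    """Bulk-tissue counts as proportion-weighted mixtures of cell-type profiles.

    Bulk mean per gene is lib_size * sum_c pi_c theta_gc / normalizer; a
    gene expressed equally in all types is untouched by pure composition
    shifts, while a pure marker's bulk abundance scales with its type's
    proportion.
    """
    cfg = truth.config
    rng = _rng(cfg, 3)
    cols, sheet_rows = {}, []
    for cond, pi in cfg.proportions.items():
        mix = np.zeros(cfg.n_genes)
        for c, ct in enumerate(cfg.cell_types):
            mix += pi[c] * _theta_under(truth, ct, cond)
        rel = mix / mix.sum()
        for rep in range(1, cfg.n_reps + 1):
            lib = np.exp(rng.uniform(*np.log(cfg.lib_size_range)))
            counts = _nb_sample(rng, lib * rel, cfg.phi)
            sid = f"bulk_{cond}_{rep}"
            cols[sid] = counts
            total = counts.sum() * rng.uniform(*cfg.intronic_factor_range)
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "condition": cond,
                    "cell_type": "bulk",
                    "total_uniq_reads": float(total),
                }
            )
    mat = pd.DataFrame(cols, index=truth.theta.index)
    sheet = pd.DataFrame(sheet_rows)
    cm = CountMatrix(
        counts=mat,
        gene_length_bp=truth.gene_length_bp,
        total_uniq_reads=sheet.set_index("sample_id")["total_uniq_reads"],
    )
    return cm, sheet


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full expression simulation: truth, sorted-cell and bulk data."""
    truth = generate_reference_truth(config)
    sorted_counts, sorted_sheet = generate_sorted_counts(truth)
    bulk_counts, bulk_sheet = generate_bulk_counts(truth)
    return SimulatedStudy(sorted_counts, sorted_sheet, bulk_counts, bulk_sheet, truth)


def generate_splicing_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-variant cassette events with a treatment logit shift on inclusion.

    Per event and sample, inclusion reads ~ Binomial(depth, vfreq) and
    skipping reads are the remainder; under treatment the inclusion
    frequency is shifted by ``logit_shift`` on the logit scale.  The
    skipping variant is emitted first (the "first variant" the filter
    cascade discards); each variant's total is split into distinct 5'/3'
    feature counts.

    Returns (event table in long TSV layout, truth table with the per-event
    true inclusion vFreq under each condition).
    """
    cfg = config
    rng = _rng(cfg, 4)
    lo, hi = cfg.baseline_vfreq_range
    v0 = rng.uniform(lo, hi, size=cfg.n_events)
    logit = np.log(v0 / (1 - v0)) + cfg.logit_shift
    v1 = 1.0 / (1.0 + np.exp(-logit))

    rows, truth_rows = [], []
    samples = [
        (f"{cond}_{rep}", cond)
        for cond in ("control", "treated")
        for rep in range(1, cfg.n_reps + 1)
    ]
    for e in range(cfg.n_events):
        event = f"event{e:04d}"
        truth_rows.append(
            {"event_id": event, "vfreq_control": v0[e], "vfreq_treated": v1[e]}
        )
        for sid, cond in samples:
            v = v0[e] if cond == "control" else v1[e]
            inc = int(rng.binomial(cfg.read_depth, v))
            skp = cfg.read_depth - inc
            for variant, role, count in (
                (f"{event}.V1", "skipping", skp),
                (f"{event}.V2", "inclusion", inc),
            ):
                rows.append(
                    {
                        "event_id": event,
                        "variant_id": variant,
                        "role": role,
                        "retained_intron": False,
                        "same_features": False,
                        "sample_id": sid,
                        "count5p": count // 2,
                        "count3p": count - count // 2,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def generate_qpcr_plate(
    config: SimulationConfig, abundance: pd.DataFrame
) -> pd.DataFrame:
    """qPCR plate from true transcript abundances.

    ``abundance`` has one row per (sample, assay) with columns
    ``sample_id, cell_type, condition, assay_id, assay_role, abundance``.
    Each technical replicate measures Ct = a - log2(abundance) + N(0, sigma);
    replicates with Ct above the failure threshold (or undetectable
    abundance) are flagged fail.  Housekeeping assays should be given
    constant abundance by the caller.
    """
    cfg = config
    rng = _rng(cfg, 5)
    rows = []
    for _, rec in abundance.iterrows():
        for r in range(1, cfg.qpcr_n_replicates + 1):
            q = float(rec["abundance"])
            if q > 0:
                ct = cfg.qpcr_intercept - np.log2(q) + rng.normal(0, cfg.qpcr_sigma)
                ok = ct <= cfg.qpcr_fail_ct
            else:
                ct, ok = np.nan, False
            rows.append(
                {
                    "sample_id": rec["sample_id"],
                    "cell_type": rec["cell_type"],
                    "condition": rec["condition"],
                    "assay_id": rec["assay_id"],
                    "assay_role": rec["assay_role"],
                    "replicate_idx": r,
                    "ct": float(ct) if np.isfinite(ct) else np.nan,
                    "pass": bool(ok),
                }
            )
    return pd.DataFrame(rows)
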