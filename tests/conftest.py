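import numpy as np
import pandas as pd
import pytest

from gliakit.normalization import CountMatrix


@pytest.fixture
def small_count_matrix() -> CountMatrix:
    counts = pd.DataFrame(
        {"s1": [10, 20, 30], "s2": [20, 40, 60]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    lengths = pd.Series([1000, 2000, 1500], index=counts.index, name="length_bp")
    totals = pd.Series([1e6, 2e6], index=counts.columns)
    return CountMatrix(counts, lengths, totals)


@pytest.fixture
def reference_profile() -> pd.DataFrame:
    """Hand-built three-cell-type profile with clear marker structure."""
    return pd.DataFrame(
        {
            "microglia": [100.0, 5.0, 0.0, 10.0, 50.0],
            "astrocyte": [5.0, 100.0, 0.0, 10.0, 5.0],
            "neuron": [4.0, 2.0, 200.0, 10.0, 0.0],
        },
        index=pd.Index(["mg1", "as1", "nr1", "flat", "mg2"], name="gene_id"),
    )


def event_rows(event_id, variant_id, role, counts5p, counts3p, samples,
               retained_intron=False, same_features=False):
    """Long-format event-table rows for one variant across samples."""
    return [
        {
            "event_id": event_id,
            "variant_id": variant_id,
            "role": role,
            "retained_intron": retained_intron,
            "same_features": same_features,
            "sample_id": s,
            "count5p": c5,
            "count3p": c3,
        }
        for s, c5, c3 in zip(samples, counts5p, counts3p)
    ]


@pytest.fixture
def toy_event_table() -> pd.DataFrame:
    """Six hand-built events exercising every branch of the filter cascade.

    Expected cascade outcome (min_count=5, min_samples=3):
      E1 cassette, both variants pass        -> kept, V2 testable
      E2 second variant low counts           -> variant dropped, event dropped
      E3 retained-intron, counts pass        -> event dropped
      E4 both variants low counts            -> dropped at count filter
      E5 three variants, all pass            -> kept, V2 and V3 testable
      E6 cassette, both pass                 -> kept, V2 testable
    """
    samples = [f"s{i}" for i in range(1, 7)]
    rows = []
    rows += event_rows("E1", "E1.V1", "skipping", [3, 3, 3, 3, 3, 3], [3, 3, 3, 3, 3, 3], samples)
    rows += event_rows("E1", "E1.V2", "inclusion", [5, 5, 5, 5, 5, 5], [5, 5, 5, 5, 5, 5], samples)
    rows += event_rows("E2", "E2.V1", "skipping", [3, 3, 3, 3, 3, 3], [3, 3, 3, 3, 3, 3], samples)
    rows += event_rows("E2", "E2.V2", "inclusion", [1, 1, 0, 0, 0, 0], [0, 0, 0, 1, 1, 0], samples)
    rows += event_rows("E3", "E3.V1", "other", [4, 4, 4, 4, 4, 4], [4, 4, 4, 4, 4, 4], samples,
                       retained_intron=True)
    rows += event_rows("E3", "E3.V2", "other", [6, 6, 6, 6, 6, 6], [6, 6, 6, 6, 6, 6], samples,
                       retained_intron=True)
    rows += event_rows("E4", "E4.V1", "skipping", [1, 1, 1, 1, 1, 1], [1, 1, 1, 1, 1, 1], samples)
    rows += event_rows("E4", "E4.V2", "inclusion", [2, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 2], samples)
    rows += event_rows("E5", "E5.V1", "skipping", [4, 4, 4, 4, 4, 4], [4, 4, 4, 4, 4, 4], samples)
    rows += event_rows("E5", "E5.V2", "inclusion", [8, 8, 8, 8, 8, 8], [8, 8, 8, 8, 8, 8], samples)
    rows += event_rows("E5", "E5.V3", "inclusion", [3, 3, 3, 3, 3, 3], [3, 3, 3, 3, 3, 3], samples)
    rows += event_rows("E6", "E6.V1", "skipping", [10, 10, 10, 10, 10, 10], [4, 4, 4, 4, 4, 4], samples)
    rows += event_rows("E6", "E6.V2", "inclusion", [20, 20, 20, 20, 2, 2], [0, 0, 0, 0, 0, 0], samples)
    return pd.DataFrame(rows)


@pytest.fixture
def hand_plate() -> pd.DataFrame:
    """Four-sample qPCR plate whose ddCt arithmetic is fully hand-computable.

    Samples v1, v2 (vehicle) and t1, t2 (treated), one event with inclusion
    and skipping assays plus an Actb housekeeping assay.  Sample t2's
    inclusion assay fails on all replicates: Ct^max for inclusion over
    passing values is 30.0, so its Ct imputes at 31.0.
    """
    rows = []

    def add(sample, cond, assay, role, cts, passes):
        for i, (ct, ok) in enumerate(zip(cts, passes), start=1):
            rows.append(
                {
                    "sample_id": sample,
                    "cell_type": "microglia",
                    "condition": cond,
                    "assay_id": assay,
                    "assay_role": role,
                    "replicate_idx": i,
                    "ct": ct,
                    "pass": ok,
                }
            )

    add("v1", "vehicle", "Actb", "housekeeping", [20.0, 20.0], [True, True])
    add("v1", "vehicle", "incl", "inclusion", [24.0, 24.2, 31.0], [True, True, False])
    add("v1", "vehicle", "skip", "skipping", [28.0, 28.0], [True, True])
    add("v2", "vehicle", "Actb", "housekeeping", [21.0, 21.0], [True, True])
    add("v2", "vehicle", "incl", "inclusion", [25.1, 25.1], [True, True])
    add("v2", "vehicle", "skip", "skipping", [29.1, 29.1], [True, True])
    add("t1", "treated", "Actb", "housekeeping", [20.0, 20.0], [True, True])
    add("t1", "treated", "incl", "inclusion", [30.0, 30.0], [True, True])
    add("t1", "treated", "skip", "skipping", [24.0, 24.0], [True, True])
    add("t2", "treated", "Actb", "housekeeping", [20.5, 20.5], [True, True])
    add("t2", "treated", "incl", "inclusion", [33.0, 34.0], [False, False])
    add("t2", "treated", "skip", "skipping", [24.5, 24.5], [True, True])
    return pd.DataFrame(rows)
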