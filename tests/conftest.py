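import numpy as np
import pandas as pd
import pytest

from labyprot.io import IntensityMatrix, SampleDesign
from labyprot.simulate import SimulationConfig, simulate_all


def make_design(timepoints=(0, 2, 4, 6, 8), n_replicates=3):
    rows = [
        {"sample_id": f"T{t}_{r}", "timepoint": t, "replicate": str(r), "batch": str(r)}
        for t in timepoints for r in range(1, n_replicates + 1)
    ]
    return SampleDesign(pd.DataFrame(rows).set_index("sample_id"))


def make_matrix(values, timepoints=(0, 2, 4, 6, 8), n_replicates=3,
                protein_ids=None, scale_tag="glog"):
    design = make_design(timepoints, n_replicates)
    values = np.asarray(values, dtype=float)
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=protein_ids, columns=design.sample_ids)
    return IntensityMatrix(frame, design, scale_tag)


@pytest.fixture(scope="session")
def default_sim():
    """One medium simulation shared across read-only tests."""
    cfg = SimulationConfig(n_proteins=600, missing_rate=0.0, seed=42)
    matrix, truth, hits, orthogroups, lineages, annotations = simulate_all(cfg)
    return {
        "config": cfg, "matrix": matrix, "truth": truth, "hits": hits,
        "orthogroups": orthogroups, "lineages": lineages, "annotations": annotations,
    }
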