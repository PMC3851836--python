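import numpy as np
import pandas as pd
import pytest

from tfmirnet import (
    EdgeClass,
    MPGEDataset,
    ParallelExpressionDataset,
    RegulationLibrary,
)


@pytest.fixture
def tiny_libraries():
    """Minimal consistent trio of libraries: T1->g1/g2/T2, T1->m1, m1->g1/T2."""
    tf2gene = RegulationLibrary(
        EdgeClass.TF2GENE, [("T1", "g1"), ("T1", "g2"), ("T1", "T2"), ("T2", "g2")]
    )
    tf2mir = RegulationLibrary(EdgeClass.TF2MIR, [("T1", "hsa-miR-210")])
    mir2gene = RegulationLibrary(
        EdgeClass.MIR2GENE, [("hsa-miR-210", "g1"), ("hsa-miR-210", "T2")]
    )
    return tf2gene, tf2mir, mir2gene


@pytest.fixture
def shifted_mpge():
    """100 putative targets shifted by -1 against 100 standard-normal non-targets."""
    rng = np.random.default_rng(42)
    nontargets = rng.normal(size=100)
    targets = rng.normal(size=100) - 1.0
    genes = [f"t{i}" for i in range(100)] + [f"n{i}" for i in range(100)]
    values = np.concatenate([targets, nontargets])
    dataset = MPGEDataset("hsa-miR-1", pd.Series(values, index=genes))
    lib = RegulationLibrary(
        EdgeClass.MIR2GENE, [("hsa-miR-1", f"t{i}") for i in range(100)]
    )
    return dataset, lib, targets, nontargets


def make_parallel_dataset(rng, n_cond=20, mirnas=("hsa-miR-500",), genes=("gA", "gB")):
    mir = pd.DataFrame(
        rng.normal(size=(len(mirnas), n_cond)),
        index=list(mirnas),
        columns=[f"C{i}" for i in range(n_cond)],
    )
    mrna = pd.DataFrame(
        rng.normal(size=(len(genes), n_cond)),
        index=list(genes),
        columns=[f"C{i}" for i in range(n_cond)],
    )
    return ParallelExpressionDataset(mir, mrna)
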