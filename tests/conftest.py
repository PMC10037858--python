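import numpy as np
import pandas as pd
import pytest

from grnstack.grn_data import (
    CandidateEdgeUniverse,
    ExpressionDataset,
    RegulatoryNetwork,
    build_candidate_universe,
)
from grnstack.netsim import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_simulation():
    """A 30-gene / 5-TF simulated dataset shared across method tests."""
    cfg = SimulationConfig(n_genes=30, n_tfs=5, mean_out_degree=3.0, seed=11)
    ds, annotated = simulate(cfg)
    universe = build_candidate_universe(ds, annotated.network)
    return ds, annotated, universe


@pytest.fixture()
def tiny_dataset():
    """3 genes x 4 samples, one TF, no time metadata."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [5.0, 5.0, 4.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionDataset(values=values, tf_ids=("g1",))


def make_timed_dataset(mat, gene_ids, tf_ids, times_per_traj):
    """Build an ExpressionDataset from a matrix and per-trajectory times."""
    columns, meta = [], []
    for traj, times in times_per_traj.items():
        for t in times:
            columns.append(f"{traj}_t{t}")
            meta.append((traj, float(t)))
    values = pd.DataFrame(np.asarray(mat, dtype=float), index=gene_ids, columns=columns)
    sample_meta = pd.DataFrame(
        meta, index=columns, columns=["trajectory_id", "time_minutes"]
    )
    return ExpressionDataset(values=values, tf_ids=tuple(tf_ids), sample_meta=sample_meta)


def universe_for(gene_ids, regulators, gold_edges=()):
    gold = RegulatoryNetwork(
        edges=frozenset(gold_edges), regulator_universe=frozenset(regulators)
    )
    edges = tuple(
        (r, t) for r in sorted(regulators) for t in gene_ids if r != t
    )
    labels = np.array([1 if e in gold.edges else 0 for e in edges], dtype=np.int8)
    return CandidateEdgeUniverse(
        edges=edges,
        regulators=tuple(sorted(regulators)),
        targets=tuple(gene_ids),
        labels=labels,
    )
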