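"""Synthetic validation scenarios for the stacking pipeline.

Two generators live here because both the test suite and the reproduction
script need them:

* :func:`complementary_oracle_table` builds a level-1 score table with two
  synthetic columns that are individually informative only on disjoint
  halves of the TFs — the cleanest setting in which a stacking ensemble
  must beat every single input method.
* :func:`simulated_pipeline_ratios` runs the whole pipeline (ODE simulator
  -> six built-in level-1 methods -> kurtosis filter -> Naive Bayes
  ensemble) on one synthetic network and reports per-system test AUPRC
  ratios for a single TF-disjoint split.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from .grn_data import CandidateEdgeUniverse, build_candidate_universe
from .level1 import DEFAULT_SUITE, EdgeScoreTable, run_level1_suite
from .netsim import SimulationConfig, simulate


def complementary_oracle_table(
    n_tfs: int = 60,
    n_targets: int = 40,
    prevalence: float = 0.1,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> EdgeScoreTable:
    """Two-column score table in which each column knows half the TFs.

    TFs and targets are disjoint identifier sets, so the candidate universe
    is the full ``n_tfs x n_targets`` cross product.  Edge labels are i.i.d.
    Bernoulli(prevalence).  Column ``oracle_a`` scores an edge as
    ``label + N(0, noise_sd)`` when its TF lies in the first half of the
    TFs and as an uninformative Uniform(0, 1) draw otherwise;
    ``oracle_b`` is the mirror image on the second half.  A level-2 model
    that combines both columns can rank all test TFs well; either column
    alone is blind on half of them.
    """
    rng = np.random.default_rng(seed)
    tfs = tuple(f"TF{i:03d}" for i in range(n_tfs))
    targets = tuple(f"T{i:03d}" for i in range(n_targets))
    edges = tuple((r, t) for r in tfs for t in targets)
    labels = rng.binomial(1, prevalence, size=len(edges)).astype(np.int8)
    # guarantee at least one positive per TF half so every split is usable
    half = n_tfs // 2
    for block in (range(0, half), range(half, n_tfs)):
        rows = [i * n_targets + j for i in block for j in range(n_targets)]
        if labels[rows].sum() == 0:
            labels[rng.choice(rows)] = 1

    first_half = set(tfs[:half])
    informative_a = np.array([r in first_half for r, _ in edges])
    signal = labels + rng.normal(0.0, noise_sd, size=len(edges))
    col_a = np.where(informative_a, signal, rng.uniform(0, 1, size=len(edges)))
    signal_b = labels + rng.normal(0.0, noise_sd, size=len(edges))
    col_b = np.where(~informative_a, signal_b, rng.uniform(0, 1, size=len(edges)))

    universe = CandidateEdgeUniverse(
        edges=edges, regulators=tfs, targets=targets, labels=labels
    )
    return EdgeScoreTable(
        universe=universe,
        method_names=["oracle_a", "oracle_b"],
        scores=np.column_stack([col_a, col_b]),
    )


def simulated_pipeline_ratios(
    seed: int,
    n_genes: int = 50,
    n_tfs: int = 10,
    noise_sd: float = 0.05,
    interval_minutes: float = 50.0,
    n_trees: int = 50,
    ensemble_kind: str = "naive_bayes",
    ratio: float = 2.0 / 3.0,
    n_splits: int = 20,
    apply_kurtosis_filter: bool = True,
) -> dict[str, float]:
    """One end-to-end run: simulate, score, and benchmark over repeated splits.

    Runs the standard repeated-split protocol (default 20 TF-disjoint
    splits) on one simulated network and returns mean test AUPRC ratios per
    system: each level-1 method, ``ensemble``, ``average_rank``, and
    ``best_level1_test`` (the level-1 method with the highest mean test
    ratio, i.e. the fixed post-hoc best single method).
    """
    from .evaluation import benchmark_score_table

    cfg = SimulationConfig(
        n_genes=n_genes,
        n_tfs=n_tfs,
        noise_sd=noise_sd,
        interval_minutes=interval_minutes,
        seed=seed,
    )
    ds, annotated = simulate(cfg)
    universe = build_candidate_universe(ds, annotated.network)
    specs: list[dict[str, Any]] = [
        dict(s, params={"n_trees": n_trees, "seed": seed})
        if s["name"] == "tree_importance"
        else dict(s)
        for s in DEFAULT_SUITE
    ]
    table = run_level1_suite(ds, universe, specs)
    report = benchmark_score_table(
        table,
        [{"kind": ensemble_kind, "label": "ensemble"}],
        n_splits=n_splits,
        ratio=ratio,
        seed=seed,
        apply_kurtosis_filter=apply_kurtosis_filter,
        n_resamples=200,
    )
    out = {
        name: float(report.summary.loc[name, "mean_ratio"])
        for name in table.method_names + ["ensemble", "average_rank"]
    }
    out["best_level1_test"] = max(out[m] for m in table.method_names)
    return out
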