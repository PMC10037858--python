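"""AUPRC machinery, random-predictor ratios, repeated-split benchmarking and
the paired sign-flip resampling test.

AUPRC here is the average-precision (step) form: the mean, over positives
taken in descending score order, of the precision at each positive's
threshold.  Tied scores form one threshold group whose group precision is
assigned to every positive in the group — no trapezoidal interpolation.
The headline comparison statistic is the AUPRC *ratio*: AUPRC divided by
the positive prevalence of the same edge set, i.e. by the expected AUPRC
of a random predictor, so 1.0 means "no better than random".
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    BenchmarkError,
    GrnValidationError,
    UndefinedMetricError,
)
from .grn_data import CandidateEdgeUniverse, ExpressionDataset, RegulatoryNetwork
from .grn_data import build_candidate_universe
from .level1 import EdgeScoreTable, run_level1_suite
from .stacking import (
    SplitSpec,
    assemble_features,
    average_rank_baseline,
    fit_level2,
    kurtosis_filter,
    predict_level2,
    tf_disjoint_split,
)

logger = logging.getLogger(__name__)


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (average-precision form).

    Requires at least one positive; with no negatives returns 1.0 with a
    warning.  Tied scores are handled as one threshold group: the precision
    at the group's lower boundary is assigned to all positives in it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise GrnValidationError("scores and labels must have equal length")
    if not np.all(np.isfinite(scores)):
        raise GrnValidationError("scores must be finite")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos + n_neg != len(labels):
        raise GrnValidationError("labels must be 0/1")
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC undefined without positives")
    if n_neg == 0:
        warnings.warn("no negatives: AUPRC trivially 1.0", stacklevel=2)
        return 1.0
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group boundaries: last index of each distinct score value
    boundary = np.flatnonzero(np.diff(s) != 0)
    ends = np.append(boundary, len(s) - 1)
    cum_tp = np.cumsum(y == 1)[ends]
    cum_all = ends + 1
    precision = cum_tp / cum_all
    tp_in_group = np.diff(np.concatenate(([0], cum_tp)))
    return float(np.sum(tp_in_group * precision) / n_pos)


def auprc_ratio(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUPRC divided by the prevalence of positives (random-predictor AUPRC)."""
    labels = np.asarray(labels)
    prevalence = float(np.mean(labels == 1))
    return auprc(scores, labels) / prevalence


def paired_resampling_pvalue(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    n_resamples: int | str = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> float:
    """One-sided paired sign-flip permutation test on per-split differences.

    The statistic is the mean paired difference ``d_i = a_i - b_i``.  Under
    the null of exchangeable signs, each ``d_i`` is flipped independently;
    the p-value is the fraction of flipped-sign means at least as large as
    the observed mean (ties count).  Pass ``n_resamples="exhaustive"`` to
    enumerate all 2^n sign patterns (n <= 20); otherwise Monte-Carlo
    resampling with the +1 correction is used.  ``alternative="two-sided"``
    compares absolute means.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.shape != b.shape:
        raise GrnValidationError("paired series must have equal length")
    if len(a) < 5:
        raise GrnValidationError("need >= 5 pairs for the resampling test")
    d = a - b
    n = len(d)
    tol = 1e-12

    def stat(x: np.ndarray) -> np.ndarray:
        m = x.mean(axis=-1)
        return np.abs(m) if alternative == "two-sided" else m

    observed = float(stat(d))
    if n_resamples == "exhaustive":
        if n > 20:
            raise GrnValidationError("exhaustive enumeration limited to n <= 20")
        patterns = np.array(
            [[1 if (i >> j) & 1 else -1 for j in range(n)] for i in range(2**n)]
        )
        means = stat(patterns * d)
        return float(np.sum(means >= observed - tol) / len(means))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(int(n_resamples), n))
    means = stat(signs * d)
    exceed = int(np.sum(means >= observed - tol))
    return float((1 + exceed) / (1 + int(n_resamples)))


@dataclass
class BenchmarkReport:
    """Per-split AUPRC ratios for every system plus paired-test p-values."""

    per_split: pd.DataFrame  # columns: system, split, seed, auprc, ratio, checksum
    summary: pd.DataFrame  # index: system; columns: mean_ratio, sd_ratio, n_splits
    pvalues: dict[str, float]
    split_seeds: list[int]
    config: dict[str, Any] = field(default_factory=dict)
    redraws: int = 0

    def ratios(self, system: str) -> np.ndarray:
        sub = self.per_split[self.per_split["system"] == system]
        return sub.sort_values("split")["ratio"].to_numpy()

    def systems(self) -> list[str]:
        return list(self.summary.index)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_split.to_csv(out / "per_split.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "summary.tsv", sep="\t", index_label="system")
        with (out / "pvalues.tsv").open("w") as fh:
            fh.write("comparison\tp_value\n")
            for name, p in self.pvalues.items():
                fh.write(f"{name}\t{p}\n")


def _edge_checksum(edges: Sequence[tuple[str, str]]) -> str:
    h = hashlib.sha1()
    for r, t in edges:
        h.update(f"{r}\t{t}\n".encode())
    return h.hexdigest()[:12]


def benchmark_score_table(
    table: EdgeScoreTable,
    ensemble_specs: Sequence[Mapping[str, Any]],
    n_splits: int = 20,
    ratio: float = 2.0 / 3.0,
    seed: int = 0,
    apply_kurtosis_filter: bool = True,
    n_resamples: int = 10_000,
) -> BenchmarkReport:
    """Repeated-split benchmark over a pre-computed level-1 score table.

    For each TF-disjoint split: every level-1 column, every requested
    ensemble, and the average-rank community baseline score the test-side
    edges; AUPRC ratios are recorded.  Identical splits are reused across
    all systems, so the per-split series are paired by construction.
    Splits whose test side has no positive (or whose train side is
    single-class) are redrawn with a fresh seed; more than 50% redraws
    aborts the benchmark.  Paired sign-flip p-values compare each ensemble
    against the per-split best level-1 column and the average-rank baseline.
    """
    universe = table.universe
    if universe.labels is None:
        raise GrnValidationError("benchmark needs a labelled candidate universe")
    if n_splits < 1:
        raise GrnValidationError("n_splits must be >= 1")

    if apply_kurtosis_filter:
        retained, kurt = kurtosis_filter(table)
    else:
        retained, kurt = list(table.method_names), {}
    avg_rank_all = average_rank_baseline(table, retained)

    regulators = sorted({r for r, _ in universe.edges})
    edge_regs = np.array([r for r, _ in universe.edges])
    seed_stream = np.random.SeedSequence(seed)
    split_seeds: list[int] = []
    rows: list[dict[str, Any]] = []
    redraws = 0
    max_redraws = max(1, n_splits)  # >50% of requested splits aborts

    for split_idx in range(n_splits):
        while True:
            s = int(seed_stream.spawn(1)[0].generate_state(1)[0] % (2**31))
            split = tf_disjoint_split(regulators, ratio=ratio, seed=s)
            test_mask = np.isin(edge_regs, list(split.test_tfs))
            train_mask = ~test_mask
            y_test = universe.labels[test_mask]
            y_train = universe.labels[train_mask]
            if y_test.sum() > 0 and len(np.unique(y_train)) == 2:
                break
            redraws += 1
            logger.warning("redrawing split %d (degenerate side)", split_idx)
            if redraws > max_redraws // 2:
                raise BenchmarkError("more than 50% of splits required redraws")
        split_seeds.append(s)
        test_edges = tuple(e for e, m in zip(universe.edges, test_mask) if m)
        checksum = _edge_checksum(test_edges)

        def record(system: str, scores: np.ndarray) -> float:
            r = auprc_ratio(scores, y_test)
            rows.append(
                {
                    "system": system,
                    "split": split_idx,
                    "seed": s,
                    "auprc": auprc(scores, y_test),
                    "ratio": r,
                    "checksum": checksum,
                }
            )
            return r

        # level-1 columns evaluated on the same test edges
        l1_test_ratios: dict[str, float] = {}
        l1_train_ratios: dict[str, float] = {}
        for name in table.method_names:
            col = table.column(name)
            l1_test_ratios[name] = record(name, col[test_mask])
            l1_train_ratios[name] = auprc_ratio(col[train_mask], y_train)

        best_test_name = max(l1_test_ratios, key=l1_test_ratios.get)
        record("best_level1_test", table.column(best_test_name)[test_mask])
        best_train_name = max(l1_train_ratios, key=l1_train_ratios.get)
        record("best_level1_train", table.column(best_train_name)[test_mask])
        record("average_rank", avg_rank_all[test_mask])

        train_ft = assemble_features(table, retained, universe, split, "train")
        test_ft = assemble_features(table, retained, universe, split, "test")
        for spec in ensemble_specs:
            kind = spec["kind"]
            label = spec.get("label", kind)
            model = fit_level2(
                kind, train_ft, spec.get("hyperparameters"), seed=s
            )
            record(label, predict_level2(model, test_ft))

    per_split = pd.DataFrame(rows)
    summary = (
        per_split.groupby("system")["ratio"]
        .agg(mean_ratio="mean", sd_ratio="std", n_splits="count")
        .sort_values("mean_ratio", ascending=False)
    )

    pvalues: dict[str, float] = {}
    if n_splits >= 5:
        def series(system: str) -> np.ndarray:
            sub = per_split[per_split["system"] == system]
            return sub.sort_values("split")["ratio"].to_numpy()

        best_l1 = series("best_level1_test")
        avg_rank = series("average_rank")
        for spec in ensemble_specs:
            label = spec.get("label", spec["kind"])
            ens = series(label)
            pvalues[f"{label}_vs_best_level1_test"] = paired_resampling_pvalue(
                ens, best_l1, n_resamples=n_resamples, seed=seed
            )
            pvalues[f"{label}_vs_average_rank"] = paired_resampling_pvalue(
                ens, avg_rank, n_resamples=n_resamples, seed=seed
            )

    return BenchmarkReport(
        per_split=per_split,
        summary=summary,
        pvalues=pvalues,
        split_seeds=split_seeds,
        config={
            "n_splits": n_splits,
            "ratio": ratio,
            "seed": seed,
            "kurtosis_filter": apply_kurtosis_filter,
            "retained_methods": retained,
            "kurtosis": kurt,
            "ensembles": [dict(s) for s in ensemble_specs],
        },
        redraws=redraws,
    )


def run_benchmark(
    ds: ExpressionDataset,
    gold: RegulatoryNetwork,
    level1_specs: Sequence[Mapping[str, Any]] | None,
    ensemble_specs: Sequence[Mapping[str, Any]],
    n_splits: int = 20,
    ratio: float = 2.0 / 3.0,
    seed: int = 0,
    apply_kurtosis_filter: bool = True,
    include_tf_targets: bool = True,
    n_resamples: int = 10_000,
) -> BenchmarkReport:
    """Full pipeline benchmark: level-1 once on all expression data, then the
    repeated TF-disjoint split protocol of :func:`benchmark_score_table`.

    Level-1 methods see the complete expression matrix (unsupervised); only
    the gold-standard labels are split by TF, so there is no label leakage
    across the train/test boundary.
    """
    universe = build_candidate_universe(ds, gold, include_tf_targets=include_tf_targets)
    table = run_level1_suite(ds, universe, level1_specs)
    return benchmark_score_table(
        table,
        ensemble_specs,
        n_splits=n_splits,
        ratio=ratio,
        seed=seed,
        apply_kurtosis_filter=apply_kurtosis_filter,
        n_resamples=n_resamples,
    )
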