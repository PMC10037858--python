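"""Level-1 edge-scoring methods: simplified representatives of the three
families of base network-inference algorithms (pairwise correlation, tree
feature importance, ODE regression), plus an adapter for externally produced
ranked-edge files.

Each operation returns one confidence score per candidate edge (higher =
more confident edge presence), aligned with the edge order of the
:class:`~grnstack.grn_data.CandidateEdgeUniverse`.  These are category-level
stand-ins for published tools (GENIE3, PPCOR, LEAP, PIDC, Inferelator-style
regression), not numerical reimplementations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge

from .exceptions import (
    ConfigError,
    ConsistencyError,
    EmptyTableError,
    GrnUsageError,
    InsufficientDataError,
    NumericalError,
)
from .grn_data import CandidateEdgeUniverse, ExpressionDataset, read_ranked_edges

logger = logging.getLogger(__name__)

TIME_REQUIRED = {"lagged_correlation", "ode_ridge"}


@dataclass
class EdgeScoreTable:
    """Candidate-edge x method matrix of level-1 confidence scores."""

    universe: CandidateEdgeUniverse
    method_names: list[str]
    scores: np.ndarray  # shape (n_edges, n_methods)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (self.universe.n_edges, len(self.method_names)):
            raise ValueError("scores shape does not match universe/methods")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("score table contains non-finite values")
        for j, name in enumerate(self.method_names):
            if np.unique(self.scores[:, j]).size < 2:
                msg = f"method {name!r} ties all edges (degenerate column)"
                self.warnings.append(msg)
                logger.warning(msg)

    def column(self, name: str) -> np.ndarray:
        return self.scores[:, self.method_names.index(name)]


def _standardized_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores and a mask of constant rows (left as zeros)."""
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    return (mat - mean) / sd, constant


def _positions(ds: ExpressionDataset, ids: Sequence[str]) -> np.ndarray:
    pos = {g: i for i, g in enumerate(ds.values.index)}
    return np.array([pos[g] for g in ids], dtype=int)


def pearson_scores(
    ds: ExpressionDataset, universe: CandidateEdgeUniverse
) -> np.ndarray:
    """|Pearson correlation| between regulator and target across all samples.

    Constant genes get score 0 (with a warning).  Requires >= 3 samples.
    """
    if ds.n_samples < 3:
        raise InsufficientDataError("pearson_scores requires >= 3 samples")
    mat = ds.values.to_numpy()
    z, constant = _standardized_rows(mat)
    if constant.any():
        logger.warning(
            "%d constant gene(s) scored 0 by pearson", int(constant.sum())
        )
    ridx = _positions(ds, universe.regulators)
    tidx = _positions(ds, universe.targets)
    corr = np.abs(z[ridx] @ z[tidx].T / ds.n_samples)
    cell = {
        (r, t): corr[i, j]
        for i, r in enumerate(universe.regulators)
        for j, t in enumerate(universe.targets)
    }
    return np.array([cell[e] for e in universe.edges])


def partial_correlation_scores(
    ds: ExpressionDataset,
    universe: CandidateEdgeUniverse,
    shrinkage: float = 0.1,
) -> np.ndarray:
    """|partial correlation| from the inverse of a shrunk correlation matrix.

    The correlation matrix over the candidate gene set is shrunk toward the
    identity, ``R* = (1 - shrinkage) R + shrinkage I``, and the score for
    edge r->t is ``|-P_rt / sqrt(P_rr P_tt)|`` with ``P = (R*)^-1``.
    """
    if not 0 <= shrinkage <= 1:
        raise ConfigError("shrinkage must lie in [0, 1]")
    if ds.n_samples < 3:
        raise InsufficientDataError("partial_correlation requires >= 3 samples")
    gene_set = sorted(set(universe.regulators) | set(universe.targets))
    idx = _positions(ds, gene_set)
    z, _ = _standardized_rows(ds.values.to_numpy()[idx])
    r_mat = z @ z.T / ds.n_samples
    np.fill_diagonal(r_mat, 1.0)
    shrunk = (1.0 - shrinkage) * r_mat + shrinkage * np.eye(len(gene_set))
    try:
        prec = np.linalg.inv(shrunk)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "correlation matrix singular; increase shrinkage above 0"
        ) from exc
    if not np.all(np.isfinite(prec)):
        raise NumericalError(
            "precision matrix non-finite; increase shrinkage above 0"
        )
    d = np.sqrt(np.diag(prec))
    pcorr = np.abs(-prec / np.outer(d, d))
    gpos = {g: i for i, g in enumerate(gene_set)}
    return np.array([pcorr[gpos[r], gpos[t]] for r, t in universe.edges])


def lagged_correlation_scores(
    ds: ExpressionDataset,
    universe: CandidateEdgeUniverse,
    max_lag_steps: int = 2,
) -> np.ndarray:
    """Max over lags of |Pearson(r at t_i, target at t_{i+lag})|.

    Pairs are pooled across trajectories and never cross a trajectory
    boundary.  Requires time metadata and each trajectory longer than
    ``max_lag_steps``.
    """
    if not ds.has_time:
        raise GrnUsageError(
            "lagged_correlation needs time metadata; use pearson_scores"
        )
    if max_lag_steps < 0:
        raise ConfigError("max_lag_steps must be >= 0")
    trajs = ds.trajectories()
    for traj_id, idx, _ in trajs:
        if len(idx) <= max_lag_steps:
            raise InsufficientDataError(
                f"trajectory {traj_id} has <= max_lag_steps samples"
            )
    mat = ds.values.to_numpy()
    ridx = _positions(ds, universe.regulators)
    tidx = _positions(ds, universe.targets)
    best = np.zeros((len(ridx), len(tidx)))
    for lag in range(max_lag_steps + 1):
        left, right = [], []
        for _, idx, _ in trajs:
            if len(idx) - lag < 3:
                continue
            left.extend(idx[: len(idx) - lag])
            right.extend(idx[lag:])
        if len(left) < 3:
            continue
        a = mat[np.ix_(ridx, np.array(left))]
        b = mat[np.ix_(tidx, np.array(right))]
        za, _ = _standardized_rows(a)
        zb, _ = _standardized_rows(b)
        corr = np.abs(za @ zb.T / len(left))
        best = np.maximum(best, corr)
    cell = {
        (r, t): best[i, j]
        for i, r in enumerate(universe.regulators)
        for j, t in enumerate(universe.targets)
    }
    return np.array([cell[e] for e in universe.edges])


def _equal_frequency_bins(vals: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency binning; ties broken by stable sort order."""
    order = np.argsort(vals, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(vals))
    return (ranks * n_bins) // len(vals)


def mutual_information_scores(
    ds: ExpressionDataset,
    universe: CandidateEdgeUniverse,
    n_bins: int = 4,
) -> np.ndarray:
    """Plug-in mutual information (nats) of the equal-frequency joint histogram.

    Symmetric by construction: both edge directions receive the same value.
    """
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    if ds.n_samples < n_bins:
        raise InsufficientDataError("need at least n_bins samples")
    mat = ds.values.to_numpy()
    gene_set = sorted(set(universe.regulators) | set(universe.targets))
    idx = _positions(ds, gene_set)
    bins = np.stack([_equal_frequency_bins(mat[i], n_bins) for i in idx])
    gpos = {g: i for i, g in enumerate(gene_set)}
    n = ds.n_samples
    cache: dict[tuple[int, int], float] = {}

    def mi(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in cache:
            joint = np.bincount(
                bins[key[0]] * n_bins + bins[key[1]], minlength=n_bins * n_bins
            ).reshape(n_bins, n_bins) / n
            pi = joint.sum(axis=1, keepdims=True)
            pj = joint.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = joint * np.log(joint / (pi * pj))
            cache[key] = float(np.nansum(terms))
        return cache[key]

    return np.array([mi(gpos[r], gpos[t]) for r, t in universe.edges])


def tree_importance_scores(
    ds: ExpressionDataset,
    universe: CandidateEdgeUniverse,
    n_trees: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Random-forest feature importance of each regulator for each target.

    Per target, a forest regresses the target's expression on all candidate
    regulators (excluding the target itself); importances are normalised to
    sum to 1 over regulators.  Regulator features are taken in sorted-id
    order so the result is invariant to input gene ordering.
    """
    if ds.n_samples < 10:
        raise InsufficientDataError("tree_importance requires >= 10 samples")
    mat = ds.values.to_numpy()
    regs_sorted = sorted(universe.regulators)
    reg_pos = dict(zip(regs_sorted, _positions(ds, regs_sorted)))
    scores: dict[tuple[str, str], float] = {}
    for target in universe.targets:
        feats = [r for r in regs_sorted if r != target]
        if not feats:
            raise ConsistencyError(f"no regulators available for target {target}")
        X = mat[[reg_pos[r] for r in feats]].T
        y = mat[_positions(ds, [target])[0]]
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
        forest.fit(X, y)
        imp = forest.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        else:
            logger.warning("zero total importance for target %s", target)
        for r, v in zip(feats, imp):
            scores[(r, target)] = float(v)
    return np.array([scores.get(e, 0.0) for e in universe.edges])


def ode_ridge_scores(
    ds: ExpressionDataset,
    universe: CandidateEdgeUniverse,
    ridge_penalty: float = 1.0,
) -> np.ndarray:
    """ODE-regression scores: |ridge coefficient| of each TF on the target's
    finite-difference expression derivative.

    Per target, derivatives ``(x_{i+1} - x_i) / (t_{i+1} - t_i)`` within each
    trajectory are regressed on regulator levels at the left endpoint plus
    the target's own level (a decay term, not emitted as an edge).  The
    ridge penalty applies on standardised predictors; reported coefficients
    are back-transformed to the original predictor scale.
    """
    if ridge_penalty <= 0:
        raise ConfigError("ridge_penalty must be positive")
    if not ds.has_time:
        raise GrnUsageError("ode_ridge requires time metadata")
    trajs = [t for t in ds.trajectories() if len(t[1]) >= 2]
    if not trajs:
        raise InsufficientDataError("no trajectory with >= 2 samples")
    mat = ds.values.to_numpy()
    left_idx, right_idx, dts = [], [], []
    for _, idx, times in trajs:
        left_idx.extend(idx[:-1])
        right_idx.extend(idx[1:])
        dts.extend(np.diff(times))
    left_idx = np.array(left_idx)
    right_idx = np.array(right_idx)
    dts = np.array(dts, dtype=float)

    regs_sorted = sorted(universe.regulators)
    reg_pos = dict(zip(regs_sorted, _positions(ds, regs_sorted)))
    tgt_pos = dict(zip(universe.targets, _positions(ds, list(universe.targets))))
    scores: dict[tuple[str, str], float] = {}
    for target in universe.targets:
        feats = [r for r in regs_sorted if r != target]
        cols = [reg_pos[r] for r in feats] + [tgt_pos[target]]
        X = mat[np.ix_(np.array(cols), left_idx)].T
        y = (mat[tgt_pos[target], right_idx] - mat[tgt_pos[target], left_idx]) / dts
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        live = sd > 0
        sd_safe = np.where(live, sd, 1.0)
        Xz = (X - mean) / sd_safe
        Xz[:, ~live] = 0.0
        model = Ridge(alpha=ridge_penalty, fit_intercept=True)
        model.fit(Xz, y)
        coef = np.where(live, model.coef_ / sd_safe, 0.0)
        for r, c in zip(feats, coef[:-1]):
            scores[(r, target)] = abs(float(c))
    return np.array([scores.get(e, 0.0) for e in universe.edges])


def load_external_scores(
    path: str | Path, universe: CandidateEdgeUniverse
) -> np.ndarray:
    """Map a ranked-edges file onto the candidate universe.

    Universe edges missing from the file get the file's minimum score (a
    deliberate fill policy: absent edges are no more confident than the
    least confident listed one); rows outside the universe are ignored and
    counted in the log.
    """
    rows = read_ranked_edges(path)
    if not rows:
        raise EmptyTableError(f"{path}: no scored edges")
    in_universe = set(universe.edges)
    fill = min(score for _, _, score in rows)
    lookup: dict[tuple[str, str], float] = {}
    ignored = 0
    for reg, tgt, score in rows:
        if (reg, tgt) in in_universe:
            lookup[(reg, tgt)] = score
        else:
            ignored += 1
    if ignored:
        logger.warning("%s: ignored %d out-of-universe edges", path, ignored)
    missing = universe.n_edges - len(lookup)
    if missing:
        logger.info("%s: filled %d missing edges with min score %g", path, missing, fill)
    return np.array([lookup.get(e, fill) for e in universe.edges])


BUILTIN_METHODS = {
    "pearson": pearson_scores,
    "partial_correlation": partial_correlation_scores,
    "lagged_correlation": lagged_correlation_scores,
    "mutual_information": mutual_information_scores,
    "tree_importance": tree_importance_scores,
    "ode_ridge": ode_ridge_scores,
}

DEFAULT_SUITE: list[dict[str, Any]] = [
    {"name": "pearson"},
    {"name": "partial_correlation"},
    {"name": "lagged_correlation"},
    {"name": "mutual_information"},
    {"name": "tree_importance"},
    {"name": "ode_ridge"},
]


def run_level1_suite(
    ds: ExpressionDataset,
    universe: CandidateEdgeUniverse,
    specs: Sequence[dict[str, Any]] | None = None,
) -> EdgeScoreTable:
    """Run a list of method specs and assemble the edge x method score table.

    Each spec is ``{"name": <builtin>, "params": {...}}`` or
    ``{"name": <label>, "path": <ranked-edges file>}`` for external scores.
    Methods requiring time metadata are skipped with a warning when the
    dataset is steady-state; duplicate column names get ``_2``, ``_3``
    suffixes.
    """
    if specs is None:
        specs = DEFAULT_SUITE
    columns: list[np.ndarray] = []
    names: list[str] = []
    warnings: list[str] = []
    for spec in specs:
        name = spec["name"]
        params = dict(spec.get("params", {}))
        if "path" in spec:
            col = load_external_scores(spec["path"], universe)
        else:
            if name not in BUILTIN_METHODS:
                raise ConfigError(f"unknown level-1 method {name!r}")
            if name in TIME_REQUIRED and not ds.has_time:
                msg = f"skipping {name}: dataset has no time metadata"
                warnings.append(msg)
                logger.warning(msg)
                continue
            col = BUILTIN_METHODS[name](ds, universe, **params)
        unique = name
        k = 2
        while unique in names:
            unique = f"{name}_{k}"
            k += 1
        names.append(unique)
        columns.append(np.asarray(col, dtype=float))
    if not columns:
        raise EmptyTableError("all level-1 methods were skipped")
    table = EdgeScoreTable(
        universe=universe,
        method_names=names,
        scores=np.column_stack(columns),
    )
    table.warnings = warnings + table.warnings
    return table
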