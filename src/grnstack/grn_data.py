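"""Core data types and I/O for expression matrices, TF lists and edge lists.

The on-disk conventions follow the BEELINE benchmarking suite: expression
matrices are delimited text with genes in rows and samples in columns, edge
lists are two-column (regulator, target) files, and ranked-edge files carry
the header ``Gene1  Gene2  EdgeWeight`` sorted by descending confidence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConsistencyError,
    FormatError,
    GrnParseError,
    GrnValidationError,
)

logger = logging.getLogger(__name__)

RANKED_EDGES_HEADER = ("Gene1", "Gene2", "EdgeWeight")


def _detect_delimiter(first_line: str) -> str:
    """Tab wins over comma when both are present."""
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return "\t"


@dataclass(frozen=True)
class ExpressionDataset:
    """A genes x samples expression matrix with TF flags and optional time metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample; nonnegative
        expression levels in arbitrary units.
    tf_ids
        Genes flagged as transcription factors (candidate regulators).
        Every entry must be a row of ``values``.
    sample_meta
        Optional per-sample metadata with columns ``trajectory_id`` and
        ``time_minutes``, indexed like ``values.columns``.  Absent for
        steady-state data.  Within a trajectory, times must be strictly
        increasing in column order.
    """

    values: pd.DataFrame
    tf_ids: tuple[str, ...]
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        index = self.values.index
        if index.has_duplicates:
            dupes = index[index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes}")
        object.__setattr__(self, "tf_ids", tuple(self.tf_ids))
        missing = [tf for tf in self.tf_ids if tf not in index]
        if missing:
            raise ConsistencyError(f"TF ids not present in matrix: {missing}")
        if len(set(self.tf_ids)) != len(self.tf_ids):
            raise FormatError("duplicate TF ids")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise GrnParseError("expression matrix contains non-numeric cells")
        if self.sample_meta is not None:
            meta = self.sample_meta
            if list(meta.index) != list(self.values.columns):
                raise ConsistencyError(
                    "sample_meta index does not match matrix columns"
                )
            for needed in ("trajectory_id", "time_minutes"):
                if needed not in meta.columns:
                    raise FormatError(f"sample_meta missing column {needed!r}")
            for traj, sub in meta.groupby("trajectory_id", sort=False):
                times = sub["time_minutes"].to_numpy(dtype=float)
                if np.any(np.diff(times) <= 0):
                    raise GrnValidationError(
                        f"times not strictly increasing in trajectory {traj!r}"
                    )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def has_time(self) -> bool:
        return self.sample_meta is not None

    def trajectories(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """Yield (trajectory_id, column positions, times) per trajectory.

        Raises if the dataset has no time metadata.
        """
        if self.sample_meta is None:
            raise GrnValidationError("dataset has no time metadata")
        out = []
        positions = {s: i for i, s in enumerate(self.values.columns)}
        for traj, sub in self.sample_meta.groupby("trajectory_id", sort=False):
            idx = np.array([positions[s] for s in sub.index], dtype=int)
            times = sub["time_minutes"].to_numpy(dtype=float)
            out.append((str(traj), idx, times))
        return out


@dataclass(frozen=True)
class RegulatoryNetwork:
    """A directed gold-standard edge set over (regulator, target) pairs."""

    edges: frozenset[tuple[str, str]]
    regulator_universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        edges = frozenset(tuple(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        for r, t in edges:
            if r == t:
                raise GrnValidationError(f"self-edge {r}->{t} not allowed")
        universe = frozenset(self.regulator_universe) or frozenset(
            r for r, _ in edges
        )
        missing = {r for r, _ in edges} - universe
        if missing:
            raise ConsistencyError(
                f"edge regulators outside regulator_universe: {sorted(missing)}"
            )
        object.__setattr__(self, "regulator_universe", universe)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class CandidateEdgeUniverse:
    """The ordered list of scoreable (regulator, target) pairs with labels.

    Edges are the full cross product regulator_universe x targets minus
    self-edges; ``labels[i]`` is 1 iff ``edges[i]`` is in the gold standard
    (closed-world assumption over the covered regulators).
    """

    edges: tuple[tuple[str, str], ...]
    regulators: tuple[str, ...]
    targets: tuple[str, ...]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=np.int8)
            if labels.shape != (len(self.edges),):
                raise GrnValidationError("labels length must match edges")
            object.__setattr__(self, "labels", labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self) -> dict[tuple[str, str], int]:
        return {e: i for i, e in enumerate(self.edges)}


def read_expression_matrix(
    path: str | Path,
    tf_list_path: str | Path,
    time_meta_path: str | Path | None = None,
) -> ExpressionDataset:
    """Read a delimited expression matrix plus TF list (and optional times).

    The matrix file has gene ids in the first column and a header row of
    sample ids; tab and comma delimiters are auto-detected (tab first).
    The TF list holds one gene id per line.  The time-metadata file has
    columns ``sample_id``, ``trajectory_id``, ``time_minutes``.
    """
    path = Path(path)
    first = path.open().readline()
    sep = _detect_delimiter(first)
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise GrnParseError(f"non-numeric cell in {path}: {exc}") from exc

    tf_ids = [
        line.strip()
        for line in Path(tf_list_path).read_text().splitlines()
        if line.strip()
    ]

    meta = None
    if time_meta_path is not None:
        tpath = Path(time_meta_path)
        tsep = _detect_delimiter(tpath.open().readline())
        meta = pd.read_csv(tpath, sep=tsep)
        needed = {"sample_id", "trajectory_id", "time_minutes"}
        if not needed.issubset(meta.columns):
            raise FormatError(
                f"time metadata must have columns {sorted(needed)}"
            )
        meta = meta.set_index("sample_id")
        meta.index = meta.index.astype(str)
        missing = [s for s in frame.columns if s not in meta.index]
        if missing:
            raise ConsistencyError(f"samples without time metadata: {missing}")
        meta = meta.loc[list(frame.columns), ["trajectory_id", "time_minutes"]]

    return ExpressionDataset(values=frame, tf_ids=tuple(tf_ids), sample_meta=meta)


def read_edge_list(
    path: str | Path, self_edges: str = "error"
) -> RegulatoryNetwork:
    """Read a BEELINE-style edge list: ``regulator<TAB>target`` per line.

    An optional third column (confidence) is ignored.  A header line whose
    first field is Gene1/regulator (case-insensitive) is skipped.  Duplicate
    lines collapse to one edge.  ``self_edges`` is ``"error"`` (default) or
    ``"skip"`` to drop self-edges with a warning.
    """
    if self_edges not in ("error", "skip"):
        raise ValueError("self_edges must be 'error' or 'skip'")
    edges: set[tuple[str, str]] = set()
    lines = Path(path).read_text().splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        sep = _detect_delimiter(line)
        parts = [p.strip() for p in line.split(sep)]
        if lineno == 1 and parts[0].lower() in ("gene1", "regulator", "tf"):
            continue
        if len(parts) < 2 or not parts[1]:
            raise GrnParseError(f"{path}:{lineno}: expected >=2 columns")
        reg, tgt = parts[0], parts[1]
        if reg == tgt:
            if self_edges == "error":
                raise GrnValidationError(
                    f"{path}:{lineno}: self-edge {reg}->{tgt}"
                )
            logger.warning("skipping self-edge %s->%s at line %d", reg, tgt, lineno)
            continue
        edges.add((reg, tgt))
    return RegulatoryNetwork(edges=frozenset(edges))


def write_ranked_edges(
    scored: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """Write a ranked-edge file (header ``Gene1 Gene2 EdgeWeight``, tab-sep).

    Rows are sorted by descending score; ties break lexicographically by
    (regulator, target).  Scores are written with ``repr`` so a read-back
    round-trips bit-exactly.
    """
    rows = []
    for reg, tgt, score in scored:
        score = float(score)
        if math.isnan(score) or math.isinf(score):
            raise GrnValidationError(f"non-finite score for edge {reg}->{tgt}")
        rows.append((reg, tgt, score))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with Path(path).open("w") as fh:
        fh.write("\t".join(RANKED_EDGES_HEADER) + "\n")
        for reg, tgt, score in rows:
            fh.write(f"{reg}\t{tgt}\t{score!r}\n")


def read_ranked_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a ranked-edge file produced by :func:`write_ranked_edges`."""
    out: list[tuple[str, str, float]] = []
    lines = Path(path).read_text().splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[0] == RANKED_EDGES_HEADER[0]:
            continue
        if len(parts) < 3:
            raise GrnParseError(f"{path}:{lineno}: expected 3 columns")
        try:
            score = float(parts[2])
        except ValueError as exc:
            raise GrnParseError(
                f"{path}:{lineno}: bad score {parts[2]!r}"
            ) from exc
        out.append((parts[0], parts[1], score))
    return out


def build_candidate_universe(
    ds: ExpressionDataset,
    gold: RegulatoryNetwork,
    include_tf_targets: bool = True,
) -> CandidateEdgeUniverse:
    """Cross gold-standard regulators with the dataset's genes, minus self-edges.

    Only regulators covered by the gold standard enter the universe; edges
    absent from the gold standard are labelled 0 (closed-world).  By default
    TFs may also appear as targets; set ``include_tf_targets=False`` to
    restrict targets to non-TF genes.
    """
    regulators = tuple(sorted(gold.regulator_universe))
    not_in_tfs = [r for r in regulators if r not in ds.tf_ids]
    if not_in_tfs:
        raise ConsistencyError(
            f"gold regulators not flagged as TFs in dataset: {not_in_tfs}"
        )
    if include_tf_targets:
        targets = tuple(ds.gene_ids)
    else:
        tfset = set(ds.tf_ids)
        targets = tuple(g for g in ds.gene_ids if g not in tfset)
    edges = tuple(
        (r, t) for r in regulators for t in targets if r != t
    )
    labels = np.fromiter(
        (1 if e in gold.edges else 0 for e in edges), dtype=np.int8, count=len(edges)
    )
    return CandidateEdgeUniverse(
        edges=edges, regulators=regulators, targets=targets, labels=labels
    )
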