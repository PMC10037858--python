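"""Synthetic GRN and time-series expression generator.

Emulates the style of the DREAM in-silico challenges: a random directed
network in which only transcription factors have outgoing edges drives a
deterministic Hill-kinetics ODE per gene,

    dx_g/dt = alpha_g * f_g(x_regulators) - lambda * x_g,

where ``f_g`` is a strength-weighted mean of Hill terms, ``h(x) =
x^n / (K^n + x^n)`` for activators and ``1 - h(x)`` for repressors, and
``f_g = 1`` for unregulated genes.  Each trajectory starts from the
unperturbed steady state with one randomly chosen TF knocked down
(its synthesis rate scaled into ``knockdown_range``), mimicking the
perturbation time courses of the DREAM challenges.  Samples are taken on a
regular grid and corrupted with multiplicative lognormal measurement noise.

The half-saturation constant ``hill_k`` is expressed as a fraction of the
unregulated steady-state level ``alpha / decay_rate``, so the Hill terms
operate in their responsive range regardless of the absolute expression
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, SimulationError
from .grn_data import ExpressionDataset, RegulatoryNetwork, write_ranked_edges

__all__ = [
    "SimulationConfig",
    "AnnotatedNetwork",
    "generate_network",
    "simulate_expression",
    "simulate",
    "write_simulation",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the network generator and ODE simulator.

    Defaults follow a DREAM4-like regime: 100-gene networks, time series of
    ~20 points at 50-minute spacing, 10 perturbation trajectories, 5%
    multiplicative measurement noise.
    """

    n_genes: int = 100
    n_tfs: int = 10
    mean_out_degree: float = 3.0
    interval_minutes: float = 50.0
    horizon_minutes: float = 1000.0
    n_trajectories: int = 10
    noise_sd: float = 0.05
    hill_coefficient: float = 2.0
    hill_k: float = 0.5  # fraction of the unregulated steady state alpha/decay
    alpha: float = 1.0
    decay_rate: float = 0.02  # per minute
    activator_prob: float = 0.7
    strength_range: tuple[float, float] = (0.5, 2.0)
    knockdown_range: tuple[float, float] = (0.0, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 1:
            raise ConfigError("n_tfs must be >= 1")
        if self.n_tfs > self.n_genes:
            raise ConfigError("n_tfs cannot exceed n_genes")
        if self.horizon_minutes < self.interval_minutes:
            raise ConfigError("horizon_minutes must be >= interval_minutes")
        for name in ("interval_minutes", "horizon_minutes", "hill_coefficient",
                     "hill_k", "alpha", "decay_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.mean_out_degree < 0:
            raise ConfigError("mean_out_degree must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.n_trajectories < 1:
            raise ConfigError("n_trajectories must be >= 1")


@dataclass(frozen=True)
class AnnotatedNetwork:
    """A regulatory network with per-edge sign and strength annotations."""

    network: RegulatoryNetwork
    signs: dict[tuple[str, str], int] = field(default_factory=dict)  # +1/-1
    strengths: dict[tuple[str, str], float] = field(default_factory=dict)


def _gene_names(cfg: SimulationConfig) -> list[str]:
    width = max(3, len(str(cfg.n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]


def generate_network(cfg: SimulationConfig) -> AnnotatedNetwork:
    """Draw a random directed network in which only TFs have outgoing edges.

    Each TF->gene pair (excluding self-edges) is included independently with
    probability ``mean_out_degree / (n_genes - 1)``; included edges are
    activators with probability ``activator_prob`` and carry a strength
    drawn uniformly from ``strength_range``.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg)
    tfs = genes[: cfg.n_tfs]
    p = 0.0
    if cfg.n_genes > 1:
        p = min(1.0, cfg.mean_out_degree / (cfg.n_genes - 1))
    edges: set[tuple[str, str]] = set()
    signs: dict[tuple[str, str], int] = {}
    strengths: dict[tuple[str, str], float] = {}
    for tf in tfs:
        for gene in genes:
            if gene == tf:
                continue
            if rng.random() < p:
                edge = (tf, gene)
                edges.add(edge)
                signs[edge] = 1 if rng.random() < cfg.activator_prob else -1
                lo, hi = cfg.strength_range
                strengths[edge] = float(rng.uniform(lo, hi))
    net = RegulatoryNetwork(edges=frozenset(edges), regulator_universe=frozenset(tfs))
    return AnnotatedNetwork(network=net, signs=signs, strengths=strengths)


def _build_kinetics(annotated: AnnotatedNetwork, cfg: SimulationConfig):
    """Precompute dense weight matrices for the vectorised ODE right-hand side."""
    genes = _gene_names(cfg)
    gidx = {g: i for i, g in enumerate(genes)}
    n = cfg.n_genes
    w_act = np.zeros((n, n))
    w_rep = np.zeros((n, n))
    for (reg, tgt), sign in annotated.signs.items():
        w = annotated.strengths[(reg, tgt)]
        if sign > 0:
            w_act[gidx[tgt], gidx[reg]] = w
        else:
            w_rep[gidx[tgt], gidx[reg]] = w
    wsum = w_act.sum(axis=1) + w_rep.sum(axis=1)
    regulated = wsum > 0
    k_abs = cfg.hill_k * cfg.alpha / cfg.decay_rate
    n_hill = cfg.hill_coefficient

    def rhs(x: np.ndarray, alpha_vec: np.ndarray) -> np.ndarray:
        # x and alpha_vec may be (n,) or (n, n_trajectories)
        xp = np.maximum(x, 0.0) ** n_hill
        h = xp / (k_abs**n_hill + xp)
        f = np.ones_like(h)
        agg = w_act @ h + w_rep @ (1.0 - h)
        f[regulated] = (agg[regulated].T / wsum[regulated]).T
        return alpha_vec * f - cfg.decay_rate * x

    return genes, rhs


def _rk4(x, rhs, alpha_vec, t_end, dt):
    """Fixed-step classical Runge-Kutta over [0, t_end]; returns final state."""
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        k1 = rhs(x, alpha_vec)
        k2 = rhs(x + 0.5 * dt * k1, alpha_vec)
        k3 = rhs(x + 0.5 * dt * k2, alpha_vec)
        k4 = rhs(x + dt * k3, alpha_vec)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        x = np.maximum(x, 0.0)
    return x


def simulate_expression(
    annotated: AnnotatedNetwork, cfg: SimulationConfig
) -> ExpressionDataset:
    """Integrate the Hill-kinetics ODE and sample noisy time series.

    Returns an :class:`ExpressionDataset` with ``n_trajectories`` time
    courses sampled at ``t = 0, dt, 2*dt, ... <= horizon`` and trajectory /
    time metadata attached.  Deterministic given ``cfg.seed``; with
    ``noise_sd = 0`` the output is the exact (noise-free) ODE solution at
    the sample times.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_919]))
    genes, rhs = _build_kinetics(annotated, cfg)
    n = cfg.n_genes
    alpha_vec = np.full(n, cfg.alpha)
    dt = min(0.5, cfg.interval_minutes / 20.0)

    # Relax to the unperturbed fixed point (burn-in ~100 decay time constants).
    x0 = np.full(n, 0.5 * cfg.alpha / cfg.decay_rate)
    burn = 100.0 / cfg.decay_rate
    x_star = _rk4(x0, rhs, alpha_vec, burn, 0.5)

    times = np.arange(0.0, cfg.horizon_minutes + 1e-9, cfg.interval_minutes)
    n_times = len(times)
    tf_indices = np.arange(cfg.n_tfs)

    # all trajectories integrated simultaneously: state is (n_genes, n_traj)
    n_traj = cfg.n_trajectories
    alphas = np.tile(alpha_vec[:, None], (1, n_traj))
    for traj in range(n_traj):
        tf_hit = int(rng.choice(tf_indices))
        lo, hi = cfg.knockdown_range
        alphas[tf_hit, traj] *= float(rng.uniform(lo, hi))
    traj_ids = [f"traj{traj:02d}" for traj in range(n_traj)]

    snapshots = np.empty((n_times, n, n_traj))
    x = np.tile(x_star[:, None], (1, n_traj))
    for it, t in enumerate(times):
        if it > 0:
            x = _rk4(x, rhs, alphas, cfg.interval_minutes, dt)
        if not np.all(np.isfinite(x)):
            bad_gene, bad_traj = np.argwhere(~np.isfinite(x))[0]
            raise SimulationError(
                f"non-finite expression for gene {genes[bad_gene]} in "
                f"{traj_ids[bad_traj]} at t={t}"
            )
        snapshots[it] = x

    columns: list[str] = []
    meta_rows: list[tuple[str, float]] = []
    data = np.empty((n, n_traj * n_times))
    col = 0
    for traj in range(n_traj):
        for it, t in enumerate(times):
            data[:, col] = snapshots[it, :, traj]
            columns.append(f"{traj_ids[traj]}_t{int(round(t))}")
            meta_rows.append((traj_ids[traj], float(t)))
            col += 1

    if cfg.noise_sd > 0:
        noise = rng.normal(0.0, cfg.noise_sd, size=data.shape)
        data = data * np.exp(noise)

    values = pd.DataFrame(data, index=genes, columns=columns)
    meta = pd.DataFrame(
        meta_rows, index=columns, columns=["trajectory_id", "time_minutes"]
    )
    return ExpressionDataset(
        values=values, tf_ids=tuple(genes[: cfg.n_tfs]), sample_meta=meta
    )


def simulate(cfg: SimulationConfig) -> tuple[ExpressionDataset, AnnotatedNetwork]:
    """Generate a network and simulate expression from it in one call."""
    annotated = generate_network(cfg)
    ds = simulate_expression(annotated, cfg)
    return ds, annotated


def write_simulation(
    ds: ExpressionDataset,
    annotated: AnnotatedNetwork,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write matrix, TF list, time metadata and ground-truth edges to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "tfs": out / "tfs.txt",
        "time_meta": out / "time_meta.tsv",
        "gold": out / "gold_edges.tsv",
    }
    ds.values.to_csv(paths["expression"], sep="\t", index_label="gene")
    paths["tfs"].write_text("\n".join(ds.tf_ids) + "\n")
    meta = ds.sample_meta.reset_index(names="sample_id")
    meta.to_csv(paths["time_meta"], sep="\t", index=False)
    scored = [
        (r, t, annotated.strengths.get((r, t), 1.0))
        for (r, t) in sorted(annotated.network.edges)
    ]
    write_ranked_edges(scored, paths["gold"])
    return paths
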