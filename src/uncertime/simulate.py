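"""Synthetic single-cell datasets with known pseudotime ground truth.

Every downstream stage (embedding, trajectory posterior, switch-model
differential expression, robustness classification) is tested against data
generated here, where the true pseudotimes, the true 2-D trajectory and the
identity and parameters of every switch gene are known.

The generative world mimics the structure of published scRNA-seq
differentiation datasets: N ~ 100-400 cells on a smooth non-self-intersecting
1-D curve embedded in two dimensions with isotropic cell-to-cell noise, and
log2 expression in which a fraction of genes follows a sigmoidal switch
across pseudotime while the rest fluctuate around a constant mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .embed import Embedding, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "trajectory_curve",
    "simulate_pseudotimes",
    "simulate_embedding",
    "simulate_expression",
    "simulate_dataset",
]


class InvalidConfigError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic world.

    Defaults describe a mid-sized differentiation experiment: 150 cells,
    200 genes of which 20% switch sigmoidally, moderate embedding scatter
    and log2-expression noise of 0.5 (the level used in the noisy-recovery
    checks).  Switch genes get activation strengths strong enough to be
    visually switch-like (|k| in [5, 20]), activation times away from the
    trajectory ends, and half-peak expressions in [1, 4] log2 units.
    """

    n_cells: int = 150
    n_genes: int = 200
    frac_switch: float = 0.2
    noise_sd_embedding: float = 0.05
    noise_sd_expression: float = 0.5
    k_range: tuple[float, float] = (5.0, 20.0)
    t0_range: tuple[float, float] = (0.2, 0.8)
    mu0_range: tuple[float, float] = (1.0, 4.0)
    pseudotime_mode: str = "uniform"
    mu_t: float = 0.5
    sigma_t: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise InvalidConfigError("n_cells must be >= 2")
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be >= 1")
        if not 0.0 <= self.frac_switch <= 1.0:
            raise InvalidConfigError("frac_switch must be in [0, 1]")
        if self.noise_sd_embedding < 0 or self.noise_sd_expression < 0:
            raise InvalidConfigError("noise standard deviations must be >= 0")
        for name in ("k_range", "t0_range", "mu0_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise InvalidConfigError(f"{name} must be a non-empty interval")
        lo, hi = self.t0_range
        if lo < 0 or hi > 1:
            raise InvalidConfigError("t0_range must lie within [0, 1]")
        if self.pseudotime_mode not in ("uniform", "truncnorm"):
            raise InvalidConfigError("pseudotime_mode must be 'uniform' or 'truncnorm'")
        if self.sigma_t <= 0:
            raise InvalidConfigError("sigma_t must be > 0")


@dataclass(frozen=True)
class SyntheticDataset:
    truth_pseudotimes: np.ndarray
    expression: ExpressionMatrix
    embedding: Embedding
    truth_labels: "object"  # pandas DataFrame: gene, is_switch, mu0, k, t0


def trajectory_curve(t: np.ndarray) -> np.ndarray:
    """Mean trajectory: a half-circle arc scaled to the unit box.

    t in [0, 1) maps to ((1 + cos(pi t)) / 2, sin(pi t)) — smooth and
    non-self-intersecting, so both graph-based (MST) and GP-based fits apply.
    """
    t = np.asarray(t, dtype=float)
    return np.column_stack([(1.0 + np.cos(np.pi * t)) / 2.0, np.sin(np.pi * t)])


def simulate_pseudotimes(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw N true pseudotimes in [0, 1), uniformly or truncated-normally."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    if config.pseudotime_mode == "uniform":
        t = rng.uniform(0.0, 1.0, size=n)
    else:
        a = (0.0 - config.mu_t) / config.sigma_t
        b = (1.0 - config.mu_t) / config.sigma_t
        t = truncnorm.rvs(
            a, b, loc=config.mu_t, scale=config.sigma_t, size=n, random_state=rng
        )
    return np.clip(t, 0.0, np.nextafter(1.0, 0.0))


def simulate_embedding(
    t: np.ndarray, config: SimulationConfig, rng: np.random.Generator | None = None
) -> Embedding:
    """Place cells on the trajectory curve at their pseudotimes plus
    isotropic Gaussian noise of sd ``noise_sd_embedding``."""
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t >= 1)):
        raise ValueError("pseudotimes must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    coords = trajectory_curve(t)
    coords = coords + rng.normal(0.0, config.noise_sd_embedding, size=coords.shape)
    cell_ids = tuple(f"cell_{i:04d}" for i in range(len(t)))
    return Embedding(coords, cell_ids, method_tag="synthetic")


def _sigmoid_mean(mu0: float, k: float, t0: float, t: np.ndarray) -> np.ndarray:
    from .switchde import sigmoid_mean

    return sigmoid_mean(mu0, k, t0, t)


def simulate_expression(
    t: np.ndarray, config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Simulate the G x N log2 expression matrix and its truth table.

    Exactly round(frac_switch * n_genes) genes follow the sigmoidal switch
    mean 2*mu0 / (1 + exp(-k (t - t0))); the rest sit at the constant mean
    mu0.  Gaussian noise of sd ``noise_sd_expression`` is added and the
    result clamped at 0 (log2(counts + 1) data are nonnegative).

    Returns ``(ExpressionMatrix, truth)`` where ``truth`` is a DataFrame
    with columns gene, is_switch, mu0, k, t0 (k = 0, t0 = NaN for constant
    genes).
    """
    import pandas as pd

    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t >= 1)):
        raise ValueError("pseudotimes must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    G, N = config.n_genes, len(t)
    n_switch = int(round(config.frac_switch * G))
    switch_idx = rng.choice(G, size=n_switch, replace=False)
    is_switch = np.zeros(G, dtype=bool)
    is_switch[switch_idx] = True

    mu0 = rng.uniform(*config.mu0_range, size=G)
    k = np.zeros(G)
    t0 = np.full(G, np.nan)
    k[is_switch] = rng.uniform(*config.k_range, size=n_switch) * rng.choice(
        [-1.0, 1.0], size=n_switch
    )
    t0[is_switch] = rng.uniform(*config.t0_range, size=n_switch)

    mean = np.empty((G, N))
    for g in range(G):
        if is_switch[g]:
            mean[g] = _sigmoid_mean(mu0[g], k[g], t0[g], t)
        else:
            mean[g] = mu0[g]
    values = mean + rng.normal(0.0, config.noise_sd_expression, size=(G, N))
    values = np.clip(values, 0.0, None)

    gene_ids = tuple(f"gene_{g:04d}" for g in range(G))
    cell_ids = tuple(f"cell_{i:04d}" for i in range(N))
    E = ExpressionMatrix(values, gene_ids, cell_ids)
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "is_switch": is_switch,
            "mu0": mu0,
            "k": k,
            "t0": t0,
        }
    )
    return E, truth


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset (pseudotimes, embedding,
    expression, truth table) from a single seed."""
    rng = np.random.default_rng(config.seed)
    t = simulate_pseudotimes(config, rng)
    X = simulate_embedding(t, config, rng)
    E, truth = simulate_expression(t, config, rng)
    return SyntheticDataset(truth_pseudotimes=t, expression=E, embedding=X, truth_labels=truth)
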