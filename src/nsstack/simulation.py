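"""Synthetic data generator for the six benchmark scenarios.

Each dataset has N samples and M continuous features drawn from a
block-structured multivariate normal: features are laid out in
contiguous blocks of size M / n_groups with compound-symmetry
correlation r = 0.6 inside a block and independence between blocks
(sampled via the factor construction x = sqrt(r) g_block + sqrt(1-r) e,
so no M x M covariance matrix is ever materialized).  A sparse signed
coefficient vector beta (eight non-zeros, in blocks 1, 5 and 20)
defines the linear predictor mu_n; a latent Gaussian response
z_n ~ N(mu_n, sigma^2) is dichotomized at its median — the N/2 largest
z are labelled 1 — giving exactly 50% prevalence.

The six scenarios differ in the coefficient set (scenarios 1-3 share
one, 4-6 the other) and the residual SD sigma, which calibrates the
nominal generalized R^2 of the data to 0.50 / 0.25 / 0.10 within each
coefficient set:

==========  ====================================  =====  ==========
scenario    non-zero beta (indices 5, 20, 40,     sigma  nominal R2
            210, 220, 240, 975, 995; 1-based)
==========  ====================================  =====  ==========
1           0.8 -0.7 1.0 -0.9 -0.8 0.9 -1.0 0.7   1.60   0.50
2           (same)                                2.60   0.25
3           (same)                                4.50   0.10
4           0.8 -0.3 1.4 -0.9 -0.8 0.9 -1.5 0.2   1.80   0.50
5           (same)                                3.10   0.25
6           (same)                                5.50   0.10
==========  ====================================  =====  ==========

Feature groups default to the 20 contiguous 50-feature blocks extended
by a 5-feature forward overlap into the next block (the last group has
no extension); overlap affects group membership only, never the
covariance.  The non-zero coefficients therefore fall in groups 1, 5
and 20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stacking import GroupStructure

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "SCENARIOS",
    "NONZERO_INDICES",
    "default_groups",
    "block_covariance",
    "BlockCovariance",
    "simulate_scenario",
]

# 1-based indices of the non-zero coefficients (blocks 1, 5, 20)
NONZERO_INDICES = (5, 20, 40, 210, 220, 240, 975, 995)

_COEF_SET_1 = (0.80, -0.70, 1.00, -0.90, -0.80, 0.90, -1.00, 0.70)
_COEF_SET_2 = (0.80, -0.30, 1.40, -0.90, -0.80, 0.90, -1.50, 0.20)

# scenario id -> (coefficient set, residual SD sigma, nominal generalized R^2)
SCENARIOS: dict[int, tuple[tuple[float, ...], float, float]] = {
    1: (_COEF_SET_1, 1.60, 0.50),
    2: (_COEF_SET_1, 2.60, 0.25),
    3: (_COEF_SET_1, 4.50, 0.10),
    4: (_COEF_SET_2, 1.80, 0.50),
    5: (_COEF_SET_2, 3.10, 0.25),
    6: (_COEF_SET_2, 5.50, 0.10),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulation scenario."""

    scenario_id: int
    N: int = 500
    M: int = 1000
    n_groups: int = 20
    within_r: float = 0.6
    sigma: float = 0.0
    beta_values: tuple[float, ...] = ()
    beta_indices: tuple[int, ...] = NONZERO_INDICES
    beta0: float = 0.0
    target_r2: float = 0.0
    overlap: int = 5

    @classmethod
    def from_id(cls, scenario_id: int, N: int = 500, M: int = 1000,
                overlap: int = 5) -> "ScenarioSpec":
        if scenario_id not in SCENARIOS:
            raise ValueError(f"scenario_id must be 1..6, got {scenario_id}")
        coefs, sigma, r2 = SCENARIOS[scenario_id]
        return cls(scenario_id=scenario_id, N=N, M=M, sigma=sigma,
                   beta_values=coefs, target_r2=r2, overlap=overlap)

    def __post_init__(self) -> None:
        if self.beta_indices and max(self.beta_indices) > self.M:
            raise ValueError(
                f"non-zero coefficient index {max(self.beta_indices)} "
                f"exceeds M={self.M}"
            )

    @property
    def beta(self) -> np.ndarray:
        """Dense length-M coefficient vector (0-based internally)."""
        b = np.zeros(self.M)
        for idx, val in zip(self.beta_indices, self.beta_values):
            b[idx - 1] = val
        return b


@dataclass
class SimulatedDataset:
    """One simulated draw: features, latent response, binary outcome, truth."""

    X: np.ndarray
    z: np.ndarray
    y: np.ndarray
    mu: np.ndarray
    groups: GroupStructure
    true_beta: np.ndarray
    feature_names: list[str]
    seed: int
    spec: ScenarioSpec | None = None


def feature_name(i: int) -> str:
    """1-based feature identifier, e.g. ``x5``."""
    return f"x{i}"


def default_groups(M: int = 1000, n_groups: int = 20, overlap: int = 5) -> GroupStructure:
    """Contiguous blocks of M/n_groups features, each extended by the first
    ``overlap`` features of the following block (the last group is not
    extended).  Feature identifiers are 1-based (``x1`` .. ``xM``)."""
    if M % n_groups != 0:
        raise ValueError("n_groups must divide M")
    block = M // n_groups
    if overlap >= block:
        raise ValueError("overlap must be smaller than the block size")
    groups = {}
    for g in range(n_groups):
        start = g * block + 1
        stop = (g + 1) * block
        members = list(range(start, stop + 1))
        if overlap and g < n_groups - 1:
            members += list(range(stop + 1, stop + overlap + 1))
        groups[f"group{g + 1}"] = [feature_name(i) for i in members]
    return GroupStructure(groups)


@dataclass(frozen=True)
class BlockCovariance:
    """Unit-variance compound-symmetry blocks: corr r within a block of
    ``block_size`` consecutive features, zero between blocks."""

    M: int
    block_size: int
    r: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r < 1.0):
            raise ValueError("r must lie in [0, 1)")
        if self.M % self.block_size != 0:
            raise ValueError("block_size must divide M")

    @property
    def n_blocks(self) -> int:
        return self.M // self.block_size

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n rows via x = sqrt(r) g_block + sqrt(1 - r) e."""
        e = rng.standard_normal((n, self.M))
        if self.r == 0.0:
            return e
        g = rng.standard_normal((n, self.n_blocks))
        shared = np.repeat(g, self.block_size, axis=1)
        return np.sqrt(self.r) * shared + np.sqrt(1.0 - self.r) * e


def block_covariance(M: int, block_size: int, r: float) -> BlockCovariance:
    """Factor-form description of the block compound-symmetry covariance."""
    return BlockCovariance(M=M, block_size=block_size, r=r)


def simulate_scenario(spec: ScenarioSpec | int, seed: int = 0,
                      N: int | None = None) -> SimulatedDataset:
    """Simulate one dataset for a scenario (id or full spec).

    The binary outcome labels the N/2 samples with the largest latent z
    as 1 (ties, probability zero for continuous z, would resolve in
    favour of the lower index), so prevalence is exactly 0.5 for even N.
    """
    if isinstance(spec, int):
        spec = ScenarioSpec.from_id(spec)
    n = N if N is not None else spec.N
    rng = np.random.default_rng(seed)
    cov = block_covariance(spec.M, spec.M // spec.n_groups, spec.within_r)
    X = cov.sample(n, rng)
    beta = spec.beta
    mu = spec.beta0 + X @ beta
    z = mu + spec.sigma * rng.standard_normal(n)
    # top half of z (stable order: lower index wins ties) -> positive
    order = np.argsort(-z, kind="stable")
    y = np.zeros(n)
    y[order[: n // 2]] = 1.0
    groups = default_groups(spec.M, spec.n_groups, spec.overlap)
    names = [feature_name(i + 1) for i in range(spec.M)]
    return SimulatedDataset(X=X, z=z, y=y, mu=mu, groups=groups,
                            true_beta=beta, feature_names=names,
                            seed=seed, spec=spec)
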