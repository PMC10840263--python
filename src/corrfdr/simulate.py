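"""Monte-Carlo harness: equicorrelated two-group Gaussian screening study.

Each replication draws P random standardized effect sizes
``delta ~ N(0, sigma2_delta * I)``, then n1 case samples from
``MVN(delta, (1-rho) I + rho J)`` and n2 control samples from
``MVN(0, (1-rho) I + rho J)`` — compound symmetry, all off-diagonal
feature correlations equal to rho.  The covariance is realised by the
one-factor construction

    x = delta * group + sqrt(rho) * g * 1 + sqrt(1-rho) * eps

with a scalar standard-normal factor ``g`` per sample and i.i.d.
standard-normal ``eps`` per entry, which is exact for this structure
and avoids factorising a P x P matrix.

The replicate is screened end to end (t-tests, sort, neighbour
correlations estimated from the replicate's own data, ladders, max-k)
and the per-procedure discovery counts are aggregated over
replications.  Replication r uses an RNG stream spawned from
``(seed, r)``, so results are independent of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidArgumentError
from .procedures import PROCEDURES, M_PROCEDURES
from .screening import FeatureMatrix, FdrScreen

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "generate_replicate",
    "run_study",
    "run_grid",
    "power_formula",
]

#: column label for the unadjusted (p <= alpha) discovery count
UNADJUSTED = "Non"


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of the generation-and-screening scheme.

    Defaults are the study conditions: P=1000 features, 100 samples per
    group, effect-size variance 0.0678 (chosen so the Bonferroni count
    stays below 5% of the features, i.e. strong FWER control), alpha
    0.05, 1000 replications.
    """

    P: int = 1000
    n1: int = 100
    n2: int = 100
    sigma2_delta: float = 0.0678
    rho: float = 0.0
    alpha: float = 0.05
    reps: int = 1000
    seed: int = 0
    procedures: tuple = PROCEDURES
    centering: str = "none"
    freeze_delta: bool = False  # one delta shared by all replications
    use_true_rho: bool = False  # oracle correlations instead of estimates

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise InvalidArgumentError(
                f"rho must lie in [0, 1) (the equicorrelation structure is "
                f"not PSD in general otherwise), got {self.rho}"
            )
        if self.sigma2_delta < 0:
            raise InvalidArgumentError("sigma2_delta must be >= 0")
        if self.reps < 1:
            raise InvalidArgumentError("reps must be >= 1")
        if self.P < 1 or self.n1 < 2 or self.n2 < 2:
            raise InvalidArgumentError("need P >= 1 and at least 2 samples per group")
        if not (0.0 < self.alpha < 1.0):
            raise InvalidArgumentError("alpha must lie in (0, 1)")
        object.__setattr__(self, "procedures",
                           tuple(p.upper() for p in self.procedures))

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(mapping) - known
        if unknown:
            raise InvalidArgumentError(
                f"unknown simulation config field {sorted(unknown)[0]!r}"
            )
        return cls(**mapping)


def _draw_delta(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(config.sigma2_delta), size=config.P)


def generate_replicate(
    config: SimulationConfig,
    rng: np.random.Generator,
    delta: np.ndarray | None = None,
) -> FeatureMatrix:
    """One synthetic samples x features matrix under the scheme above.

    ``delta`` overrides the per-replicate effect draw (used when effects
    are frozen across replications).
    """
    if delta is None:
        delta = _draw_delta(config, rng)
    n = config.n1 + config.n2
    group = np.concatenate([np.ones(config.n1, int), np.zeros(config.n2, int)])
    g = rng.standard_normal(n)  # shared factor, one per sample
    eps = rng.standard_normal((n, config.P))
    values = (
        group[:, None] * delta[None, :]
        + math.sqrt(config.rho) * g[:, None]
        + math.sqrt(1.0 - config.rho) * eps
    )
    return FeatureMatrix.from_arrays(values, group)


@dataclass(frozen=True)
class SimulationSummary:
    """Per-procedure discovery-count distribution over replications."""

    config: SimulationConfig
    counts: pd.DataFrame  # reps x (Non + procedures)

    def stats(self) -> pd.DataFrame:
        """Tidy summary: one row per procedure (and unadjusted)."""
        rows = []
        for col in self.counts.columns:
            x = self.counts[col].to_numpy(dtype=float)
            rows.append({
                "rho": self.config.rho,
                "procedure": col,
                "mean": x.mean(),
                "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                "q1": float(np.quantile(x, 0.25)),
                "median": float(np.quantile(x, 0.5)),
                "q3": float(np.quantile(x, 0.75)),
                "reps": self.config.reps,
                "seed": self.config.seed,
            })
        return pd.DataFrame(rows)

    def mean(self) -> pd.Series:
        return self.counts.mean()


def _replicate_counts(config: SimulationConfig, rng, delta=None) -> dict:
    matrix = generate_replicate(config, rng, delta)
    correlations = (
        np.full(config.P - 1, config.rho) if config.use_true_rho else None
    )
    fit = FdrScreen(matrix).fit(
        alpha=config.alpha,
        procedures=config.procedures,
        centering=config.centering,
        correlations=correlations,
    )
    counts = {UNADJUSTED: int((fit.sorted_input.p_sorted <= config.alpha).sum())}
    counts.update(fit.k)
    return counts


def run_study(config: SimulationConfig) -> SimulationSummary:
    """Replicated generate-and-screen study, deterministic given seed.

    Replication r draws from a child stream spawned as ``(seed, r)``,
    so individual replications can be recomputed in isolation and the
    aggregate does not depend on execution order.
    """
    root = np.random.SeedSequence(config.seed)
    frozen = None
    if config.freeze_delta:
        frozen = _draw_delta(config, np.random.default_rng(root.spawn(1)[0]))
    rows = []
    for r in range(config.reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1, r))
        )
        rows.append(_replicate_counts(config, rng, frozen))
    counts = pd.DataFrame(rows, columns=[UNADJUSTED, *config.procedures])
    counts.index.name = "replication"
    return SimulationSummary(config, counts)


def run_grid(config: SimulationConfig, rhos: Sequence[float]) -> pd.DataFrame:
    """run_study over a rho grid; concatenated tidy summary table."""
    frames = [run_study(replace(config, rho=float(r))).stats() for r in rhos]
    return pd.concat(frames, ignore_index=True)


def power_formula(delta: float, n: float, alpha: float) -> float:
    """Normal-approximation screening power, evaluated verbatim:

        1 - beta = 2 * (1 - Phi(delta * sqrt(n/2) - z_{1-alpha/2}))

    Convenience utility only.  Note this expression is not bounded by 1
    (delta=0, alpha=0.05 gives ~1.95): it doubles the upper-tail power
    of a two-sided z-test without subtracting the lower-tail term, so
    treat it as a rough large-effect approximation, not a probability.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidArgumentError("alpha must lie in (0, 1)")
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(2.0 * (1.0 - stats.norm.cdf(delta * math.sqrt(n / 2.0) - z)))
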