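"""Threshold ladders, adjusted p-values and step-up rejection rules.

Six multiple-comparison procedures are implemented through a single
"threshold ladder" abstraction.  A procedure assigns each rank ``i`` of
the ascending sorted p-values a multiplier ``l_i``; the sorted p-value
``p_(i)`` is compared against the threshold ``l_i * alpha / P_eff``
where ``P_eff = P`` except for Benjamini–Yekutieli, which inflates the
denominator by the harmonic constant ``C(P)``.

========  =========================================================
BF        Bonferroni: ``l_i = 1`` for all ranks (constant threshold)
BH        Benjamini–Hochberg: ``l_i = i``
BY        Benjamini–Yekutieli: ``l_i = i``, denominator ``P * C(P)``
M1        strong modification:   ``l_i = l_{i-1} + (1-|r_i|)/(1+|r_i|)``
M2        moderate modification: ``l_i = l_{i-1} + (1-|r_i|)``
M3        mild modification:     ``l_i = l_{i-1} + (1-r_i^2)``
========  =========================================================

The M-procedures discount each rank's contribution to the ladder by the
conditional Fisher information that the rank-``i`` test statistic adds
beyond its predecessor, given the Pearson correlation ``r_i`` between
the two features occupying consecutive ranks.  Independent neighbours
(``r_i = 0``) contribute a full unit and the ladders collapse to BH;
perfectly collinear neighbours (``|r_i| = 1``) contribute nothing and
the ladders collapse to Bonferroni.

Rejection uses the step-up (max-k) rule: reject the hypotheses of the
``k`` smallest p-values, where ``k`` is the largest rank whose sorted
p-value lies at or below its threshold — even if some intermediate rank
exceeds its own threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, InvalidArgumentError

__all__ = [
    "PROCEDURES",
    "M_PROCEDURES",
    "SortedScreenInput",
    "ThresholdLadder",
    "ScreenResult",
    "harmonic_constant",
    "increment",
    "build_ladder",
    "adjust_pvalues",
    "reject",
    "screen_sorted",
]

#: canonical procedure order used everywhere (tables, CLI, summaries)
PROCEDURES = ("BF", "BH", "BY", "M1", "M2", "M3")

#: the correlation-modified procedures and their assumption strength
M_PROCEDURES: Mapping[str, str] = {"M1": "strong", "M2": "moderate", "M3": "mild"}

#: correlations within this distance outside [-1, 1] are clamped
CLAMP_TOL = 1e-12


def harmonic_constant(P: int) -> float:
    """P-th harmonic number ``C(P) = sum_{i=1..P} 1/i``.

    This is the Benjamini–Yekutieli correction constant for arbitrary
    dependence.  Summation runs from the smallest term upward so the
    partial sums stay accurate for large ``P``.
    """
    if isinstance(P, bool) or not isinstance(P, (int, np.integer)):
        raise InvalidArgumentError(f"P must be a positive integer, got {P!r}")
    if P < 1:
        raise InvalidArgumentError(f"P must be >= 1, got {P}")
    return math.fsum(1.0 / i for i in range(P, 0, -1))


def _clamp_correlations(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.isnan(r).any():
        raise InvalidArgumentError("correlations contain NaN")
    over = np.abs(r) - 1.0
    if (over > CLAMP_TOL).any():
        bad = float(r[np.argmax(over)])
        raise InvalidArgumentError(
            f"correlation {bad} lies outside [-1, 1] beyond clamp tolerance"
        )
    return np.clip(r, -1.0, 1.0)


def increment(r, mode: str):
    """Conditional Fisher-information increment for one ladder step.

    Parameters
    ----------
    r : float or array-like
        Pearson correlation(s) between the features at consecutive
        ranks, in [-1, 1] (values within 1e-12 outside are clamped).
    mode : {"strong", "moderate", "mild"}
        Assumption strength: ``strong`` gives ``(1-|r|)/(1+|r|)``,
        ``moderate`` gives ``1-|r|``, ``mild`` gives ``1-r**2``.

    Returns
    -------
    float or ndarray in [0, 1]; for every r, strong <= moderate <= mild.
    """
    scalar = np.isscalar(r) or getattr(r, "ndim", 1) == 0
    a = np.abs(_clamp_correlations(np.atleast_1d(r)))
    if mode == "strong":
        out = (1.0 - a) / (1.0 + a)
    elif mode == "moderate":
        out = 1.0 - a
    elif mode == "mild":
        out = 1.0 - a * a
    else:
        raise InvalidArgumentError(
            f"mode must be one of strong/moderate/mild, got {mode!r}"
        )
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class SortedScreenInput:
    """Ascending sorted p-values with consecutive-rank correlations.

    Attributes
    ----------
    p_sorted : ndarray, shape (P,)
        p-values in non-decreasing order, all in [0, 1].
    feature_ids : ndarray, shape (P,)
        Original feature identifier occupying each rank.
    r_consecutive : ndarray, shape (P-1,), optional
        Entry ``i-2`` (0-based) is the Pearson correlation between the
        features at ranks ``i-1`` and ``i`` for ``i = 2..P``.  Only
        required by the M-procedures.
    """

    p_sorted: np.ndarray
    feature_ids: np.ndarray
    r_consecutive: np.ndarray | None = None

    def __post_init__(self):
        p = np.asarray(self.p_sorted, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise InvalidArgumentError("p_sorted must be a non-empty 1-d array")
        if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
            raise InvalidArgumentError("p-values must be finite and in [0, 1]")
        if (np.diff(p) < 0).any():
            raise InvalidArgumentError("p_sorted must be non-decreasing")
        ids = np.asarray(self.feature_ids)
        if ids.shape != p.shape:
            raise InvalidArgumentError("feature_ids must match p_sorted in length")
        if len(set(ids.tolist())) != ids.size:
            raise InvalidArgumentError("feature_ids must be unique")
        object.__setattr__(self, "p_sorted", p)
        object.__setattr__(self, "feature_ids", ids)
        if self.r_consecutive is not None:
            r = _clamp_correlations(self.r_consecutive)
            if r.shape != (p.size - 1,):
                raise InvalidArgumentError(
                    f"r_consecutive must have length P-1 = {p.size - 1}, "
                    f"got {r.shape}"
                )
            object.__setattr__(self, "r_consecutive", r)

    @property
    def P(self) -> int:
        return int(self.p_sorted.size)

    @classmethod
    def from_pvalues(cls, p, r=None, feature_ids=None) -> "SortedScreenInput":
        """Build from an already-sorted p-value sequence (adjust-only mode)."""
        p = np.asarray(p, dtype=float)
        if feature_ids is None:
            feature_ids = np.arange(1, p.size + 1)
        return cls(p, np.asarray(feature_ids), r)


@dataclass(frozen=True)
class ThresholdLadder:
    """Per-rank multipliers and rejection thresholds for one procedure."""

    procedure: str
    alpha: float
    multipliers: np.ndarray
    thresholds: np.ndarray

    @property
    def P(self) -> int:
        return int(self.thresholds.size)


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of one procedure on one sorted input.

    ``adjusted_p`` is the pointwise ratio ``p_(i) * P_eff / l_i``; it is
    deliberately not monotonicity-enforced and not capped at 1, so that
    ``adjusted_p[i] <= alpha``  iff  ``p_(i) <= threshold[i]`` holds
    rank by rank.  ``adjusted_p_monotone`` (optional) applies a running
    minimum from the largest rank downward and caps at 1, the
    conventional step-up reporting.  Rejection always comes from the
    max-k rule, never from pointwise adjusted-p comparison.
    """

    procedure: str
    k: int
    rejected_ids: np.ndarray
    adjusted_p: np.ndarray
    ladder: ThresholdLadder
    adjusted_p_monotone: np.ndarray | None = None


def _require_procedure(procedure: str) -> str:
    proc = str(procedure).upper()
    if proc not in PROCEDURES:
        raise InvalidArgumentError(
            f"unknown procedure {procedure!r}; choose from {PROCEDURES}"
        )
    return proc


def build_ladder(inp: SortedScreenInput, alpha: float, procedure: str) -> ThresholdLadder:
    """Multipliers ``l_i`` and thresholds ``l_i * alpha / P_eff`` for one procedure."""
    proc = _require_procedure(procedure)
    if not (0.0 < alpha < 1.0):
        raise InvalidArgumentError(f"alpha must lie in (0, 1), got {alpha}")
    P = inp.P
    ranks = np.arange(1, P + 1, dtype=float)
    if proc == "BF":
        mult = np.ones(P)
        thresholds = np.full(P, alpha / P)
    elif proc == "BH":
        mult = ranks
        thresholds = ranks * alpha / P
    elif proc == "BY":
        mult = ranks
        thresholds = ranks * alpha / (P * harmonic_constant(P))
    else:
        if inp.r_consecutive is None:
            raise ConfigurationError(
                f"procedure {proc} needs consecutive correlations; none supplied"
            )
        inc = increment(inp.r_consecutive, M_PROCEDURES[proc]) if P > 1 else np.empty(0)
        mult = np.concatenate(([1.0], 1.0 + np.cumsum(inc)))
        thresholds = mult * alpha / P
    return ThresholdLadder(proc, float(alpha), mult, thresholds)


def adjust_pvalues(
    inp: SortedScreenInput,
    procedure: str,
    alpha: float = 0.05,
    monotone: bool = False,
) -> np.ndarray:
    """Adjusted p-values ``p_(i) * P_eff / l_i`` for one procedure.

    ``alpha`` only parameterises the underlying ladder; the adjusted
    values themselves are alpha-free.  With ``monotone=True`` a running
    minimum is taken from rank P down to rank 1 and values are capped
    at 1 (the conventional step-up report); the default is the raw
    pointwise ratio, which preserves the exact duality
    ``adjusted_p[i] <= alpha  <=>  p_(i) <= threshold[i]``.
    """
    ladder = build_ladder(inp, alpha, procedure)
    return _adjust_from_ladder(inp, ladder, monotone)


def _adjust_from_ladder(
    inp: SortedScreenInput, ladder: ThresholdLadder, monotone: bool = False
) -> np.ndarray:
    P = inp.P
    p_eff = P * harmonic_constant(P) if ladder.procedure == "BY" else float(P)
    adj = inp.p_sorted * p_eff / ladder.multipliers
    if monotone:
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
    return adj


def reject(inp: SortedScreenInput, ladder: ThresholdLadder,
           monotone_adjust: bool = False) -> ScreenResult:
    """Apply the step-up (max-k) rule of a ladder to its sorted input.

    ``k`` is the largest rank with ``p_(i) <= threshold_i`` under exact
    floating comparison; ranks 1..k are rejected even if an intermediate
    rank exceeds its own threshold.
    """
    if ladder.P != inp.P:
        raise InvalidArgumentError(
            f"ladder has P={ladder.P} but input has P={inp.P}"
        )
    hits = np.nonzero(inp.p_sorted <= ladder.thresholds)[0]
    k = int(hits[-1] + 1) if hits.size else 0
    adj = _adjust_from_ladder(inp, ladder)
    adj_mono = _adjust_from_ladder(inp, ladder, monotone=True) if monotone_adjust else None
    return ScreenResult(
        procedure=ladder.procedure,
        k=k,
        rejected_ids=inp.feature_ids[:k].copy(),
        adjusted_p=adj,
        ladder=ladder,
        adjusted_p_monotone=adj_mono,
    )


def screen_sorted(
    inp: SortedScreenInput,
    alpha: float = 0.05,
    procedures: Iterable[str] = PROCEDURES,
    monotone_adjust: bool = False,
) -> dict[str, ScreenResult]:
    """Run several procedures on one sorted input; keys in canonical order."""
    requested = {_require_procedure(p) for p in procedures}
    out = {}
    for proc in PROCEDURES:
        if proc in requested:
            out[proc] = reject(inp, build_ladder(inp, alpha, proc), monotone_adjust)
    return out
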