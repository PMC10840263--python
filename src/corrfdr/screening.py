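"""Two-group screening: pooled t-tests, sorted-neighbour correlations, model API.

The pipeline turns a samples x features matrix with a binary group
label into a :class:`~corrfdr.procedures.SortedScreenInput`:

1. per-feature pooled-variance two-sample t-test (two-sided, df = n1+n2-2);
2. stable ascending sort of the p-values, ties broken by original
   feature index;
3. Pearson correlation between the data columns of consecutively
   ranked features (the estimator of the neighbour correlation the
   M-procedures discount by).

The statsmodels-style entry point is :class:`FdrScreen` whose
``fit()`` returns an :class:`FdrScreenResults` object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DegenerateFeatureError,
    InvalidArgumentError,
)
from .procedures import (
    PROCEDURES,
    M_PROCEDURES,
    ScreenResult,
    SortedScreenInput,
    screen_sorted,
)

__all__ = [
    "FeatureMatrix",
    "TestResult",
    "FdrScreen",
    "FdrScreenResults",
    "pooled_t_test",
    "pooled_t_tests",
    "consecutive_correlations",
    "screen",
]

logger = logging.getLogger("corrfdr")


@dataclass(frozen=True)
class FeatureMatrix:
    """Validated samples x features matrix with a binary group label.

    ``group`` holds 1 for case samples and 0 for controls.  Missing
    values are a load-time error, never imputed.
    """

    values: np.ndarray
    group: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InvalidArgumentError("values must be a 2-d samples x features array")
        if np.isnan(v).any():
            rows, cols = np.nonzero(np.isnan(v))
            raise InvalidArgumentError(
                f"missing value at sample {self.sample_ids[rows[0]]!r}, "
                f"feature {self.feature_ids[cols[0]]!r}"
            )
        if not np.isfinite(v).all():
            raise InvalidArgumentError("values must be finite")
        g = np.asarray(self.group)
        if g.shape != (v.shape[0],) or not np.isin(g, (0, 1)).all():
            raise InvalidArgumentError("group must be a 0/1 label per sample row")
        g = g.astype(int)
        if g.sum() == 0 or g.sum() == g.size:
            raise InvalidArgumentError("both groups must be non-empty")
        fids = np.asarray(self.feature_ids)
        sids = np.asarray(self.sample_ids)
        if fids.shape != (v.shape[1],):
            raise InvalidArgumentError("feature_ids must match the number of columns")
        if sids.shape != (v.shape[0],):
            raise InvalidArgumentError("sample_ids must match the number of rows")
        if len(set(fids.tolist())) != fids.size:
            raise InvalidArgumentError("feature_ids must be unique")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "group", g)
        object.__setattr__(self, "feature_ids", fids)
        object.__setattr__(self, "sample_ids", sids)

    @classmethod
    def from_arrays(cls, values, group, feature_ids=None, sample_ids=None):
        values = np.asarray(values, dtype=float)
        if feature_ids is None:
            feature_ids = np.arange(values.shape[1])
        if sample_ids is None:
            sample_ids = np.arange(values.shape[0])
        return cls(values, np.asarray(group), np.asarray(feature_ids),
                   np.asarray(sample_ids))

    @property
    def n1(self) -> int:
        return int(self.group.sum())

    @property
    def n2(self) -> int:
        return int(self.group.size - self.group.sum())

    @property
    def P(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class TestResult:
    """One pooled-variance t-test: |t|, df = n1+n2-2, two-sided p."""

    feature_id: object
    t_stat: float
    df: int
    p_value: float


def _group_slices(matrix: FeatureMatrix):
    case = matrix.values[matrix.group == 1]
    control = matrix.values[matrix.group == 0]
    if case.shape[0] < 2 or control.shape[0] < 2:
        raise InvalidArgumentError(
            "each group needs at least 2 samples for a pooled t-test "
            f"(got n1={case.shape[0]}, n2={control.shape[0]})"
        )
    return case, control


def _check_pooled_variance(matrix: FeatureMatrix, case, control):
    n1, n2 = case.shape[0], control.shape[0]
    pooled = (n1 - 1) * case.var(axis=0, ddof=1) + (n2 - 1) * control.var(axis=0, ddof=1)
    degenerate = np.nonzero(pooled <= 0.0)[0]
    if degenerate.size:
        raise DegenerateFeatureError(matrix.feature_ids[degenerate[0]])


def pooled_t_tests(matrix: FeatureMatrix, normal_approx: bool = False) -> pd.DataFrame:
    """Pooled two-sample t-tests for every feature (vectorised).

    Returns a DataFrame indexed by feature id with columns
    ``t_stat`` (absolute pooled t), ``df`` and ``p_value`` (two-sided).
    With ``normal_approx=True`` the p-value comes from the standard
    normal reference instead of the t distribution (large-sample
    emulation); the default is always the exact t reference.
    """
    case, control = _group_slices(matrix)
    _check_pooled_variance(matrix, case, control)
    res = stats.ttest_ind(case, control, axis=0, equal_var=True)
    t_abs = np.abs(res.statistic)
    df = case.shape[0] + control.shape[0] - 2
    if normal_approx:
        p = 2.0 * stats.norm.sf(t_abs)
    else:
        p = np.asarray(res.pvalue)
    return pd.DataFrame(
        {"t_stat": t_abs, "df": df, "p_value": p},
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )


def pooled_t_test(matrix: FeatureMatrix, feature, normal_approx: bool = False) -> TestResult:
    """Pooled t-test for a single named feature."""
    where = np.nonzero(matrix.feature_ids == feature)[0]
    if where.size == 0:
        raise InvalidArgumentError(f"unknown feature {feature!r}")
    sub = FeatureMatrix(
        matrix.values[:, where], matrix.group,
        matrix.feature_ids[where], matrix.sample_ids,
    )
    row = pooled_t_tests(sub, normal_approx=normal_approx).iloc[0]
    return TestResult(feature, float(row.t_stat), int(row.df), float(row.p_value))


def consecutive_correlations(
    matrix: FeatureMatrix,
    rank_order: Sequence,
    centering: str = "none",
) -> np.ndarray:
    """Pearson correlation between consecutively ranked feature columns.

    ``rank_order`` is the permutation of feature ids from rank 1 to
    rank P (ascending p-value order).  Entry ``i-2`` of the result is
    ``corr(X_(i-1), X_(i))`` for ranks ``i = 2..P``.

    ``centering="none"`` correlates the raw columns across all samples;
    ``centering="within_group"`` subtracts each group's mean first,
    which removes the correlation inflation that a shared group-mean
    shift induces between two genuinely differential features.
    """
    if centering not in ("none", "within_group"):
        raise InvalidArgumentError(
            f"centering must be 'none' or 'within_group', got {centering!r}"
        )
    order = np.asarray(rank_order)
    pos = {fid: j for j, fid in enumerate(matrix.feature_ids.tolist())}
    try:
        cols = np.array([pos[f] for f in order.tolist()])
    except KeyError as e:
        raise InvalidArgumentError(f"rank_order names unknown feature {e.args[0]!r}")
    X = matrix.values[:, cols]
    if centering == "within_group":
        X = X.copy()
        for g in (0, 1):
            rows = matrix.group == g
            X[rows] -= X[rows].mean(axis=0)
    else:
        X = X - X.mean(axis=0)
    norms = np.sqrt((X * X).sum(axis=0))
    zero = np.nonzero(norms == 0.0)[0]
    if zero.size:
        raise DegenerateFeatureError(order[zero[0]])
    num = (X[:, 1:] * X[:, :-1]).sum(axis=0)
    r = num / (norms[1:] * norms[:-1])
    return np.clip(r, -1.0, 1.0)


def _sorted_input(
    matrix: FeatureMatrix,
    centering: str,
    need_correlations: bool,
    correlations=None,
    normal_approx: bool = False,
):
    tests = pooled_t_tests(matrix, normal_approx=normal_approx)
    p = tests["p_value"].to_numpy()
    # stable ascending sort; ties broken by original feature index
    order = np.lexsort((np.arange(p.size), p))
    ranked_ids = matrix.feature_ids[order]
    r = None
    if correlations is not None:
        r = np.asarray(correlations, dtype=float)
        logger.info("correlations: supplied externally (P=%d)", p.size)
    elif need_correlations:
        r = consecutive_correlations(matrix, ranked_ids, centering)
        logger.info("correlations: estimated from data (P=%d, centering=%s)",
                    p.size, centering)
    else:
        logger.info("correlations: skipped (no M-procedure requested)")
    return SortedScreenInput(p[order], ranked_ids, r), tests


def screen(
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    procedures: Iterable[str] = PROCEDURES,
    centering: str = "none",
    monotone_adjust: bool = False,
    correlations=None,
    normal_approx: bool = False,
) -> dict[str, ScreenResult]:
    """End-to-end screening of a matrix: t-tests, sort, correlate, adjust, reject.

    Correlations are only computed when an M-procedure is requested (or
    supplied via ``correlations``, aligned to the sorted rank order);
    BF/BH/BY results never depend on them.
    """
    return FdrScreen(matrix).fit(
        alpha=alpha, procedures=procedures, centering=centering,
        monotone_adjust=monotone_adjust, correlations=correlations,
        normal_approx=normal_approx,
    ).results


class FdrScreen:
    """Two-group feature-screening model.

    Parameters
    ----------
    matrix : FeatureMatrix, or array-like samples x features
    group : 0/1 array per sample (omit when ``matrix`` is a FeatureMatrix)

    Examples
    --------
    >>> model = FdrScreen.from_dataframe(df, labels)
    >>> res = model.fit(alpha=0.05, procedures=("BH", "M1"))
    >>> res.k["M1"], res.rejected["M1"]
    """

    def __init__(self, matrix, group=None, feature_ids=None, sample_ids=None):
        if isinstance(matrix, FeatureMatrix):
            self.data = matrix
        else:
            if group is None:
                raise InvalidArgumentError("group labels are required")
            self.data = FeatureMatrix.from_arrays(matrix, group, feature_ids, sample_ids)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, labels) -> "FdrScreen":
        """Build from a samples x features DataFrame and a sample->0/1 mapping.

        ``labels`` may be a Series indexed by sample id or a dict; every
        row of ``frame`` must be labelled.
        """
        labels = pd.Series(labels)
        missing = [s for s in frame.index if s not in labels.index]
        if missing:
            raise InvalidArgumentError(f"no group label for sample {missing[0]!r}")
        group = labels.reindex(frame.index).to_numpy()
        values = frame.to_numpy(dtype=float)
        return cls(FeatureMatrix(values, group, frame.columns.to_numpy(),
                                 frame.index.to_numpy()))

    def fit(
        self,
        alpha: float = 0.05,
        procedures: Iterable[str] = PROCEDURES,
        centering: str = "none",
        monotone_adjust: bool = False,
        correlations=None,
        normal_approx: bool = False,
    ) -> "FdrScreenResults":
        procs = [p.upper() for p in procedures]
        need_r = correlations is None and any(p in M_PROCEDURES for p in procs)
        sorted_input, tests = _sorted_input(
            self.data, centering, need_r, correlations, normal_approx
        )
        results = screen_sorted(sorted_input, alpha, procs, monotone_adjust)
        for proc, res in results.items():
            not_rejected = sorted_input.p_sorted[res.k:]
            logger.info(
                "%s: P=%d k=%d smallest non-rejected p=%s", proc,
                sorted_input.P, res.k,
                f"{not_rejected[0]:.4g}" if not_rejected.size else "none",
            )
        return FdrScreenResults(self, sorted_input, results, float(alpha),
                                centering, tests)


class FdrScreenResults:
    """Fitted screening results for one matrix at one alpha.

    Attributes
    ----------
    sorted_input : SortedScreenInput
    results : dict procedure -> ScreenResult
    k : dict procedure -> rejection count
    rejected : dict procedure -> ndarray of rejected feature ids
    """

    def __init__(self, model, sorted_input, results, alpha, centering, tests):
        self.model = model
        self.sorted_input = sorted_input
        self.results = results
        self.alpha = alpha
        self.centering = centering
        self.tests = tests

    @property
    def k(self) -> dict[str, int]:
        return {proc: res.k for proc, res in self.results.items()}

    @property
    def rejected(self) -> dict[str, np.ndarray]:
        return {proc: res.rejected_ids for proc, res in self.results.items()}

    def table(self) -> pd.DataFrame:
        """Rank-ordered results table (one row per feature).

        Columns: feature_id, rank, p_value, r_consecutive (NaN at rank 1),
        then ``threshold_<proc>``, ``adjusted_p_<proc>``,
        ``rejected_<proc>`` for each fitted procedure.
        """
        inp = self.sorted_input
        P = inp.P
        out = pd.DataFrame({
            "feature_id": inp.feature_ids,
            "rank": np.arange(1, P + 1),
            "p_value": inp.p_sorted,
        })
        if inp.r_consecutive is not None:
            out["r_consecutive"] = np.concatenate(([np.nan], inp.r_consecutive))
        for proc, res in self.results.items():
            out[f"threshold_{proc}"] = res.ladder.thresholds
            out[f"adjusted_p_{proc}"] = res.adjusted_p
            if res.adjusted_p_monotone is not None:
                out[f"adjusted_p_monotone_{proc}"] = res.adjusted_p_monotone
            out[f"rejected_{proc}"] = out["rank"] <= res.k
        return out

    def summary(self) -> str:
        """Human-readable per-procedure summary."""
        lines = [
            "Correlation-modified FDR screening",
            f"  features: {self.sorted_input.P}   alpha: {self.alpha}",
            f"  samples: n1={self.model.data.n1} (case), n2={self.model.data.n2} (control)",
            "",
            f"  {'procedure':<10}{'k':>6}  rejected feature ids (first 5)",
        ]
        for proc, res in self.results.items():
            head = ", ".join(map(str, res.rejected_ids[:5]))
            if res.k > 5:
                head += ", ..."
            lines.append(f"  {proc:<10}{res.k:>6}  {head}")
        return "\n".join(lines)
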