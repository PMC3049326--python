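"""Second-level (across-subject) robust tests on parameter maps.

All tests operate on stacks of per-subject channel x frame maps (typically
level-1 beta or contrast maps).  Resampling draws whole subject maps: the
subject-index sequence for each bootstrap iteration is drawn once and
reused across every channel/frame cell, which preserves the
spatio-temporal dependence of the data and is what makes the resampled
maps usable for cluster-level inference downstream.

Implemented tests
-----------------
- one-sample bootstrap-t (pivot) with the quantile CI of the studentized
  bootstrap distribution,
- two-sample and paired percentile bootstrap on mean differences (the
  reported parametric statistic is Welch's t -- equal variances are never
  assumed),
- modified percentile-bootstrap regression (no p-value; significance is
  the CI excluding zero),
- 20% trimmed-mean summaries with a bootstrap-standard-error CI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model_io import ConfidenceMap, StatMap

logger = logging.getLogger("erpglm")

MAX_REDRAWS = 100

#: (a, c) for the modified percentile bootstrap of a simple regression
#: slope at alpha = .05 with B = 599, keyed by the smallest sample size of
#: each band (Wilcox's regci lookup).
_SIMPLE_REG_TABLE = ((250, 15), (180, 13), (80, 10), (40, 7), (0, 6))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SubjectStack:
    """Per-subject maps stacked along the first axis: ``maps[subject, channel, frame]``."""

    maps: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim == 2:        # single-channel convenience
            self.maps = self.maps[:, None, :]
        if self.maps.ndim == 1:
            self.maps = self.maps[:, None, None]
        if self.maps.ndim != 3:
            raise ValueError("maps must be [subject, channel, frame]")
        if self.maps.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if self.subject_ids is None:
            self.subject_ids = [f"s{i}" for i in range(self.maps.shape[0])]
        elif len(self.subject_ids) != self.maps.shape[0]:
            raise ValueError("subject_ids length must equal number of subjects")

    @property
    def n_subjects(self) -> int:
        return self.maps.shape[0]

    @property
    def cell_shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]


# ---------------------------------------------------------------------------
# quantile bookkeeping
# ---------------------------------------------------------------------------

def quantile_indices(alpha: float, n_boot: int) -> tuple[int, int]:
    """1-based sorted-sample positions (L, U) of the two-sided CI bounds.

    L = round(alpha * B / 2) (half away from zero), U = B - L.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    L = _round_half_away(alpha * n_boot / 2.0)
    if L < 1:
        raise ValueError(
            f"n_boot={n_boot} too small for alpha={alpha}: L would be 0")
    return L, n_boot - L


def regression_ci_indices(alpha: float, n_boot: int, n_regressors: int,
                          n_subjects: int | None = None) -> tuple[int, int]:
    """(a, c) for the modified percentile bootstrap of regression slopes.

    For a simple regression at alpha=.05 with B=599 the indices follow a
    sample-size-dependent lookup (Wilcox's regci values); otherwise the
    Bonferroni-style rule a = round(alpha*B / (2*k)), c = B - a applies.
    """
    if n_regressors == 1 and n_boot == 599 and abs(alpha - 0.05) < 1e-12 \
            and n_subjects is not None:
        for n_min, a in _SIMPLE_REG_TABLE:
            if n_subjects >= n_min:
                return a, n_boot - a
    a = _round_half_away(alpha * n_boot / (2.0 * n_regressors))
    if a < 1:
        raise ValueError("n_boot too small for alpha / number of regressors")
    return a, n_boot - a


# ---------------------------------------------------------------------------
# shared resampling machinery
# ---------------------------------------------------------------------------

def draw_bootstrap_indices(rng: np.random.Generator, n: int, n_boot: int,
                           ) -> np.ndarray:
    """Draw ``n_boot`` with-replacement index vectors of length n.

    Draws in which every index is identical (a guaranteed zero-variance
    bootstrap sample) are redrawn, at most :data:`MAX_REDRAWS` times.
    """
    idx = rng.integers(0, n, size=(n_boot, n))
    if n == 1:
        return idx
    for attempt in range(MAX_REDRAWS):
        bad = np.all(idx == idx[:, :1], axis=1)
        if not bad.any():
            return idx
        logger.debug("redrawing %d degenerate bootstrap draws", int(bad.sum()))
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    raise RuntimeError(
        f"could not obtain non-degenerate bootstrap draws in {MAX_REDRAWS} attempts")


def _counts(idx: np.ndarray, n: int) -> np.ndarray:
    """(B, n) multiplicity matrix of each subject in each draw."""
    B = idx.shape[0]
    S = np.zeros((B, n))
    rows = np.repeat(np.arange(B), idx.shape[1])
    np.add.at(S, (rows, idx.ravel()), 1.0)
    return S


def _boot_mean_sd(maps: np.ndarray, idx: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap means and sample SDs for every draw and cell.

    maps: (n, ...) -> returns (B, ...) means and SDs, computed from the
    multiplicity matrix so every cell shares the same subject draws.
    """
    n = maps.shape[0]
    flat = maps.reshape(n, -1)
    S = _counts(idx, n)
    m = (S @ flat) / idx.shape[1]
    m2 = (S @ flat ** 2) / idx.shape[1]
    var = np.maximum(m2 - m ** 2, 0.0) * (idx.shape[1] / (idx.shape[1] - 1))
    out_shape = (idx.shape[0],) + maps.shape[1:]
    return m.reshape(out_shape), np.sqrt(var).reshape(out_shape)


# ---------------------------------------------------------------------------
# one-sample bootstrap-t
# ---------------------------------------------------------------------------

@dataclass
class OneSampleResult:
    statmap: StatMap
    ci: ConfidenceMap
    mean: np.ndarray
    t_boot: np.ndarray | None = None     # (B, channel, frame), unsorted draws
    boot_indices: np.ndarray | None = None


def one_sample_bootstrap_t(stack: SubjectStack, alpha: float = 0.05,
                           n_boot: int = 1000, seed=None,
                           keep_boot: bool = False) -> OneSampleResult:
    """Bootstrap-t one-sample test of mean zero at every cell.

    Subjects are drawn with replacement (one shared index sequence for all
    cells); each draw's pivot T* = (mean* - mean) / (s*/sqrt(n))
    approximates the sampling distribution of T under H0.  The CI is
    [mean - T*_(U) s/sqrt(n), mean - T*_(L) s/sqrt(n)] with (L, U) from
    :func:`quantile_indices`, and the two-sided p compares the observed
    T = mean/(s/sqrt(n)) against the pivot distribution.
    """
    rng = np.random.default_rng(seed)
    maps = stack.maps
    n = stack.n_subjects
    L, U = quantile_indices(alpha, n_boot)

    mean = maps.mean(axis=0)
    s = maps.std(axis=0, ddof=1)
    degenerate = s == 0
    sem = np.where(degenerate, 1.0, s / math.sqrt(n))
    with np.errstate(invalid="ignore"):
        T = np.where(degenerate,
                     np.where(mean == 0, 0.0, np.inf * np.sign(mean)),
                     mean / sem)

    idx = draw_bootstrap_indices(rng, n, n_boot)
    m_b, s_b = _boot_mean_sd(maps, idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_b = (m_b - mean) / (s_b / math.sqrt(n))
    t_b = np.where(np.isnan(t_b), 0.0, t_b)          # 0/0: draw equals sample

    t_sorted = np.sort(t_b, axis=0)
    lower = mean - t_sorted[U - 1] * s / math.sqrt(n)
    upper = mean - t_sorted[L - 1] * s / math.sqrt(n)
    lower = np.where(degenerate, mean, lower)
    upper = np.where(degenerate, mean, upper)

    p = 2.0 * np.minimum((t_b >= T).mean(axis=0), (t_b <= T).mean(axis=0))
    p = np.clip(p, 1.0 / n_boot, 1.0)
    p = np.where(degenerate & (mean == 0), 1.0, p)

    statmap = StatMap(stat=T, kind="T", df=(1.0, float(n - 1)),
                      p_uncorrected=p, degenerate=degenerate)
    ci = ConfidenceMap(lower=lower, upper=upper, alpha=alpha, n_boot=n_boot,
                       quantile_low_index=L, quantile_high_index=U,
                       degenerate=degenerate)
    return OneSampleResult(statmap=statmap, ci=ci, mean=mean,
                           t_boot=t_b if keep_boot else None,
                           boot_indices=idx if keep_boot else None)


# ---------------------------------------------------------------------------
# two-sample / paired percentile bootstrap
# ---------------------------------------------------------------------------

def welch_t(x: np.ndarray, y: np.ndarray) -> StatMap:
    """Welch's two-sample t (unequal variances) with Satterthwaite df.

    x, y: (n_subjects, channel, frame).  Variance homogeneity is never
    assumed.
    """
    n1, n2 = x.shape[0], y.shape[0]
    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    v1, v2 = x.var(axis=0, ddof=1), y.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    degenerate = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate,
                     np.where(m1 == m2, 0.0, np.inf * np.sign(m1 - m2)),
                     (m1 - m2) / np.sqrt(np.where(degenerate, 1.0, se2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1))
                         + v2 ** 2 / (n2 ** 2 * (n2 - 1)))
    df = np.where(degenerate, float(n1 + n2 - 2), df)
    p = 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), df)
    p = np.where(np.isinf(t), np.finfo(float).tiny, p)
    p = np.where(degenerate & (m1 == m2), 1.0, p)
    return StatMap(stat=t, kind="T", df=(1.0, float(np.mean(df))),
                   p_uncorrected=np.clip(p, np.finfo(float).tiny, 1.0),
                   degenerate=degenerate)


@dataclass
class DifferenceResult:
    difference: np.ndarray
    ci: ConfidenceMap
    p: np.ndarray
    welch: StatMap
    significant: np.ndarray
    d_boot: np.ndarray | None = None


def _percentile_difference(d_boot: np.ndarray, difference: np.ndarray,
                           alpha: float, welch: StatMap) -> DifferenceResult:
    n_boot = d_boot.shape[0]
    L, U = quantile_indices(alpha, n_boot)
    d_sorted = np.sort(d_boot, axis=0)
    lower = d_sorted[L]          # D_(L+1), 1-based
    upper = d_sorted[U - 1]      # D_(U)
    pos = (d_boot > 0).mean(axis=0)
    p = np.clip(2.0 * np.minimum(pos, 1.0 - pos), 1.0 / n_boot, 1.0)
    significant = (lower > 0) | (upper < 0)
    ci = ConfidenceMap(lower=lower, upper=upper, alpha=alpha, n_boot=n_boot,
                       quantile_low_index=L + 1, quantile_high_index=U)
    return DifferenceResult(difference=difference, ci=ci, p=p, welch=welch,
                            significant=significant, d_boot=None)


def two_sample_percentile(stack1: SubjectStack, stack2: SubjectStack,
                          alpha: float = 0.05, n_boot: int = 1000, seed=None,
                          keep_boot: bool = False) -> DifferenceResult:
    """Percentile bootstrap on the mean difference of two independent groups.

    Each group is resampled independently with replacement; the CI is
    [D_(L+1), D_(U)] of the sorted bootstrap differences, the two-sided p
    doubles the tail proportion of D* above zero, and significance is the
    CI excluding zero.  The accompanying parametric map is Welch's t.
    """
    if stack1.cell_shape != stack2.cell_shape:
        raise ValueError("group stacks must share channel/frame dimensions")
    rng = np.random.default_rng(seed)
    idx1 = draw_bootstrap_indices(rng, stack1.n_subjects, n_boot)
    idx2 = draw_bootstrap_indices(rng, stack2.n_subjects, n_boot)
    m1, _ = _boot_mean_sd(stack1.maps, idx1)
    m2, _ = _boot_mean_sd(stack2.maps, idx2)
    d_boot = m1 - m2
    diff = stack1.maps.mean(axis=0) - stack2.maps.mean(axis=0)
    res = _percentile_difference(d_boot, diff, alpha,
                                 welch_t(stack1.maps, stack2.maps))
    if keep_boot:
        res.d_boot = d_boot
    return res


def paired_t(x: np.ndarray, y: np.ndarray) -> StatMap:
    """Paired t on the subject-wise differences."""
    d = x - y
    n = d.shape[0]
    m = d.mean(axis=0)
    s = d.std(axis=0, ddof=1)
    degenerate = s == 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(m == 0, 0.0, np.inf * np.sign(m)),
                     m / np.where(degenerate, 1.0, s / math.sqrt(n)))
    p = 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), n - 1)
    p = np.where(np.isinf(t), np.finfo(float).tiny, p)
    p = np.where(degenerate & (m == 0), 1.0, p)
    return StatMap(stat=t, kind="T", df=(1.0, float(n - 1)),
                   p_uncorrected=np.clip(p, np.finfo(float).tiny, 1.0),
                   degenerate=degenerate)


def paired_percentile(stack1: SubjectStack, stack2: SubjectStack,
                      alpha: float = 0.05, n_boot: int = 1000, seed=None,
                      keep_boot: bool = False) -> DifferenceResult:
    """Percentile bootstrap for paired samples.

    Pair indices are resampled jointly, preserving the within-subject
    covariance; otherwise identical to :func:`two_sample_percentile`.
    Equivalent to the percentile bootstrap of the mean of the subject-wise
    differences driven by the same index draws.
    """
    if stack1.n_subjects != stack2.n_subjects:
        raise ValueError("paired stacks must have the same subjects")
    if stack1.subject_ids != stack2.subject_ids:
        raise ValueError("paired stacks must list the same subjects in order")
    if stack1.cell_shape != stack2.cell_shape:
        raise ValueError("paired stacks must share channel/frame dimensions")
    rng = np.random.default_rng(seed)
    idx = draw_bootstrap_indices(rng, stack1.n_subjects, n_boot)
    d = stack1.maps - stack2.maps
    d_boot, _ = _boot_mean_sd(d, idx)
    res = _percentile_difference(d_boot, d.mean(axis=0), alpha,
                                 paired_t(stack1.maps, stack2.maps))
    if keep_boot:
        res.d_boot = d_boot
    return res


# ---------------------------------------------------------------------------
# percentile-bootstrap regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    slopes: np.ndarray          # (k, channel, frame)
    lower: np.ndarray           # (k, channel, frame)
    upper: np.ndarray
    significant: np.ndarray     # (k, channel, frame)
    index_low: int              # 1-based a+1
    index_high: int             # 1-based c
    n_boot: int
    slope_boot: np.ndarray | None = None


def regression_percentile(stack: SubjectStack, predictors, alpha: float = 0.05,
                          n_boot: int | None = None, seed=None,
                          keep_boot: bool = False) -> RegressionResult:
    """Modified percentile-bootstrap CIs for between-subject regression slopes.

    Whole subject maps are resampled jointly with their predictor rows, so
    the subject-predictor link is preserved.  For a simple regression the
    default is B = 599 with the sample-size-dependent (a, c) indices; for
    k > 1 the Bonferroni rule a = round(alpha*B/(2k)) applies.  No p-value
    is produced: a slope is significant iff its CI excludes zero.
    """
    P = np.atleast_2d(np.asarray(predictors, dtype=float))
    if P.shape[0] == 1 and stack.n_subjects != 1:
        P = P.T
    n, k = P.shape
    if n != stack.n_subjects:
        raise ValueError("predictor rows must equal number of subjects")
    if n <= k + 1:
        raise ValueError("need more subjects than regressors plus intercept")
    X = np.column_stack([P, np.ones(n)])
    if np.linalg.matrix_rank(X) < k + 1:
        raise ValueError("predictor matrix is rank deficient")
    if n_boot is None:
        n_boot = 599
    a, c = regression_ci_indices(alpha, n_boot, k, n_subjects=n)

    flat = stack.maps.reshape(n, -1)
    slopes = (np.linalg.pinv(X) @ flat)[:k]

    rng = np.random.default_rng(seed)
    idx = draw_bootstrap_indices(rng, n, n_boot)
    boot = np.empty((n_boot, k, flat.shape[1]))
    for b in range(n_boot):
        rows = idx[b]
        Xb = X[rows]
        for _ in range(MAX_REDRAWS):
            if np.linalg.matrix_rank(Xb) == k + 1:
                break
            rows = rng.integers(0, n, size=n)
            Xb = X[rows]
        else:
            raise RuntimeError("could not draw a full-rank bootstrap design")
        boot[b] = (np.linalg.pinv(Xb) @ flat[rows])[:k]

    boot_sorted = np.sort(boot, axis=0)
    lower = boot_sorted[a]          # beta_(a+1), 1-based
    upper = boot_sorted[c - 1]      # beta_(c)
    cell_shape = stack.cell_shape
    out = lambda arr: arr.reshape((k,) + cell_shape)
    significant = (lower > 0) | (upper < 0)
    return RegressionResult(
        slopes=out(slopes), lower=out(lower), upper=out(upper),
        significant=out(significant), index_low=a + 1, index_high=c,
        n_boot=n_boot,
        slope_boot=boot.reshape((n_boot, k) + cell_shape) if keep_boot else None)


# ---------------------------------------------------------------------------
# trimmed means
# ---------------------------------------------------------------------------

def trimmed_mean(x: np.ndarray, trim: float = 0.2, axis: int = 0) -> np.ndarray:
    """Mean after dropping floor(trim*n) lowest and highest values per cell."""
    if not 0 <= trim < 0.5:
        raise ValueError("trim proportion must lie in [0, 0.5)")
    return stats.trim_mean(x, trim, axis=axis)


def trimmed_mean_erp(maps: np.ndarray, trim: float = 0.2, alpha: float = 0.05,
                     n_boot: int = 599, seed=None
                     ) -> tuple[np.ndarray, ConfidenceMap]:
    """20% trimmed-mean summary with a bootstrap-standard-error CI.

    CI = estimate +/- z_{1-alpha/2} * SE_boot, where SE_boot is the SD of
    the bootstrap trimmed means (shared subject draws across cells).
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if 2 * math.floor(trim * n) >= n:
        raise ValueError("sample too small for this trim proportion")
    est = trimmed_mean(maps, trim, axis=0)
    rng = np.random.default_rng(seed)
    idx = draw_bootstrap_indices(rng, n, n_boot)
    boot = stats.trim_mean(maps[idx], trim, axis=1)   # (B, ...)
    se = boot.std(axis=0, ddof=1)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    L, U = quantile_indices(alpha, n_boot)
    ci = ConfidenceMap(lower=est - z * se, upper=est + z * se, alpha=alpha,
                       n_boot=n_boot, quantile_low_index=L,
                       quantile_high_index=U, degenerate=se == 0)
    return est, ci
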