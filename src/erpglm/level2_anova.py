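"""Bootstrap ANOVA family at the group level.

Between-subject ANOVA uses ordinary least squares; repeated measures are
handled by a multivariate approach (Hotelling T^2 on difference scores,
Hotelling-Lawley trace for within-by-between interactions), which
sidesteps the sphericity assumption entirely.  All p-values come from an
H0 bootstrap: each cell of the design is mean-centred so the null is
exactly true, subjects are resampled with replacement (keeping repeated
measures together), and the observed F is referred to the resampled F
distribution.  Confidence intervals on condition differences are computed
under H1 with the percentile machinery of :mod:`.level2_robust`.

An optional univariate repeated-measures path with a Huynh-Feldt
sphericity correction is provided for comparison; the multivariate route
is the default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .data_model_io import DesignMatrix, StatMap
from .level2_robust import (SubjectStack, draw_bootstrap_indices,
                            regression_ci_indices, two_sample_percentile)


@dataclass
class AnovaLayout:
    """Declares the factorial structure of a group analysis.

    group_labels assigns each subject to a between-subject cell;
    condition_axis gives the ordered within-subject levels (length k);
    design optionally carries covariates for ANCOVA.
    """

    group_labels: list[str] = field(default_factory=list)
    condition_axis: list[str] = field(default_factory=list)
    design: DesignMatrix | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "AnovaLayout":
        with open(path) as fh:
            d = json.load(fh)
        return cls(group_labels=list(d.get("group_labels", [])),
                   condition_axis=list(d.get("condition_axis", [])))


@dataclass
class AnovaResult:
    statmap: StatMap                  # observed F with parametric p
    p_boot: np.ndarray                # H0-bootstrap p per cell
    f_boot: np.ndarray | None = None  # (B, channel, frame) null F draws
    pair_cis: dict | None = None      # (i, j) -> DifferenceResult under H1
    extra: dict | None = None


def _monte_carlo_p(f_obs: np.ndarray, f_null: np.ndarray) -> np.ndarray:
    """Add-one Monte-Carlo p: (1 + #{F* >= F_obs}) / (B + 1)."""
    B = f_null.shape[0]
    return (1.0 + (f_null >= f_obs).sum(axis=0)) / (B + 1.0)


def _assert_centred(arrs, axis=0, tol=1e-12):
    for a in arrs:
        m = np.abs(np.asarray(a).mean(axis=axis)).max()
        if m > tol * max(1.0, float(np.abs(a).max())):
            raise AssertionError(f"H0 centring failed: residual mean {m}")


# ---------------------------------------------------------------------------
# between-subject one-way ANOVA
# ---------------------------------------------------------------------------

def _oneway_f(groups: list[np.ndarray]) -> np.ndarray:
    """One-way OLS F per cell from a list of (n_g, ...) group arrays."""
    ns = np.array([g.shape[0] for g in groups], dtype=float)
    N = ns.sum()
    g = len(groups)
    means = np.stack([gr.mean(axis=0) for gr in groups])
    grand = np.tensordot(ns, means, axes=1) / N
    ssb = np.tensordot(ns, (means - grand) ** 2, axes=1)
    ssw = sum(((gr - m) ** 2).sum(axis=0) for gr, m in zip(groups, means))
    msb = ssb / (g - 1)
    msw = ssw / (N - g)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(msw > 0, msb / msw, np.where(msb > 0, np.inf, 0.0))
    return F


def _oneway_f_boot(centred: list[np.ndarray], idx_per_group: list[np.ndarray]
                   ) -> np.ndarray:
    """Vectorised null F for all bootstrap draws at once.

    centred: per-group (n_g, ...) arrays with zero cell means;
    idx_per_group: per-group (B, n_g) subject draws.
    """
    ns = [c.shape[0] for c in centred]
    N = float(sum(ns))
    g = len(centred)
    B = idx_per_group[0].shape[0]
    cell_shape = centred[0].shape[1:]
    sums = []
    sumsqs = []
    for c, idx in zip(centred, idx_per_group):
        flat = c.reshape(c.shape[0], -1)
        S = np.zeros((B, c.shape[0]))
        rows = np.repeat(np.arange(B), idx.shape[1])
        np.add.at(S, (rows, idx.ravel()), 1.0)
        sums.append(S @ flat)
        sumsqs.append(S @ flat ** 2)
    tot = sum(sums)
    grand = tot / N
    ssb = sum(s ** 2 / n for s, n in zip(sums, ns)) - N * grand ** 2
    ssw = sum(sq - s ** 2 / n for sq, s, n in zip(sumsqs, sums, ns))
    msb = ssb / (g - 1)
    msw = ssw / (N - g)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(msw > 0, msb / msw, np.where(msb > 0, np.inf, 0.0))
    return np.maximum(F, 0.0).reshape((B,) + cell_shape)


def anova_between(stacks: list[SubjectStack], alpha: float = 0.05,
                  n_boot: int = 1000, seed=None, keep_boot: bool = False,
                  pair_cis: bool = True) -> AnovaResult:
    """One-way between-subject bootstrap ANOVA.

    The observed F comes from the OLS decomposition.  For the null, each
    group is mean-centred per cell (every ANOVA cell then has mean zero),
    subjects are resampled with replacement independently per group, and
    the F recomputed B times; p = (1 + #{F* >= F_obs}) / (B + 1).
    Pairwise condition-difference CIs are computed under H1 (uncentred
    resampling) with the two-sample percentile bootstrap.
    """
    if len(stacks) < 2:
        raise ValueError("need at least two groups")
    for s in stacks:
        if s.n_subjects < 2:
            raise ValueError("every group needs at least 2 subjects")
    groups = [s.maps for s in stacks]
    g = len(groups)
    N = sum(gr.shape[0] for gr in groups)
    f_obs = _oneway_f(groups)
    df = (float(g - 1), float(N - g))
    p_par = stats.f.sf(np.where(np.isinf(f_obs), 0, f_obs), *df)
    p_par = np.where(np.isinf(f_obs), np.finfo(float).tiny, p_par)

    rng = np.random.default_rng(seed)
    centred = [gr - gr.mean(axis=0) for gr in groups]
    _assert_centred(centred)
    idx = [draw_bootstrap_indices(rng, gr.shape[0], n_boot) for gr in groups]
    f_null = _oneway_f_boot(centred, idx)
    p_boot = _monte_carlo_p(f_obs, f_null)

    cis = None
    if pair_cis:
        cis = {}
        for i in range(g):
            for j in range(i + 1, g):
                cis[(i, j)] = two_sample_percentile(
                    stacks[i], stacks[j], alpha=alpha, n_boot=n_boot,
                    seed=rng.integers(2 ** 31))
    statmap = StatMap(stat=np.maximum(f_obs, 0.0), kind="F", df=df,
                      p_uncorrected=np.clip(p_par, np.finfo(float).tiny, 1.0))
    return AnovaResult(statmap=statmap, p_boot=p_boot,
                       f_boot=f_null if keep_boot else None, pair_cis=cis)


# ---------------------------------------------------------------------------
# repeated measures: Hotelling T^2 on difference scores
# ---------------------------------------------------------------------------

def successive_difference_contrast(k: int) -> np.ndarray:
    """(k-1) x k matrix mapping condition scores to successive differences."""
    C = np.zeros((k - 1, k))
    idx = np.arange(k - 1)
    C[idx, idx] = 1.0
    C[idx, idx + 1] = -1.0
    return C


def _hotelling_t2(d: np.ndarray, allow_pinv: bool = False) -> np.ndarray:
    """T^2 = n * dbar' S^{-1} dbar per cell.

    d: (n, k-1, n_cells).  With allow_pinv a singular S falls back to the
    pseudoinverse (used for bootstrap draws); otherwise it is an error.
    """
    n, p = d.shape[0], d.shape[1]
    dbar = d.mean(axis=0)                           # (k-1, cells)
    dc = d - dbar
    S = np.einsum("nic,njc->cij", dc, dc) / (n - 1)  # (cells, k-1, k-1)
    b = dbar.T[..., None]                            # (cells, k-1, 1)
    try:
        x = np.linalg.solve(S, b)
    except np.linalg.LinAlgError:
        # a singular S is fine when the mean difference vanishes too
        # (identical conditions: T^2 = 0) or inside bootstrap draws
        sing = np.linalg.matrix_rank(S) < p
        zero_mean = np.abs(dbar.T) <= 1e-12 * max(1.0, float(np.abs(d).max()))
        if not allow_pinv and not zero_mean[sing].all():
            raise ValueError(
                "singular covariance of difference scores: too few subjects "
                "for this number of conditions") from None
        x = np.linalg.pinv(S) @ b
    t2 = n * np.einsum("ci,ci->c", dbar.T, x[..., 0])
    return np.maximum(t2, 0.0)


def rm_anova_hotelling(data: np.ndarray, alpha: float = 0.05,
                       n_boot: int = 1000, seed=None,
                       keep_boot: bool = False) -> AnovaResult:
    """Repeated-measures ANOVA via Hotelling T^2 on difference scores.

    data: (subjects, conditions, channel, frame).  Per cell, the k-1
    successive-difference scores d give T^2 = n dbar' S^{-1} dbar and
    F = T^2 (n-k+1) / ((n-1)(k-1)) with df (k-1, n-k+1).  Any full-rank
    (k-1) x k contrast yields the same T^2.  The null centres each
    condition (per cell) and resamples subjects keeping their condition
    tuples together.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None, None]
    if data.ndim == 3:
        data = data[:, :, :, None]
    n, k = data.shape[:2]
    if n <= k - 1:
        raise ValueError("need more subjects than conditions minus one")
    cell_shape = data.shape[2:]
    C = successive_difference_contrast(k)
    flat = data.reshape(n, k, -1)
    d = np.einsum("jk,nkc->njc", C, flat)
    t2 = _hotelling_t2(d)
    conv = (n - k + 1) / ((n - 1.0) * (k - 1.0))
    f_obs = (t2 * conv).reshape(cell_shape)
    df = (float(k - 1), float(n - k + 1))
    p_par = stats.f.sf(f_obs, *df)

    rng = np.random.default_rng(seed)
    centred = flat - flat.mean(axis=0)               # per condition & cell
    _assert_centred([centred])
    idx = draw_bootstrap_indices(rng, n, n_boot)
    f_null = np.empty((n_boot,) + cell_shape)
    for b in range(n_boot):
        db = np.einsum("jk,nkc->njc", C, centred[idx[b]])
        f_null[b] = (_hotelling_t2(db, allow_pinv=True) * conv
                     ).reshape(cell_shape)
    p_boot = _monte_carlo_p(f_obs, f_null)
    statmap = StatMap(stat=f_obs, kind="F", df=df,
                      p_uncorrected=np.clip(p_par, np.finfo(float).tiny, 1.0))
    return AnovaResult(statmap=statmap, p_boot=p_boot,
                       f_boot=f_null if keep_boot else None,
                       extra={"t2": t2.reshape(cell_shape)})


# ---------------------------------------------------------------------------
# within-by-between interaction: Hotelling-Lawley trace
# ---------------------------------------------------------------------------

def _hotelling_lawley_f(d_groups: list[np.ndarray]
                        ) -> tuple[np.ndarray, tuple[float, float]]:
    """Hotelling-Lawley trace on group means of difference scores, as F.

    d_groups: per-group (n_g, p, cells) difference scores (p = k-1).
    Uses the standard F approximation with s = min(p, g-1),
    m = (|p-g+1|-1)/2, n' = (N-g-p-1)/2:
    F = 2(sn'+1) U / (s^2 (2m+s+1)), df = (s(2m+s+1), 2(sn'+1)).
    Exact when s = 1 (two groups or univariate d).
    """
    g = len(d_groups)
    p = d_groups[0].shape[1]
    ns = np.array([d.shape[0] for d in d_groups], dtype=float)
    N = ns.sum()
    means = np.stack([d.mean(axis=0) for d in d_groups])   # (g, p, cells)
    grand = np.tensordot(ns, means, axes=1) / N
    dev = means - grand
    H = np.einsum("g,gic,gjc->cij", ns, dev, dev)
    E = np.zeros_like(H)
    for d, m in zip(d_groups, means):
        dc = d - m
        E += np.einsum("nic,njc->cij", dc, dc)
    try:
        U = np.einsum("cii->c", np.linalg.solve(E, H))
    except np.linalg.LinAlgError:
        U = np.einsum("cii->c", np.linalg.pinv(E) @ H)
    U = np.maximum(U, 0.0)
    s = min(p, g - 1)
    m_par = (abs(p - g + 1) - 1) / 2.0
    n_par = (N - g - p - 1) / 2.0
    if n_par <= -0.5:
        raise ValueError("too few subjects for the interaction test")
    df1 = s * (2 * m_par + s + 1)
    df2 = 2 * (s * n_par + 1)
    F = df2 * U / (s * df1)
    return np.maximum(F, 0.0), (float(df1), float(df2))


def rm_anova_interaction(data_groups: list[np.ndarray], alpha: float = 0.05,
                         n_boot: int = 1000, seed=None,
                         keep_boot: bool = False) -> AnovaResult:
    """Within-by-between interaction via the Hotelling generalized T^2.

    data_groups: per group, (subjects, conditions, channel, frame).  The
    interaction is a multivariate test of equal group means of the
    difference scores.  The null centres every group x condition cell and
    resamples subjects within groups, keeping condition tuples together.
    """
    arrs = [np.asarray(d, dtype=float) for d in data_groups]
    arrs = [a[:, :, None, None] if a.ndim == 2 else
            (a[:, :, :, None] if a.ndim == 3 else a) for a in arrs]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    k = arrs[0].shape[1]
    cell_shape = arrs[0].shape[2:]
    C = successive_difference_contrast(k)
    flats = [a.reshape(a.shape[0], k, -1) for a in arrs]
    d_groups = [np.einsum("jk,nkc->njc", C, f) for f in flats]
    f_obs_flat, df = _hotelling_lawley_f(d_groups)
    f_obs = f_obs_flat.reshape(cell_shape)
    p_par = stats.f.sf(f_obs, *df)

    rng = np.random.default_rng(seed)
    centred = [f - f.mean(axis=0) for f in flats]      # per group x condition
    _assert_centred(centred)
    idx = [draw_bootstrap_indices(rng, f.shape[0], n_boot) for f in centred]
    f_null = np.empty((n_boot,) + cell_shape)
    for b in range(n_boot):
        db = [np.einsum("jk,nkc->njc", C, c[i[b]])
              for c, i in zip(centred, idx)]
        f_null[b] = _hotelling_lawley_f(db)[0].reshape(cell_shape)
    p_boot = _monte_carlo_p(f_obs, f_null)
    statmap = StatMap(stat=f_obs, kind="F", df=df,
                      p_uncorrected=np.clip(p_par, np.finfo(float).tiny, 1.0))
    return AnovaResult(statmap=statmap, p_boot=p_boot,
                       f_boot=f_null if keep_boot else None)


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

def _partial_f(X_full: np.ndarray, cols_drop: list[int], flat: np.ndarray,
               ) -> tuple[np.ndarray, tuple[float, float]]:
    """Partial (extra-sum-of-squares) F for dropping cols_drop from X_full."""
    n = X_full.shape[0]
    keep = [j for j in range(X_full.shape[1]) if j not in cols_drop]
    X_red = X_full[:, keep]
    r_full = np.linalg.matrix_rank(X_full)
    r_red = np.linalg.matrix_rank(X_red)
    q = r_full - r_red
    if q < 1:
        raise ValueError(
            "effect is collinear with the remaining design columns")
    dfe = n - r_full
    H_full = X_full @ np.linalg.pinv(X_full)
    H_red = X_red @ np.linalg.pinv(X_red)
    sse_full = np.einsum("nc,nc->c", flat, flat) \
        - np.einsum("nc,nm,mc->c", flat, H_full, flat)
    sse_red = np.einsum("nc,nc->c", flat, flat) \
        - np.einsum("nc,nm,mc->c", flat, H_red, flat)
    sse_full = np.maximum(sse_full, 0.0)
    num = np.maximum(sse_red - sse_full, 0.0) / q
    den = sse_full / dfe
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))
    return F, (float(q), float(dfe))


@dataclass
class AncovaResult:
    group: AnovaResult
    covariates: list[AnovaResult]
    slope_lower: np.ndarray      # (k_cov, channel, frame)
    slope_upper: np.ndarray
    slopes: np.ndarray
    slope_significant: np.ndarray


def ancova(stack: SubjectStack, design: DesignMatrix, alpha: float = 0.05,
           n_boot: int = 1000, seed=None, keep_boot: bool = False
           ) -> AncovaResult:
    """Bootstrap ANCOVA: group and covariate partial-F tests.

    Observed Fs are OLS extra-sum-of-squares tests against the rank-
    deficient group coding.  The H0 bootstrap resamples the data rows
    only and refits them to the ORIGINAL design, breaking the data-design
    link; CIs for covariate slopes are built under H1 by resampling
    subject indices jointly (data, group membership and predictors stay
    together) with the Bonferroni-style quantile indices.
    """
    X = design.X
    n = stack.n_subjects
    if X.shape[0] != n:
        raise ValueError("design rows must equal number of subjects")
    r_full = np.linalg.matrix_rank(X)
    if n <= r_full:
        raise ValueError("need more subjects than rank(X)")
    cond_cols = design.columns_of_kind("condition")
    cov_cols = design.columns_of_kind("covariate")
    flat = stack.maps.reshape(n, -1)
    cell_shape = stack.cell_shape

    effects = []
    if cond_cols:
        effects.append(("group", cond_cols))
    for j in cov_cols:
        effects.append((design.column_names[j], [j]))
    obs = {}
    for name, cols in effects:
        F, df = _partial_f(X, cols, flat)
        obs[name] = (F, df)

    # H0: resample data rows against the original design
    rng = np.random.default_rng(seed)
    idx0 = draw_bootstrap_indices(rng, n, n_boot)
    null = {name: np.empty((n_boot, flat.shape[1])) for name, _ in effects}
    for b in range(n_boot):
        fb = flat[idx0[b]]
        for name, cols in effects:
            null[name][b] = _partial_f(X, cols, fb)[0]

    def _mk_result(name):
        F, df = obs[name]
        p_par = stats.f.sf(np.where(np.isinf(F), 0, F), *df)
        p_par = np.where(np.isinf(F), np.finfo(float).tiny, p_par)
        sm = StatMap(stat=np.maximum(F, 0.0).reshape(cell_shape), kind="F",
                     df=df,
                     p_uncorrected=np.clip(p_par, np.finfo(float).tiny, 1.0
                                           ).reshape(cell_shape))
        pb = _monte_carlo_p(F, null[name]).reshape(cell_shape)
        return AnovaResult(statmap=sm, p_boot=pb,
                           f_boot=(null[name].reshape((n_boot,) + cell_shape)
                                   if keep_boot else None))

    group_res = _mk_result("group") if cond_cols else _mk_result(effects[0][0])
    cov_res = [_mk_result(design.column_names[j]) for j in cov_cols]

    # H1: joint index resampling for covariate slope CIs (Bonferroni quantiles)
    k_cov = len(cov_cols)
    if k_cov:
        a, c = regression_ci_indices(alpha, n_boot, k_cov)
        Xp = np.linalg.pinv(X)
        slopes = (Xp @ flat)[cov_cols]
        idx1 = draw_bootstrap_indices(rng, n, n_boot)
        boot = np.empty((n_boot, k_cov, flat.shape[1]))
        for b in range(n_boot):
            rows = idx1[b]
            boot[b] = (np.linalg.pinv(X[rows]) @ flat[rows])[cov_cols]
        bs = np.sort(boot, axis=0)
        lower, upper = bs[a], bs[c - 1]
        sig = (lower > 0) | (upper < 0)
        shape = (k_cov,) + cell_shape
        slope_l, slope_u = lower.reshape(shape), upper.reshape(shape)
        slope_v, slope_s = slopes.reshape(shape), sig.reshape(shape)
    else:
        shape = (0,) + cell_shape
        slope_l = slope_u = slope_v = np.empty(shape)
        slope_s = np.empty(shape, dtype=bool)

    return AncovaResult(group=group_res, covariates=cov_res,
                        slope_lower=slope_l, slope_upper=slope_u,
                        slopes=slope_v, slope_significant=slope_s)


# ---------------------------------------------------------------------------
# optional univariate path with Huynh-Feldt correction
# ---------------------------------------------------------------------------

def rm_anova_univariate(data: np.ndarray, correction: str = "huynh-feldt"
                        ) -> StatMap:
    """Classic univariate repeated-measures F with a sphericity correction.

    The Huynh-Feldt epsilon uses the corrected formula
    eps~ = ((n - g + 1)(k-1) eps_GG - 2) / ((k-1)(n - g - (k-1) eps_GG))
    with g = 1 group, clipped at 1.  Provided as an alternative to the
    default multivariate route; not used by the correction pipeline.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None, None]
    if data.ndim == 3:
        data = data[:, :, :, None]
    n, k = data.shape[:2]
    cell_shape = data.shape[2:]
    flat = data.reshape(n, k, -1)
    subj_mean = flat.mean(axis=1, keepdims=True)
    cond_mean = flat.mean(axis=0, keepdims=True)
    grand = flat.mean(axis=(0, 1), keepdims=True)
    ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=(0, 1))
    resid = flat - subj_mean - cond_mean + grand
    ss_err = (resid ** 2).sum(axis=(0, 1))
    F = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))

    # Greenhouse-Geisser epsilon per cell from the condition covariance
    centred = flat - flat.mean(axis=0)
    S = np.einsum("nic,njc->cij", centred, centred) / (n - 1)
    C = successive_difference_contrast(k)
    Q, _ = np.linalg.qr(C.T)                       # orthonormal contrast
    V = np.einsum("ji,cjk,kl->cil", Q, S, Q)
    tr = np.einsum("cii->c", V)
    tr2 = np.einsum("cij,cji->c", V, V)
    eps_gg = tr ** 2 / ((k - 1) * tr2)
    eps_gg = np.clip(eps_gg, 1.0 / (k - 1), 1.0)
    if correction == "greenhouse-geisser":
        eps = eps_gg
    elif correction == "huynh-feldt":
        g = 1
        num = (n - g + 1) * (k - 1) * eps_gg - 2.0
        den = (k - 1) * (n - g - (k - 1) * eps_gg)
        eps = np.clip(num / den, eps_gg, 1.0)
    elif correction == "none":
        eps = np.ones_like(eps_gg)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    p = stats.f.sf(F, eps * (k - 1), eps * (k - 1) * (n - 1))
    return StatMap(stat=np.maximum(F, 0.0).reshape(cell_shape), kind="F",
                   df=(float(k - 1), float((k - 1) * (n - 1))),
                   p_uncorrected=np.clip(p, np.finfo(float).tiny, 1.0
                                         ).reshape(cell_shape))
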