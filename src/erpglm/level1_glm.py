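"""Level-1 (within-subject) single-trial mass-univariate GLM.

Each electrode's trials x frames data slice Y is fit to a shared design
matrix X (one indicator column per condition, then covariates, then a
constant), all frames at once:

    Y = X B + E,    B = pinv(X) Y.

The condition coding makes X rank deficient by construction; the
Moore-Penrose pseudoinverse yields the minimum-norm solution, and every
estimable contrast — and hence every T or F statistic — is identical to
what a full-rank reparameterization would give.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .data_model_io import BetaSet, DesignMatrix, EpochSet, FitStats, StatMap

logger = logging.getLogger("erpglm")

#: smallest positive p reported for zero-residual (degenerate) cells
P_FLOOR = np.finfo(float).tiny


def build_design_matrix(condition_labels,
                        covariates=None,
                        covariate_names=None,
                        center_covariates: bool = True) -> DesignMatrix:
    """Build a single-trial design matrix.

    Columns are: one 0/1 indicator per distinct condition (first-appearance
    order), then covariates (mean-centred by default), then a constant.

    Parameters
    ----------
    condition_labels
        Per-trial categorical labels, length = number of trials.
    covariates
        Optional trials x k array of per-trial covariates.
    center_covariates
        Subtract each covariate's mean (keeps the constant interpretable).
    """
    labels = list(condition_labels)
    n = len(labels)
    seen: dict = {}
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen)
    conds = list(seen)
    cols = []
    names = []
    kinds = []
    for lab in conds:
        cols.append(np.array([1.0 if x == lab else 0.0 for x in labels]))
        names.append(str(lab))
        kinds.append("condition")
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] == 1 and n != 1:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate rows must equal trial count")
        for j in range(C.shape[1]):
            col = C[:, j]
            if np.ptp(col) == 0:
                raise ValueError(
                    f"covariate column {j} is constant (confounded with the intercept)")
            if center_covariates:
                col = col - col.mean()
            cols.append(col)
            names.append(covariate_names[j] if covariate_names else f"cov{j}")
            kinds.append("covariate")
    cols.append(np.ones(n))
    names.append("constant")
    kinds.append("constant")
    return DesignMatrix(X=np.column_stack(cols), column_kinds=kinds,
                        column_names=names)


def fit_glm(epochs: EpochSet, design: DesignMatrix) -> tuple[BetaSet, FitStats]:
    """Fit the GLM at every channel via the Moore-Penrose pseudoinverse.

    Returns the minimum-norm parameter estimates, the residuals, per-cell
    R-squared (about the mean across trials) and MSE = SSE/dfe with
    dfe = trials - rank(X).
    """
    X = design.X
    n_tr = epochs.n_trials
    if X.shape[0] != n_tr:
        raise ValueError(
            f"design has {X.shape[0]} rows but data has {n_tr} trials")
    r = design.rank
    dfe = n_tr - r
    if dfe < 1:
        raise ValueError(
            f"no error degrees of freedom: {n_tr} trials <= rank(X) = {r}")

    Xp = np.linalg.pinv(X)                     # m x p, shared by all channels
    # Y per channel: trials x frames
    Y = epochs.data.transpose(0, 2, 1)         # channel x trial x frame
    B = np.einsum("mp,cpf->cmf", Xp, Y)        # channel x regressor x frame
    fitted = np.einsum("pm,cmf->cpf", X, B)
    E = Y - fitted
    sse = np.sum(E ** 2, axis=1)               # channel x frame
    sst = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    # zero residual variance up to float error: a perfect (degenerate) fit
    scale = np.maximum(sst, np.sum(Y ** 2, axis=1))
    degenerate = sse <= 1e-24 * np.maximum(scale, np.finfo(float).tiny)

    betaset = BetaSet(betas=B.transpose(0, 2, 1), design=design, dfe=float(dfe))
    fitstats = FitStats(residuals=E.transpose(0, 2, 1), r2=r2, mse=sse / dfe,
                        degenerate=degenerate)
    return betaset, fitstats


def is_estimable(design: DesignMatrix, c: np.ndarray,
                 rtol: float = 1e-10) -> bool:
    """A contrast is estimable iff it lies in the row space of X."""
    c = np.asarray(c, dtype=float)
    X = design.X
    proj = X.T @ np.linalg.pinv(X).T @ c   # projection onto row space
    return bool(np.linalg.norm(c - proj) <= rtol * max(np.linalg.norm(c), 1.0))


def contrast(betaset: BetaSet, fitstats: FitStats, c) -> StatMap:
    """T (vector contrast) or F (matrix contrast) map over all cells.

    T = c'b / sqrt(MSE * c'(X'X)^+ c); for a q x m contrast matrix C,
    F = (Cb)'[C (X'X)^+ C']^{-1} (Cb) / (rank(C) * MSE) with
    (rank(C), dfe) degrees of freedom.  Zero-MSE cells are reported at the
    p floor with a degenerate flag.
    """
    X = betaset.design.X
    dfe = betaset.dfe
    c_arr = np.asarray(c, dtype=float)
    as_matrix = c_arr.ndim == 2          # 2-D input always yields an F map
    C = np.atleast_2d(c_arr)
    if C.shape[1] != betaset.design.n_columns:
        raise ValueError(
            f"contrast has {C.shape[1]} entries, design has "
            f"{betaset.design.n_columns} columns")
    if not np.any(C):
        raise ValueError("contrast is all zeros")
    for row in C:
        if not is_estimable(betaset.design, row):
            raise ValueError(
                f"non-estimable contrast {row}: not in the row space of X")

    xtx_pinv = np.linalg.pinv(X.T @ X)
    mse = fitstats.mse                              # channel x frame
    degenerate = fitstats.degenerate
    eff = np.einsum("qm,cfm->cfq", C, betaset.betas)   # C b per cell

    if C.shape[0] == 1 and not as_matrix:
        cvar = float((C @ xtx_pinv @ C.T).item())
        denom = np.sqrt(np.where(degenerate, 1.0, mse * cvar))
        with np.errstate(invalid="ignore"):
            T = np.where(degenerate,
                         np.sign(eff[..., 0]) * np.inf,
                         eff[..., 0] / denom)
        T = np.where(degenerate & (eff[..., 0] == 0), 0.0, T)
        with np.errstate(invalid="ignore"):
            p = 2.0 * stats.t.sf(np.abs(np.where(np.isinf(T), 0, T)), dfe)
        p = np.where(np.isinf(T) | (degenerate & (eff[..., 0] != 0)),
                     P_FLOOR, p)
        p = np.where(degenerate & (eff[..., 0] == 0), 1.0, p)
        return StatMap(stat=T, kind="T", df=(1.0, dfe),
                       p_uncorrected=np.clip(p, P_FLOOR, 1.0),
                       degenerate=degenerate)

    q = int(np.linalg.matrix_rank(C))
    M = C @ xtx_pinv @ C.T
    Minv = np.linalg.pinv(M)
    quad = np.einsum("cfq,qr,cfr->cf", eff, Minv, eff)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(degenerate, np.inf, quad / (q * np.where(degenerate, 1.0, mse)))
    F = np.where(degenerate & (quad == 0), 0.0, F)
    p = stats.f.sf(np.where(np.isinf(F), 0, F), q, dfe)
    p = np.where(np.isinf(F), P_FLOOR, p)
    p = np.where(degenerate & (quad == 0), 1.0, p)
    return StatMap(stat=np.maximum(F, 0.0), kind="F", df=(float(q), dfe),
                   p_uncorrected=np.clip(p, P_FLOOR, 1.0),
                   degenerate=degenerate)


def select_optimized_electrode(fitstats_per_subject,
                               aggregate: str = "max_r2_overall",
                               frame: int | None = None) -> np.ndarray:
    """Pick, per subject, the channel with the strongest model fit (R^2).

    ``max_r2_overall`` maximizes the per-channel max of R^2 over frames;
    ``max_r2_at_frame`` maximizes R^2 at a given frame.  Ties go to the
    lowest channel index (logged).
    """
    picks = []
    for i, fs in enumerate(fitstats_per_subject):
        if aggregate == "max_r2_overall":
            score = fs.r2.max(axis=1)
        elif aggregate == "max_r2_at_frame":
            if frame is None:
                raise ValueError("max_r2_at_frame requires a frame index")
            score = fs.r2[:, frame]
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        best = int(np.argmax(score))
        if np.sum(score == score[best]) > 1:
            logger.warning("subject %d: R^2 tie; choosing lowest channel %d",
                           i, best)
        picks.append(best)
    return np.array(picks, dtype=int)
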