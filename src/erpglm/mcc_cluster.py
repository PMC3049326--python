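"""Familywise-error control over channels x frames.

Three corrections, all driven by the same H0 bootstrap of the underlying
second-level test (each resample yields a full map of F -- or t^2 --
values computed under a true or estimated null):

1. **max statistic** -- the empirical distribution of the per-resample
   maximum over all cells gives an exact-height threshold;
2. **spatio-temporal cluster sum** -- suprathreshold cells are grouped
   into clusters connected in space (channel neighbourhood) and time, and
   an observed cluster is significant when its sum of F values beats the
   null distribution of per-resample maximum cluster sums;
3. **temporal cluster sum** -- clusters are formed per channel along time
   only; each resample contributes the largest per-channel run sum.

t statistics are squared before clustering, so all effects live in F
space; direction is read off the sign of the difference map separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .data_model_io import (BootstrapNull, ClusterSet, NeighbourhoodGraph,
                            StatMap)
from .level2_anova import _oneway_f_boot, _hotelling_t2, _partial_f
from .level2_anova import successive_difference_contrast
from .level2_robust import SubjectStack, draw_bootstrap_indices, _boot_mean_sd


# ---------------------------------------------------------------------------
# H0 resampling drivers
# ---------------------------------------------------------------------------

def h0_resample_maps(test_spec: str, data, n_boot: int, seed=None
                     ) -> np.ndarray:
    """B full channels x frames maps of F (or t^2) under H0.

    The resampling scheme follows the test: one-sample / paired /
    two-sample and the ANOVAs centre each cell (group / condition) before
    resampling subjects with replacement, so the null is exactly true;
    regression and ANCOVA resample the data rows against the original
    design matrix, breaking the data-predictor link.  Within one
    resample, a single subject-index draw produces the entire map.

    Returns an array (n_boot, channel, frame); t statistics are squared.
    """
    rng = np.random.default_rng(seed)
    if test_spec == "one_sample":
        stack = data if isinstance(data, SubjectStack) else SubjectStack(data)
        maps = stack.maps
        centred = maps - maps.mean(axis=0)
        return _t2_resample(centred, rng, n_boot)
    if test_spec == "paired":
        s1, s2 = data
        d = np.asarray(s1.maps if isinstance(s1, SubjectStack) else s1) \
            - np.asarray(s2.maps if isinstance(s2, SubjectStack) else s2)
        centred = d - d.mean(axis=0)
        return _t2_resample(centred, rng, n_boot)
    if test_spec == "two_sample":
        s1, s2 = data
        a = s1.maps if isinstance(s1, SubjectStack) else np.asarray(s1)
        b = s2.maps if isinstance(s2, SubjectStack) else np.asarray(s2)
        ca, cb = a - a.mean(axis=0), b - b.mean(axis=0)
        ia = draw_bootstrap_indices(rng, ca.shape[0], n_boot)
        ib = draw_bootstrap_indices(rng, cb.shape[0], n_boot)
        m1, s1_ = _boot_mean_sd(ca, ia)
        m2, s2_ = _boot_mean_sd(cb, ib)
        n1, n2 = ca.shape[0], cb.shape[0]
        se2 = s1_ ** 2 / n1 + s2_ ** 2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se2 > 0, (m1 - m2) / np.sqrt(se2), 0.0)
        return t ** 2
    if test_spec == "anova":
        stacks = [s.maps if isinstance(s, SubjectStack) else np.asarray(s)
                  for s in data]
        centred = [g - g.mean(axis=0) for g in stacks]
        idx = [draw_bootstrap_indices(rng, g.shape[0], n_boot)
               for g in centred]
        return _oneway_f_boot(centred, idx)
    if test_spec == "rm_anova":
        arr = np.asarray(data, dtype=float)
        n, k = arr.shape[:2]
        cell_shape = arr.shape[2:]
        flat = arr.reshape(n, k, -1)
        centred = flat - flat.mean(axis=0)
        C = successive_difference_contrast(k)
        conv = (n - k + 1) / ((n - 1.0) * (k - 1.0))
        idx = draw_bootstrap_indices(rng, n, n_boot)
        out = np.empty((n_boot,) + cell_shape)
        for b in range(n_boot):
            db = np.einsum("jk,nkc->njc", C, centred[idx[b]])
            out[b] = (_hotelling_t2(db, allow_pinv=True) * conv
                      ).reshape(cell_shape)
        return out
    if test_spec in ("regression", "ancova"):
        stack, design = data
        maps = stack.maps if isinstance(stack, SubjectStack) else np.asarray(stack)
        X = np.asarray(getattr(design, "X", design), dtype=float)
        if hasattr(design, "columns_of_kind"):
            if test_spec == "ancova":
                cols = design.columns_of_kind("condition")
            else:
                cols = design.columns_of_kind("covariate")
        else:   # bare matrix: last column is the constant
            cols = list(range(X.shape[1] - 1))
        n = maps.shape[0]
        flat = maps.reshape(n, -1)
        idx = draw_bootstrap_indices(rng, n, n_boot)
        out = np.empty((n_boot, flat.shape[1]))
        for b in range(n_boot):
            out[b] = _partial_f(X, cols, flat[idx[b]])[0]
        return out.reshape((n_boot,) + maps.shape[1:])
    raise ValueError(f"unknown H0 resampling scheme {test_spec!r}")


def _t2_resample(centred: np.ndarray, rng: np.random.Generator,
                 n_boot: int) -> np.ndarray:
    n = centred.shape[0]
    idx = draw_bootstrap_indices(rng, n, n_boot)
    m, s = _boot_mean_sd(centred, idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s > 0, m / (s / math.sqrt(n)), 0.0)
    return t ** 2


# ---------------------------------------------------------------------------
# Method 1: maximum statistic
# ---------------------------------------------------------------------------

@dataclass
class MaxStatResult:
    critical: float
    significant: np.ndarray          # boolean [channel, frame]
    null: BootstrapNull


def one_sided_critical_index(alpha: float, n_boot: int) -> int:
    """1-based position of the (1 - alpha) empirical quantile: ceil((1-alpha)B)."""
    return int(math.ceil((1.0 - alpha) * n_boot))


def max_stat_correct(observed: StatMap, null_maps: np.ndarray,
                     alpha: float = 0.05) -> MaxStatResult:
    """Height threshold from the H0 distribution of per-resample maxima.

    A cell is significant iff its F (or t^2) reaches the empirical
    (1 - alpha) quantile of the maximum statistic over all cells under H0.
    """
    null_maps = np.asarray(null_maps, dtype=float)
    B = null_maps.shape[0]
    if B < 1.0 / alpha:
        raise ValueError(f"need at least {math.ceil(1 / alpha)} null maps "
                         f"for alpha={alpha}")
    stat = observed.stat ** 2 if observed.kind == "T" else observed.stat
    null_max = np.sort(null_maps.reshape(B, -1).max(axis=1))
    pos = one_sided_critical_index(alpha, B)
    critical = -np.inf if pos < 1 else float(null_max[pos - 1])
    return MaxStatResult(critical=critical, significant=stat >= critical,
                         null=BootstrapNull(values=null_max,
                                            method="max_stat", alpha=alpha))


# ---------------------------------------------------------------------------
# space-time connectivity
# ---------------------------------------------------------------------------

def spacetime_edges(graph: NeighbourhoodGraph | None, n_channels: int,
                    n_frames: int, include_diagonal: bool = False
                    ) -> np.ndarray:
    """Edge list over flattened (channel, frame) cells, C order.

    Two cells are connected iff they share a channel and are adjacent in
    time, or share a frame and their channels are graph neighbours.  With
    ``include_diagonal`` the channel-and-frame-adjacent corner cells are
    connected too (off by default).
    """
    edges = []
    node = lambda c, f: c * n_frames + f
    for c in range(n_channels):
        for f in range(n_frames - 1):
            edges.append((node(c, f), node(c, f + 1)))
    if graph is not None:
        if graph.n_channels != n_channels:
            raise ValueError("graph channels must match the map")
        ii, jj = np.nonzero(np.triu(graph.adjacency, k=1))
        for a, b in zip(ii, jj):
            for f in range(n_frames):
                edges.append((node(a, f), node(b, f)))
            if include_diagonal:
                for f in range(n_frames - 1):
                    edges.append((node(a, f), node(b, f + 1)))
                    edges.append((node(a, f + 1), node(b, f)))
    return np.array(edges, dtype=np.int64).reshape(-1, 2)


def connected_components_spacetime(mask: np.ndarray,
                                   graph: NeighbourhoodGraph | None,
                                   include_diagonal: bool = False
                                   ) -> np.ndarray:
    """Label connected space-time components of a boolean mask.

    Returns an integer [channel, frame] array; 0 is background and
    cluster ids are assigned in scan (C) order of first appearance.
    """
    mask = np.asarray(mask, dtype=bool)
    n_ch, n_fr = mask.shape
    edges = spacetime_edges(graph, n_ch, n_fr, include_diagonal)
    flat = mask.ravel()
    nodes = np.flatnonzero(flat)
    labels = np.zeros(flat.size, dtype=int)
    if nodes.size:
        keep = flat[edges[:, 0]] & flat[edges[:, 1]]
        e = edges[keep]
        local = -np.ones(flat.size, dtype=np.int64)
        local[nodes] = np.arange(nodes.size)
        A = coo_matrix((np.ones(e.shape[0]), (local[e[:, 0]], local[e[:, 1]])),
                       shape=(nodes.size, nodes.size))
        _, comp = _cc(A, directed=False)
        # deterministic relabelling: first appearance in scan order
        order = {}
        lab = np.empty(nodes.size, dtype=int)
        for i, c in enumerate(comp):
            if c not in order:
                order[c] = len(order) + 1
            lab[i] = order[c]
        labels[nodes] = lab
    return labels.reshape(n_ch, n_fr)


def max_cluster_sum(stat_flat: np.ndarray, mask_flat: np.ndarray,
                    edges: np.ndarray) -> float:
    """Largest component sum of ``stat`` over a masked cell set.

    Union-find over the precomputed edge list; a resample with no
    suprathreshold cells contributes 0.  Used in the hot loop of the
    cluster null, so it avoids building sparse matrices.
    """
    nodes = np.flatnonzero(mask_flat)
    if nodes.size == 0:
        return 0.0
    keep = mask_flat[edges[:, 0]] & mask_flat[edges[:, 1]]
    active = edges[keep]
    local = np.empty(mask_flat.size, dtype=np.int64)
    local[nodes] = np.arange(nodes.size)
    parent = list(range(nodes.size))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in zip(local[active[:, 0]], local[active[:, 1]]):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = np.fromiter((find(i) for i in range(nodes.size)), dtype=np.int64)
    sums = np.bincount(roots, weights=stat_flat[nodes])
    return float(sums.max())


# ---------------------------------------------------------------------------
# Methods 2 & 3: cluster-sum corrections
# ---------------------------------------------------------------------------

def cluster_sum_correct(observed: StatMap, null_maps: np.ndarray,
                        graph: NeighbourhoodGraph | None = None,
                        alpha: float = 0.05, forming_alpha: float = 0.05,
                        mode: str = "spatiotemporal",
                        include_diagonal: bool = False,
                        null_masks: np.ndarray | None = None) -> ClusterSet:
    """Cluster-sum familywise correction (spatio-temporal or temporal).

    Clusters are formed from cells whose parametric uncorrected p falls
    below ``forming_alpha``; the test statistic of a cluster is the sum of
    its F (or t^2) values.  Each null resample contributes its maximum
    cluster sum, formed the same way (via the parametric critical value of
    the observed map's reference distribution, or explicit ``null_masks``).
    A cluster is significant iff its sum reaches the empirical (1 - alpha)
    quantile of the null maxima; its corrected p is the add-one
    Monte-Carlo proportion of null maxima at or above its sum.
    """
    if mode not in ("spatiotemporal", "temporal"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "spatiotemporal" and graph is None:
        raise ValueError("spatiotemporal mode requires a neighbourhood graph")
    null_maps = np.asarray(null_maps, dtype=float)
    B, n_ch, n_fr = null_maps.shape
    stat = observed.stat ** 2 if observed.kind == "T" else observed.stat
    if stat.shape != (n_ch, n_fr):
        raise ValueError("observed map and null maps have different shapes")

    use_graph = graph if mode == "spatiotemporal" else None
    edges = spacetime_edges(use_graph, n_ch, n_fr, include_diagonal)

    obs_mask = observed.p_uncorrected < forming_alpha
    labels = connected_components_spacetime(obs_mask, use_graph,
                                            include_diagonal)
    n_clusters = labels.max()
    sums = np.array([stat[labels == i].sum() for i in range(1, n_clusters + 1)])

    if null_masks is None:
        q, dfe = observed.df
        crit = stats.f.ppf(1.0 - forming_alpha, q, dfe)
        null_masks = null_maps >= crit
    null_max = np.empty(B)
    flat_maps = null_maps.reshape(B, -1)
    flat_masks = np.asarray(null_masks, dtype=bool).reshape(B, -1)
    for b in range(B):
        null_max[b] = max_cluster_sum(flat_maps[b], flat_masks[b], edges)
    null_sorted = np.sort(null_max)
    pos = one_sided_critical_index(alpha, B)
    critical = -np.inf if pos < 1 else float(null_sorted[pos - 1])

    p_corr = np.array([(1.0 + np.sum(null_max >= s)) / (B + 1.0)
                       for s in sums])
    significant = sums >= critical if sums.size else np.zeros(0, dtype=bool)
    return ClusterSet(labels=labels, sums=sums, p_corrected=p_corr,
                      significant=significant, critical_sum=critical)


def cluster_table(clusters: ClusterSet, times_ms: np.ndarray | None = None,
                  channel_labels=None) -> list[dict]:
    """Flat per-cluster summary rows (id, channels, frame span, sum, p)."""
    rows = []
    for i in range(1, clusters.labels.max() + 1):
        ch, fr = np.nonzero(clusters.labels == i)
        chans = sorted(set(ch.tolist()))
        if channel_labels is not None:
            chans = [channel_labels[c] for c in chans]
        span = (int(fr.min()), int(fr.max()))
        if times_ms is not None:
            span = (float(times_ms[span[0]]), float(times_ms[span[1]]))
        rows.append({
            "cluster": i,
            "channels": chans,
            "frame_span": span,
            "n_cells": int(ch.size),
            "sum": float(clusters.sums[i - 1]),
            "p_corrected": float(clusters.p_corrected[i - 1]),
            "significant": bool(clusters.significant[i - 1]),
        })
    return rows
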