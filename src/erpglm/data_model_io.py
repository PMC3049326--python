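"""Domain containers and file I/O for the two-level ERP GLM pipeline.

Data follow the common EEG convention of a 3-D cube indexed
``[channel, frame, trial]``.  Epoched data and statistical maps are
exchanged as HDF5 containers with fixed dataset names; design matrices
and channel neighbourhoods travel as plain CSV so they stay hand-editable.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

logger = logging.getLogger("erpglm")

#: Column roles a design matrix may carry.
COLUMN_KINDS = ("condition", "covariate", "constant")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Epoched multichannel data: ``data[channel, frame, trial]``."""

    data: np.ndarray
    channel_labels: list[str]
    times_ms: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D [channel, frame, trial]")
        if np.isnan(self.data).any():
            raise ValueError("data contains NaN")
        n_ch, n_fr, n_tr = self.data.shape
        if len(self.channel_labels) != n_ch:
            raise ValueError(
                f"channel_labels length {len(self.channel_labels)} != {n_ch} channels"
            )
        if self.times_ms.shape != (n_fr,):
            raise ValueError(f"times_ms length {self.times_ms.size} != {n_fr} frames")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("times_ms must be strictly increasing")
        if n_tr < 1:
            raise ValueError("need at least one trial")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


@dataclass
class DesignMatrix:
    """Trials (or subjects) x regressors matrix with per-column roles."""

    X: np.ndarray
    column_kinds: list[str]
    column_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if len(self.column_kinds) != self.X.shape[1]:
            raise ValueError("column_kinds length must match number of columns")
        if len(self.column_names) != self.X.shape[1]:
            raise ValueError("column_names length must match number of columns")
        for kind in self.column_kinds:
            if kind not in COLUMN_KINDS:
                raise ValueError(f"unknown column kind {kind!r}")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))

    def columns_of_kind(self, kind: str) -> list[int]:
        return [i for i, k in enumerate(self.column_kinds) if k == kind]


@dataclass
class BetaSet:
    """Estimated GLM parameters: ``betas[channel, frame, regressor]``."""

    betas: np.ndarray
    design: DesignMatrix
    dfe: float

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be 3-D [channel, frame, regressor]")
        if self.betas.shape[2] != self.design.n_columns:
            raise ValueError("regressor axis must match design columns")
        if not self.dfe >= 1:
            raise ValueError("dfe must be >= 1")


@dataclass
class FitStats:
    """Residuals and per-cell goodness of fit from a level-1 fit."""

    residuals: np.ndarray      # [channel, frame, trial]
    r2: np.ndarray             # [channel, frame]
    mse: np.ndarray            # [channel, frame], SSE / dfe
    degenerate: np.ndarray | None = None   # cells with zero residual variance

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        self.mse = np.asarray(self.mse, dtype=float)
        if self.degenerate is None:
            self.degenerate = self.mse <= 0


@dataclass
class StatMap:
    """A channels x frames map of T or F values with df and uncorrected p."""

    stat: np.ndarray
    kind: str                  # "T" or "F"
    df: tuple[float, float]
    p_uncorrected: np.ndarray
    degenerate: np.ndarray | None = None   # cells where the error variance was 0

    def __post_init__(self) -> None:
        self.stat = np.asarray(self.stat, dtype=float)
        self.p_uncorrected = np.asarray(self.p_uncorrected, dtype=float)
        if self.kind not in ("T", "F"):
            raise ValueError("kind must be 'T' or 'F'")
        if self.kind == "F" and np.any(self.stat < 0):
            raise ValueError("F maps must be non-negative")
        if self.stat.shape != self.p_uncorrected.shape:
            raise ValueError("stat and p_uncorrected shapes differ")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.stat.shape, dtype=bool)


@dataclass
class ConfidenceMap:
    """Elementwise confidence band with the bootstrap quantile bookkeeping."""

    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    n_boot: int
    quantile_low_index: int
    quantile_high_index: int
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("lower bound exceeds upper bound")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.lower.shape, dtype=bool)


@dataclass
class BootstrapNull:
    """Sorted null distribution of per-resample maxima (statistic or cluster sum)."""

    values: np.ndarray
    method: str                # max_stat | st_cluster | t_cluster
    alpha: float

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))

    @property
    def n_boot(self) -> int:
        return self.values.size


@dataclass
class NeighbourhoodGraph:
    """Symmetric, irreflexive channel adjacency used for spatial clustering."""

    adjacency: np.ndarray
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=bool)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            logger.warning("nonzero diagonal in adjacency; zeroing self-edges")
            A = A.copy()
            np.fill_diagonal(A, False)
        self.adjacency = A

    @property
    def n_channels(self) -> int:
        return self.adjacency.shape[0]

    @classmethod
    def empty(cls, n_channels: int) -> "NeighbourhoodGraph":
        return cls(np.zeros((n_channels, n_channels), dtype=bool))

    @classmethod
    def chain(cls, n_channels: int) -> "NeighbourhoodGraph":
        """First-order chain: channel i adjacent to i-1 and i+1."""
        A = np.zeros((n_channels, n_channels), dtype=bool)
        idx = np.arange(n_channels - 1)
        A[idx, idx + 1] = A[idx + 1, idx] = True
        return cls(A)


@dataclass
class ClusterSet:
    """Labelled space-time clusters with their sums and corrected p-values."""

    labels: np.ndarray          # [channel, frame]; 0 = background
    sums: np.ndarray            # per-cluster sum of F (or t^2)
    p_corrected: np.ndarray
    significant: np.ndarray
    critical_sum: float = np.nan

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sums = np.asarray(self.sums, dtype=float)
        self.p_corrected = np.asarray(self.p_corrected, dtype=float)
        self.significant = np.asarray(self.significant, dtype=bool)

    @property
    def n_clusters(self) -> int:
        return self.sums.size


@dataclass
class DiffDistribution:
    """Sorted bootstrap distribution of mean differences or slopes per cell."""

    diffs: np.ndarray           # [..., B], sorted ascending along the last axis
    index_low: int              # 1-based position of the lower CI bound
    index_high: int             # 1-based position of the upper CI bound

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=float)
        B = self.diffs.shape[-1]
        if not (1 <= self.index_low <= B and 1 <= self.index_high <= B):
            raise ValueError("CI indices must lie in [1, B]")


# ---------------------------------------------------------------------------
# HDF5 readers / writers
# ---------------------------------------------------------------------------

_EPOCH_DATASETS = ("data", "channel_labels", "times_ms", "sampling_rate_hz")


def read_epochs(path: str | Path) -> EpochSet:
    """Read an :class:`EpochSet` from an HDF5 container.

    The container must hold datasets ``data`` (channel x frame x trial),
    ``channel_labels``, ``times_ms`` and ``sampling_rate_hz``.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in _EPOCH_DATASETS:
            if name not in f:
                raise KeyError(f"{name} absent from {path}")
        data = f["data"][()]
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in f["channel_labels"][()]]
        times = f["times_ms"][()]
        sr = float(f["sampling_rate_hz"][()])
    return EpochSet(data=data, channel_labels=labels, times_ms=times,
                    sampling_rate_hz=sr)


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("channel_labels",
                         data=np.array(epochs.channel_labels, dtype="S"))
        f.create_dataset("times_ms", data=epochs.times_ms)
        f.create_dataset("sampling_rate_hz", data=epochs.sampling_rate_hz)


def write_statmap(statmap: StatMap, path: str | Path) -> None:
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("stat", data=statmap.stat)
        f.create_dataset("p_uncorrected", data=statmap.p_uncorrected)
        f.create_dataset("degenerate", data=statmap.degenerate)
        f.attrs["kind"] = statmap.kind
        f.attrs["df"] = statmap.df


def read_statmap(path: str | Path) -> StatMap:
    with h5py.File(Path(path), "r") as f:
        return StatMap(
            stat=f["stat"][()],
            kind=str(f.attrs["kind"]),
            df=tuple(float(v) for v in f.attrs["df"]),
            p_uncorrected=f["p_uncorrected"][()],
            degenerate=f["degenerate"][()].astype(bool),
        )


def write_betaset(betaset: BetaSet, path: str | Path) -> None:
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("betas", data=betaset.betas)
        f.create_dataset("design", data=betaset.design.X)
        f.create_dataset("column_kinds",
                         data=np.array(betaset.design.column_kinds, dtype="S"))
        f.create_dataset("column_names",
                         data=np.array(betaset.design.column_names, dtype="S"))
        f.attrs["dfe"] = betaset.dfe


def read_betaset(path: str | Path) -> BetaSet:
    with h5py.File(Path(path), "r") as f:
        design = DesignMatrix(
            X=f["design"][()],
            column_kinds=[s.decode() for s in f["column_kinds"][()]],
            column_names=[s.decode() for s in f["column_names"][()]],
        )
        return BetaSet(betas=f["betas"][()], design=design,
                       dfe=float(f.attrs["dfe"]))


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> DesignMatrix:
    """Read a design matrix from CSV.

    Line 1: column names.  Line 2: column kinds (condition/covariate/constant).
    Remaining lines: numeric rows.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise ValueError(f"{path}: need name row, kind row and >=1 data row")
    names = [c.strip() for c in rows[0]]
    kinds = [c.strip() for c in rows[1]]
    X = np.array([[float(v) for v in r] for r in rows[2:]], dtype=float)
    return DesignMatrix(X=X, column_kinds=kinds, column_names=names)


def write_design(design: DesignMatrix, path: str | Path) -> None:
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(design.column_names)
        w.writerow(design.column_kinds)
        for row in design.X:
            w.writerow([repr(float(v)) for v in row])


def read_neighbourhood(path: str | Path,
                       channel_labels: Sequence[str] | None = None,
                       ) -> NeighbourhoodGraph:
    """Read a channel neighbourhood from CSV.

    Two dialects are accepted:

    * a square 0/1 matrix with a header row and a leading label column;
    * an edge list, one ``label_a,label_b`` pair per line (no header).

    The result is symmetrized; an explicit asymmetric 0/1 conflict in the
    matrix dialect is an error.  When ``channel_labels`` is given, the edge
    list is resolved against it and the matrix row order is checked.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"{path}: empty neighbourhood file")

    is_matrix = len(rows) >= 2 and len(rows[0]) == len(rows) and len(rows[0]) > 2
    if is_matrix:
        header = [c.strip() for c in rows[0][1:]]
        labels_col = [r[0].strip() for r in rows[1:]]
        if header != labels_col:
            raise ValueError(f"{path}: header row and label column disagree")
        M = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
        if np.any((M != 0) & (M != 1)):
            raise ValueError(f"{path}: adjacency entries must be 0 or 1")
        if not np.array_equal(M, M.T):
            raise ValueError(f"{path}: explicit asymmetric adjacency (1 vs 0)")
        graph = NeighbourhoodGraph(M.astype(bool), channel_labels=header)
    else:
        # edge list
        edge_labels = sorted({c.strip() for r in rows for c in r[:2]})
        labels = list(channel_labels) if channel_labels is not None else edge_labels
        index = {lab: i for i, lab in enumerate(labels)}
        A = np.zeros((len(labels), len(labels)), dtype=bool)
        for r in rows:
            a, b = r[0].strip(), r[1].strip()
            for lab in (a, b):
                if lab not in index:
                    raise ValueError(f"{path}: unknown channel label {lab!r}")
            if a != b:
                A[index[a], index[b]] = A[index[b], index[a]] = True
        graph = NeighbourhoodGraph(A, channel_labels=labels)

    if channel_labels is not None:
        missing = set(graph.channel_labels or []) - set(channel_labels)
        if missing:
            raise ValueError(
                f"adjacency labels {sorted(missing)} not present in the data")
    return graph


def write_neighbourhood(graph: NeighbourhoodGraph, path: str | Path) -> None:
    labels = graph.channel_labels or [f"ch{i}" for i in range(graph.n_channels)]
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + list(labels))
        for lab, row in zip(labels, graph.adjacency.astype(int)):
            w.writerow([lab] + list(row))


def write_run_log(path: str | Path, **entries) -> None:
    """Write a JSON run-log (inputs, seed, versions) next to an output file."""
    import scipy

    log = {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        **{k: (str(v) if isinstance(v, Path) else v) for k, v in entries.items()},
    }
    with open(Path(path), "w") as fh:
        json.dump(log, fh, indent=2, default=str)
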