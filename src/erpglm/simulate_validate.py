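"""Synthetic evoked-response data and the type-I-error validation harness.

The generator emulates a face-discrimination-style recording at desk
scale: a small number of channels carrying one or more Gaussian-windowed
ERP components (a spatial weight vector times a temporal bump), additive
trial-level condition offsets and covariate slopes on the component
amplitude, and spatially correlated Gaussian noise (first-order
autoregressive filter across the channel axis).

The validation harness reproduces the cluster-correction experiment: two
"fake conditions" are drawn from a common null pool of trials, and the
familywise error rate of three resampling schemes -- random partitioning
(permutation), pooled with-replacement sampling (bootstrap), and
independent per-group sampling after mean-centring (centered bootstrap)
-- is measured with the spatio-temporal max-cluster-sum correction on
squared Welch t values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .data_model_io import EpochSet, NeighbourhoodGraph
from .level1_glm import build_design_matrix, fit_glm
from .mcc_cluster import max_cluster_sum, one_sided_critical_index, \
    spacetime_edges


@dataclass
class ErpComponent:
    """One evoked component: spatial weights x Gaussian temporal window."""

    channel_weights: np.ndarray
    latency_ms: float
    width_ms: float
    amplitude: float

    def __post_init__(self) -> None:
        self.channel_weights = np.asarray(self.channel_weights, dtype=float)
        if not self.width_ms > 0:
            raise ValueError("component width must be positive")


def _default_components(n_channels: int) -> list[ErpComponent]:
    # one posterior-looking component peaking mid-array, ~N170 latency
    peak = n_channels // 2
    w = np.exp(-0.5 * ((np.arange(n_channels) - peak) / 1.5) ** 2)
    return [ErpComponent(channel_weights=w, latency_ms=170.0, width_ms=25.0,
                         amplitude=5.0)]


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic generator.

    Times run 0..(n_frames-1)/sampling_rate; amplitudes are in arbitrary
    microvolt-like units.  ``noise_sd`` is the per-cell noise SD and
    ``channel_corr`` the lag-one spatial correlation of the noise.
    """

    n_channels: int = 8
    n_frames: int = 50
    n_trials: int = 200
    sampling_rate_hz: float = 250.0
    erp_components: list[ErpComponent] = field(default_factory=list)
    noise_sd: float = 5.0
    channel_corr: float = 0.6
    trial_covariate_effect: float = 0.0
    subject_covariate_effect: float = 0.0
    between_subject_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.channel_corr < 1:
            raise ValueError("channel_corr must lie in [0, 1)")
        if not self.erp_components:
            self.erp_components = _default_components(self.n_channels)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * 1000.0 / self.sampling_rate_hz


def _spatially_correlated_noise(rng: np.random.Generator, n_ch: int,
                                n_fr: int, n_tr: int, rho: float,
                                sd: float) -> np.ndarray:
    """AR(1) filter across channels; unit marginal variance, scaled by sd."""
    w = rng.standard_normal((n_ch, n_fr, n_tr))
    out = np.empty_like(w)
    out[0] = w[0]
    scale = math.sqrt(1.0 - rho ** 2)
    for c in range(1, n_ch):
        out[c] = rho * out[c - 1] + scale * w[c]
    return sd * out


def generate_erp_epochs(spec: SimulationSpec, condition_labels=None,
                        covariate=None, condition_offsets=None,
                        rng=None) -> EpochSet:
    """Synthesize an epoched recording.

    Each trial is the sum over components of
    (amplitude + slope * covariate + condition offset) x spatial weights
    x Gaussian temporal window, plus spatially correlated noise.
    """
    if rng is None or not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.seed if rng is None else rng)
    n_ch, n_fr, n_tr = spec.n_channels, spec.n_frames, spec.n_trials
    if condition_labels is not None and len(condition_labels) != n_tr:
        raise ValueError("condition_labels length must equal n_trials")
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)
        if covariate.size != n_tr:
            raise ValueError("covariate length must equal n_trials")
    offsets = np.zeros(n_tr)
    if condition_offsets is not None and condition_labels is not None:
        offsets = np.array([condition_offsets.get(lab, 0.0)
                            for lab in condition_labels])

    t = spec.times_ms
    data = np.zeros((n_ch, n_fr, n_tr))
    for comp in spec.erp_components:
        window = np.exp(-0.5 * ((t - comp.latency_ms) / comp.width_ms) ** 2)
        amp = np.full(n_tr, comp.amplitude)
        if covariate is not None:
            amp = amp + spec.trial_covariate_effect * covariate
        amp = amp + offsets
        data += (comp.channel_weights[:, None, None]
                 * window[None, :, None] * amp[None, None, :])
    data += _spatially_correlated_noise(rng, n_ch, n_fr, n_tr,
                                        spec.channel_corr, spec.noise_sd)
    return EpochSet(data=data,
                    channel_labels=[f"ch{i}" for i in range(n_ch)],
                    times_ms=t, sampling_rate_hz=spec.sampling_rate_hz)


def generate_group_dataset(spec: SimulationSpec, n_subjects: int,
                           between_covariate=None, seed=None):
    """Simulate a group and run the level-1 fits: the full two-level path.

    Each subject gets a trial-level design with two conditions (A/B, split
    evenly) and one uniform(0, 1) trial covariate.  The subject's true
    covariate slope is
    ``trial_covariate_effect + subject_covariate_effect * z_s + N(0, between_subject_sd)``
    where z_s is the (centred) between-subject covariate, so a nonzero
    ``subject_covariate_effect`` makes the covariate beta map depend
    linearly on the subject predictor.  Returns the per-subject BetaSets,
    FitStats and the design used.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if between_covariate is None:
        between_covariate = np.zeros(n_subjects)
    z = np.asarray(between_covariate, dtype=float)
    z_c = z - z.mean()
    betasets, fitstats_list = [], []
    labels = ["A" if i < spec.n_trials // 2 else "B"
              for i in range(spec.n_trials)]
    for s in range(n_subjects):
        slope = (spec.trial_covariate_effect
                 + spec.subject_covariate_effect * z_c[s]
                 + spec.between_subject_sd * rng.standard_normal())
        sub_spec = SimulationSpec(
            n_channels=spec.n_channels, n_frames=spec.n_frames,
            n_trials=spec.n_trials, sampling_rate_hz=spec.sampling_rate_hz,
            erp_components=spec.erp_components, noise_sd=spec.noise_sd,
            channel_corr=spec.channel_corr, trial_covariate_effect=slope)
        cov = rng.uniform(0.0, 1.0, size=spec.n_trials)
        epochs = generate_erp_epochs(sub_spec, condition_labels=labels,
                                     covariate=cov, rng=rng)
        design = build_design_matrix(labels, covariates=cov[:, None],
                                     covariate_names=["cov"])
        bs, fs = fit_glm(epochs, design)
        betasets.append(bs)
        fitstats_list.append(fs)
    return betasets, fitstats_list


# ---------------------------------------------------------------------------
# type-I-error experiment
# ---------------------------------------------------------------------------

METHODS = ("permutation", "bootstrap", "centered_bootstrap")


def selection_matrices(method: str, rng: np.random.Generator, n_pool: int,
                       n_per_group: int, n_resample: int):
    """Per-resample group-selection count matrices for one scheme.

    Returns (S1, S2) of shape (n_resample, n_pool) for the pooled schemes
    (permutation: exact 0/1 partitions; bootstrap: with-replacement
    counts), or (S1, S2) of shape (n_resample, n_per_group) referring to
    the two separate (centred) groups for the centered bootstrap.
    """
    B = n_resample
    if method == "permutation":
        perm = rng.permuted(np.tile(np.arange(n_pool), (B, 1)), axis=1)
        S1 = np.zeros((B, n_pool))
        rows = np.repeat(np.arange(B), n_per_group)
        S1[rows, perm[:, :n_per_group].ravel()] = 1.0
        return S1, 1.0 - S1
    if method == "bootstrap":
        idx = rng.integers(0, n_pool, size=(B, 2 * n_per_group))
        S = np.zeros((2, B, n_pool))
        rows = np.repeat(np.arange(B), n_per_group)
        np.add.at(S[0], (rows, idx[:, :n_per_group].ravel()), 1.0)
        np.add.at(S[1], (rows, idx[:, n_per_group:].ravel()), 1.0)
        return S[0], S[1]
    if method == "centered_bootstrap":
        S = np.zeros((2, B, n_per_group))
        rows = np.repeat(np.arange(B), n_per_group)
        for g in range(2):
            idx = rng.integers(0, n_per_group, size=(B, n_per_group))
            np.add.at(S[g], (rows, idx.ravel()), 1.0)
        return S[0], S[1]
    raise ValueError(f"unknown method {method!r}")


def _welch_from_counts(S1, S2, pool1, pool2, n1, n2):
    """Vectorised Welch t^2 and two-sided p for count-matrix resamples."""
    m1 = (S1 @ pool1) / n1
    m2 = (S2 @ pool2) / n2
    v1 = np.maximum((S1 @ pool1 ** 2) / n1 - m1 ** 2, 0.0) * (n1 / (n1 - 1.0))
    v2 = np.maximum((S2 @ pool2 ** 2) / n2 - m2 ** 2, 0.0) * (n2 / (n2 - 1.0))
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(se2 > 0, (m1 - m2) ** 2 / se2, 0.0)
        df = np.where(se2 > 0,
                      se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1))
                                  + v2 ** 2 / (n2 ** 2 * (n2 - 1))),
                      n1 + n2 - 2.0)
    p = 2.0 * special.stdtr(df, -np.sqrt(t2))
    return t2, p


def type1_error_experiment(pool_spec: SimulationSpec | None = None,
                           n_sim: int = 200, n_resample: int = 1000,
                           trials_per_condition: int = 100,
                           methods=METHODS, alpha: float = 0.05,
                           forming_alpha: float = 0.05,
                           graph: NeighbourhoodGraph | None = None,
                           seed=None, pool_data: np.ndarray | None = None,
                           ) -> dict:
    """Familywise type-I error of cluster-corrected two-sample trial tests.

    Per simulation, two fake conditions of ``trials_per_condition`` trials
    each are drawn with replacement from a common null pool.  Welch t is
    computed per cell and squared; spatio-temporal clusters are formed at
    parametric p < ``forming_alpha`` and tested against the per-method
    null distribution of maximum cluster sums over ``n_resample``
    resamples.  The FWER of a method is the proportion of simulations in
    which any observed cluster is declared significant.

    ``pool_data`` (trials x channels x frames) may supply an external
    trial pool; otherwise the pool comes from the synthetic generator.
    """
    rng = np.random.default_rng(seed)
    if pool_data is None:
        if pool_spec is None:
            pool_spec = SimulationSpec(n_trials=1000)
        if pool_spec.n_trials < 2 * trials_per_condition:
            raise ValueError("pool must hold at least 2 x trials_per_condition")
        epochs = generate_erp_epochs(pool_spec, rng=rng)
        pool = epochs.data.transpose(2, 0, 1)       # trial x channel x frame
    else:
        pool = np.asarray(pool_data, dtype=float)
    n_pool_trials, n_ch, n_fr = pool.shape
    pool_flat = pool.reshape(n_pool_trials, -1)
    if graph is None:
        graph = NeighbourhoodGraph.chain(n_ch)
    edges = spacetime_edges(graph, n_ch, n_fr)
    npc = trials_per_condition
    pos_idx = one_sided_critical_index(alpha, n_resample)

    positives = {m: np.zeros(n_sim, dtype=bool) for m in methods}
    for s in range(n_sim):
        i1 = rng.integers(0, n_pool_trials, size=npc)
        i2 = rng.integers(0, n_pool_trials, size=npc)
        g1, g2 = pool_flat[i1], pool_flat[i2]
        ones = np.ones((1, npc))
        t2_obs, p_obs = _welch_from_counts(ones, ones, g1, g2, npc, npc)
        obs_max = max_cluster_sum(t2_obs[0], p_obs[0] < forming_alpha, edges)

        pooled = np.concatenate([g1, g2], axis=0)
        c1 = g1 - g1.mean(axis=0)
        c2 = g2 - g2.mean(axis=0)
        assert abs(c1.mean(axis=0)).max() < 1e-10 * max(1.0, abs(g1).max())
        for method in methods:
            S1, S2 = selection_matrices(method, rng, 2 * npc, npc, n_resample)
            if method == "centered_bootstrap":
                t2, p = _welch_from_counts(S1, S2, c1, c2, npc, npc)
            else:
                t2, p = _welch_from_counts(S1, S2, pooled, pooled, npc, npc)
            null_max = np.empty(n_resample)
            masks = p < forming_alpha
            for b in range(n_resample):
                null_max[b] = max_cluster_sum(t2[b], masks[b], edges)
            null_sorted = np.sort(null_max)
            if pos_idx < 1:
                positives[method][s] = True
            else:
                crit = null_sorted[pos_idx - 1]
                positives[method][s] = (obs_max > 0) and (obs_max >= crit)

    report = {"n_sim": n_sim, "n_resample": n_resample,
              "trials_per_condition": npc, "alpha": alpha,
              "forming_alpha": forming_alpha,
              "n_channels": n_ch, "n_frames": n_fr, "methods": {}}
    for m in methods:
        p = positives[m]
        report["methods"][m] = {
            "fwer": float(p.mean()),
            "n_positive": int(p.sum()),
            "n_sim": n_sim,
        }
    return report
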