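"""Ground-truth surrogate ("teacher") for the decomposed somatic voltage.

The somatic subthreshold response is generated as the sum of two components
with fully known parameters:

    v_soma(t) = v_noNa(t) + v_Na(t)

* ``v_noNa`` — the slow, global, saturating component: every synapse's spike
  train is filtered with a slow kernel, weighted (background excitatory
  weights decay with somatic distance, clustered weights do not, inhibition is
  subtractive), summed over the whole tree and passed through one saturating
  nonlinearity.
* ``v_Na`` — cluster-triggered transient spikelets: each synaptic cluster
  leak-integrates its members' spikes locally (normalized per member, so the
  drive reads as the synchronously active fraction of the cluster); each
  upward crossing of a cluster-specific threshold (affine in the branch's
  membrane area) emits one stereotyped spikelet into the somatic trace, with
  a per-cluster refractory period.  The somatic spikelet waveform is
  cluster-specific through dendritic filtering: its amplitude falls and its
  decay time grows affinely with the cluster's somatic distance, so distal
  clusters produce small slow deflections and proximal clusters large sharp
  ones.

The teacher is deliberately a different and simpler generative family than the
student cascade models (thresholded leaky integrators and stereotyped
waveforms rather than GRUs or LN channels), so that fitting it tests
approximation of an external ground truth rather than self-fitting.
Somatic action potentials for spike-prediction analyses are generated by
threshold crossings of v_soma and a stereotyped AP waveform (v_AP).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import fftconvolve

from .inputs import SpikeTrainSet
from .morphology import Morphology, SynapsePlacement, BACKGROUND
from .traces import VoltageTrace

__all__ = ["TeacherParams", "teacher_vnona", "teacher_vna", "compose_vsoma",
           "teacher_spikes", "double_exp_kernel", "detect_threshold_crossings"]


def double_exp_kernel(rise_ms: float, decay_ms: float, dt_ms: float,
                      n_ms: float | None = None) -> np.ndarray:
    """Peak-normalized difference-of-exponentials kernel, causal, kernel[0]=t=0."""
    if n_ms is None:
        n_ms = 8.0 * decay_ms
    t = np.arange(0.0, n_ms, dt_ms)
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    peak = k.max()
    return k / peak if peak > 0 else k


@dataclass
class TeacherParams:
    """All generative parameters of the teacher (recorded in the manifest)."""

    # v_noNa: slow global saturating component
    exc_drive_total: float = 230.0   # mV-scale; split over synapses as weights
    bg_distance_lambda: float = 200.0  # um, e-fold decay of background weights
    cluster_weight_boost: float = 1.0  # clustered weights are distance-free
    inh_drive_total: float = 21.0
    perisomatic_boost: float = 2.0
    slow_rise_ms: float = 5.0
    slow_decay_ms: float = 40.0
    inh_rise_ms: float = 2.0
    inh_decay_ms: float = 20.0
    sat_ceiling_mv: float = 12.0     # v_noNa saturates at +- this level

    # v_Na: cluster-triggered spikelets
    integration_tau_ms: float = 4.0
    local_bg_weight: float = 0.1     # same-branch background, vs 1.0 clustered
    threshold_base: float = 0.055    # fraction of cluster synchronously active
    threshold_area_slope: float = 0.40  # per unit relative area deviation
    # per-cluster thresholds calibrated from drive statistics (see
    # calibrate_thresholds); when set they replace threshold_base
    threshold_quantile: float = 0.9985
    threshold_margin: float = 1.02   # clears quantization plateaus of the
                                     # discrete per-member drive
    cluster_thresholds: list | None = None
    spikelet_refractory_ms: float = 10.0
    spikelet_amp_mv: float = 3.0     # at reference distance
    spikelet_amp_slope: float = 0.02   # mV per um of somatic distance
    spikelet_ref_distance: float = 150.0
    spikelet_amp_min: float = 0.5
    spikelet_rise_ms: float = 1.0    # at reference distance
    spikelet_decay_ms: float = 5.0   # at reference distance
    spikelet_decay_distance_factor: float = 0.8  # distal events decay slower
    spikelet_rise_distance_factor: float = 0.8   # ... and rise slower
    spikelet_amp_area_exp: float = 0.0  # amplitude ~ (branch area / mean)^p:
                                        # branch impedance scales the somatic
                                        # spikelet independently of distance
    spikelet_decay_area_exp: float = 0.0  # decay ~ (area / mean)^q (q < 0:
                                          # thin branches filter more slowly)
    local_spikelet_amp_mv: float = 30.0  # in the local branch trace

    # somatic action potentials
    ap_threshold_mv: float = 8.0
    ap_refractory_ms: float = 5.0
    ap_amp_mv: float = 60.0
    ap_rise_ms: float = 0.4
    ap_decay_ms: float = 1.2
    ap_noise_sd_mv: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def synaptic_weights(placement: SynapsePlacement,
                     params: TeacherParams) -> tuple[np.ndarray, np.ndarray]:
    """Teacher synaptic weights for the v_noNa component.

    Background excitatory weights decay exponentially with somatic distance;
    clustered weights are distance-independent (set to the background weight
    at distance zero times ``cluster_weight_boost``).  Weights are normalized
    so their sum equals ``exc_drive_total`` / ``inh_drive_total``, which makes
    the component's magnitude independent of the synapse count.
    """
    w = np.exp(-placement.exc_distance / params.bg_distance_lambda)
    clustered = placement.exc_cluster != BACKGROUND
    w[clustered] = params.cluster_weight_boost
    w *= params.exc_drive_total / w.sum()

    wi = np.ones(placement.n_inh)
    wi[placement.inh_perisomatic] = params.perisomatic_boost
    wi *= params.inh_drive_total / wi.sum()
    return w, wi


def teacher_vnona(exc_spikes: SpikeTrainSet, inh_spikes: SpikeTrainSet,
                  placement: SynapsePlacement, params: TeacherParams,
                  dt_ms: float = 1.0) -> VoltageTrace:
    """Slow global saturating component of the somatic voltage."""
    w_e, w_i = synaptic_weights(placement, params)
    n_bins = int(round(exc_spikes.duration_ms / dt_ms))
    Se = exc_spikes.binned()
    Si = inh_spikes.binned()
    ke = double_exp_kernel(params.slow_rise_ms, params.slow_decay_ms, dt_ms)
    ki = double_exp_kernel(params.inh_rise_ms, params.inh_decay_ms, dt_ms)
    drive_e = fftconvolve(w_e @ Se, ke)[:n_bins]
    drive_i = fftconvolve(w_i @ Si, ki)[:n_bins]
    u = drive_e - drive_i
    c = params.sat_ceiling_mv
    v = c * np.tanh(u / c)
    return VoltageTrace(v, dt_ms, "v_noNa")


def detect_threshold_crossings(x: np.ndarray, threshold: float,
                               refractory_bins: int) -> np.ndarray:
    """Indices of upward threshold crossings separated by >= refractory."""
    above = x >= threshold
    ups = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if x[0] >= threshold:
        ups = np.concatenate(([0], ups))
    kept = []
    last = -np.inf
    for i in ups:
        if i - last >= refractory_bins:
            kept.append(i)
            last = i
    return np.asarray(kept, dtype=int)


def cluster_drive(exc_spikes: SpikeTrainSet, placement: SynapsePlacement,
                  params: TeacherParams, cluster: int,
                  dt_ms: float = 1.0) -> np.ndarray:
    """Local leaky-integrated drive of one cluster, normalized to total
    local weight.

    Member efficacies are graded (0.7 to 1.3 across the within-cluster
    index): synaptic strengths are heterogeneous in reality, and the spread
    of efficacies also removes the discrete plateaus an equal-weight count
    signal would have at small cluster sizes, keeping threshold calibration
    smooth.
    """
    n_bins = int(round(exc_spikes.duration_ms / dt_ms))
    k_int = np.exp(-np.arange(0.0, 6 * params.integration_tau_ms, dt_ms)
                   / params.integration_tau_ms)
    members = placement.cluster_members(cluster)
    branch = placement.cluster_branch(cluster)
    same_branch_bg = np.flatnonzero(
        (placement.exc_branch == branch)
        & (placement.exc_cluster == BACKGROUND))
    w_m = np.linspace(0.7, 1.3, max(len(members), 2))[:len(members)]
    counts = w_m @ exc_spikes.binned(members)
    if len(same_branch_bg):
        counts = counts + params.local_bg_weight * \
            exc_spikes.binned(same_branch_bg).sum(axis=0)
    return fftconvolve(counts / w_m.sum(), k_int)[:n_bins]


def _area_factor(placement: SynapsePlacement, morph: Morphology,
                 params: TeacherParams, cluster: int) -> float:
    area = morph[placement.cluster_branch(cluster)].surface_area
    mean_area = np.mean([b.surface_area for b in morph.branches])
    return 1.0 + params.threshold_area_slope * (area / mean_area - 1.0)


def cluster_threshold(placement: SynapsePlacement, morph: Morphology,
                      params: TeacherParams, cluster: int) -> float:
    """Spikelet threshold: calibrated per cluster if available, else the
    base synchrony fraction; both modulated affinely by relative branch area."""
    if params.cluster_thresholds is not None:
        return float(params.cluster_thresholds[cluster])
    return params.threshold_base * _area_factor(placement, morph, params,
                                                cluster)


def calibrate_thresholds(exc_spikes: SpikeTrainSet,
                         placement: SynapsePlacement, morph: Morphology,
                         params: TeacherParams,
                         dt_ms: float = 1.0) -> list[float]:
    """Per-cluster thresholds from drive statistics on a calibration trial.

    The threshold is an upper-tail quantile of the cluster's own drive, so
    crossings stay in the sparse, synchrony-fluctuation-driven regime
    regardless of cluster size.  The branch-area dependence enters through
    the quantile: a larger relative membrane area deepens the quantile
    (tail mass scaled by 1/area_factor), so thresholds increase — and event
    rates decrease — monotonically with branch area while always remaining
    in the synchrony tail.  The returned values are stored in the teacher
    parameters and the dataset manifest.
    """
    out = []
    for c in range(placement.n_clusters):
        drive = cluster_drive(exc_spikes, placement, params, c, dt_ms)
        af = max(_area_factor(placement, morph, params, c), 0.1)
        q = 1.0 - (1.0 - params.threshold_quantile) / af
        q = float(np.clip(q, 0.99, 0.99995))
        out.append(float(np.quantile(drive, q)) * params.threshold_margin)
    return out


def teacher_vna(exc_spikes: SpikeTrainSet, placement: SynapsePlacement,
                morph: Morphology, params: TeacherParams, dt_ms: float = 1.0
                ) -> tuple[VoltageTrace, dict[int, VoltageTrace], dict[int, np.ndarray]]:
    """Cluster-triggered spikelet component, with per-branch local traces.

    Returns ``(v_Na, local_traces, spikelet_times)`` where ``local_traces``
    maps cluster id to the local dendritic voltage of its branch and
    ``spikelet_times`` maps cluster id to spikelet event times (ms).
    """
    n_bins = int(round(exc_spikes.duration_ms / dt_ms))
    v = np.zeros(n_bins)
    locals_: dict[int, VoltageTrace] = {}
    events: dict[int, np.ndarray] = {}
    refr = max(int(round(params.spikelet_refractory_ms / dt_ms)), 1)
    for c in range(placement.n_clusters):
        members = placement.cluster_members(c)
        branch = placement.cluster_branch(c)
        drive = cluster_drive(exc_spikes, placement, params, c, dt_ms)
        theta = cluster_threshold(placement, morph, params, c)
        idx = detect_threshold_crossings(drive, theta, refr)
        events[c] = idx * dt_ms
        d = placement.exc_distance[members].mean()
        amp = max(params.spikelet_amp_mv
                  + params.spikelet_amp_slope * (params.spikelet_ref_distance - d),
                  params.spikelet_amp_min)
        if params.spikelet_amp_area_exp:
            mean_area = np.mean([b.surface_area for b in morph.branches])
            amp *= (morph[branch].surface_area / mean_area) \
                ** params.spikelet_amp_area_exp
        rel = d / params.spikelet_ref_distance
        decay = params.spikelet_decay_ms * \
            (1.0 + params.spikelet_decay_distance_factor * (rel - 1.0))
        if params.spikelet_decay_area_exp:
            mean_area = np.mean([b.surface_area for b in morph.branches])
            decay *= (morph[branch].surface_area / mean_area) \
                ** params.spikelet_decay_area_exp
        decay = float(np.clip(decay, 2.0, 12.0))
        rise = params.spikelet_rise_ms * \
            (1.0 + params.spikelet_rise_distance_factor * (rel - 1.0))
        rise = float(np.clip(rise, 0.3, 0.8 * decay))
        spikelet = double_exp_kernel(rise, decay, dt_ms)
        train = np.zeros(n_bins)
        train[idx] = 1.0
        v += amp * fftconvolve(train, spikelet)[:n_bins]
        local = drive * 10.0 + params.local_spikelet_amp_mv * \
            fftconvolve(train, spikelet)[:n_bins]
        locals_[c] = VoltageTrace(local, dt_ms, f"local:{branch}")
    return VoltageTrace(v, dt_ms, "v_Na"), locals_, events


def compose_vsoma(vnona: VoltageTrace, vna: VoltageTrace) -> VoltageTrace:
    """v_soma = v_noNa + v_Na, samplewise on identical grids."""
    if not vnona.same_grid(vna):
        raise ValueError("voltage traces are on different time grids")
    return VoltageTrace(vnona.values + vna.values, vnona.dt_ms, "v_soma")


def teacher_spikes(vsoma: VoltageTrace, params: TeacherParams,
                   seed: int | np.random.Generator = 0
                   ) -> tuple[np.ndarray, VoltageTrace]:
    """Reference somatic spike train and stereotyped-AP trace from v_soma."""
    rng = np.random.default_rng(seed)
    x = vsoma.values
    if params.ap_noise_sd_mv > 0:
        x = x + rng.normal(0.0, params.ap_noise_sd_mv, size=len(x))
    refr = max(int(round(params.ap_refractory_ms / vsoma.dt_ms)), 1)
    idx = detect_threshold_crossings(x, params.ap_threshold_mv, refr)
    train = np.zeros(len(x))
    train[idx] = 1.0
    wave = params.ap_amp_mv * double_exp_kernel(
        params.ap_rise_ms, params.ap_decay_ms, vsoma.dt_ms)
    vap = fftconvolve(train, wave)[:len(x)]
    return idx * vsoma.dt_ms, VoltageTrace(vap, vsoma.dt_ms, "v_AP")
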