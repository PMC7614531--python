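"""Trial datasets: simulated inputs plus teacher target voltages.

A dataset is a set of trials (laps of the circular track) sharing one
morphology, synapse placement, presynaptic population and teacher
parameterization, with independent input spike patterns per trial.  Cells
presynaptic to clustered synapses are co-tuned: all members of a cluster share
the cluster's place-field shift (optionally jittered), which is what makes
the cluster's local drive synchronize inside the field and trigger dendritic
spikelets.  By default all clusters are co-tuned with the same place field
(see :func:`_cluster_cotuned_cells` for why this makes the organization
identifiable); a configurable span spreads their centers instead.

The manifest records every seed and generative parameter, so any trial can be
re-simulated bit-exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import inputs as inp
from .inputs import SpikeTrainSet, Trajectory
from .morphology import (BACKGROUND, Morphology, SynapsePlacement,
                         build_morphology, place_synapses)
from .teacher import (TeacherParams, calibrate_thresholds, compose_vsoma,
                      teacher_spikes, teacher_vna, teacher_vnona)
from .traces import VoltageTrace

__all__ = ["DatasetConfig", "Trial", "Dataset", "make_dataset",
           "AssemblyTrial", "make_assembly_dataset"]


@dataclass
class DatasetConfig:
    """Study conditions for one dataset (defaults are the full-scale regime)."""

    n_exc: int = 2000
    n_inh: int = 200
    n_clusters: int = 4
    n_clustered: int = 240
    n_train: int = 80
    n_test: int = 8
    trial_duration_ms: float = 10_000.0   # one lap
    dt_ms: float = 1.0
    n_subtrees: int = 5
    branches_per_subtree: int = 7
    cluster_jitter_steps: int = 0         # within-cluster tuning jitter (basis steps)
    cluster_span_steps: int = 0           # spread of cluster field centers;
                                          # 0 = all clusters co-tuned with the
                                          # same (postsynaptic) place field
    trial_start: str = "zero"             # 'zero' | 'random' | 'stratified' |
                                          # 'field'.  Sub-lap trials should
                                          # use 'random'/'stratified' (sample
                                          # all segments) or 'field' (anchor
                                          # every trial's window on the
                                          # cluster field, the scaled-down
                                          # analog of full laps, which cross
                                          # the field once per trial)
    inh_mean_rate: float = 7.4
    inh_theta_depth: float = 0.3
    teacher: TeacherParams = field(default_factory=TeacherParams)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class Trial:
    exc_spikes: SpikeTrainSet
    inh_spikes: SpikeTrainSet
    trajectory: Trajectory
    v_nona: VoltageTrace
    v_na: VoltageTrace
    v_soma: VoltageTrace
    ref_spike_times: np.ndarray
    v_ap: VoltageTrace
    spikelet_times: dict[int, np.ndarray]
    seed: int

    def target(self, name: str) -> VoltageTrace:
        return {"vsoma": self.v_soma, "vnona": self.v_nona,
                "vna": self.v_na, "vap": self.v_ap}[name]


@dataclass
class Dataset:
    config: DatasetConfig
    morphology: Morphology
    placement: SynapsePlacement
    cells: list
    train: list[Trial]
    test: list[Trial]
    manifest: dict

    @property
    def trials(self) -> list[Trial]:
        return self.train + self.test


def _substream(seed: int, name: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes (str.hash is salted)
    ss = np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    return np.random.default_rng(ss)


def _cluster_cotuned_cells(cells, placement: SynapsePlacement,
                           basis: inp.BasisSet, template: np.ndarray,
                           template_rate: float, jitter_steps: int,
                           rng: np.random.Generator,
                           span_steps: int = 6):
    """Retune cells feeding clustered synapses to their cluster's field center.

    By default all clusters share one field center (co-tuned with the
    postsynaptic place field): inside the field every cluster is co-active,
    so each cluster's dendritic spikelets are triggered by its *own*
    synchrony fluctuations, which a pooled drive averages away — this is
    what makes the synapse-to-subunit assignment identifiable.  A nonzero
    ``span_steps`` spreads the centers over that many basis steps instead.
    """
    w_const = inp._constant_coefficients(basis)
    grid = np.asarray(template).reshape(basis.n_x, basis.n_psi)
    n_cl = placement.n_clusters
    offset = int(rng.integers(basis.n_x))
    if span_steps:
        centers = (offset + (np.arange(n_cl) * span_steps) // max(n_cl - 1, 1)) \
            % basis.n_x
    else:
        centers = np.full(n_cl, offset)
    for c in range(n_cl):
        for sid in placement.cluster_members(c):
            cell = cells[sid]
            step = int(centers[c])
            if jitter_steps:
                step = (step + int(rng.integers(-jitter_steps, jitter_steps + 1))) \
                    % basis.n_x
            w = np.roll(grid, step, axis=0).ravel()
            w = w + np.log(cell.mean_rate / template_rate) * w_const
            cell.w_phi = w
            cell.spatial_shift = step * basis.track_length / basis.n_x
    return centers


def make_dataset(config: DatasetConfig | None = None, seed: int = 0,
                 target_mean_rate: float = 0.5) -> Dataset:
    """Simulate a full dataset under ``config`` with all randomness seeded.

    All randomness flows from ``seed`` through named substreams (morphology,
    placement, population, cluster tuning, and one stream per trial), so two
    builds with the same config and seed are identical.
    """
    cfg = config or DatasetConfig()
    morph = build_morphology(cfg.n_subtrees, cfg.branches_per_subtree,
                             seed=_substream(seed, "morphology"))
    placement = place_synapses(morph, cfg.n_clusters, cfg.n_exc, cfg.n_inh,
                               cfg.n_clustered, seed=_substream(seed, "placement"))
    basis = inp.build_basis()
    template = inp.build_template(basis, target_mean_rate=target_mean_rate)
    cells = inp.sample_population(cfg.n_exc, basis=basis, template=template,
                                  template_rate=target_mean_rate,
                                  seed=_substream(seed, "population"))
    centers = _cluster_cotuned_cells(cells, placement, basis, template,
                                     target_mean_rate, cfg.cluster_jitter_steps,
                                     _substream(seed, "clusters"),
                                     span_steps=cfg.cluster_span_steps)

    if cfg.teacher.cluster_thresholds is None:
        # fix per-cluster spikelet thresholds from a calibration lap, so the
        # crossing regime is independent of cluster size and trial layout
        cal_traj = inp.make_trajectory(
            1000.0 * inp.TRACK_LENGTH_CM / inp.RUN_SPEED_CM_S, cfg.dt_ms)
        cal_spikes = inp.simulate_excitatory(
            cells, basis, cal_traj, seed=_substream(seed, "threshold-calibration"))
        cfg.teacher.cluster_thresholds = calibrate_thresholds(
            cal_spikes, placement, morph, cfg.teacher, cfg.dt_ms)

    n_total = cfg.n_train + cfg.n_test
    trial_seeds = _substream(seed, "trials").integers(2 ** 31, size=n_total)
    field_center_cm = float(centers[0]) * basis.track_length / basis.n_x
    trials = []
    for k in range(n_total):
        trials.append(_simulate_trial(cfg, morph, placement, cells, basis,
                                      int(trial_seeds[k]), k, n_total,
                                      field_center_cm))
    manifest = {
        "seed": seed,
        "trial_seeds": [int(s) for s in trial_seeds],
        "cluster_centers_steps": [int(c) for c in centers],
        "config": cfg.to_dict(),
        "target_mean_rate": target_mean_rate,
    }
    return Dataset(cfg, morph, placement, cells,
                   trials[:cfg.n_train], trials[cfg.n_train:], manifest)


@dataclass
class AssemblyTrial:
    """A trial with engineered assembly inputs (no trajectory)."""

    exc_spikes: SpikeTrainSet
    inh_spikes: SpikeTrainSet
    v_na: VoltageTrace
    spikelet_times: dict

    def target(self, name: str) -> VoltageTrace:
        if name != "vna":
            raise KeyError("assembly trials carry only the v_Na target")
        return self.v_na


def make_assembly_dataset(n_clusters: int = 4, members: int = 8,
                          n_background: int = 16, n_inh: int = 4,
                          event_rate_hz: float = 5.0,
                          background_rate_hz: float = 2.0,
                          jitter_ms: float = 1.5,
                          trial_duration_ms: float = 2000.0,
                          n_trials: int = 10,
                          cluster_midpoints_um=(50.0, 130.0, 210.0, 290.0),
                          cluster_diameters=None,
                          teacher: TeacherParams | None = None,
                          seed: int = 0):
    """Controlled assignment-recovery benchmark: cluster-exclusive assemblies.

    Each cluster's presynaptic cells fire together as an assembly at
    independent Poisson event times (every member fires per event, jittered
    by up to ``jitter_ms``), so each cluster exclusively drives its own
    spikelet generator; background synapses fire independent Poisson trains.
    The morphology is a comb of single-branch subtrees whose midpoints are
    at ``cluster_midpoints_um``, giving the clusters well-separated
    electrotonic positions and hence distinct spikelet waveforms.

    Returns ``(morphology, placement, teacher_params, trials)``; trials
    expose ``exc_spikes``/``inh_spikes``/``target('vna')`` as the fitting
    module expects.
    """
    from .morphology import Branch
    lengths = [2.0 * d for d in cluster_midpoints_um]
    diams = cluster_diameters or [1.5] * len(lengths)
    branches = [Branch(i, -1, 0.0, L, np.pi * dia * L, i + 1)
                for i, (L, dia) in enumerate(zip(lengths, diams))]
    morph = Morphology(branches)
    n_exc = n_clusters * members + n_background
    placement = place_synapses(morph, n_clusters, n_exc, n_inh,
                               n_clusters * members,
                               seed=_substream(seed, "assembly-placement"))
    prm = teacher or TeacherParams(threshold_base=0.5, local_bg_weight=0.0,
                                   spikelet_amp_slope=0.012)
    rng = np.random.default_rng(_substream(seed, "assembly-trials"))
    trials = []
    T = trial_duration_ms
    for _ in range(n_trials):
        ids, times = [], []
        for c in range(n_clusters):
            mem = placement.cluster_members(c)
            n_ev = rng.poisson(event_rate_hz * T / 1000.0)
            for t0 in np.sort(rng.uniform(0, T - 60.0, n_ev)):
                for m in mem:
                    ids.append(m)
                    times.append(t0 + rng.uniform(0, jitter_ms))
        for b in np.flatnonzero(placement.exc_cluster == BACKGROUND):
            n = rng.poisson(background_rate_hz * T / 1000.0)
            ids += [int(b)] * n
            times += list(rng.uniform(0, T, n))
        exc = SpikeTrainSet(np.asarray(ids, dtype=int), np.asarray(times),
                            np.array(["exc"] * n_exc), n_exc, T)
        inh = SpikeTrainSet(np.arange(n_inh), np.full(n_inh, 50.0),
                            np.array(["inh"] * n_inh), n_inh, T)
        v_na, _, events = teacher_vna(exc, placement, morph, prm)
        trials.append(AssemblyTrial(exc, inh, v_na, events))
    return morph, placement, prm, trials


def _simulate_trial(cfg: DatasetConfig, morph: Morphology,
                    placement: SynapsePlacement, cells, basis,
                    trial_seed: int, index: int = 0, n_total: int = 1,
                    field_center_cm: float = 0.0) -> Trial:
    rng = np.random.default_rng(trial_seed)
    if cfg.trial_start == "random":
        x0 = float(rng.uniform(0.0, inp.TRACK_LENGTH_CM))
    elif cfg.trial_start == "stratified":
        x0 = inp.TRACK_LENGTH_CM * index / max(n_total, 1)
    elif cfg.trial_start == "field":
        window_cm = cfg.trial_duration_ms * inp.RUN_SPEED_CM_S / 1000.0
        x0 = float(np.mod(field_center_cm - 0.5 * window_cm,
                          inp.TRACK_LENGTH_CM))
    else:
        x0 = 0.0
    traj = inp.make_trajectory(cfg.trial_duration_ms, cfg.dt_ms, x0=x0)
    exc = inp.simulate_excitatory(cells, basis, traj, seed=rng)
    inh = inp.generate_inhibitory(cfg.n_inh, cfg.inh_mean_rate,
                                  cfg.inh_theta_depth, traj, seed=rng)
    v_nona = teacher_vnona(exc, inh, placement, cfg.teacher, cfg.dt_ms)
    v_na, _locals, spikelet_times = teacher_vna(exc, placement, morph,
                                                cfg.teacher, cfg.dt_ms)
    v_soma = compose_vsoma(v_nona, v_na)
    # store v_Na as the difference it is defined to be, so that
    # v_soma - v_noNa recovers it bit-exactly
    v_na = VoltageTrace(v_soma.values - v_nona.values, cfg.dt_ms, "v_Na")
    ref_times, v_ap = teacher_spikes(v_soma, cfg.teacher, seed=rng)
    return Trial(exc, inh, traj, v_nona, v_na, v_soma, ref_times, v_ap,
                 spikelet_times, trial_seed)
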