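"""In-vivo-like presynaptic spike trains for a CA1-style neuron.

Simulates the input regime of a rodent running at constant speed around a
circular track: 2,000 excitatory inputs behave as CA3 place cells — a single
idealized place field, modulation by the 8 Hz theta oscillation, theta phase
precession, and a short refractory period — while 200 inhibitory inputs are
spatially untuned but weakly theta-modulated.

Each excitatory cell i fires as a discrete-time Poisson GLM at Delta_t = 1 ms:

    s_i(t) ~ Poisson(Delta_t * lambda_i(t))
    lambda_i(t) = exp(a_i(t)) + lambda_bar
    a_i(t) = w_phi(i) . phi(x(t), psi(t)) + w_chi * (chi * s_i)(t)

where phi is a bank of N_x x N_psi = 40 x 4 = 160 factorized circular Gaussian
basis functions over position x and theta phase psi, w_phi(i) is a circularly
shifted copy of a shared tuning template, and the spike-history term chi
models refractoriness.  Per-cell mean rates are drawn from Gamma(3, 6)
(mean 0.5 Hz); the 0.1 Hz baseline lambda_bar brings the grand-average input
rate to 0.6 Hz.

Sampling with spike-history feedback uses exact Poisson thinning: candidate
events are drawn from the history-free intensity (an upper bound, since the
history term is suppressive) and accepted with probability
lambda_with_history / lambda_history_free, in time order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory", "BasisSet", "PresynapticCell", "SpikeTrainSet",
    "make_trajectory", "build_basis", "build_template", "sample_population",
    "refractory_kernel", "compute_activation", "compute_intensity",
    "sample_spikes", "simulate_excitatory", "generate_inhibitory",
    "TRACK_LENGTH_CM", "RUN_SPEED_CM_S", "THETA_FREQ_HZ", "BASELINE_RATE_HZ",
    "REFRACTORY_TAU_MS", "W_CHI_DEFAULT",
]

TRACK_LENGTH_CM = 200.0
RUN_SPEED_CM_S = 20.0
THETA_FREQ_HZ = 8.0
BASELINE_RATE_HZ = 0.1
REFRACTORY_TAU_MS = 5.0
W_CHI_DEFAULT = -5.0


# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Constant-speed run on a circular track with an ongoing theta rhythm.

    position(t) = (x0 + speed*t) mod L; theta_phase advances at theta_freq.
    One lap takes L/speed seconds (10 s with the defaults).
    """

    time_ms: np.ndarray
    position_cm: np.ndarray
    theta_phase: np.ndarray
    track_length: float = TRACK_LENGTH_CM
    speed: float = RUN_SPEED_CM_S
    theta_freq: float = THETA_FREQ_HZ

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def duration_ms(self) -> float:
        return float(len(self.time_ms) * self.dt_ms)

    @property
    def lap_duration_ms(self) -> float:
        return 1000.0 * self.track_length / self.speed


def make_trajectory(duration_ms: float, dt_ms: float = 1.0,
                    track_length: float = TRACK_LENGTH_CM,
                    speed: float = RUN_SPEED_CM_S,
                    theta_freq: float = THETA_FREQ_HZ,
                    x0: float = 0.0, phase0: float = 0.0) -> Trajectory:
    n = int(round(duration_ms / dt_ms))
    t = np.arange(n) * dt_ms
    x = np.mod(x0 + speed * t / 1000.0, track_length)
    psi = np.mod(phase0 + 2.0 * np.pi * theta_freq * t / 1000.0, 2.0 * np.pi)
    return Trajectory(t, x, psi, track_length, speed, theta_freq)


# ---------------------------------------------------------------------------


@dataclass
class BasisSet:
    """Factorized circular Gaussian basis over (position, theta phase).

    Centers tile [0, L) x [0, 2 pi) uniformly on an N_x x N_psi grid; each
    basis function is a product of two circular (wrapped-distance) Gaussians
    with peak value 1 at its center.
    """

    track_length: float
    n_x: int
    n_psi: int
    sigma_x: float
    sigma_psi: float
    x_centers: np.ndarray = field(init=False)
    psi_centers: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.n_x < 1 or self.n_psi < 1:
            raise ValueError("basis grid counts must be >= 1")
        if self.sigma_x <= 0 or self.sigma_psi <= 0:
            raise ValueError("basis widths must be positive")
        self.x_centers = np.arange(self.n_x) * self.track_length / self.n_x
        self.psi_centers = np.arange(self.n_psi) * 2.0 * np.pi / self.n_psi

    @property
    def n_basis(self) -> int:
        return self.n_x * self.n_psi

    def evaluate(self, x, psi) -> np.ndarray:
        """Basis matrix, shape (len(x), n_basis); flat index = ix * n_psi + ipsi."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        psi = np.atleast_1d(np.asarray(psi, dtype=float))
        L = self.track_length
        dx = np.abs(x[:, None] - self.x_centers[None, :])
        dx = np.minimum(dx, L - dx)
        gx = np.exp(-0.5 * (dx / self.sigma_x) ** 2)
        dpsi = np.abs(psi[:, None] - self.psi_centers[None, :])
        dpsi = np.minimum(dpsi, 2.0 * np.pi - dpsi)
        gpsi = np.exp(-0.5 * (dpsi / self.sigma_psi) ** 2)
        return (gx[:, :, None] * gpsi[:, None, :]).reshape(len(x), self.n_basis)


def build_basis(track_length: float = TRACK_LENGTH_CM, n_x: int = 40,
                n_psi: int = 4, sigma_x: float = 5.0,
                sigma_psi: float = np.pi / 2) -> BasisSet:
    return BasisSet(track_length, n_x, n_psi, sigma_x, sigma_psi)


# ---------------------------------------------------------------------------


@dataclass
class PresynapticCell:
    """One excitatory place cell of the presynaptic population."""

    id: int
    w_phi: np.ndarray
    w_chi: float
    mean_rate: float           # Hz, place-field component (excl. baseline)
    baseline_rate: float
    spatial_shift: float       # cm, circular shift of the shared template


class CalibrationError(RuntimeError):
    """Raised when the tuning template cannot be calibrated to the target rate."""


def _constant_coefficients(basis: BasisSet) -> np.ndarray:
    """Least-squares representation of the constant function 1 in the basis.

    Because the basis tiles the torus uniformly, a constant is representable
    up to a small ripple; adding c * w_const to a cell's coefficients
    multiplies its firing rate by ~exp(c).
    """
    xg = np.linspace(0, basis.track_length, 80, endpoint=False)
    pg = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    X, P = np.meshgrid(xg, pg, indexing="ij")
    F = basis.evaluate(X.ravel(), P.ravel())
    w, *_ = np.linalg.lstsq(F, np.ones(F.shape[0]), rcond=None)
    return w


def build_template(basis: BasisSet, field_diameter: float = 30.0,
                   precession_span: float = 1.5 * np.pi,
                   target_mean_rate: float = 0.5,
                   theta_amplitude: float = 1.0,
                   field_sharpness: float = 2.1,
                   trajectory: Trajectory | None = None,
                   max_iter: int = 8, tol: float = 0.005) -> np.ndarray:
    """Construct the shared tuning-curve template coefficients w_phi.

    The template is parametric: log-rate is a circular Gaussian place-field
    envelope (sd = field_diameter / 4, so +-2 sd spans the stated diameter)
    multiplied by a theta-phase tuning bump whose preferred phase advances
    linearly with the fraction of the field traversed (phase precession over
    ``precession_span`` radians).  A scalar offset is calibrated iteratively
    so that the trajectory-averaged rate exp(a(t)) equals
    ``target_mean_rate`` to within 1 %.

    ``field_sharpness`` sets the peak log-rate of the uncalibrated field; the
    default 2.1 yields a peak-to-mean rate ratio of ~14, consistent with a
    ~30 cm place field on a 200 cm track (mean rate ~= peak * field fraction
    * mean in-field gain ~= peak / 13).
    """
    if target_mean_rate <= 0:
        raise ValueError("target_mean_rate must be positive")
    L = basis.track_length
    traj = trajectory or make_trajectory(1000.0 * L / RUN_SPEED_CM_S)

    sigma_f = field_diameter / 4.0
    x_c = L / 2.0
    half = field_diameter / 2.0

    def signed_circ(x, c):
        d = np.mod(x - c + L / 2.0, L) - L / 2.0
        return d

    def log_gain(x, psi):
        dx = signed_circ(x, x_c)
        env = np.exp(-0.5 * (dx / sigma_f) ** 2)
        frac = np.clip((dx + half) / max(field_diameter, 1e-9), 0.0, 1.0)
        psi_pref = np.mod(precession_span * (1.0 - frac), 2.0 * np.pi)
        dpsi = np.mod(psi - psi_pref + np.pi, 2.0 * np.pi) - np.pi
        phase_tuning = 0.5 * (np.cos(dpsi) + 1.0)
        return env * (theta_amplitude * phase_tuning + 0.5)

    # fit the surface over the full (x, psi) torus so that circularly
    # shifted coefficient vectors express the same shifted tuning curve
    xg = np.linspace(0, L, 200, endpoint=False)
    pg = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    X, P = np.meshgrid(xg, pg, indexing="ij")
    target_surface = field_sharpness * log_gain(X.ravel(), P.ravel())
    F = basis.evaluate(X.ravel(), P.ravel())
    w, *_ = np.linalg.lstsq(F, target_surface, rcond=None)

    w_const = _constant_coefficients(basis)
    Ftraj = basis.evaluate(traj.position_cm, traj.theta_phase)
    for _ in range(max_iter):
        mean_rate = np.exp(Ftraj @ w).mean()
        if abs(mean_rate - target_mean_rate) <= tol * target_mean_rate:
            return w
        w = w + np.log(target_mean_rate / mean_rate) * w_const
    raise CalibrationError(
        f"template calibration did not converge: mean rate {mean_rate:.4f} Hz "
        f"vs target {target_mean_rate:.4f} Hz")


def sample_population(n_cells: int = 2000, rate_shape: float = 3.0,
                      rate_rate: float = 6.0, *, basis: BasisSet,
                      template: np.ndarray,
                      template_rate: float = 0.5,
                      w_chi: float = W_CHI_DEFAULT,
                      baseline_rate: float = BASELINE_RATE_HZ,
                      seed: int | np.random.Generator = 0) -> list[PresynapticCell]:
    """Draw a population of place cells from the shared template.

    Each cell receives (i) a mean rate from Gamma(shape=3, rate=6), whose
    analytic mean 0.5 Hz is the grand-average place-field rate, and (ii) an
    independent circular shift of the template along the spatial dimension,
    implemented by rolling the coefficient grid by a whole number of basis
    columns (multiples of L / N_x), so that the shifted cell expresses exactly
    the same tuning curve displaced along the track.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if rate_shape <= 0 or rate_rate <= 0:
        raise ValueError("gamma parameters must be positive")
    rng = np.random.default_rng(seed)
    w_const = _constant_coefficients(basis)
    grid = np.asarray(template).reshape(basis.n_x, basis.n_psi)
    cells = []
    for i in range(n_cells):
        rate = rng.gamma(rate_shape, 1.0 / rate_rate)
        rate = max(rate, 1e-3)
        shift_steps = int(rng.integers(basis.n_x))
        w = np.roll(grid, shift_steps, axis=0).ravel()
        w = w + np.log(rate / template_rate) * w_const
        cells.append(PresynapticCell(
            id=i, w_phi=w, w_chi=w_chi, mean_rate=rate,
            baseline_rate=baseline_rate,
            spatial_shift=shift_steps * basis.track_length / basis.n_x))
    return cells


# ---------------------------------------------------------------------------


@dataclass
class SpikeTrainSet:
    """Timestamped spike events for a set of synapses, with a binned view."""

    synapse_ids: np.ndarray     # int, parallel to times
    times_ms: np.ndarray        # float
    synapse_type: np.ndarray    # 'exc' | 'inh' per synapse id (length n_synapses)
    n_synapses: int
    duration_ms: float
    bin_width_ms: float = 1.0

    def __post_init__(self):
        order = np.lexsort((self.synapse_ids, self.times_ms))
        self.synapse_ids = np.asarray(self.synapse_ids)[order]
        self.times_ms = np.asarray(self.times_ms, dtype=float)[order]

    @property
    def n_events(self) -> int:
        return len(self.times_ms)

    def events_for(self, synapse_id: int) -> np.ndarray:
        return self.times_ms[self.synapse_ids == synapse_id]

    def binned(self, synapse_ids=None) -> np.ndarray:
        """Spike-count matrix, shape (n_selected_synapses, n_bins)."""
        n_bins = int(round(self.duration_ms / self.bin_width_ms))
        if synapse_ids is None:
            synapse_ids = np.arange(self.n_synapses)
        synapse_ids = np.asarray(synapse_ids)
        remap = -np.ones(self.n_synapses, dtype=int)
        remap[synapse_ids] = np.arange(len(synapse_ids))
        rows = remap[self.synapse_ids]
        keep = rows >= 0
        cols = np.floor(self.times_ms[keep] / self.bin_width_ms).astype(int)
        cols = np.clip(cols, 0, n_bins - 1)
        out = np.zeros((len(synapse_ids), n_bins))
        np.add.at(out, (rows[keep], cols), 1.0)
        return out

    def subset(self, synapse_ids) -> "SpikeTrainSet":
        synapse_ids = np.asarray(synapse_ids)
        keep = np.isin(self.synapse_ids, synapse_ids)
        return SpikeTrainSet(self.synapse_ids[keep], self.times_ms[keep],
                             self.synapse_type, self.n_synapses,
                             self.duration_ms, self.bin_width_ms)


def merge_spike_trains(parts: list[SpikeTrainSet]) -> SpikeTrainSet:
    assert parts
    ids = np.concatenate([p.synapse_ids for p in parts])
    times = np.concatenate([p.times_ms for p in parts])
    return SpikeTrainSet(ids, times, parts[0].synapse_type,
                         parts[0].n_synapses, parts[0].duration_ms,
                         parts[0].bin_width_ms)


# ---------------------------------------------------------------------------


def refractory_kernel(n_lags: int = 40, tau_ms: float = REFRACTORY_TAU_MS,
                      dt_ms: float = 1.0) -> np.ndarray:
    """Spike-history kernel chi at lags 1..n_lags bins (strictly causal)."""
    lags = np.arange(1, n_lags + 1) * dt_ms
    return np.exp(-lags / tau_ms)


def compute_activation(cell: PresynapticCell, basis: BasisSet,
                       trajectory: Trajectory,
                       history_times_ms: np.ndarray | None = None) -> np.ndarray:
    """GLM activation a_i(t) = w_phi . phi(x, psi) + w_chi * (chi * s_i)(t).

    ``history_times_ms`` are this cell's own past spike times; the history
    kernel is strictly causal, so a spike influences only later bins.
    """
    F = basis.evaluate(trajectory.position_cm, trajectory.theta_phase)
    a = F @ cell.w_phi
    if history_times_ms is not None and len(history_times_ms):
        dt = trajectory.dt_ms
        n = len(a)
        chi = refractory_kernel(dt_ms=dt)
        hist = np.zeros(n + 1)
        bins = np.floor(np.asarray(history_times_ms) / dt).astype(int)
        if np.any(bins >= n):
            raise ValueError("history contains spikes beyond the trajectory")
        for b in bins:
            lo = b + 1
            hi = min(lo + len(chi), n)
            hist[lo:hi] += chi[: hi - lo]
        a = a + cell.w_chi * hist[:n]
    return a


def compute_intensity(activation: np.ndarray,
                      baseline: float = BASELINE_RATE_HZ) -> np.ndarray:
    """Conditional intensity lambda(t) = exp(a(t)) + baseline, in Hz."""
    if baseline < 0:
        raise ValueError("baseline rate must be >= 0")
    return np.exp(activation) + baseline


def sample_spikes(rate_hz: np.ndarray, bin_ms: float = 1.0,
                  seed: int | np.random.Generator = 0,
                  synapse_id: int = 0, n_synapses: int = 1,
                  synapse_type: str = "exc") -> SpikeTrainSet:
    """Sample an inhomogeneous Poisson train: count_t ~ Poisson(dt * rate_t)."""
    rate_hz = np.asarray(rate_hz, dtype=float)
    if np.any(rate_hz < 0):
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate_hz * bin_ms / 1000.0)
    bins = np.repeat(np.arange(len(counts)), counts)
    times = bins * bin_ms
    types = np.array([synapse_type] * n_synapses)
    return SpikeTrainSet(np.full(len(times), synapse_id), times, types,
                         n_synapses, len(rate_hz) * bin_ms, bin_ms)


def simulate_excitatory(cells: list[PresynapticCell], basis: BasisSet,
                        trajectory: Trajectory,
                        seed: int | np.random.Generator = 0,
                        block: int = 256) -> SpikeTrainSet:
    """Simulate the full excitatory population with spike-history feedback.

    Exact thinning: since w_chi <= 0, the history-free intensity
    exp(a_tuning) + baseline upper-bounds the true intensity.  Candidate
    events are drawn from it in bulk (vectorized over cells and bins) and
    accepted in time order with probability lambda_true / lambda_upper, the
    history term being computed from previously *accepted* spikes only
    (spikes in bins < t).  At most one spike is emitted per 1 ms bin (the
    refractory period makes sub-millisecond doublets unphysical).
    """
    rng = np.random.default_rng(seed)
    dt = trajectory.dt_ms
    n = len(trajectory.time_ms)
    tau = REFRACTORY_TAU_MS
    F = basis.evaluate(trajectory.position_cm, trajectory.theta_phase)

    all_ids, all_times = [], []
    for start in range(0, len(cells), block):
        chunk = cells[start:start + block]
        W = np.stack([c.w_phi for c in chunk])          # (B, n_basis)
        A = W @ F.T                                     # (B, n)
        lam_up = np.exp(A) + np.array([c.baseline_rate for c in chunk])[:, None]
        counts = rng.poisson(lam_up * dt / 1000.0)
        rows, cols = np.nonzero(counts)
        for ci in np.unique(rows):
            cell = chunk[ci]
            mask = rows == ci
            cbins = np.repeat(cols[mask], counts[ci, cols[mask]])
            cbins.sort()
            # state = sum over accepted spikes s <= t_ref of exp(-(t_ref-s)dt/tau),
            # referenced at the bin of the most recent accepted spike
            state, t_ref = 0.0, None
            accepted = []
            for b in cbins:
                if t_ref is None:
                    hist = 0.0
                elif b > t_ref:
                    hist = state * np.exp(-(b - t_ref) * dt / tau)
                else:  # at most one spike per bin
                    continue
                lam_true = np.exp(A[ci, b] + cell.w_chi * hist) + cell.baseline_rate
                if rng.random() < lam_true / lam_up[ci, b]:
                    accepted.append(b)
                    state = hist + 1.0
                    t_ref = b
            if accepted:
                all_ids.append(np.full(len(accepted), cell.id))
                all_times.append(np.asarray(accepted, dtype=float) * dt)

    ids = np.concatenate(all_ids) if all_ids else np.empty(0, dtype=int)
    times = np.concatenate(all_times) if all_times else np.empty(0)
    types = np.array(["exc"] * len(cells))
    return SpikeTrainSet(ids, times, types, len(cells), n * dt, dt)


def generate_inhibitory(n_cells: int = 200, mean_rate: float = 7.4,
                        theta_depth: float = 0.3,
                        trajectory: Trajectory | None = None,
                        seed: int | np.random.Generator = 0,
                        preferred_phase: float = 0.0,
                        id_offset: int = 0) -> SpikeTrainSet:
    """Theta-modulated, spatially untuned inhibitory population.

    lambda(t) = mean_rate * (1 + theta_depth * cos(psi(t) - psi_0)); the
    phase average of the modulation is zero, so the trajectory-averaged rate
    equals ``mean_rate`` exactly in expectation.
    """
    if not (0.0 <= theta_depth < 1.0):
        raise ValueError("theta_depth must be in [0, 1)")
    traj = trajectory or make_trajectory(10_000.0)
    rng = np.random.default_rng(seed)
    lam = mean_rate * (1.0 + theta_depth * np.cos(traj.theta_phase - preferred_phase))
    dt = traj.dt_ms
    counts = rng.poisson(np.broadcast_to(lam * dt / 1000.0, (n_cells, len(lam))))
    rows, cols = np.nonzero(counts)
    reps = counts[rows, cols]
    ids = np.repeat(rows, reps) + id_offset
    times = np.repeat(cols, reps) * dt
    types = np.array(["inh"] * n_cells)
    return SpikeTrainSet(ids, times, types, n_cells, len(lam) * dt, dt)
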