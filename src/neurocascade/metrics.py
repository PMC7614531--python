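"""Prediction-quality metrics: variance explained, spike detection and
binarization, precision/recall, the coincidence factor Gamma, decoder-based
ROC analysis, spike-rate cross-correlation, and dendritic/somatic event
coincidence.

Somatic spikes are detected as threshold crossings with positive derivative
(threshold 16 mV on the AP component by default); dendritic spikes either as
positive crossings of a voltage threshold or as downward crossings of a
derivative threshold.  Binary spike trains use a 1 ms window: each bin is 0
(no spike) or 1 (one or more spikes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .traces import VoltageTrace

__all__ = [
    "BinarySpikeTrain", "GammaResult", "variance_explained",
    "detect_crossings", "precision_recall", "coincidence_factor",
    "SpikeDecoder", "fit_spike_decoder", "roc_curve", "auroc",
    "spike_rate_crosscorr", "classify_events",
]


# -- variance explained ------------------------------------------------------


def variance_explained(prediction, target) -> float:
    """1 - MSE/Var(target), pooled over concatenated trials.

    Accepts single traces/arrays or lists of them (test trials are
    concatenated before pooling, as for cross-validated reporting).
    """
    def flat(x):
        if isinstance(x, (list, tuple)):
            return np.concatenate([flat(e) for e in x])
        if isinstance(x, VoltageTrace):
            return x.values
        return np.asarray(x, dtype=float)

    p, t = flat(prediction), flat(target)
    if p.shape != t.shape:
        raise ValueError("prediction and target must share the time grid")
    var = t.var()
    if var == 0:
        raise ValueError("variance explained undefined for a constant target")
    return float(1.0 - np.mean((p - t) ** 2) / var)


# -- spike trains ------------------------------------------------------------


@dataclass
class BinarySpikeTrain:
    """0/1 per bin: no spike vs. one or more spikes."""

    values: np.ndarray
    bin_ms: float = 1.0

    def __post_init__(self):
        self.values = (np.asarray(self.values) > 0).astype(np.int8)

    @classmethod
    def from_times(cls, times_ms: np.ndarray, duration_ms: float,
                   bin_ms: float = 1.0) -> "BinarySpikeTrain":
        n = int(round(duration_ms / bin_ms))
        v = np.zeros(n, dtype=np.int8)
        idx = np.floor(np.asarray(times_ms) / bin_ms).astype(int)
        v[np.clip(idx, 0, n - 1)] = 1
        return cls(v, bin_ms)

    @property
    def spike_bins(self) -> np.ndarray:
        return np.flatnonzero(self.values)

    @property
    def times_ms(self) -> np.ndarray:
        return self.spike_bins * self.bin_ms

    @property
    def duration_ms(self) -> float:
        return len(self.values) * self.bin_ms


def detect_crossings(trace: VoltageTrace, threshold: float,
                     direction: str = "up", on_derivative: bool = False,
                     refractory_ms: float = 0.0) -> np.ndarray:
    """Times (ms) where the trace (or its derivative) crosses a threshold.

    ``direction='up'`` detects crossings with positive derivative (value
    passes from below to >= threshold), ``'down'`` the reverse.  With
    ``on_derivative`` the temporal derivative (per-second units) is
    thresholded instead of the value, e.g. dendritic-spike detection by the
    downward crossing of -8 V/s.
    """
    x = np.asarray(trace.values, dtype=float)
    dt = trace.dt_ms
    if on_derivative:
        x = np.diff(x, prepend=x[0]) / (dt * 1e-3)  # mV/s
    if direction == "up":
        hits = (x[1:] >= threshold) & (x[:-1] < threshold)
    elif direction == "down":
        hits = (x[1:] <= threshold) & (x[:-1] > threshold)
    else:
        raise ValueError("direction must be 'up' or 'down'")
    idx = np.flatnonzero(hits) + 1
    if refractory_ms > 0 and len(idx):
        refr = refractory_ms / dt
        kept = [idx[0]]
        for i in idx[1:]:
            if i - kept[-1] >= refr:
                kept.append(i)
        idx = np.asarray(kept)
    return idx * dt


def precision_recall(predicted: BinarySpikeTrain, reference: BinarySpikeTrain,
                     match_window_ms: float = 0.0) -> tuple[float, float]:
    """Precision and recall with one-to-one greedy matching in time order.

    A predicted spike is a true positive if an unmatched reference spike lies
    within +-match_window_ms (0 = exact-bin matching at the 1 ms resolution).
    An empty prediction yields precision 0 (flagged by recall 0 unless the
    reference is empty too); an empty reference makes recall undefined.
    """
    if len(predicted.values) != len(reference.values):
        raise ValueError("trains must have equal durations")
    pred = predicted.spike_bins
    ref = reference.spike_bins
    if len(ref) == 0:
        raise ValueError("recall undefined: reference train is empty")
    if len(pred) == 0:
        return 0.0, 0.0
    w = match_window_ms / predicted.bin_ms
    tp = 0
    j = 0
    used = np.zeros(len(ref), bool)
    for p in pred:
        while j < len(ref) and ref[j] < p - w:
            j += 1
        for k in range(j, len(ref)):
            if ref[k] > p + w:
                break
            if not used[k]:
                used[k] = True
                tp += 1
                break
    precision = tp / len(pred)
    recall = tp / len(ref)
    return precision, recall


# -- coincidence factor ------------------------------------------------------


@dataclass
class GammaResult:
    gamma: float
    n_ref: int
    n_pred: int
    n_coinc: int
    expected_coinc: float
    delta_ms: float
    normalizer: float
    out_of_range: bool = False


def coincidence_factor(reference_times_ms: np.ndarray,
                       predicted_times_ms: np.ndarray,
                       delta_ms: float = 4.0,
                       duration_ms: float | None = None) -> GammaResult:
    """Chance-corrected spike-timing agreement within a +-delta window.

        Gamma = (1/N) * (N_coinc - <N_coinc>) / (0.5 * (N_ref + N_pred))

    with <N_coinc> = 2 f_pred delta N_ref the expected coincidences of a
    homogeneous Poisson train at the predicted rate, and the normalizer
    N = 1 - 2 f_pred delta.  Each predicted spike is counted as coincident
    with at most one reference spike (greedy matching in time order).
    """
    ref = np.sort(np.asarray(reference_times_ms, dtype=float))
    pred = np.sort(np.asarray(predicted_times_ms, dtype=float))
    if duration_ms is None:
        duration_ms = max(ref.max(initial=0.0), pred.max(initial=0.0)) + 1.0
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    # one-to-one greedy coincidence count
    n_coinc = 0
    j = 0
    for r in ref:
        while j < len(pred) and pred[j] < r - delta_ms:
            j += 1
        if j < len(pred) and abs(pred[j] - r) <= delta_ms:
            n_coinc += 1
            j += 1
    f_pred = len(pred) / (duration_ms * 1e-3)            # Hz
    expected = 2.0 * f_pred * (delta_ms * 1e-3) * len(ref)
    normalizer = 1.0 - 2.0 * f_pred * (delta_ms * 1e-3)
    if normalizer <= 0:
        return GammaResult(np.nan, len(ref), len(pred), n_coinc, expected,
                           delta_ms, normalizer, out_of_range=True)
    denom = 0.5 * (len(ref) + len(pred))
    gamma = 0.0 if denom == 0 else (n_coinc - expected) / denom / normalizer
    return GammaResult(float(gamma), len(ref), len(pred), n_coinc, expected,
                       delta_ms, normalizer)


# -- GRU spike decoder -------------------------------------------------------


class SpikeDecoder:
    """A single dynamic (GRU) subunit mapping a voltage trace to either a
    per-bin spiking probability (cross-entropy loss) or a v_AP regression
    (squared-error loss)."""

    def __init__(self, G: int = 20, loss: str = "xent", seed: int = 0):
        if loss not in ("xent", "mse"):
            raise ValueError("loss must be 'xent' or 'mse'")
        self.loss = loss
        rng = np.random.default_rng(seed)

        def P(shape, s=1.0):
            return Tensor(rng.standard_normal(shape) * s, requires_grad=True)

        self.t = {"wr": P(G), "wz": P(G), "wk": P(G),
                  "Whr": P((G, G)), "Whz": P((G, G)), "Whk": P((G, G)),
                  "br": P(G), "bz": P(G), "bk": P(G),
                  "w_out": P(G), "b_out": P(1)}

    def _logits(self, x: np.ndarray) -> Tensor:
        t = self.t
        H = ad.gru_sequence(Tensor(x), t["wr"], t["wz"], t["wk"],
                            t["Whr"], t["Whz"], t["Whk"],
                            t["br"], t["bz"], t["bk"])
        return ad.add(ad.matmul(H, t["w_out"]), t["b_out"])

    def predict(self, x: np.ndarray) -> np.ndarray:
        z = self._logits(np.asarray(x, dtype=float)).data
        return 1.0 / (1.0 + np.exp(-z)) if self.loss == "xent" else z

    def train(self, inputs: list[np.ndarray], targets: list[np.ndarray],
              epochs: int = 30, lr: float = 0.005, seed: int = 0) -> list[float]:
        rng = np.random.default_rng(seed)
        opt = ad.Adam(list(self.t.values()), lr=lr)
        losses = []
        for _ in range(epochs):
            for i in rng.permutation(len(inputs)):
                opt.zero_grad()
                z = self._logits(np.asarray(inputs[i], dtype=float))
                y = np.asarray(targets[i], dtype=float)
                if self.loss == "xent":
                    # -[y log sig(z) + (1-y) log(1-sig(z))] = softplus(z) - y z
                    loss = ad.tmean(ad.sub(ad.softplus(z), ad.mul(Tensor(y), z)))
                else:
                    loss = ad.mse(z, y)
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
        return losses


def fit_spike_decoder(inputs, targets, loss: str = "xent", G: int = 20,
                      epochs: int = 30, lr: float = 0.005,
                      seed: int = 0) -> SpikeDecoder:
    """Train a single-GRU decoder; see :class:`SpikeDecoder`."""
    dec = SpikeDecoder(G=G, loss=loss, seed=seed)
    inputs = [np.asarray(x.values if isinstance(x, VoltageTrace) else x)
              for x in inputs]
    targets = [np.asarray(t.values if isinstance(t, VoltageTrace) else t)
               for t in targets]
    dec.train(inputs, targets, epochs=epochs, lr=lr, seed=seed)
    return dec


# -- ROC ---------------------------------------------------------------------


def roc_curve(probability: np.ndarray, reference: BinarySpikeTrain,
              thresholds: np.ndarray, bin_ms: float = 1.0) -> dict:
    """ROC by sweeping a detection threshold on a spiking-probability trace.

    Predicted spikes are threshold crossings with positive derivative; per
    threshold, TPR and FPR are computed over binarized 1 ms bins.  The report
    includes the empty-bin fraction, since per-bin ROC is dominated by the
    many bins without spikes.
    """
    prob = np.asarray(probability, dtype=float)
    ref = reference.values.astype(bool)
    points = []
    for th in thresholds:
        tr = VoltageTrace(prob, bin_ms, "prob")
        times = detect_crossings(tr, th, "up")
        pred = BinarySpikeTrain.from_times(times, len(prob) * bin_ms, bin_ms)
        p = pred.values.astype(bool)
        tpr = (p & ref).sum() / max(ref.sum(), 1)
        fpr = (p & ~ref).sum() / max((~ref).sum(), 1)
        points.append((float(fpr), float(tpr)))
    return {"points": points,
            "empty_bin_fraction": float(1.0 - ref.mean())}


def auroc(probability: np.ndarray, reference: BinarySpikeTrain) -> float:
    """Ranking AUROC of per-bin probabilities against the reference bins."""
    p = np.asarray(probability, dtype=float)
    y = reference.values.astype(bool)
    pos, neg = p[y], p[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUROC undefined without both classes")
    ranks = _midranks(np.concatenate([pos, neg]))
    return float((ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


# -- cross-correlation and event coincidence ---------------------------------


def spike_rate_crosscorr(reference_times_ms: np.ndarray,
                         predicted_times_ms: np.ndarray,
                         window_ms: float = 20.0, bin_ms: float = 1.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted-spike rate (Hz) conditioned on reference spikes, per lag bin."""
    ref = np.asarray(reference_times_ms, dtype=float)
    pred = np.asarray(predicted_times_ms, dtype=float)
    if len(ref) == 0:
        raise ValueError("cross-correlation undefined without reference spikes")
    edges = np.arange(-window_ms, window_ms + bin_ms, bin_ms)
    counts = np.zeros(len(edges) - 1)
    for r in ref:
        d = pred - r
        d = d[(d >= -window_ms) & (d < window_ms + bin_ms)]
        counts += np.histogram(d, bins=edges)[0]
    lags = 0.5 * (edges[:-1] + edges[1:])
    rate = counts / (len(ref) * bin_ms * 1e-3)
    return lags, rate


def classify_events(dendritic_times_ms: np.ndarray,
                    somatic_times_ms: np.ndarray,
                    window_ms: float = 5.0) -> tuple[np.ndarray, float]:
    """Label dendritic events as coincident/isolated; soma-dendrite coupling.

    An event is *coincident* if a somatic spike occurs within +-window_ms.
    Coupling is the fraction of somatic spikes with a dendritic event within
    the window (NaN when there are no somatic spikes).
    """
    dend = np.asarray(dendritic_times_ms, dtype=float)
    soma = np.asarray(somatic_times_ms, dtype=float)
    if len(soma) == 0:
        return np.array(["isolated"] * len(dend)), float("nan")
    labels = np.where(
        np.array([np.any(np.abs(soma - d) <= window_ms) for d in dend]),
        "coincident", "isolated")
    coupled = np.mean([np.any(np.abs(dend - s) <= window_ms) for s in soma]) \
        if len(dend) else 0.0
    return labels, float(coupled)
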