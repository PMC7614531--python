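"""Training cascade models and discovering synaptic organization.

Models are fitted by minimizing the mean squared error between the predicted
and target voltage with the Adam optimizer (learning rate 0.005, batches of
5 trials).  Dynamic-subunit parameters are initialized from a standard normal
distribution, static-subunit parameters from a normal with scale 0.01.
Synaptic weights are kept nonnegative by optimizing an unconstrained
parameter through a softplus transform.

Organization discovery starts from full connectivity: every synapse is
connected to every subunit through a tempered softmax over connection
parameters omega (initialized from Gumbel(0, 0.01)), whose inverse
temperature beta grows exponentially over optimizer steps,
beta(theta) = exp(theta / tau) with tau = 724, capped at its value at
step 5000 (~1000).  At test time the softmax is replaced by a hard argmax,
yielding a binary assignment.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cascade import (ArchitectureSpec, CascadeModel, DynamicSubunitParams,
                      StaticSubunitParams, hard_assignment)
from .kernels import KernelBank

__all__ = ["TrainConfig", "AnnealConfig", "anneal_beta", "initialize",
           "initialize_omega", "TrainableCascade", "fit",
           "discover_organization", "FitDiverged"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.005
    batch_trials: int = 5
    epochs: int = 100
    seed: int = 0
    init_scale_static: float = 0.01
    early_stop_patience: int | None = None  # epochs without val improvement
    standardize: bool = True  # fit standardized targets; affine folded into model

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_trials < 1:
            raise ValueError("invalid training configuration")


@dataclass
class AnnealConfig:
    tau_iterations: float = 724.0
    cap_iteration: int = 5000
    gumbel_loc: float = 0.0
    gumbel_scale: float = 0.01


class FitDiverged(RuntimeError):
    pass


def anneal_beta(iteration: int, config: AnnealConfig | None = None) -> float:
    """Inverse temperature beta(theta) = exp(theta/tau), held fixed past the cap."""
    cfg = config or AnnealConfig()
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    theta = min(iteration, cfg.cap_iteration)
    return math.exp(theta / cfg.tau_iterations)


# -- initialization ----------------------------------------------------------


def _inv_softplus(y: float) -> float:
    return float(np.log(np.expm1(y)))


def initialize(arch: ArchitectureSpec, config: TrainConfig,
               seed: int | np.random.Generator | None = None,
               bank: KernelBank | None = None) -> list:
    """Random initial subunit parameters (deterministic per seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    bank = bank or KernelBank()
    params = []
    for kind in arch.kinds:
        if kind == "static":
            s = config.init_scale_static
            params.append(StaticSubunitParams(
                w=rng.normal(0, s, arch.n_ch),
                b=rng.normal(0, s, arch.n_ch),
                alpha_e=rng.normal(0, s, (arch.n_ch, bank.n_bumps)),
                alpha_i=rng.normal(0, s, (arch.n_ch, bank.n_bumps))))
        else:
            G = arch.G
            params.append(DynamicSubunitParams(
                wr=rng.standard_normal(G), wz=rng.standard_normal(G),
                wk=rng.standard_normal(G),
                Whr=rng.standard_normal((G, G)), Whz=rng.standard_normal((G, G)),
                Whk=rng.standard_normal((G, G)),
                br=rng.standard_normal(G), bz=rng.standard_normal(G),
                bk=rng.standard_normal(G),
                w_out=rng.standard_normal(G), b_out=float(rng.standard_normal())))
    return params


def initialize_omega(n_subunits: int, n_synapses: int, config: AnnealConfig,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.gumbel(config.gumbel_loc, config.gumbel_scale,
                      (n_subunits, n_synapses))


# -- fused batched GRU for flat trees ----------------------------------------


def _gru_cascade(X: Tensor, tensors: list[dict]) -> Tensor:
    """All-subunit GRU scan for a flat tree: N independent GRUs side by side.

    ``X`` is the (N, T) per-subunit input; ``tensors`` holds each subunit's
    parameter Tensors (as created by :class:`TrainableCascade`).  Returns the
    (N, T) subunit outputs including the affine readout.  Equivalent to
    running ``gru_sequence`` per subunit but with one time loop over batched
    (N, G) states, which is substantially faster for multi-subunit models.
    """
    names = ["wr", "wz", "wk", "br", "bz", "bk", "w_out"]
    Vr, Vz, Vk, Br, Bz, Bk, Wout = (np.stack([t[n].data for t in tensors])
                                    for n in names)
    Wr, Wz, Wk = (np.stack([t[n].data for t in tensors])
                  for n in ["Whr", "Whz", "Whk"])
    Bout = np.stack([t["b_out"].data[0] for t in tensors])
    xs = X.data
    N, T = xs.shape
    G = Br.shape[1]
    H = np.empty((T, N, G)); R = np.empty((T, N, G))
    Z = np.empty((T, N, G)); K = np.empty((T, N, G))
    h = np.zeros((N, G))
    for t in range(T):
        xt = xs[:, t][:, None]
        hr = np.einsum("ngh,nh->ng", Wr, h)
        hz = np.einsum("ngh,nh->ng", Wz, h)
        r = 1.0 / (1.0 + np.exp(-(Vr * xt + hr + Br)))
        z = 1.0 / (1.0 + np.exp(-(Vz * xt + hz + Bz)))
        k = np.tanh(Vk * xt + Bk + np.einsum("ngh,nh->ng", Wk, r * h))
        R[t], Z[t], K[t] = r, z, k
        h = (1.0 - z) * k + z * h
        H[t] = h
    Y = np.einsum("tng,ng->nt", H, Wout) + Bout[:, None]

    def bw(gY):
        dVr = np.zeros((N, G)); dVz = np.zeros((N, G)); dVk = np.zeros((N, G))
        dWr = np.zeros((N, G, G)); dWz = np.zeros((N, G, G)); dWk = np.zeros((N, G, G))
        dBr = np.zeros((N, G)); dBz = np.zeros((N, G)); dBk = np.zeros((N, G))
        dWout = np.einsum("nt,tng->ng", gY, H)
        dBout = gY.sum(axis=1)
        dX = np.zeros((N, T))
        carry = np.zeros((N, G))
        for t in range(T - 1, -1, -1):
            dh = gY[:, t][:, None] * Wout + carry
            h_prev = H[t - 1] if t > 0 else np.zeros((N, G))
            r, z, k = R[t], Z[t], K[t]
            dz = dh * (h_prev - k)
            dk = dh * (1.0 - z)
            dh_prev = dh * z
            dak = dk * (1.0 - k * k)
            rh_grad = np.einsum("ngh,ng->nh", Wk, dak)
            dr = rh_grad * h_prev
            dh_prev += rh_grad * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            xt = xs[:, t][:, None]
            dVk += dak * xt; dBk += dak
            dWk += np.einsum("ng,nh->ngh", dak, r * h_prev)
            dVz += daz * xt; dBz += daz
            dWz += np.einsum("ng,nh->ngh", daz, h_prev)
            dVr += dar * xt; dBr += dar
            dWr += np.einsum("ng,nh->ngh", dar, h_prev)
            dh_prev += np.einsum("ngh,ng->nh", Wz, daz)
            dh_prev += np.einsum("ngh,ng->nh", Wr, dar)
            dX[:, t] = (Vr * dar + Vz * daz + Vk * dak).sum(axis=1)
            carry = dh_prev
        X._accumulate(dX)
        grads = {"wr": dVr, "wz": dVz, "wk": dVk, "br": dBr, "bz": dBz,
                 "bk": dBk, "w_out": dWout, "Whr": dWr, "Whz": dWz,
                 "Whk": dWk}
        for n, t in enumerate(tensors):
            for name, g in grads.items():
                t[name]._accumulate(g[n])
            t["b_out"]._accumulate(np.atleast_1d(dBout[n]))

    parents = [X]
    for t in tensors:
        parents.extend(t.values())
    return ad._make(Y, tuple(parents), bw)


# -- differentiable model ----------------------------------------------------


class TrainableCascade:
    """A cascade model expressed as an autodiff graph over its parameters.

    Wraps an :class:`ArchitectureSpec`; parameter Tensors are created once and
    a fresh graph is built per trial.  ``omega`` tensors are present only in
    discovery mode (soft assignment); otherwise the assignment matrices of the
    architecture are treated as fixed constants.
    """

    def __init__(self, arch: ArchitectureSpec, params: list,
                 bank: KernelBank | None = None, discover: bool = False,
                 anneal: AnnealConfig | None = None,
                 omega_seed: int | np.random.Generator = 0):
        arch.validate()
        self.arch = arch
        self.bank = bank or KernelBank()
        self.discover = discover
        self.anneal = anneal or AnnealConfig()
        self._bank_table = self.bank.table
        C = np.asarray(arch.C)
        self._flat_dynamic = (all(k == "dynamic" for k in arch.kinds)
                              and bool(C[0, 1:].all())
                              and C[1:, :].sum() == 0)

        def P(x):
            return Tensor(np.array(x, dtype=float), requires_grad=True)

        self.subunit_tensors = []
        for p in params:
            if isinstance(p, StaticSubunitParams):
                tensors = {"w": [P(p.w[j:j + 1]) for j in range(p.n_ch)],
                           "b": [P(p.b[j:j + 1]) for j in range(p.n_ch)],
                           "alpha_e": [P(p.alpha_e[j]) for j in range(p.n_ch)],
                           "alpha_i": [P(p.alpha_i[j]) for j in range(p.n_ch)]}
            else:
                tensors = {k: P(v) for k, v in p.arrays().items()}
            self.subunit_tensors.append(tensors)
        # nonnegative synaptic weights via softplus reparameterization
        rho0 = _inv_softplus(1.0)
        self.rho_e = P(np.full(arch.C_syn_e.shape[1], rho0))
        self.rho_i = P(np.full(arch.C_syn_i.shape[1], rho0))
        self.target_affine = (0.0, 1.0)   # (offset, scale) set when fitting
                                          # against standardized targets
        if discover:
            self.omega_e = P(initialize_omega(arch.n_subunits,
                                              arch.C_syn_e.shape[1],
                                              self.anneal, omega_seed))
            self.omega_i = P(initialize_omega(arch.n_subunits,
                                              arch.C_syn_i.shape[1],
                                              self.anneal, omega_seed))

    # -- parameters ----------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        out = []
        for tensors in self.subunit_tensors:
            for v in tensors.values():
                out.extend(v if isinstance(v, list) else [v])
        out += [self.rho_e, self.rho_i]
        if self.discover:
            out += [self.omega_e, self.omega_i]
        return out

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data[...] = s

    # -- graph construction --------------------------------------------------

    def predict(self, exc_binned: np.ndarray, inh_binned: np.ndarray,
                beta: float = 1.0) -> Tensor:
        arch = self.arch
        w_e = ad.softplus(self.rho_e)
        w_i = ad.softplus(self.rho_i)
        if self.discover:
            Ce = ad.softmax_columns(self.omega_e, beta)
            Ci = ad.softmax_columns(self.omega_i, beta)
        else:
            Ce = Tensor(arch.C_syn_e)
            Ci = Tensor(arch.C_syn_i)
        De = ad.matmul(ad.mul(Ce, w_e), Tensor(exc_binned))   # (N, T)
        Di = ad.matmul(ad.mul(Ci, w_i), Tensor(inh_binned))
        if self._flat_dynamic:
            Y = _gru_cascade(ad.sub(De, Di), self.subunit_tensors)
            return ad.sum_axis0(Y)
        outputs: dict[int, Tensor] = {}
        for n in arch.eval_order():
            kids = [int(m) for m in arch.children(n)]
            ybar = None
            for m in kids:
                ybar = outputs[m] if ybar is None else ad.add(ybar, outputs[m])
            de, di = ad.row(De, n - 1), ad.row(Di, n - 1)
            t = self.subunit_tensors[n - 1]
            if arch.kinds[n - 1] == "static":
                y = None
                for j in range(arch.n_ch):
                    ke = ad.matmul(t["alpha_e"][j], Tensor(self._bank_table))
                    ki = ad.matmul(t["alpha_i"][j], Tensor(self._bank_table))
                    u = ad.add(ad.causal_conv(de, ke), ad.causal_conv(di, ki))
                    if ybar is not None:
                        u = ad.add(u, ybar)
                    ch = ad.mul(t["w"][j], ad.tanh(ad.add(u, t["b"][j])))
                    y = ch if y is None else ad.add(y, ch)
            else:
                x = ad.sub(de, di)
                if ybar is not None:
                    x = ad.add(x, ybar)
                H = ad.gru_sequence(x, t["wr"], t["wz"], t["wk"],
                                    t["Whr"], t["Whz"], t["Whk"],
                                    t["br"], t["bz"], t["bk"])
                y = ad.add(ad.matmul(H, t["w_out"]), t["b_out"])
            outputs[n] = y
        v = None
        for n in arch.children(0):
            v = outputs[int(n)] if v is None else ad.add(v, outputs[int(n)])
        return v

    # -- export --------------------------------------------------------------

    def to_model(self, hard: bool = False) -> CascadeModel:
        """Materialize a numpy :class:`CascadeModel` from the current state."""
        arch = copy.deepcopy(self.arch)
        arch.w_syn_e = np.logaddexp(0.0, self.rho_e.data)
        arch.w_syn_i = np.logaddexp(0.0, self.rho_i.data)
        if self.discover:
            if hard:
                arch.C_syn_e = hard_assignment(self.omega_e.data)
                arch.C_syn_i = hard_assignment(self.omega_i.data)
            else:
                from .cascade import soft_assignment
                arch.C_syn_e = soft_assignment(self.omega_e.data, 1.0)
                arch.C_syn_i = soft_assignment(self.omega_i.data, 1.0)
        params = []
        for kind, t in zip(arch.kinds, self.subunit_tensors):
            if kind == "static":
                params.append(StaticSubunitParams(
                    w=np.concatenate([x.data for x in t["w"]]),
                    b=np.concatenate([x.data for x in t["b"]]),
                    alpha_e=np.stack([x.data for x in t["alpha_e"]]),
                    alpha_i=np.stack([x.data for x in t["alpha_i"]])))
            else:
                params.append(DynamicSubunitParams(
                    wr=t["wr"].data.copy(), wz=t["wz"].data.copy(),
                    wk=t["wk"].data.copy(), Whr=t["Whr"].data.copy(),
                    Whz=t["Whz"].data.copy(), Whk=t["Whk"].data.copy(),
                    br=t["br"].data.copy(), bz=t["bz"].data.copy(),
                    bk=t["bk"].data.copy(), w_out=t["w_out"].data.copy(),
                    b_out=float(t["b_out"].data[0])))
        off, sc = self.target_affine
        return CascadeModel(arch, params, self.bank,
                            output_offset=off, output_scale=sc)


# -- training loops ----------------------------------------------------------


def _binned_trials(trials, target: str):
    """Precompute (exc_binned, inh_binned, target_values) per trial."""
    out = []
    for tr in trials:
        out.append((tr.exc_spikes.binned(), tr.inh_spikes.binned(),
                    tr.target(target).values))
    return out


def _val_loss(model: TrainableCascade, val, beta: float) -> float:
    total = 0.0
    for exc, inh, y in val:
        pred = model.predict(exc, inh, beta)
        total += float(np.mean((pred.data - y) ** 2))
    return total / len(val)


def fit(model: TrainableCascade, trials, target: str = "vsoma",
        config: TrainConfig | None = None, val_trials=None,
        log: list | None = None) -> tuple[TrainableCascade, list[dict]]:
    """Mini-batch Adam on mean squared voltage error; best-on-validation.

    ``trials`` is a list of dataset trials; ``val_trials`` (default: the last
    training trial) is used for early stopping and for selecting the returned
    parameters.  Returns the model (state set to the best parameters) and a
    log of dicts (epoch, step, loss, beta).
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    if val_trials is None and len(trials) > 1:
        trials, val_trials = trials[:-1], trials[-1:]
    data = _binned_trials(trials, target)
    val = _binned_trials(val_trials, target) if val_trials else None
    if cfg.standardize:
        pooled = np.concatenate([y for _, _, y in data])
        mu, sd = float(pooled.mean()), float(pooled.std())
        sd = sd if sd > 0 else 1.0
        data = [(e, i, (y - mu) / sd) for e, i, y in data]
        if val is not None:
            val = [(e, i, (y - mu) / sd) for e, i, y in val]
        model.target_affine = (mu, sd)
    opt = ad.Adam(model.parameters(), lr=cfg.learning_rate)
    log = [] if log is None else log
    step = 0
    best = (np.inf, model.state())
    stale = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(data))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_trials):
            batch = order[start:start + cfg.batch_trials]
            beta = anneal_beta(step, model.anneal) if model.discover else 1.0
            opt.zero_grad()
            losses = []
            for i in batch:
                exc, inh, y = data[i]
                losses.append(ad.mse(model.predict(exc, inh, beta), y))
            loss = losses[0]
            for l in losses[1:]:
                loss = ad.add(loss, l)
            loss = ad.scale(loss, 1.0 / len(losses))
            if not np.isfinite(loss.data):
                raise FitDiverged(f"loss became non-finite at step {step}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
            log.append({"epoch": epoch, "step": step,
                        "loss": float(loss.data), "beta": beta})
            step += 1
        if val is not None:
            beta = anneal_beta(step, model.anneal) if model.discover else 1.0
            vl = _val_loss(model, val, beta)
            log[-1]["val_loss"] = vl
            if vl < best[0]:
                best = (vl, model.state())
                stale = 0
            else:
                stale += 1
                if cfg.early_stop_patience and stale >= cfg.early_stop_patience:
                    break
        else:
            best = (epoch_loss / len(data), model.state())
    model.load_state(best[1])
    return model, log


def discover_organization(arch: ArchitectureSpec, trials,
                          target: str = "vsoma",
                          train_config: TrainConfig | None = None,
                          anneal_config: AnnealConfig | None = None,
                          bank: KernelBank | None = None
                          ) -> tuple[np.ndarray, np.ndarray, TrainableCascade, list]:
    """Annealed discovery of the synapse-to-subunit assignment.

    Optimizes omega jointly with all model parameters under the tempered
    softmax with the exponential beta schedule; at the end the softmax is
    replaced by a hard argmax.  Returns (binary C_syn_e, w_syn_e, model, log).

    Unlike plain fitting there is no best-on-validation selection: mid-run
    states pair their parameters with a *soft* low-beta assignment and break
    when hard-maxed, so the final (hardened, self-consistent) state is the
    estimate and the annealing itself acts as the regularizer.
    """
    cfg = train_config or TrainConfig()
    params = initialize(arch, cfg, seed=np.random.default_rng(cfg.seed),
                        bank=bank)
    model = TrainableCascade(arch, params, bank=bank, discover=True,
                             anneal=anneal_config,
                             omega_seed=np.random.default_rng(cfg.seed + 1))
    model, log = fit(model, trials, target, cfg, val_trials=[])
    C_e = hard_assignment(model.omega_e.data)
    w_e = np.logaddexp(0.0, model.rho_e.data)
    return C_e, w_e, model, log
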