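"""Plain-text serialization: spike files, voltage traces, morphology tables,
dissimilarity matrices, model files and manifests.

All tabular files are tab-separated with ``#``-prefixed header lines.  Model
files store every parameter array with 17 significant digits, which
round-trips float64 exactly, so save -> load -> save is byte-identical.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import yaml

from .cascade import (ArchitectureSpec, CascadeModel, DynamicSubunitParams,
                      StaticSubunitParams)
from .inputs import SpikeTrainSet, Trajectory
from .kernels import KernelBank
from .morphology import Branch, Morphology
from .rsa import DissimilarityMatrix
from .traces import VoltageTrace

MODEL_FORMAT_VERSION = 1

__all__ = ["save_spikes", "load_spikes", "save_trajectory", "load_trajectory",
           "save_voltage", "load_voltage", "save_morphology",
           "load_morphology", "save_dissimilarity", "load_dissimilarity",
           "save_model", "load_model", "save_manifest", "load_manifest",
           "save_curve", "load_curve", "save_log"]


def save_spikes(path, spikes: SpikeTrainSet) -> None:
    order = np.lexsort((spikes.synapse_ids, spikes.times_ms))
    with open(path, "w") as f:
        f.write("synapse_id\ttime_ms\ttype\n")
        for i in order:
            sid = int(spikes.synapse_ids[i])
            f.write(f"{sid}\t{spikes.times_ms[i]:.3f}\t"
                    f"{spikes.synapse_type[sid]}\n")


def load_spikes(path, n_synapses: int, duration_ms: float,
                bin_width_ms: float = 1.0) -> SpikeTrainSet:
    ids, times, types = [], [], {}
    with open(path) as f:
        header = f.readline()
        for line in f:
            s, t, ty = line.rstrip("\n").split("\t")
            ids.append(int(s)); times.append(float(t)); types[int(s)] = ty
    type_arr = np.array([types.get(i, "exc") for i in range(n_synapses)])
    return SpikeTrainSet(np.asarray(ids, dtype=int), np.asarray(times),
                         type_arr, n_synapses, duration_ms, bin_width_ms)


def save_trajectory(path, traj: Trajectory) -> None:
    with open(path, "w") as f:
        f.write("time_ms\tposition_cm\ttheta_phase_rad\n")
        for t, x, p in zip(traj.time_ms, traj.position_cm, traj.theta_phase):
            f.write(f"{t:.3f}\t{x:.6f}\t{p:.9f}\n")


def load_trajectory(path) -> Trajectory:
    data = np.loadtxt(path, skiprows=1)
    return Trajectory(data[:, 0], data[:, 1], data[:, 2])


def save_voltage(path, trace: VoltageTrace) -> None:
    with open(path, "w") as f:
        f.write(f"# component: {trace.component}\n")
        f.write("time_ms\tvalue_mV\n")
        for t, v in zip(trace.time_ms, trace.values):
            f.write(f"{t:.3f}\t{v:.9g}\n")


def load_voltage(path) -> VoltageTrace:
    with open(path) as f:
        component = f.readline().split(":", 1)[1].strip()
    data = np.loadtxt(path, skiprows=2)
    dt = data[1, 0] - data[0, 0] if len(data) > 1 else 1.0
    return VoltageTrace(data[:, 1], float(dt), component)


def save_morphology(path, morph: Morphology) -> None:
    with open(path, "w") as f:
        f.write("branch_id\tparent_id\tproximal_distance_um\tlength_um\t"
                "surface_area_um2\tsubtree_id\n")
        for b in morph.branches:
            f.write(f"{b.branch_id}\t{b.parent_id}\t{b.proximal_distance:.17g}"
                    f"\t{b.length:.17g}\t{b.surface_area:.17g}\t{b.subtree_id}\n")


def load_morphology(path) -> Morphology:
    branches = []
    with open(path) as f:
        f.readline()
        for line in f:
            p = line.split("\t")
            branches.append(Branch(int(p[0]), int(p[1]), float(p[2]),
                                   float(p[3]), float(p[4]), int(p[5])))
    return Morphology(branches)


def save_dissimilarity(path, D: DissimilarityMatrix) -> None:
    with open(path, "w") as f:
        f.write(f"# kind: {D.kind}\n")
        f.write("\t".join(str(int(s)) for s in D.synapse_ids) + "\n")
        for row in D.values:
            f.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def load_dissimilarity(path) -> DissimilarityMatrix:
    with open(path) as f:
        kind = f.readline().split(":", 1)[1].strip()
        ids = np.array([int(s) for s in f.readline().split()])
        vals = np.loadtxt(f)
    return DissimilarityMatrix(np.atleast_2d(vals), kind, ids)


# -- model files -------------------------------------------------------------


def _write_array(f, name: str, a: np.ndarray) -> None:
    a = np.asarray(a, dtype=float)
    f.write(f"@array {name} {' '.join(map(str, a.shape))}\n")
    flat = a.ravel()
    f.write("\t".join(f"{v:.17g}" for v in flat) + "\n")


def _read_array(lines, i: int):
    head = lines[i].split()
    name = head[1]
    shape = tuple(int(s) for s in head[2:])
    vals = np.array([float(v) for v in lines[i + 1].split("\t")] if
                    lines[i + 1].strip() else [])
    return name, vals.reshape(shape), i + 2


def save_model(path, model: CascadeModel) -> None:
    arch = model.arch
    with open(path, "w") as f:
        f.write(f"# neurocascade model format v{MODEL_FORMAT_VERSION}\n")
        f.write(f"@kinds {' '.join(arch.kinds)}\n")
        f.write(f"@n_ch {arch.n_ch}\n@G {arch.G}\n")
        f.write(f"@output_affine {model.output_offset:.17g} "
                f"{model.output_scale:.17g}\n")
        f.write(f"@bank {model.bank.n_bumps} {model.bank.a:.17g} "
                f"{model.bank.c:.17g} {model.bank.phi_max:.17g} "
                f"{model.bank.span_ms:.17g} {model.bank.dt_ms:.17g}\n")
        _write_array(f, "C", arch.C)
        _write_array(f, "C_syn_e", arch.C_syn_e)
        _write_array(f, "C_syn_i", arch.C_syn_i)
        _write_array(f, "w_syn_e", arch.w_syn_e)
        _write_array(f, "w_syn_i", arch.w_syn_i)
        for n, p in enumerate(model.params):
            for name, a in p.arrays().items():
                _write_array(f, f"subunit{n}.{name}", a)


def load_model(path) -> CascadeModel:
    lines = Path(path).read_text().splitlines()
    kinds = lines[1].split()[1:]
    n_ch = int(lines[2].split()[1])
    G = int(lines[3].split()[1])
    aff = lines[4].split()[1:]
    offset, scale = float(aff[0]), float(aff[1])
    bk = lines[5].split()[1:]
    bank = KernelBank(n_bumps=int(bk[0]), a=float(bk[1]), c=float(bk[2]),
                      phi_max=float(bk[3]), span_ms=float(bk[4]),
                      dt_ms=float(bk[5]))
    arrays = {}
    i = 6
    while i < len(lines):
        if lines[i].startswith("@array"):
            name, a, i = _read_array(lines, i)
            arrays[name] = a
        else:
            i += 1
    arch = ArchitectureSpec(arrays["C"], kinds, n_ch, G,
                            arrays["C_syn_e"], arrays["C_syn_i"],
                            arrays["w_syn_e"], arrays["w_syn_i"])
    params = []
    for n, kind in enumerate(kinds):
        g = {k.split(".", 1)[1]: v for k, v in arrays.items()
             if k.startswith(f"subunit{n}.")}
        if kind == "static":
            params.append(StaticSubunitParams(g["w"], g["b"], g["alpha_e"],
                                              g["alpha_i"]))
        else:
            params.append(DynamicSubunitParams(
                g["wr"], g["wz"], g["wk"], g["Whr"], g["Whz"], g["Whk"],
                g["br"], g["bz"], g["bk"], g["w_out"], float(g["b_out"][0])))
    return CascadeModel(arch, params, bank, output_offset=offset,
                        output_scale=scale)


def save_manifest(path, manifest: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=True)


def load_manifest(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_curve(path, x, y, header: tuple[str, str]) -> None:
    """Two-column table (ROC points, cross-correlograms, ...)."""
    with open(path, "w") as f:
        f.write(f"{header[0]}\t{header[1]}\n")
        for a, b in zip(x, y):
            f.write(f"{a:.9g}\t{b:.9g}\n")


def load_curve(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    return data[:, 0], data[:, 1]


def save_log(path, log: list[dict]) -> None:
    keys = ["epoch", "step", "loss", "beta", "val_loss"]
    with open(path, "w") as f:
        f.write("\t".join(keys) + "\n")
        for rec in log:
            f.write("\t".join(str(rec.get(k, "")) for k in keys) + "\n")
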