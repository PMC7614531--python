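"""End-to-end orchestration: simulate -> fit -> evaluate -> RSA.

Every stage takes a :class:`RunConfig` (YAML-serializable) and writes its
artifacts under the run's output directory; all randomness flows from the
config's root seed through named substreams, so re-running an archived
config reproduces every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as ncio
from .cascade import (CascadeModel, discovery_architecture,
                      single_subunit_architecture, two_layer_architecture)
from .dataset import Dataset, DatasetConfig, make_dataset
from .fitting import (AnnealConfig, TrainConfig, TrainableCascade,
                      discover_organization, fit, initialize)
from .kernels import KernelBank
from .metrics import variance_explained
from .rsa import (distance_dissimilarity, orthogonalized_cluster,
                  subunit_dissimilarity, weight_dissimilarity)

__all__ = ["RunConfig", "cmd_simulate", "cmd_fit", "cmd_discover",
           "cmd_evaluate", "cmd_rsa", "make_fixtures"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    arch: str = "two_layer"        # two_layer | single | discovery
    kind: str = "dynamic"          # static | dynamic
    n_ch: int = 2
    G: int = 20
    n_subunits: int = 5            # for discovery architectures
    target: str = "vsoma"          # vsoma | vnona | vna
    train: TrainConfig = field(default_factory=TrainConfig)
    anneal: AnnealConfig = field(default_factory=AnnealConfig)
    paper_scale: bool = False      # 980/20 trials at 0.2 ms instead of 80/8 at 1 ms

    def __post_init__(self):
        if self.paper_scale:
            self.dataset.n_train = 980
            self.dataset.n_test = 20
            self.dataset.dt_ms = 0.2

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        from .teacher import TeacherParams
        ds = raw.pop("dataset", {})
        teacher = TeacherParams(**ds.pop("teacher", {}))
        cfg = cls(**{k: v for k, v in raw.items()
                     if k not in ("train", "anneal")})
        cfg.dataset = DatasetConfig(teacher=teacher, **ds)
        cfg.train = TrainConfig(**raw.get("train", {}))
        cfg.anneal = AnnealConfig(**raw.get("anneal", {}))
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _build_arch(cfg: RunConfig, placement):
    if cfg.arch == "two_layer":
        return two_layer_architecture(placement, cfg.kind, cfg.n_ch, cfg.G)
    if cfg.arch == "single":
        return single_subunit_architecture(placement, cfg.kind, cfg.n_ch, cfg.G)
    if cfg.arch == "discovery":
        return discovery_architecture(placement, cfg.n_subunits, cfg.kind,
                                      cfg.n_ch, cfg.G)
    raise ValueError(f"unknown architecture '{cfg.arch}'")


def cmd_simulate(cfg: RunConfig) -> Dataset:
    """Simulate a dataset and write it under <out_dir>/dataset."""
    out = Path(cfg.out_dir) / "dataset"
    out.mkdir(parents=True, exist_ok=True)
    ds = make_dataset(cfg.dataset, seed=cfg.seed)
    ncio.save_morphology(out / "morphology.tsv", ds.morphology)
    for split, trials in (("train", ds.train), ("test", ds.test)):
        for k, tr in enumerate(trials):
            stem = out / f"{split}_{k:03d}"
            ncio.save_spikes(f"{stem}.exc.spikes.tsv", tr.exc_spikes)
            ncio.save_spikes(f"{stem}.inh.spikes.tsv", tr.inh_spikes)
            for name in ("v_nona", "v_na", "v_soma"):
                ncio.save_voltage(f"{stem}.{name}.tsv", getattr(tr, name))
    manifest = dict(ds.manifest)
    manifest["config_hash"] = cfg.config_hash()
    ncio.save_manifest(out / "manifest.yaml", manifest)
    return ds


def cmd_fit(cfg: RunConfig, ds: Dataset) -> tuple[CascadeModel, list]:
    """Fit the configured architecture to the configured target."""
    bank = KernelBank(dt_ms=cfg.dataset.dt_ms)
    arch = _build_arch(cfg, ds.placement)
    params = initialize(arch, cfg.train, bank=bank)
    model = TrainableCascade(arch, params, bank=bank)
    model, log = fit(model, ds.train, cfg.target, cfg.train)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm = model.to_model()
    ncio.save_model(out / f"model_{cfg.target}_{cfg.arch}_{cfg.kind}.txt", cm)
    ncio.save_log(out / f"fit_{cfg.target}_{cfg.arch}_{cfg.kind}.log.tsv", log)
    return cm, log


def cmd_discover(cfg: RunConfig, ds: Dataset):
    """Annealed discovery of the synaptic organization."""
    bank = KernelBank(dt_ms=cfg.dataset.dt_ms)
    arch = discovery_architecture(ds.placement, cfg.n_subunits, cfg.kind,
                                  cfg.n_ch, cfg.G)
    C_e, w_e, model, log = discover_organization(
        arch, ds.train, cfg.target, cfg.train, cfg.anneal, bank)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm = model.to_model(hard=True)
    ncio.save_model(out / f"discovered_{cfg.target}.txt", cm)
    ncio.save_log(out / f"discover_{cfg.target}.log.tsv", log)
    return C_e, w_e, cm, log


def cmd_evaluate(cfg: RunConfig, ds: Dataset, model: CascadeModel) -> dict:
    """Held-out variance explained of a fitted model; writes a metrics table."""
    preds, targets, rows = [], [], []
    for k, tr in enumerate(ds.test):
        pred = model.forward(tr.exc_spikes.binned(), tr.inh_spikes.binned())
        tgt = tr.target(cfg.target).values
        preds.append(pred); targets.append(tgt)
        rows.append({"trial_id": k, "metric": "ve",
                     "value": variance_explained(pred, tgt)})
    pooled = variance_explained(preds, targets)
    rows.append({"trial_id": "pooled", "metric": "ve", "value": pooled})
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"metrics_{cfg.target}_{cfg.arch}_{cfg.kind}.tsv", "w") as f:
        f.write("trial_id\tmetric\tvalue\n")
        for r in rows:
            f.write(f"{r['trial_id']}\t{r['metric']}\t{r['value']:.6f}\n")
    return {"ve": pooled, "per_trial": rows}


def cmd_rsa(cfg: RunConfig, ds: Dataset, model: CascadeModel) -> dict:
    """Dissimilarity matrices of a fitted model vs the ground truth."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Dd = distance_dissimilarity(ds.placement)
    Dc = orthogonalized_cluster(ds.placement)
    Dw = weight_dissimilarity(model.arch.w_syn_e, Dd.synapse_ids)
    ncio.save_dissimilarity(out / "D_distance.tsv", Dd)
    ncio.save_dissimilarity(out / "D_cluster_orth.tsv", Dc)
    ncio.save_dissimilarity(out / "D_weight.tsv", Dw)
    result = {"distance": Dd, "cluster_orth": Dc, "weight": Dw}
    C = model.arch.C_syn_e
    if np.allclose(np.sort(C, axis=0)[-1], 1.0):
        Ds = subunit_dissimilarity(C, Dd.synapse_ids)
        ncio.save_dissimilarity(out / "D_subunit.tsv", Ds)
        result["subunit"] = Ds
    return result


def make_fixtures(seed: int = 0) -> Dataset:
    """Tiny deterministic dataset for unit tests: 10 excitatory and 4
    inhibitory synapses, 2 clusters, 2 s trials."""
    cfg = DatasetConfig(n_exc=10, n_inh=4, n_clusters=2, n_clustered=6,
                        n_train=2, n_test=1, trial_duration_ms=2000.0,
                        branches_per_subtree=2, n_subtrees=2)
    return make_dataset(cfg, seed=seed)
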