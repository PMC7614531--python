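"""Synthetic dendritic morphology and synapse placement.

A random binary-branching tree stands in for a CA1 pyramidal cell's dendritic
arbor: 5 main subtrees radiate from the soma, each branch has a log-normal
length and membrane surface area, and path distances accumulate from the soma
outward.  Synapses are placed on it following the study's arrangement:
2,000 excitatory inputs of which 240 form 4, 8 or 12 clusters (of 60, 30 or
20 synapses) each confined to a single branch longer than 60 um, the rest
uniform over the tree; 200 inhibitory inputs split 80 perisomatic / 120
distributed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Branch", "Morphology", "SynapsePlacement", "build_morphology",
           "place_synapses", "PlacementError", "BACKGROUND"]

BACKGROUND = -1  # cluster_id of non-clustered synapses


@dataclass
class Branch:
    branch_id: int
    parent_id: int              # -1 for soma-attached subtree roots
    proximal_distance: float    # um, path distance soma -> branch start
    length: float               # um
    surface_area: float         # um^2
    subtree_id: int             # 1..n_subtrees

    @property
    def path_distance_to_soma(self) -> float:
        """Distance from soma to the branch midpoint (strictly > parent's)."""
        return self.proximal_distance + 0.5 * self.length


@dataclass
class Morphology:
    branches: list[Branch]

    def __getitem__(self, branch_id: int) -> Branch:
        return self.branches[branch_id]

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def eligible_branches(self, min_length: float = 60.0) -> list[int]:
        return [b.branch_id for b in self.branches if b.length > min_length]


def build_morphology(n_subtrees: int = 5, branches_per_subtree: int = 7,
                     seed: int | np.random.Generator = 0,
                     mean_length: float = 80.0) -> Morphology:
    """Random binary-branching dendritic tree.

    Each subtree grows by attaching new branches to uniformly chosen existing
    branches of the same subtree (at their distal end).  Lengths and areas are
    log-normal; area scales with length times a log-normal diameter factor.
    """
    if n_subtrees < 1 or branches_per_subtree < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    branches: list[Branch] = []
    for s in range(1, n_subtrees + 1):
        subtree: list[Branch] = []
        for j in range(branches_per_subtree):
            length = float(mean_length * rng.lognormal(0.0, 0.45))
            diameter = float(1.5 * rng.lognormal(0.0, 0.3))
            area = float(np.pi * diameter * length)
            if j == 0:
                parent, prox = -1, 0.0
            else:
                p = subtree[int(rng.integers(len(subtree)))]
                parent, prox = p.branch_id, p.proximal_distance + p.length
            bid = len(branches) + len(subtree)
            subtree.append(Branch(bid, parent, prox, length, area, s))
        branches.extend(subtree)
    return Morphology(branches)


@dataclass
class SynapsePlacement:
    """Per-synapse location, type and cluster membership.

    Excitatory synapses occupy ids [0, n_exc); inhibitory ids [0, n_inh) in a
    separate block (matching the separate excitatory/inhibitory spike-train
    and weight blocks of the cascade models).
    """

    exc_branch: np.ndarray       # (n_exc,) branch id
    exc_distance: np.ndarray     # (n_exc,) um, somatic path distance
    exc_cluster: np.ndarray      # (n_exc,) cluster id or BACKGROUND
    inh_branch: np.ndarray
    inh_distance: np.ndarray
    inh_perisomatic: np.ndarray  # (n_inh,) bool
    n_clusters: int
    branch_subtree: np.ndarray = None  # (n_branches,) subtree id per branch

    @property
    def n_exc(self) -> int:
        return len(self.exc_branch)

    @property
    def n_inh(self) -> int:
        return len(self.inh_branch)

    @property
    def clustered_ids(self) -> np.ndarray:
        return np.flatnonzero(self.exc_cluster != BACKGROUND)

    def cluster_members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.exc_cluster == cluster_id)

    def cluster_branch(self, cluster_id: int) -> int:
        members = self.cluster_members(cluster_id)
        return int(self.exc_branch[members[0]])


class PlacementError(RuntimeError):
    pass


def place_synapses(morph: Morphology, n_clusters: int = 4,
                   n_exc: int = 2000, n_inh: int = 200,
                   n_clustered: int = 240, perisomatic_count: int = 80,
                   perisomatic_threshold: float = 50.0,
                   seed: int | np.random.Generator = 0) -> SynapsePlacement:
    """Place synapses on the morphology with functional clustering.

    ``n_clustered`` excitatory synapses form ``n_clusters`` equal clusters
    (60/30/20 synapses for 4/8/12 clusters at the defaults), each cluster
    lying entirely on one distinct branch longer than 60 um, with ~1 um
    within-cluster spacing.  The remaining excitatory synapses are uniform
    over branches (position uniform along the branch).  Inhibitory synapses:
    ``perisomatic_count`` proximal (within ``perisomatic_threshold`` um of the
    soma), the rest distributed like the background excitatory ones.
    """
    if n_clustered % n_clusters:
        raise ValueError("cluster sizes must be equal")
    rng = np.random.default_rng(seed)
    eligible = morph.eligible_branches(60.0)
    if len(eligible) < n_clusters:
        raise PlacementError(
            f"need {n_clusters} branches longer than 60 um, found {len(eligible)}")
    per = n_clustered // n_clusters
    # spread clusters across the tree: pick the eligible branches closest to
    # evenly spaced somatic-distance targets, so clusters sit at distinct
    # electrotonic positions (distinct spikelet amplitude and kinetics)
    dists = np.array([morph[b].path_distance_to_soma for b in eligible])
    targets = np.linspace(dists.min(), dists.max(), n_clusters)
    cluster_branches = []
    remaining = list(range(len(eligible)))
    for t in targets:
        i = min(remaining, key=lambda j: abs(dists[j] - t))
        cluster_branches.append(eligible[i])
        remaining.remove(i)

    exc_branch = np.empty(n_exc, dtype=int)
    exc_dist = np.empty(n_exc)
    exc_cluster = np.full(n_exc, BACKGROUND, dtype=int)
    i = 0
    for c, b in enumerate(cluster_branches):
        br = morph[int(b)]
        # clusters sit at the branch midpoint, so a cluster's somatic
        # distance is the branch's path distance
        anchor = max(0.5 * (br.length - per), 0.0)
        for j in range(per):
            exc_branch[i] = br.branch_id
            exc_dist[i] = br.proximal_distance + anchor + j * 1.0
            exc_cluster[i] = c
            i += 1
    n_bg = n_exc - n_clustered
    bg_branches = rng.integers(morph.n_branches, size=n_bg)
    for k, b in enumerate(bg_branches):
        br = morph[int(b)]
        exc_branch[i + k] = br.branch_id
        exc_dist[i + k] = br.proximal_distance + rng.uniform(0.0, br.length)

    inh_branch = np.empty(n_inh, dtype=int)
    inh_dist = np.empty(n_inh)
    peri = np.zeros(n_inh, dtype=bool)
    proximal = [b.branch_id for b in morph.branches
                if b.proximal_distance < perisomatic_threshold]
    for k in range(n_inh):
        if k < perisomatic_count:
            br = morph[int(rng.choice(proximal))]
            lo = 0.0
            hi = min(br.length, perisomatic_threshold - br.proximal_distance)
            inh_dist[k] = br.proximal_distance + rng.uniform(lo, max(hi, 1.0))
            inh_branch[k] = br.branch_id
            peri[k] = True
        else:
            br = morph[int(rng.integers(morph.n_branches))]
            inh_branch[k] = br.branch_id
            inh_dist[k] = br.proximal_distance + rng.uniform(0.0, br.length)
    subtree = np.array([b.subtree_id for b in morph.branches])
    return SynapsePlacement(exc_branch, exc_dist, exc_cluster,
                            inh_branch, inh_dist, peri, n_clusters, subtree)
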