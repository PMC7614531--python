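"""Representational similarity analysis of synaptic organizations.

Different descriptions of the same neuron — the ground-truth morphology and
its synaptic clusters on one side, a fitted cascade model's weights and
subunit assignments on the other — are compared through synaptic
dissimilarity matrices: for every pair of synapses, how differently the two
synapses are treated under that description.  Two matrices are compared by
the Pearson correlation of their strict upper-triangular entries.

Matrix kinds:

* ``subunit``  — 0 if two synapses are assigned to the same subunit, else 1
* ``weight``   — |w_l - w_l'| over excitatory synaptic weights
* ``distance`` — |d_l - d_l'| over somatic path distances
* ``cluster``  — 0 if same input cluster, else 1 (clustered synapses only)

The cluster matrix is orthogonalized against the distance matrix (projecting
out the component explained by somatic distance) before any comparison, and
comparisons that involve a cluster- or subunit-based matrix are restricted to
the clustered synapses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import SynapsePlacement, BACKGROUND

__all__ = ["DissimilarityMatrix", "subunit_dissimilarity",
           "weight_dissimilarity", "distance_dissimilarity",
           "cluster_dissimilarity", "orthogonalize", "rsa_correlation",
           "consistency_analysis"]


@dataclass
class DissimilarityMatrix:
    values: np.ndarray          # (S, S) symmetric, zero diagonal
    kind: str
    synapse_ids: np.ndarray     # ordering of rows/columns

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def restrict(self, ids) -> "DissimilarityMatrix":
        ids = np.asarray(ids)
        pos = {int(s): i for i, s in enumerate(self.synapse_ids)}
        idx = np.array([pos[int(s)] for s in ids])
        return DissimilarityMatrix(self.values[np.ix_(idx, idx)], self.kind, ids)


def _ordering(placement: SynapsePlacement) -> np.ndarray:
    """Canonical synapse order: clustered first, then by somatic distance."""
    clustered = placement.clustered_ids
    clustered = clustered[np.argsort(placement.exc_distance[clustered],
                                     kind="stable")]
    bg = np.flatnonzero(placement.exc_cluster == BACKGROUND)
    bg = bg[np.argsort(placement.exc_distance[bg], kind="stable")]
    return np.concatenate([clustered, bg])


def subunit_dissimilarity(C_syn: np.ndarray,
                          synapse_ids: np.ndarray | None = None
                          ) -> DissimilarityMatrix:
    """0/1 matrix from a binary assignment: different subunit -> 1."""
    C = np.asarray(C_syn)
    if not np.array_equal(C, C.astype(bool).astype(C.dtype)) or \
            not np.allclose(C.sum(axis=0), 1.0):
        raise ValueError("subunit dissimilarity requires a hard (one-hot) "
                         "assignment; apply hard_assignment first")
    label = C.argmax(axis=0)
    if synapse_ids is None:
        synapse_ids = np.arange(C.shape[1])
    else:
        label = label[np.asarray(synapse_ids)]
    D = (label[:, None] != label[None, :]).astype(float)
    return DissimilarityMatrix(D, "subunit", np.asarray(synapse_ids))


def weight_dissimilarity(w_syn: np.ndarray,
                         synapse_ids: np.ndarray | None = None
                         ) -> DissimilarityMatrix:
    """|w_l - w_l'| over excitatory synaptic weights."""
    w = np.asarray(w_syn, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if synapse_ids is None:
        synapse_ids = np.arange(len(w))
    else:
        w = w[np.asarray(synapse_ids)]
    D = np.abs(w[:, None] - w[None, :])
    return DissimilarityMatrix(D, "weight", np.asarray(synapse_ids))


def distance_dissimilarity(placement: SynapsePlacement,
                           synapse_ids: np.ndarray | None = None
                           ) -> DissimilarityMatrix:
    """|d_l - d_l'| over somatic path distances of excitatory synapses."""
    if synapse_ids is None:
        synapse_ids = _ordering(placement)
    d = placement.exc_distance[np.asarray(synapse_ids)]
    D = np.abs(d[:, None] - d[None, :])
    return DissimilarityMatrix(D, "distance", np.asarray(synapse_ids))


def cluster_dissimilarity(placement: SynapsePlacement,
                          synapse_ids: np.ndarray | None = None
                          ) -> DissimilarityMatrix:
    """0/1 matrix over clustered synapses: different cluster -> 1."""
    if synapse_ids is None:
        synapse_ids = _ordering(placement)
        synapse_ids = synapse_ids[np.isin(synapse_ids, placement.clustered_ids)]
    c = placement.exc_cluster[np.asarray(synapse_ids)]
    if np.any(c == BACKGROUND):
        raise ValueError("cluster dissimilarity is defined for clustered "
                         "synapses only")
    D = (c[:, None] != c[None, :]).astype(float)
    return DissimilarityMatrix(D, "cluster", np.asarray(synapse_ids))


def orthogonalize(m_clust: np.ndarray, m_dist: np.ndarray) -> np.ndarray:
    """Project the vectorized cluster matrix orthogonal to the distance one.

        M_perp = M_clust - M_dist * <M_clust, M_dist> / <M_dist, M_dist>
    """
    a = np.asarray(m_clust, dtype=float)
    b = np.asarray(m_dist, dtype=float)
    denom = np.dot(b, b)
    if denom == 0:
        raise ValueError("cannot orthogonalize against a zero matrix")
    return a - b * (np.dot(a, b) / denom)


def orthogonalized_cluster(placement: SynapsePlacement
                           ) -> DissimilarityMatrix:
    """Cluster dissimilarity with the somatic-distance component removed."""
    Dc = cluster_dissimilarity(placement)
    Dd = distance_dissimilarity(placement, Dc.synapse_ids)
    iu = np.triu_indices(Dc.n, k=1)
    vec = orthogonalize(Dc.values[iu], Dd.values[iu])
    M = np.zeros_like(Dc.values)
    M[iu] = vec
    M = M + M.T
    return DissimilarityMatrix(M, "cluster-orthogonalized", Dc.synapse_ids)


def rsa_correlation(D1: DissimilarityMatrix, D2: DissimilarityMatrix,
                    subset: np.ndarray | None = None) -> float:
    """Pearson r between strict upper-triangular entries of two matrices."""
    if subset is not None:
        D1, D2 = D1.restrict(subset), D2.restrict(subset)
    if not np.array_equal(D1.synapse_ids, D2.synapse_ids):
        raise ValueError("matrices use different synapse orderings")
    a, b = D1.upper(), D2.upper()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant matrix")
    return float(np.corrcoef(a, b)[0, 1])


def consistency_analysis(fits: dict[str, list[dict]],
                         placement: SynapsePlacement) -> list[dict]:
    """Within-/across-architecture consistency of discovered organizations.

    ``fits`` maps a target name (e.g. 'vnona', 'vna') to a list of fit
    results, each a dict with keys ``C_syn_e`` (binary assignment) and
    ``w_syn_e`` (weights), obtained on independent training data.  Returns a
    tidy list of records: within-target consistency (same target, different
    data), across-target correlation (same data index, different targets),
    and correlations against the ground-truth distance and (orthogonalized)
    cluster matrices — each for both the weight- and subunit-based
    characterizations.
    """
    order = _ordering(placement)
    clustered = order[np.isin(order, placement.clustered_ids)]
    Dd = distance_dissimilarity(placement, order)
    Dc_perp = orthogonalized_cluster(placement)

    def matrices(fit):
        return {"subunit": subunit_dissimilarity(fit["C_syn_e"], order),
                "weight": weight_dissimilarity(fit["w_syn_e"], order)}

    rows = []
    targets = list(fits)
    for tgt in targets:
        ms = [matrices(f) for f in fits[tgt]]
        for kind in ("subunit", "weight"):
            sub = clustered if kind == "subunit" else None
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    rows.append({"comparison": "within", "target": tgt,
                                 "kind": kind,
                                 "r": rsa_correlation(ms[i][kind], ms[j][kind],
                                                      sub)})
            for i, m in enumerate(ms):
                # comparisons with a subunit- or cluster-based matrix are
                # restricted to the clustered synapses; weight-vs-distance
                # uses all excitatory synapses
                rows.append({"comparison": "vs_distance", "target": tgt,
                             "kind": kind,
                             "r": rsa_correlation(m[kind], Dd, sub)})
                rows.append({"comparison": "vs_cluster", "target": tgt,
                             "kind": kind,
                             "r": rsa_correlation(m[kind], Dc_perp, clustered)})
    for i, t1 in enumerate(targets):
        for t2 in targets[i + 1:]:
            n = min(len(fits[t1]), len(fits[t2]))
            for k in range(n):
                m1, m2 = matrices(fits[t1][k]), matrices(fits[t2][k])
                for kind in ("subunit", "weight"):
                    sub = clustered if kind == "subunit" else None
                    rows.append({"comparison": "across", "target": f"{t1}/{t2}",
                                 "kind": kind,
                                 "r": rsa_correlation(m1[kind], m2[kind], sub)})
    return rows
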