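"""Morphology, synapse placement, and the ground-truth teacher: the additive
voltage decomposition, cluster-triggered spikelets, and dataset manifests."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from neurocascade import teacher as T
from neurocascade.dataset import DatasetConfig, make_dataset
from neurocascade.inputs import SpikeTrainSet
from neurocascade.morphology import (BACKGROUND, PlacementError,
                                     build_morphology, place_synapses)
from neurocascade.traces import VoltageTrace


@pytest.fixture(scope="module")
def morph():
    return build_morphology(seed=0)


@pytest.fixture(scope="module")
def placement(morph):
    return place_synapses(morph, n_clusters=4, seed=1)


def empty_spikes(n_synapses, duration=1000.0, kind="exc"):
    return SpikeTrainSet(np.empty(0, dtype=int), np.empty(0),
                         np.array([kind] * n_synapses), n_synapses, duration)


def spikes_at(events, n_synapses, duration=1000.0, kind="exc"):
    ids = np.array([e[0] for e in events], dtype=int)
    times = np.array([e[1] for e in events], dtype=float)
    return SpikeTrainSet(ids, times, np.array([kind] * n_synapses),
                         n_synapses, duration)


class TestMorphology:
    def test_default_has_five_subtrees(self, morph):
        assert sorted(set(b.subtree_id for b in morph.branches)) == [1, 2, 3, 4, 5]

    def test_single_branch_configuration(self):
        m = build_morphology(n_subtrees=1, branches_per_subtree=1, seed=3)
        assert m.n_branches == 1
        b = m.branches[0]
        assert b.path_distance_to_soma == pytest.approx(b.length / 2)

    def test_path_distances_increase_from_parent_to_child(self, morph):
        for b in morph.branches:
            assert b.path_distance_to_soma > 0
            if b.parent_id >= 0:
                parent = morph[b.parent_id]
                assert b.path_distance_to_soma > parent.path_distance_to_soma

    def test_determinism(self):
        a = build_morphology(seed=7)
        b = build_morphology(seed=7)
        assert all(x.length == y.length and x.surface_area == y.surface_area
                   for x, y in zip(a.branches, b.branches))


class TestPlacement:
    @pytest.mark.parametrize("n_clusters,per_cluster", [(4, 60), (8, 30), (12, 20)])
    def test_cluster_arrangements(self, morph, n_clusters, per_cluster):
        p = place_synapses(morph, n_clusters=n_clusters, seed=2)
        for c in range(n_clusters):
            assert len(p.cluster_members(c)) == per_cluster

    def test_default_synapse_counts(self, placement):
        assert placement.n_exc == 2000
        assert placement.n_inh == 200
        assert len(placement.clustered_ids) == 240
        assert placement.inh_perisomatic.sum() == 80

    def test_each_cluster_on_one_branch(self, placement):
        for c in range(placement.n_clusters):
            members = placement.cluster_members(c)
            assert len(set(placement.exc_branch[members])) == 1

    def test_cluster_branches_are_long_and_distinct(self, morph, placement):
        branches = [placement.cluster_branch(c)
                    for c in range(placement.n_clusters)]
        assert len(set(branches)) == placement.n_clusters
        for b in branches:
            assert morph[b].length > 60.0

    def test_too_few_eligible_branches_raises(self):
        tiny = build_morphology(n_subtrees=1, branches_per_subtree=2, seed=5)
        with pytest.raises(PlacementError):
            place_synapses(tiny, n_clusters=12, seed=0)

    def test_perisomatic_inhibition_is_proximal(self, placement):
        assert np.all(placement.inh_distance[placement.inh_perisomatic] < 50.0)


class TestVnona:
    def test_empty_input_gives_zero_baseline(self, morph, placement):
        prm = T.TeacherParams()
        v = T.teacher_vnona(empty_spikes(2000), empty_spikes(200, kind="inh"),
                            placement, prm)
        assert np.allclose(v.values, 0.0)

    def test_single_spike_matches_closed_form(self, morph, placement):
        prm = T.TeacherParams()
        w_e, _ = T.synaptic_weights(placement, prm)
        sid = 100
        exc = spikes_at([(sid, 50.0)], 2000)
        v = T.teacher_vnona(exc, empty_spikes(200, kind="inh"), placement, prm)
        k = T.double_exp_kernel(prm.slow_rise_ms, prm.slow_decay_ms, 1.0)
        expected = np.zeros(1000)
        expected[50:50 + len(k)] = w_e[sid] * k[:950]
        c = prm.sat_ceiling_mv
        assert np.allclose(v.values, c * np.tanh(expected / c), atol=1e-12)
        assert v.values.argmax() == 50 + k.argmax()

    def test_doubling_input_sublinear(self, morph, placement, rng):
        prm = T.TeacherParams()
        ids = rng.integers(0, 2000, 300)
        times = rng.uniform(0, 900, 300)
        exc1 = spikes_at(list(zip(ids, times)), 2000)
        exc2 = spikes_at(list(zip(ids, times)) * 2, 2000)
        inh = empty_spikes(200, kind="inh")
        v1 = T.teacher_vnona(exc1, inh, placement, prm).values
        v2 = T.teacher_vnona(exc2, inh, placement, prm).values
        assert np.all(np.abs(v2) <= 2 * np.abs(v1) + 1e-12)

    def test_background_weights_decay_with_distance(self, placement):
        prm = T.TeacherParams()
        w_e, _ = T.synaptic_weights(placement, prm)
        bg = placement.exc_cluster == BACKGROUND
        r = np.corrcoef(placement.exc_distance[bg], w_e[bg])[0, 1]
        assert r < -0.8
        clustered = ~bg
        assert np.allclose(w_e[clustered], w_e[clustered][0])


class TestVna:
    def test_silent_clusters_give_zero(self, morph, placement):
        prm = T.TeacherParams()
        v, locals_, events = T.teacher_vna(empty_spikes(2000), placement,
                                           morph, prm)
        assert np.allclose(v.values, 0.0)
        assert all(len(e) == 0 for e in events.values())

    def test_synchronous_volley_emits_one_spikelet(self, morph, placement):
        prm = T.TeacherParams()
        members = placement.cluster_members(0)
        exc = spikes_at([(m, 100.0) for m in members], 2000)
        v, _, events = T.teacher_vna(exc, placement, morph, prm)
        assert len(events[0]) == 1
        assert all(len(events[c]) == 0 for c in range(1, 4))
        assert v.values.max() > 0

    def test_threshold_monotone_in_branch_area(self, morph, placement):
        prm = T.TeacherParams()
        areas = {c: morph[placement.cluster_branch(c)].surface_area
                 for c in range(placement.n_clusters)}
        mean_area = np.mean([b.surface_area for b in morph.branches])
        thetas = {c: prm.threshold_base
                  * (1 + prm.threshold_area_slope * (a / mean_area - 1))
                  for c, a in areas.items()}
        lo = min(thetas, key=thetas.get)
        hi = max(thetas, key=thetas.get)
        assert areas[lo] < areas[hi]
        # a drive between the two thresholds triggers only the low cluster:
        # activate the same fraction of members in both clusters
        frac = 0.5 * (thetas[lo] + thetas[hi]) / 1.0
        n_lo = len(placement.cluster_members(lo))
        n_hi = len(placement.cluster_members(hi))
        k_lo = int(np.ceil(frac * n_lo)) + 1
        k_hi = int(np.ceil(frac * n_hi)) + 1
        events_both = []
        for c, k in ((lo, k_lo), (hi, k_hi)):
            members = placement.cluster_members(c)[:k]
            exc = spikes_at([(m, 100.0) for m in members], 2000)
            _, _, ev = T.teacher_vna(exc, placement, morph, prm)
            events_both.append({cc: len(t) for cc, t in ev.items()})
        # same synchronous fraction: low-threshold cluster fires iff the
        # fraction lies between the thresholds
        if thetas[lo] < frac < thetas[hi]:
            assert events_both[0][lo] >= 1
            assert events_both[1][hi] == 0

    def test_spikelet_refractory_enforced(self, morph, placement):
        prm = T.TeacherParams()
        members = placement.cluster_members(0)
        events = [(m, t) for m in members for t in (100.0, 103.0, 106.0)]
        exc = spikes_at(events, 2000)
        _, _, ev = T.teacher_vna(exc, placement, morph, prm)
        assert np.all(np.diff(ev[0]) >= prm.spikelet_refractory_ms)


class TestComposition:
    def test_eq1_identities(self):
        a = VoltageTrace(np.sin(np.arange(100) / 7.0), 1.0, "v_noNa")
        b = VoltageTrace(np.cos(np.arange(100) / 3.0) * 0.2, 1.0, "v_Na")
        s = T.compose_vsoma(a, b)
        assert s.component == "v_soma"
        assert np.array_equal(s.values, a.values + b.values)
        assert np.array_equal(T.compose_vsoma(b, a).values, s.values)
        # the difference convention: v_Na := v_soma - v_noNa recomposes exactly
        diff = VoltageTrace(s.values - a.values, 1.0, "v_Na")
        assert np.array_equal(T.compose_vsoma(a, diff).values, s.values)

    def test_zero_na_component(self):
        a = VoltageTrace(np.sin(np.arange(50)), 1.0, "v_noNa")
        z = VoltageTrace(np.zeros(50), 1.0, "v_Na")
        assert np.array_equal(T.compose_vsoma(a, z).values, a.values)

    def test_mismatched_grids_rejected(self):
        a = VoltageTrace(np.zeros(50), 1.0)
        b = VoltageTrace(np.zeros(60), 1.0)
        with pytest.raises(ValueError):
            T.compose_vsoma(a, b)


class TestTeacherSpikes:
    def test_subthreshold_trace_gives_no_spikes(self):
        prm = T.TeacherParams()
        v = VoltageTrace(np.full(1000, prm.ap_threshold_mv - 1.0), 1.0)
        times, vap = T.teacher_spikes(v, prm)
        assert len(times) == 0
        assert np.allclose(vap.values, 0.0)

    def test_three_isolated_bumps_give_three_spikes(self):
        prm = T.TeacherParams()
        x = np.zeros(1000)
        for c in (100, 400, 700):
            x[c:c + 20] = prm.ap_threshold_mv + 2.0
        times, _ = T.teacher_spikes(VoltageTrace(x, 1.0), prm)
        assert len(times) == 3
        assert np.allclose(times, [100, 400, 700], atol=1.0)

    def test_refractory_lower_bounds_isis(self):
        prm = T.TeacherParams()
        x = 10.0 * np.sin(np.arange(20000) / 2.0) ** 2
        times, _ = T.teacher_spikes(VoltageTrace(x, 1.0), prm)
        assert len(times) > 100
        assert np.all(np.diff(times) >= prm.ap_refractory_ms)


class TestDataset:
    def test_eq1_bitexact_and_variance_regime(self, fixture_dataset):
        for tr in fixture_dataset.trials:
            assert np.array_equal(tr.v_soma.values,
                                  tr.v_nona.values + tr.v_na.values)

    def test_manifest_allows_bitexact_rebuild(self, fixture_dataset):
        from neurocascade.pipeline import make_fixtures
        rebuilt = make_fixtures(seed=0)
        for a, b in zip(fixture_dataset.trials, rebuilt.trials):
            assert np.array_equal(a.exc_spikes.times_ms, b.exc_spikes.times_ms)
            assert np.array_equal(a.v_soma.values, b.v_soma.values)
        assert fixture_dataset.manifest == rebuilt.manifest

    def test_train_test_seeds_disjoint(self, fixture_dataset):
        seeds = fixture_dataset.manifest["trial_seeds"]
        assert len(set(seeds)) == len(seeds)

    def test_vnona_dominates_vsoma_variance(self):
        cfg = DatasetConfig(n_exc=300, n_inh=40, n_clusters=4, n_clustered=48,
                            n_train=1, n_test=0, branches_per_subtree=3)
        ds = make_dataset(cfg, seed=5)
        tr = ds.train[0]
        vs = tr.v_soma.values.var()
        assert tr.v_nona.values.var() / vs > 0.9
        assert tr.v_na.values.var() / vs < 0.1

    def test_spikelet_rate_increases_with_cluster_synchrony(self):
        """Temporally jittering assembly events lowers synchrony, hence the
        cluster drive's peaks, hence the spikelet rate (fixed thresholds)."""
        from neurocascade.dataset import make_assembly_dataset
        jitters = (1.0, 4.0, 8.0, 16.0, 32.0)
        counts = []
        for j in jitters:
            prm = T.TeacherParams(threshold_base=0.5, local_bg_weight=0.0)
            _, _, _, trials = make_assembly_dataset(n_trials=4, seed=5,
                                                    jitter_ms=j, teacher=prm)
            counts.append(sum(sum(len(v) for v in t.spikelet_times.values())
                              for t in trials))
        rho = spearmanr(jitters, counts).statistic
        assert rho < -0.5  # less synchrony -> fewer spikelets
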