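import numpy as np
import pytest

from braintce.connectome_io import Connectome, normalize_adjacency
from braintce.state_modeling import DISCARDED, DominanceSequence, StateMaps
from braintce.tce_pipeline import (
    hierarchy_summary,
    occurrence_weighted_map,
    tce,
    transition_energy_matrix,
)
from conftest import random_symmetric


def make_states(maps, names, occupancy=None, total=None):
    maps = np.asarray(maps, dtype=float)
    occ = np.asarray(occupancy if occupancy is not None else [1] * len(names))
    return StateMaps(
        maps=maps,
        state_names=list(names),
        occupancy=occ,
        total_timepoints=total if total is not None else int(occ.sum()),
        region_ids=[f"r{i}" for i in range(maps.shape[1])],
    )


def make_seq(labels, run_boundaries=None):
    return DominanceSequence(
        labels=list(labels),
        threshold=0.5,
        winning_means=np.zeros(len(labels)),
        run_boundaries=run_boundaries or [0],
    )


@pytest.fixture(scope="module")
def two_state_setup():
    rng = np.random.default_rng(3)
    n = 6
    W = random_symmetric(n, rng)
    system = normalize_adjacency(Connectome(weights=W, region_ids=[f"r{i}" for i in range(n)]))
    states = make_states(rng.standard_normal((2, n)), ["VIS", "DMN"])
    te = transition_energy_matrix(states, system, n_steps=300)
    return system, states, te


class TestTransitionEnergyMatrix:
    def test_seven_states_give_49_maps(self):
        rng = np.random.default_rng(5)
        n = 14
        system = normalize_adjacency(
            Connectome(weights=random_symmetric(n, rng), region_ids=[f"r{i}" for i in range(n)])
        )
        names = ["VIS", "SMN", "DAN", "SAL", "LIM", "FPN", "DMN"]
        states = make_states(rng.standard_normal((7, n)), names)
        te = transition_energy_matrix(states, system, n_steps=200)
        assert te.node_tensor.shape == (7, 7, n)
        assert te.totals.shape == (7, 7)

    def test_identical_states_identical_totals(self):
        rng = np.random.default_rng(8)
        n = 4
        system = normalize_adjacency(
            Connectome(weights=random_symmetric(n, rng), region_ids=[f"r{i}" for i in range(n)])
        )
        one_map = rng.standard_normal(n)
        states = make_states([one_map, one_map, one_map], ["VIS", "SMN", "DMN"])
        te = transition_energy_matrix(states, system, n_steps=200)
        np.testing.assert_allclose(te.totals, te.totals[0, 0], rtol=1e-10)

    def test_totals_generically_asymmetric(self, two_state_setup):
        _, _, te = two_state_setup
        assert abs(te.totals[0, 1] - te.totals[1, 0]) > 1e-6

    def test_totals_marginal_of_tensor(self, two_state_setup):
        _, _, te = two_state_setup
        assert np.all(te.node_tensor >= 0)
        np.testing.assert_allclose(te.totals, te.node_tensor.sum(axis=2), rtol=1e-12)


class TestTCE:
    def test_single_transition(self, two_state_setup):
        _, _, te = two_state_setup
        result = tce(make_seq(["VIS", "DMN"]), te)
        np.testing.assert_allclose(result.values, te.slice("VIS", "DMN"))
        assert result.transition_count == 1

    def test_constant_sequence_counts_self_transitions(self, two_state_setup):
        _, _, te = two_state_setup
        result = tce(make_seq(["VIS"] * 4), te)
        np.testing.assert_allclose(result.values, te.slice("VIS", "VIS"))
        assert result.transition_count == 3

    def test_duplicating_transitions_leaves_tce_unchanged(self, two_state_setup):
        _, _, te = two_state_setup
        labels = ["VIS", "DMN", "DMN", "VIS"]
        base = tce(make_seq(labels), te)
        # same transition multiset twice, in two runs so no bridge pair appears
        doubled = tce(make_seq(labels + labels, run_boundaries=[0, 4]), te)
        np.testing.assert_allclose(doubled.values, base.values, rtol=0, atol=0)
        assert doubled.transition_count == 2 * base.transition_count

    def test_matches_brute_force_accumulation(self, two_state_setup):
        _, _, te = two_state_setup
        rng = np.random.default_rng(0)
        labels = [["VIS", "DMN", DISCARDED][i] for i in rng.integers(0, 3, size=40)]
        labels[0] = "VIS"  # ensure at least one retained pair exists
        labels[1] = "DMN"
        result = tce(make_seq(labels), te)
        kept = [lab for lab in labels if lab != DISCARDED]
        acc = np.zeros(te.node_tensor.shape[2])
        for a, b in zip(kept[:-1], kept[1:]):
            acc += te.slice(a, b)
        np.testing.assert_allclose(result.values, acc / (len(kept) - 1), rtol=1e-12)
        assert result.transition_count == len(kept) - 1

    def test_empty_sequence_rejected(self, two_state_setup):
        _, _, te = two_state_setup
        with pytest.raises(ValueError, match="P = 0"):
            tce(make_seq([DISCARDED, "VIS"]), te)

    def test_mean_tce_within_totals_envelope(self, two_state_setup):
        _, _, te = two_state_setup
        n = te.node_tensor.shape[2]
        result = tce(make_seq(["VIS", "DMN", "VIS", "VIS", "DMN"]), te)
        assert te.totals.min() / n - 1e-12 <= result.values.mean() <= te.totals.max() / n + 1e-12

    def test_permutation_equivariance_of_tce(self):
        rng = np.random.default_rng(21)
        n = 5
        W = random_symmetric(n, rng)
        maps = rng.standard_normal((2, n))
        perm = rng.permutation(n)
        P = np.eye(n)[perm]
        ids = [f"r{i}" for i in range(n)]
        sys_a = normalize_adjacency(Connectome(weights=W, region_ids=ids))
        sys_b = normalize_adjacency(Connectome(weights=P @ W @ P.T, region_ids=ids))
        te_a = transition_energy_matrix(make_states(maps, ["VIS", "DMN"]), sys_a, n_steps=200)
        te_b = transition_energy_matrix(
            make_states(maps @ P.T, ["VIS", "DMN"]), sys_b, n_steps=200
        )
        seq = make_seq(["VIS", "DMN", "VIS"])
        np.testing.assert_allclose(tce(seq, te_b).values, P @ tce(seq, te_a).values, rtol=1e-8)


class TestHierarchySummary:
    def test_within_unimodal_only(self, two_state_setup):
        _, _, te = two_state_setup
        # te states are VIS (U) and DMN (H); single-class sequence
        summary = hierarchy_summary(make_seq(["VIS", "VIS", "VIS"]), te)
        assert summary.counts.loc["U", "U"] == 2
        assert summary.counts.to_numpy().sum() == 2
        assert summary.within_fraction == 1.0

    def test_alternating_hand_count(self, two_state_setup):
        _, _, te = two_state_setup
        summary = hierarchy_summary(make_seq(["VIS", "DMN", "VIS", "DMN"]), te)
        assert summary.counts.loc["U", "H"] == 2
        assert summary.counts.loc["H", "U"] == 1
        assert summary.within_fraction == 0.0
        assert summary.transition_count == 3

    def test_unmapped_network_rejected(self, two_state_setup):
        _, _, te = two_state_setup
        with pytest.raises(ValueError, match="without hierarchy"):
            hierarchy_summary(make_seq(["VIS", "DMN"]), te, hierarchy={"VIS": "U"})

    def test_matches_generator_ledger(self, synth_dataset):
        from braintce.state_modeling import dominance_sequence, network_average, standardize, state_maps
        from braintce.tce_pipeline import transition_energy_matrix

        spec, conn, raw, ledger = synth_dataset
        rec = standardize(raw, region_ids=spec.region_ids)
        series = network_average(rec, dict(zip(spec.region_ids, spec.network_of_region)))
        seq = dominance_sequence(series, 0.5)
        states = state_maps(rec, seq)
        system = normalize_adjacency(conn)
        te = transition_energy_matrix(states, system, n_steps=200)
        summary = hierarchy_summary(seq, te, hierarchy=spec.hierarchy_of_network)
        for (a, b), count in ledger["class_counts"].items():
            assert summary.counts.loc[a, b] == count

    def test_between_class_energy_exceeds_within_on_separated_fixture(self):
        # U templates close to each other, H templates close to each other,
        # U and H far apart: crossing the gap must cost more control energy
        rng = np.random.default_rng(9)
        n = 8
        system = normalize_adjacency(
            Connectome(weights=random_symmetric(n, rng), region_ids=[f"r{i}" for i in range(n)])
        )
        base_u = np.concatenate([np.ones(4), -np.ones(4)])
        base_h = -base_u
        eps = 0.05 * rng.standard_normal((4, n))
        maps = np.vstack([base_u + eps[0], base_u + eps[1], base_h + eps[2], base_h + eps[3]])
        states = make_states(maps, ["VIS", "SMN", "FPN", "DMN"])
        te = transition_energy_matrix(states, system, n_steps=200)
        seq = make_seq(["VIS", "SMN", "FPN", "DMN", "VIS"])
        summary = hierarchy_summary(seq, te)
        within = np.nanmean([summary.mean_energy.loc["U", "U"], summary.mean_energy.loc["H", "H"]])
        between = np.nanmean([summary.mean_energy.loc["U", "H"], summary.mean_energy.loc["H", "U"]])
        assert between > within


class TestOccurrenceWeightedMap:
    def test_single_dominating_state(self):
        maps = np.array([[1.0, -1.0, 0.5]])
        states = make_states(maps, ["VIS"], occupancy=[5], total=5)
        out = occurrence_weighted_map(make_seq(["VIS"] * 5), states)
        np.testing.assert_allclose(out, maps[0])

    def test_two_thirds_split(self):
        maps = np.array([[3.0, 0.0], [0.0, 3.0]])
        states = make_states(maps, ["VIS", "DMN"], occupancy=[2, 2], total=6)
        labels = ["VIS", "VIS", "DMN", "DMN", DISCARDED, DISCARDED]
        out = occurrence_weighted_map(make_seq(labels), states)
        np.testing.assert_allclose(out, (maps[0] + maps[1]) / 3.0)

    def test_all_discarded_gives_zero(self):
        states = make_states(np.ones((1, 3)), ["VIS"], occupancy=[1], total=4)
        out = occurrence_weighted_map(make_seq([DISCARDED] * 4), states)
        np.testing.assert_allclose(out, 0.0)

    def test_retained_denominator_flag(self):
        maps = np.array([[2.0, 2.0]])
        states = make_states(maps, ["VIS"], occupancy=[2], total=4)
        labels = ["VIS", "VIS", DISCARDED, DISCARDED]
        total = occurrence_weighted_map(make_seq(labels), states, denominator="total")
        retained = occurrence_weighted_map(make_seq(labels), states, denominator="retained")
        np.testing.assert_allclose(total, maps[0] / 2.0)
        np.testing.assert_allclose(retained, maps[0])
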