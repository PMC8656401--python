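"""Basin frequencies, transition/staying rates, traveling and lingering scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from statescape import (
    BinaryStateSeries,
    assign_to_basins,
    basin_frequency,
    cohort_dynamics,
    pair_count_conservation,
    transition_and_staying_rates,
)

from conftest import random_landscape


def series(states, n=3, boundaries=()):
    return BinaryStateSeries(
        states=np.array(states), n=n, segment_boundaries=tuple(boundaries)
    )


class TestBasinFrequency:
    def test_fraction_of_assigned_timepoints(self, two_cluster_partition):
        # states 1,2 sit in basin 0's cluster; 5 in basin 7's
        s = series([1, 2, 5, 1])
        f = basin_frequency(s, two_cluster_partition)
        assert f == {0: pytest.approx(0.75), 7: pytest.approx(0.25)}

    def test_frequencies_sum_to_one(self, two_cluster_partition):
        rng = np.random.default_rng(0)
        s = series(rng.integers(0, 8, size=100))
        f = basin_frequency(s, two_cluster_partition)
        assert sum(f.values()) == pytest.approx(1.0)

    def test_exact_mode_counts_basin_state_visits_only(self, two_cluster_partition):
        s = series([0, 1, 7, 7])
        f = basin_frequency(s, two_cluster_partition, count="exact")
        assert f == {0: pytest.approx(0.25), 7: pytest.approx(0.5)}

    def test_long_series_matches_boltzmann_cluster_mass(self, planted6):
        from statescape import boltzmann_distribution, sample_states

        table = boltzmann_distribution(planted6)
        part = assign_to_basins(table)
        s = sample_states(planted6, 40_000, seed=42)
        f = basin_frequency(s, part)
        for b in part.major:
            mass = table.probabilities[part.cluster(b)].sum()
            sd = np.sqrt(mass * (1 - mass) / s.T)
            assert abs(f[b] - mass) < 3 * sd + 1e-9


class TestRates:
    def test_worked_six_point_trace(self, two_cluster_partition):
        # [A1, A1, p1, A2, A2, p2] with p1 in P1\{A1}, p2 in P2\{A2}
        m = transition_and_staying_rates(series([0, 0, 1, 7, 7, 6]), two_cluster_partition)
        assert m.sr_major == pytest.approx(2 / 6)
        assert m.sr_peripheral == pytest.approx(2 / 6)
        assert m.lingering == pytest.approx(2 / 3)
        assert m.tr_peripheral == pytest.approx(1 / 6)
        assert m.tr_major == 0.0
        assert m.traveling == 0.0

    def test_constant_series_at_major_basin(self, two_cluster_partition):
        T = 10
        m = transition_and_staying_rates(series([0] * T), two_cluster_partition)
        assert m.sr_major == pytest.approx((T - 1) / T)
        assert m.tr_major == m.tr_peripheral == m.sr_peripheral == 0.0
        assert m.lingering == pytest.approx((T - 1) / T)
        assert m.traveling is None  # undefined, not zero

    def test_alternating_major_basins(self, two_cluster_partition):
        m = transition_and_staying_rates(series([0, 7, 0, 7]), two_cluster_partition)
        assert m.tr_major == pytest.approx(3 / 4)
        assert m.tr_peripheral == pytest.approx(3 / 4)
        assert m.traveling == pytest.approx(1.0)
        assert m.lingering == 0.0

    def test_boundary_pairs_excluded(self, two_cluster_partition):
        # same trace split across two participants at t=3: (p1 -> A2) vanishes
        m = transition_and_staying_rates(
            series([0, 0, 1, 7, 7, 6], boundaries=(3,)), two_cluster_partition
        )
        assert m.tr_peripheral == 0.0
        assert m.sr_major == pytest.approx(2 / 6)

    def test_major_rate_never_exceeds_peripheral_rate_direct(
        self, two_cluster_partition
    ):
        rng = np.random.default_rng(1)
        for _ in range(30):
            s = series(rng.integers(0, 8, size=60))
            m = transition_and_staying_rates(s, two_cluster_partition)
            assert m.tr_major <= m.tr_peripheral + 1e-15

    def test_requires_two_major_basins(self):
        from statescape import BasinPartition

        single = BasinPartition(
            basin_codes=[0],
            assignment=np.zeros(8, dtype=np.int64),
            energies=np.array([-1.0]),
            n=3,
            major=[0],
        )
        with pytest.raises(ValueError):
            transition_and_staying_rates(series([0, 1, 0]), single)

    def test_first_passage_counts_episodes_through_periphery(
        self, two_cluster_partition
    ):
        # A1 ... A2 with peripheral excursion between: no direct A1->A2 pair,
        # but one first-passage episode
        s = series([0, 1, 2, 7])
        direct = transition_and_staying_rates(s, two_cluster_partition, mode="direct")
        fp = transition_and_staying_rates(s, two_cluster_partition, mode="first_passage")
        assert direct.tr_major == 0.0
        assert fp.tr_major == pytest.approx(1 / 4)
        # staying rates are direct pair counts in both modes
        assert fp.sr_major == direct.sr_major
        assert fp.sr_peripheral == direct.sr_peripheral


class TestConservation:
    @given(data=hst.data())
    @settings(max_examples=40, deadline=None)
    def test_pair_categories_partition_all_valid_pairs(self, data):
        rng = np.random.default_rng(data.draw(hst.integers(0, 10_000)))
        t = random_landscape(rng, n=4)
        part = assign_to_basins(t)
        if len(part.basin_codes) < 2:
            return
        T = data.draw(hst.integers(5, 80))
        states = rng.integers(0, 16, size=T)
        n_b = data.draw(hst.integers(0, max(T // 10, 1)))
        boundaries = sorted(rng.choice(np.arange(1, T), size=n_b, replace=False))
        s = BinaryStateSeries(states=states, n=4, segment_boundaries=tuple(boundaries))
        parts = pair_count_conservation(s, part)
        total = (
            parts["sr_major"]
            + parts["sr_peripheral"]
            + parts["tr_peripheral"]
            + parts["minor_cross"]
            + parts["within_minor"]
        )
        assert total == pytest.approx((T - 1 - len(boundaries)) / T)
        assert parts["total"] == pytest.approx((T - 1 - len(boundaries)) / T)

    def test_rates_match_conservation_components(self, two_cluster_partition):
        rng = np.random.default_rng(2)
        s = series(rng.integers(0, 8, size=50))
        m = transition_and_staying_rates(s, two_cluster_partition)
        c = pair_count_conservation(s, two_cluster_partition)
        assert m.sr_major == pytest.approx(c["sr_major"])
        assert m.sr_peripheral == pytest.approx(c["sr_peripheral"])
        assert m.tr_peripheral == pytest.approx(c["tr_peripheral"])


class TestCohort:
    def test_one_row_per_participant(self, two_cluster_partition):
        rng = np.random.default_rng(3)
        cohort = [
            BinaryStateSeries(
                states=rng.integers(0, 8, size=30), n=3, origin=f"sub-{i}"
            )
            for i in range(7)
        ]
        df = cohort_dynamics(cohort, two_cluster_partition)
        assert len(df) == 7
        assert set(df["participant_id"]) == {f"sub-{i}" for i in range(7)}

    def test_metrics_independent_of_cohort_order(self, two_cluster_partition):
        rng = np.random.default_rng(4)
        cohort = [
            BinaryStateSeries(
                states=rng.integers(0, 8, size=30), n=3, origin=f"sub-{i}"
            )
            for i in range(5)
        ]
        a = cohort_dynamics(cohort, two_cluster_partition)
        b = cohort_dynamics(cohort[::-1], two_cluster_partition)
        merged = a.set_index("participant_id").sort_index()
        merged_b = b.set_index("participant_id").sort_index()
        assert np.allclose(
            merged["lingering"].to_numpy(), merged_b["lingering"].to_numpy()
        )

    def test_higher_coupling_group_lingers_more(self):
        # slower-mixing (stronger-coupling) dynamics linger longer
        from statescape import (
            PlantedLandscapeSpec,
            boltzmann_distribution,
            make_planted_model,
            sample_states,
        )
        from scipy import stats as sps

        pattern = (1, 1, 0, 0)
        m_lo = make_planted_model(PlantedLandscapeSpec(4, pattern, 1.2))
        m_hi = make_planted_model(PlantedLandscapeSpec(4, pattern, 1.6))
        scores = {}
        root = np.random.SeedSequence(99)
        for name, model, ss in zip(
            ("lo", "hi"), (m_lo, m_hi), root.spawn(2)
        ):
            part = assign_to_basins(boltzmann_distribution(model))
            vals = [
                transition_and_staying_rates(
                    sample_states(model, 150, sampler="metropolis", seed=s2),
                    part,
                ).lingering
                for s2 in ss.spawn(15)
            ]
            scores[name] = vals
        t, p = sps.ttest_ind(scores["hi"], scores["lo"], alternative="greater")
        assert p < 0.05
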