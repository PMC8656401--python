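"""Basin search, steepest-descent clustering, saddles, dendrogram, profile."""

import numpy as np
import pytest

from statescape import (
    EnergyTable,
    assign_to_basins,
    build_dendrogram,
    classify_major_minor,
    find_basins,
    landscape_profile,
    saddle_energies,
)
from statescape.preprocess import encode_state

from conftest import random_landscape


def descent_oracle(energies: np.ndarray, n: int) -> np.ndarray:
    """Brute-force steepest descent with memoization, as an independent check."""
    memo: dict[int, int] = {}

    def descend(code: int) -> int:
        if code in memo:
            return memo[code]
        e = energies[code]
        best, best_key = code, (e, code)
        for i in range(n):
            nb = code ^ (1 << i)
            if (energies[nb], nb) < best_key:
                best, best_key = nb, (energies[nb], nb)
        memo[code] = code if best == code else descend(best)
        return memo[code]

    return np.array([descend(c) for c in range(2**n)])


class TestFindBasins:
    def test_worked_n2_example(self, two_roi_landscape):
        assert find_basins(two_roi_landscape) == [0, 3]

    def test_flat_landscape_single_basin_lowest_code(self):
        t = EnergyTable(energies=np.zeros(8), kind="model", n=3)
        assert find_basins(t) == [0]

    def test_planted_model_basins_are_pattern_and_complement(self, planted6):
        from statescape import boltzmann_distribution

        t = boltzmann_distribution(planted6)
        basins = find_basins(t)
        pattern_code = encode_state((1, 1, 1, 0, 0, 0))
        assert pattern_code in basins
        assert pattern_code ^ 63 in basins

    def test_rejects_empirical_tables(self):
        t = EnergyTable(energies=np.array([0.0, 1.0]), kind="empirical", n=1)
        with pytest.raises(ValueError):
            find_basins(t)

    def test_at_least_one_basin_on_random_landscapes(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert len(find_basins(random_landscape(rng))) >= 1


class TestAssignment:
    def test_worked_n2_sizes(self, two_roi_landscape):
        part = assign_to_basins(two_roi_landscape)
        assert part.sizes == {0: 3, 3: 1}
        assert part.assignment.tolist() == [0, 0, 0, 3]

    def test_basin_maps_to_itself(self, two_roi_landscape):
        part = assign_to_basins(two_roi_landscape)
        for b in part.basin_codes:
            assert part.assignment[b] == b

    def test_matches_descent_oracle_on_random_landscapes(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            t = random_landscape(rng)
            part = assign_to_basins(t)
            assert np.array_equal(part.assignment, descent_oracle(t.energies, 4))

    def test_fraction_sizes_sum_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            part = assign_to_basins(random_landscape(rng))
            assert sum(part.fractions.values()) == pytest.approx(1.0)

    def test_fixed_points_equal_local_minima(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t = random_landscape(rng)
            assert set(assign_to_basins(t).basin_codes) == set(find_basins(t))


class TestMajorMinor:
    def test_two_lowest_energy_basins_are_major(self, two_roi_landscape):
        part = assign_to_basins(two_roi_landscape)
        assert part.major == [0, 3]

    def test_three_basin_ordering(self):
        # direct construction: energies (-5, -4, -1) -> first two are major
        from statescape import BasinPartition

        p = BasinPartition(
            basin_codes=[4, 9, 2],
            assignment=np.full(16, 4),
            energies=np.array([-5.0, -4.0, -1.0]),
            n=4,
        )
        assert classify_major_minor(p).major == [4, 9]
        assert p.minor == [2]

    def test_energy_tie_broken_by_lower_code(self):
        # two states tied at second-lowest energy: lower code wins
        e = np.array([-1.0, 2.0, 2.0, -0.5, 2.0, 3.0, -0.5, 2.5])
        t = EnergyTable(energies=e, kind="model", n=3)
        part = assign_to_basins(t)
        assert part.basin_codes[0] == 0
        assert part.major[1] == 3  # codes 3 and 6 tied at -0.5


class TestSaddles:
    def test_worked_n2_saddle_and_barriers(self, two_roi_landscape):
        s = saddle_energies(two_roi_landscape, [0, 3])
        assert s.saddle[0, 1] == pytest.approx(0.5)
        assert s.barrier[0, 1] == pytest.approx(1.5)   # out of E=-1 basin
        assert s.barrier[1, 0] == pytest.approx(1.3)   # out of E=-0.8 basin

    def test_self_saddle_is_basin_energy(self, two_roi_landscape):
        s = saddle_energies(two_roi_landscape, [0, 3])
        assert s.saddle[0, 0] == pytest.approx(-1.0)
        assert s.saddle[1, 1] == pytest.approx(-0.8)

    def test_matches_brute_force_minimax(self):
        nx = pytest.importorskip("networkx")
        G = nx.hypercube_graph(4)
        G = nx.relabel_nodes(
            G, {node: sum(b << i for i, b in enumerate(node)) for node in G.nodes}
        )
        rng = np.random.default_rng(4)
        for _ in range(5):
            t = random_landscape(rng)
            basins = find_basins(t)
            if len(basins) < 2:
                continue
            s = saddle_energies(t, basins)
            a, b = basins[0], basins[1]
            brute = min(
                max(t.energies[v] for v in path)
                for path in nx.all_simple_paths(G, a, b)
            )
            assert s.saddle[0, 1] == pytest.approx(brute)

    def test_saddle_dominates_both_basin_energies(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            t = random_landscape(rng)
            basins = find_basins(t)
            if len(basins) < 2:
                continue
            s = saddle_energies(t, basins)
            e = s.basin_energies
            assert (s.saddle >= np.maximum.outer(e, e) - 1e-12).all()

    def test_ultrametric_like_inequality(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            t = random_landscape(rng)
            basins = find_basins(t)
            m = len(basins)
            if m < 3:
                continue
            s = saddle_energies(t, basins).saddle
            for i in range(m):
                for j in range(m):
                    for k in range(m):
                        assert s[i, k] <= max(s[i, j], s[j, k]) + 1e-12

    def test_single_basin_warns(self):
        t = EnergyTable(energies=np.array([-1.0, 0.0, 0.0, 1.0]), kind="model", n=2)
        with pytest.warns(UserWarning):
            saddle_energies(t, [0])

    def test_barrier_asymmetry_equals_depth_difference(self, two_roi_landscape):
        s = saddle_energies(two_roi_landscape, [0, 3])
        # barrier(a->b) - barrier(b->a) = E(b) - E(a)
        assert s.barrier[0, 1] - s.barrier[1, 0] == pytest.approx(
            s.basin_energies[1] - s.basin_energies[0]
        )


class TestDendrogram:
    def test_two_basins_root_at_saddle(self, two_roi_landscape):
        s = saddle_energies(two_roi_landscape, [0, 3])
        root = build_dendrogram(s)
        assert root.merge_energy == pytest.approx(0.5)
        assert sorted(root.leaves()) == [0, 3]

    def test_three_basin_hand_agglomeration(self):
        from statescape.landscape import SaddleMatrix

        saddle = np.array(
            [[-3.0, 1.0, 2.0], [1.0, -2.5, 2.0], [2.0, 2.0, -2.0]]
        )
        s = SaddleMatrix(
            basin_codes=[1, 2, 4],
            saddle=saddle,
            basin_energies=np.array([-3.0, -2.5, -2.0]),
        )
        root = build_dendrogram(s)
        assert root.merge_energy == pytest.approx(2.0)
        sub = [c for c in root.children if not c.is_leaf][0]
        assert sub.merge_energy == pytest.approx(1.0)
        assert sorted(sub.leaves()) == [1, 2]

    def test_leaf_count_equals_basin_count_random(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = random_landscape(rng)
            basins = find_basins(t)
            if len(basins) < 2:
                continue
            root = build_dendrogram(saddle_energies(t, basins))
            assert sorted(root.leaves()) == sorted(basins)

    def test_merge_energies_nondecreasing_to_root(self):
        rng = np.random.default_rng(8)

        def check(node):
            if node.is_leaf:
                return
            for c in node.children:
                assert node.merge_energy >= c.merge_energy - 1e-12
                check(c)

        for _ in range(10):
            t = random_landscape(rng)
            basins = find_basins(t)
            if len(basins) < 2:
                continue
            check(build_dendrogram(saddle_energies(t, basins)))

    def test_newick_export_round_structure(self, two_roi_landscape):
        s = saddle_energies(two_roi_landscape, [0, 3])
        nwk = build_dendrogram(s).to_newick()
        assert nwk.endswith(";")
        assert "S0" in nwk and "S3" in nwk
        # branch lengths: 0.5 - (-1) = 1.5 and 0.5 - (-0.8) = 1.3
        assert "1.5" in nwk and "1.3" in nwk


class TestProfile:
    def test_radius_zero_is_basin_energy(self, two_roi_landscape):
        part = assign_to_basins(two_roi_landscape)
        prof = landscape_profile(two_roi_landscape, part, 0)
        assert prof[0] == (0, pytest.approx(-1.0))

    def test_depth_rises_from_center_to_radius_one(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            t = random_landscape(rng)
            part = assign_to_basins(t)
            for b in part.basin_codes:
                prof = dict(landscape_profile(t, part, b))
                if 1 in prof:
                    assert prof[0] < prof[1]

    def test_singleton_cluster_profile(self, two_roi_landscape):
        part = assign_to_basins(two_roi_landscape)
        prof = landscape_profile(two_roi_landscape, part, 3)
        assert prof == [(0, pytest.approx(-0.8))]

    def test_non_basin_raises(self, two_roi_landscape):
        part = assign_to_basins(two_roi_landscape)
        with pytest.raises(ValueError):
            landscape_profile(two_roi_landscape, part, 1)
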