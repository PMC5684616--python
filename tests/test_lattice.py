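"""Cell-level rules: Moore rings, empty-site search, pushing, division, death."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbspheroid.lattice import (
    CellGrid,
    Phenotype,
    apply_death,
    attempt_division,
    find_empty_site,
    moore_ring,
    push_chain,
)

from conftest import fill_sites, make_grid


def cheb(a, b):
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


class TestMooreRing:
    @pytest.mark.parametrize("k,expected", [(1, 8), (2, 16), (3, 24)])
    def test_interior_ring_size_is_8k(self, k, expected):
        assert len(moore_ring((5, 5), k, 11)) == expected

    def test_corner_ring_clipped(self):
        assert sorted(moore_ring((0, 0), 1, 5)) == [(0, 1), (1, 0), (1, 1)]

    def test_all_sites_at_exact_chebyshev_distance(self):
        ring = moore_ring((4, 4), 2, 9)
        assert all(cheb(s, (4, 4)) == 2 for s in ring)

    @given(k1=st.integers(1, 4), k2=st.integers(1, 4))
    @settings(deadline=None)
    def test_rings_disjoint_and_union_fills_neighborhood(self, k1, k2):
        site, n = (10, 10), 21
        r1, r2 = set(moore_ring(site, k1, n)), set(moore_ring(site, k2, n))
        if k1 != k2:
            assert not (r1 & r2)
        total = sum(len(moore_ring(site, k, n)) for k in range(1, 5))
        assert total == (2 * 4 + 1) ** 2 - 1

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            moore_ring((0, 0), 0, 5)
        with pytest.raises(ValueError):
            moore_ring((9, 0), 1, 5)


class TestFindEmptySite:
    def test_uniform_choice_over_free_neighbors(self):
        hits = {s: 0 for s in moore_ring((3, 3), 1, 7)}
        for seed in range(4000):
            grid = make_grid()
            grid.add_cell((3, 3), 0)
            rng = np.random.default_rng(seed)
            hits[find_empty_site((3, 3), grid, 2, rng)] += 1
        freqs = np.array(list(hits.values())) / 4000
        assert np.allclose(freqs, 1 / 8, atol=0.02)

    def test_full_rings_give_none(self):
        grid = make_grid()
        for r in range(7):
            for c in range(7):
                grid.add_cell((r, c), 0)
        assert find_empty_site((3, 3), grid, 2, np.random.default_rng(0)) is None

    def test_single_gap_in_ring_two_found_with_certainty(self):
        # ring 1 around (3,3) full, exactly one empty site in ring 2
        grid = make_grid()
        grid.add_cell((3, 3), 0)
        for s in moore_ring((3, 3), 1, 7):
            grid.add_cell(s, 0)
        gap = (1, 2)
        for s in moore_ring((3, 3), 2, 7):
            if s != gap:
                grid.add_cell(s, 0)
        for seed in range(20):
            assert find_empty_site((3, 3), grid, 2, np.random.default_rng(seed)) == gap

    def test_first_ring_priority(self):
        # one empty in ring 1 and many in ring 2: ring 1 always wins
        grid = make_grid()
        grid.add_cell((3, 3), 0)
        for s in moore_ring((3, 3), 1, 7):
            if s != (2, 3):
                grid.add_cell(s, 0)
        for seed in range(20):
            assert find_empty_site((3, 3), grid, 2, np.random.default_rng(seed)) == (2, 3)

    @given(data=st.data())
    @settings(deadline=None, max_examples=60)
    def test_matches_brute_force_nearest_empty(self, data):
        n = data.draw(st.integers(5, 9))
        r = data.draw(st.integers(1, 3))
        grid = CellGrid(n, 18.0, [Phenotype(0, 24.0, r)])
        origin = (data.draw(st.integers(0, n - 1)), data.draw(st.integers(0, n - 1)))
        grid.add_cell(origin, 0)
        for row in range(n):
            for c in range(n):
                if (row, c) != origin and data.draw(st.booleans()):
                    grid.add_cell((row, c), 0)
        found = find_empty_site(origin, grid, r, np.random.default_rng(0))
        empties = [
            (row, c)
            for row in range(n)
            for c in range(n)
            if grid.occ[row, c] == -1 and 1 <= cheb((row, c), origin) <= r
        ]
        if not empties:
            assert found is None
        else:
            dmin = min(cheb(s, origin) for s in empties)
            assert found in empties and cheb(found, origin) == dmin


class TestPushChain:
    @pytest.mark.parametrize(
        "origin,target,chain",
        [
            ((5, 5), (5, 7), [(5, 6), (5, 7)]),
            ((5, 5), (7, 7), [(6, 6), (7, 7)]),
            ((5, 5), (6, 7), [(6, 6), (6, 7)]),
            ((5, 5), (2, 5), [(4, 5), (3, 5), (2, 5)]),
        ],
    )
    def test_geodesic_chain(self, origin, target, chain):
        assert push_chain(origin, target) == chain

    def test_each_step_reduces_chebyshev_distance_by_one(self):
        origin, target = (4, 4), (7, 9)
        chain = push_chain(origin, target)
        dists = [cheb(s, target) for s in [origin] + chain]
        assert dists == list(range(len(dists) - 1, -1, -1))

    def test_adjacent_target_rejected(self):
        with pytest.raises(ValueError):
            push_chain((5, 5), (5, 6))


class TestAttemptDivision:
    def test_lone_cell_divides_into_moore_neighborhood(self):
        grid = make_grid()
        i = grid.add_cell((3, 3), 0, age_h=24.0)
        ev = attempt_division(i, grid, np.random.default_rng(0))
        assert ev.divided and grid.n_cells == 2
        assert cheb(ev.daughter_site, (3, 3)) == 1
        assert grid.age_h[i] == 0.0  # carry: 24 - 24

    def test_enclosed_cell_goes_quiescent(self):
        grid = make_grid(n=7, r=2)
        center = grid.add_cell((3, 3), 0, age_h=30.0)
        for k in (1, 2):
            fill_sites(grid, moore_ring((3, 3), k, 7))
        before = grid.n_cells
        ev = attempt_division(center, grid, np.random.default_rng(0))
        assert not ev.divided
        assert grid.n_cells == before
        assert grid.age_h[center] == 30.0  # untouched on failure

    def test_push_preserves_existing_phenotype_age_multiset(self):
        # ring 1 full, ring 2 with a single gap: the division must push one
        # neighbor into the gap and add exactly one age-0 daughter.
        grid = CellGrid(7, 18.0, [Phenotype(0, 24.0, 2), Phenotype(1, 30.0, 2)])
        rng0 = np.random.default_rng(5)
        center = grid.add_cell((3, 3), 0, age_h=25.0)
        for j, s in enumerate(moore_ring((3, 3), 1, 7)):
            grid.add_cell(s, j % 2, age_h=float(j))
        gap = (5, 5)
        for j, s in enumerate(moore_ring((3, 3), 2, 7)):
            if s != gap:
                grid.add_cell(s, j % 2, age_h=10.0 + j)

        def multiset(g):
            return sorted(
                (pid, age) for _, pid, age in g.cell_states()
            )

        before = multiset(grid)
        before.remove((0, 25.0))  # divider's age will change
        n_before = grid.n_cells
        ev = attempt_division(center, grid, rng0)
        assert ev.divided
        assert grid.n_cells == n_before + 1
        assert grid.occ[gap] != -1  # the pushed neighbor landed in the gap
        after = multiset(grid)
        after.remove((0, 1.0))  # divider: 25 - 24
        after.remove((0, 0.0))  # daughter
        assert after == before

    def test_zero_policy_resets_parent_age(self):
        grid = make_grid()
        i = grid.add_cell((3, 3), 0, age_h=27.0)
        attempt_division(i, grid, np.random.default_rng(0), age_policy="zero")
        assert grid.age_h[i] == 0.0

    def test_carry_policy_keeps_age_remainder(self):
        grid = make_grid()
        i = grid.add_cell((3, 3), 0, age_h=27.0)
        attempt_division(i, grid, np.random.default_rng(0), age_policy="carry")
        assert grid.age_h[i] == pytest.approx(3.0)

    def test_unripe_cell_rejected(self):
        grid = make_grid()
        i = grid.add_cell((3, 3), 0, age_h=1.0)
        with pytest.raises(ValueError):
            attempt_division(i, grid, np.random.default_rng(0))


class TestApplyDeath:
    def test_zero_threshold_never_kills(self):
        grid = make_grid()
        fill_sites(grid, [(1, 1), (2, 2)])
        oxy = np.zeros((7, 7))
        assert apply_death(grid, oxy, 0.0) == []
        assert grid.n_cells == 2

    def test_uniformly_hypoxic_field_kills_everything(self):
        grid = make_grid()
        fill_sites(grid, [(1, 1), (2, 2), (3, 3)])
        oxy = np.full((7, 7), 0.01)
        removed = apply_death(grid, oxy, 0.1)
        assert len(removed) == 3 and grid.n_cells == 0
        assert (grid.occ == -1).all()

    def test_only_the_locally_hypoxic_cell_dies(self):
        grid = make_grid()
        fill_sites(grid, [(1, 1), (2, 2), (3, 3)])
        oxy = np.ones((7, 7))
        oxy[2, 2] = 0.05
        assert apply_death(grid, oxy, 0.1) == [(2, 2)]
        assert grid.n_cells == 2
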