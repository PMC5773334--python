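"""Species Accumulation Index machinery: S, R, O, SAI and the fraction sweep."""

import math
from itertools import combinations

import numpy as np
import pytest

import edselect as ed
from conftest import random_presence_absence


def _pa(rows):
    occ = np.asarray(rows, dtype=np.int8)
    return ed.PresenceAbsenceMatrix(
        occ=occ,
        site_ids=[f"s{i}" for i in range(occ.shape[0])],
        species_ids=[f"sp{j}" for j in range(occ.shape[1])],
    )


class TestSpeciesRepresented:
    def test_empty_selection_counts_nothing(self, small_pa):
        assert ed.species_represented([], small_pa) == 0

    def test_full_selection_counts_all_species(self, small_pa):
        assert ed.species_represented(range(small_pa.n_sites), small_pa) == small_pa.n_species

    def test_direct_count_on_tiny_matrix(self):
        pa = _pa([(1, 0), (1, 0), (0, 1)])
        assert ed.species_represented([0, 1], pa) == 1
        assert ed.species_represented([1, 2], pa) == 2


class TestRandomBaseline:
    def test_hypergeometric_identity_single_occupancy(self):
        # one species at 1 of 4 sites, p=2: E = 1 - C(3,2)/C(4,2) = 0.5
        pa = _pa([(1,), (0,), (0,), (0,)])
        assert ed.expected_random_richness(pa, 2) == pytest.approx(0.5)

    def test_closed_form_matches_subset_enumeration(self, rng):
        pa = random_presence_absence(rng, n_sites=7, n_species=5)
        p = 3
        vals = [
            ed.species_represented(sub, pa) for sub in combinations(range(7), p)
        ]
        assert ed.expected_random_richness(pa, p) == pytest.approx(np.mean(vals))

    def test_variance_matches_subset_enumeration(self, rng):
        pa = random_presence_absence(rng, n_sites=8, n_species=6)
        for p in (2, 4, 7):
            vals = np.array([
                ed.species_represented(sub, pa) for sub in combinations(range(8), p)
            ], dtype=float)
            assert ed.random_richness_variance(pa, p) == pytest.approx(
                vals.var(), abs=1e-10
            )

    def test_p_equal_n_is_exact_with_zero_variance(self, small_pa):
        n = small_pa.n_sites
        draws = ed.random_baseline_draws(small_pa, n, reps=10, seed=0)
        assert (draws == small_pa.n_species).all()

    def test_monte_carlo_agrees_with_closed_form(self, rng):
        pa = random_presence_absence(rng, n_sites=40, n_species=15)
        p = 8
        draws = ed.random_baseline_draws(pa, p, reps=1000, seed=7)
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - ed.expected_random_richness(pa, p)) <= 3 * se + 1e-9


class TestZonationRanking:
    def test_sole_refuge_ranked_near_the_top(self):
        # species 2 occurs only at site 4; sites 0-3 share common species
        pa = _pa([
            (1, 1, 0),
            (1, 1, 0),
            (1, 0, 0),
            (0, 1, 0),
            (0, 0, 1),
        ])
        ranking = ed.zonation_core_area_ranking(pa)
        assert 4 in ranking[: pa.n_species]

    def test_uniform_single_species_ranking_is_reverse_index_order(self):
        pa = _pa([(1,), (1,), (1,), (1,)])
        ranking = ed.zonation_core_area_ranking(pa)
        np.testing.assert_array_equal(ranking, [3, 2, 1, 0])

    def test_full_prefix_represents_all_species(self, small_pa):
        ranking = ed.zonation_core_area_ranking(small_pa)
        assert ed.species_represented(ranking, small_pa) == small_pa.n_species

    def test_each_removal_minimizes_the_max_occurrence_share(self, rng):
        """Step-wise oracle: the removed site always attains the minimal
        delta_i = max_j occ_ij / (remaining occurrences of j). A corollary is
        that a species' final occurrence (delta = 1, the maximum) is never
        removed while any site with alternatives for all its species remains."""
        for _ in range(5):
            pa = random_presence_absence(rng, n_sites=12, n_species=6)
            removal = ed.zonation_core_area_ranking(pa)[::-1]
            counts = pa.occ.sum(axis=0).astype(float)
            remaining = set(range(pa.n_sites))
            for site in removal:
                def delta(i):
                    inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
                    return (pa.occ[i] * inv).max()

                assert delta(site) == pytest.approx(min(delta(i) for i in remaining))
                remaining.discard(int(site))
                counts -= pa.occ[site]


class TestOptimalRepresentation:
    def test_p_equal_n_reaches_all_species_for_every_method(self, small_pa):
        n = small_pa.n_sites
        for method in ("zonation", "greedy_coverage"):
            assert ed.optimal_representation(small_pa, n, method) == small_pa.n_species

    def test_exact_finds_the_known_two_set_optimum(self):
        # sites 0 and 1 jointly cover all 5 species; no single site does
        pa = _pa([
            (1, 1, 1, 0, 0),
            (0, 0, 0, 1, 1),
            (1, 0, 0, 1, 0),
            (0, 1, 0, 0, 1),
            (0, 0, 1, 0, 0),
            (1, 0, 0, 0, 0),
        ])
        exact = ed.optimal_representation(pa, 2, "exact")
        assert exact == 5
        greedy = ed.optimal_representation(pa, 2, "greedy_coverage")
        assert greedy >= (1 - 1 / math.e) * exact

    def test_exact_dominates_heuristics_on_random_fixtures(self, rng):
        for _ in range(10):
            pa = random_presence_absence(rng, n_sites=12, n_species=8)
            exact = ed.optimal_representation(pa, 3, "exact")
            assert ed.optimal_representation(pa, 3, "zonation") <= exact
            assert ed.optimal_representation(pa, 3, "greedy_coverage") <= exact

    def test_exact_refuses_oversized_instances(self, rng):
        pa = random_presence_absence(rng, n_sites=60, n_species=5)
        with pytest.raises(ValueError, match="infeasible"):
            ed.optimal_representation(pa, 25, "exact")


class TestSai:
    def test_worked_example_is_half(self):
        assert ed.sai(150, 100, 200) == pytest.approx(0.5)

    def test_endpoints(self):
        assert ed.sai(200, 100, 200) == pytest.approx(1.0)
        assert ed.sai(100, 100, 200) == pytest.approx(0.0)

    def test_worse_than_random_is_negative(self):
        assert ed.sai(90, 100, 200) == pytest.approx(-0.1)

    def test_degenerate_denominator_flags_undefined(self):
        assert math.isnan(ed.sai(100, 100, 100))

    def test_baseline_above_optimum_raises(self):
        with pytest.raises(ValueError, match="heuristic failure"):
            ed.sai(150, 120, 100)

    def test_strictly_increasing_in_s(self):
        vals = [ed.sai(s, 40.0, 80.0) for s in range(40, 81, 5)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestFractionSweep:
    def test_fraction_to_p_rounding(self):
        assert [ed.fraction_for_p(f, 100) for f in ed.DEFAULT_FRACTIONS] == \
            [15, 20, 25, 30, 35]
        assert ed.fraction_for_p(0.15, 3) == 1  # floored at 1

    def test_oracle_selector_scores_one_everywhere(self, small_pa):
        ranking = ed.zonation_core_area_ranking(small_pa)
        report = ed.fraction_sweep(
            small_pa, lambda p: ranking[:p], reps=300, seed=5, ranking=ranking
        )
        for rec in report.records:
            if not math.isnan(rec["SAI"]):
                assert rec["SAI"] == pytest.approx(1.0)
        assert report.median_sai == pytest.approx(1.0)

    def test_random_selector_scores_near_zero(self, small_pa):
        ranking = ed.zonation_core_area_ranking(small_pa)
        medians = []
        for rep in range(50):
            sel_rng = np.random.default_rng(1000 + rep)
            selector = lambda p: sel_rng.choice(small_pa.n_sites, size=p, replace=False)
            report = ed.fraction_sweep(
                small_pa, selector, reps=300, seed=2000 + rep, ranking=ranking
            )
            medians.append(report.median_sai)
        assert abs(np.mean(medians)) < 0.1

    def test_report_frame_has_one_row_per_fraction(self, small_pa):
        ranking = ed.zonation_core_area_ranking(small_pa)
        report = ed.fraction_sweep(
            small_pa, lambda p: list(range(p)), reps=100, seed=1, ranking=ranking
        )
        df = report.to_frame()
        assert list(df["fraction"]) == list(ed.DEFAULT_FRACTIONS)
        assert list(df["p"]) == [ed.fraction_for_p(f, small_pa.n_sites)
                                 for f in ed.DEFAULT_FRACTIONS]
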