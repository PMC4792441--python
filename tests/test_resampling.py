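"""Animal-level permutation test and bootstrap, against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oemri import assign_bins, bootstrap_bin_sd, build_pixel_table, make_study, permutation_test_bins
from oemri.binning import BinAssignment

from .conftest import small_study_spec


def toy_table(animal_values: dict[str, tuple[str, list[float]]]) -> pd.DataFrame:
    """Pixel table from {animal_id: (group, values)}."""
    rows = []
    for animal, (group, values) in animal_values.items():
        for v in values:
            rows.append(
                {"animal_id": animal, "group": group, "s0_air": 1.0, "r1_air": 0.5,
                 "r1_o2": 0.52, "delta_r1": v, "delta_r2star": v / 0.46}
            )
    return pd.DataFrame(rows)


def single_bin(table: pd.DataFrame) -> BinAssignment:
    return BinAssignment(np.zeros(len(table), dtype=int), np.array([0.0, 1.0]), 1)


def exact_permutation_p(table: pd.DataFrame, response: str) -> float:
    """Brute-force oracle: enumerate every label assignment of the observed
    group sizes and count |mean difference| strictly above observed."""
    per_animal = table.groupby("animal_id", sort=False).agg(
        group=("group", "first"), s=(response, "sum"), c=(response, "count")
    )
    groups = list(dict.fromkeys(per_animal["group"]))
    animals = list(per_animal.index)
    n1 = int((per_animal["group"] == groups[0]).sum())

    def diff(group1_set):
        s1 = sum(per_animal.loc[a, "s"] for a in group1_set)
        c1 = sum(per_animal.loc[a, "c"] for a in group1_set)
        rest = [a for a in animals if a not in group1_set]
        s2 = sum(per_animal.loc[a, "s"] for a in rest)
        c2 = sum(per_animal.loc[a, "c"] for a in rest)
        return s1 / c1 - s2 / c2

    observed = diff([a for a in animals if per_animal.loc[a, "group"] == groups[0]])
    splits = list(itertools.combinations(animals, n1))
    exceed = sum(1 for s in splits if abs(diff(set(s))) > abs(observed))
    return exceed / len(splits)


@pytest.fixture()
def toy_3v2():
    return toy_table(
        {
            "a1": ("control", [1.0, 2.1]),
            "a2": ("control", [2.4, 3.0]),
            "a3": ("control", [3.3, 4.1]),
            "b1": ("challenged", [0.7, 1.9]),
            "b2": ("challenged", [4.8, 5.5]),
        }
    )


class TestPermutation:
    def test_monte_carlo_matches_exhaustive_enumeration(self, toy_3v2):
        """MC p on the 3-vs-2 toy design within 3 binomial SDs of the exact
        p from all 10 label splits."""
        p_exact = exact_permutation_p(toy_3v2, "delta_r1")
        res = permutation_test_bins(
            toy_3v2, single_bin(toy_3v2), "delta_r1", n_permutations=4000, seed=3
        )
        tol = 3 * np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert 0 < p_exact < 1  # a discriminating toy design
        assert abs(res.p_value[0] - p_exact) <= tol

    def test_null_centered_observation_gives_p_near_one(self):
        """Mirrored 5-vs-5 design: observed difference is exactly 0, almost
        every relabeling moves it away from zero, so p approaches 1 (the
        exact enumeration value is 1 - 32/252)."""
        # integer magnitudes keep all permutation sums exact in float64, so
        # "difference exactly zero" is unambiguous (the 32 one-of-each-value
        # splits), and p_exact = 1 - 32/252
        values = [1.0, 10.0, 100.0, 1000.0, 10000.0]
        table = toy_table(
            {f"a{i}": ("control", [v]) for i, v in enumerate(values)}
            | {f"b{i}": ("challenged", [v]) for i, v in enumerate(values)}
        )
        res = permutation_test_bins(table, single_bin(table), "delta_r1", 4000, seed=1)
        p_exact = exact_permutation_p(table, "delta_r1")
        assert res.observed_diff[0] == 0.0
        assert p_exact == pytest.approx(1 - 32 / 252)
        assert abs(res.p_value[0] - p_exact) < 3 * np.sqrt(p_exact * (1 - p_exact) / 4000)

    def test_two_tailed_symmetry_under_group_relabeling(self, toy_3v2):
        """Swapping which group is 'group 1' flips the sign of the observed
        difference but leaves every p unchanged."""
        res1 = permutation_test_bins(toy_3v2, single_bin(toy_3v2), "delta_r1", 2000, seed=9)
        swapped = toy_3v2.copy()
        swapped["group"] = swapped["group"].map(
            {"control": "challenged", "challenged": "control"}
        )
        # reorder so the swapped first-seen group has the same animal count
        p_exact = exact_permutation_p(toy_3v2, "delta_r1")
        p_exact_swapped = exact_permutation_p(swapped, "delta_r1")
        assert p_exact == p_exact_swapped
        assert abs(res1.p_value[0] - p_exact) <= 3 * np.sqrt(p_exact * (1 - p_exact) / 2000)

    def test_seed_reproducibility_and_mc_noise(self, toy_3v2):
        bins = single_bin(toy_3v2)
        r1 = permutation_test_bins(toy_3v2, bins, "delta_r1", 10_000, seed=5)
        r2 = permutation_test_bins(toy_3v2, bins, "delta_r1", 10_000, seed=5)
        r3 = permutation_test_bins(toy_3v2, bins, "delta_r1", 10_000, seed=6)
        np.testing.assert_array_equal(r1.p_value, r2.p_value)
        p = r1.p_value[0]
        assert abs(r3.p_value[0] - p) < 4 * np.sqrt(max(p * (1 - p), 1e-4) / 10_000)

    def test_small_groups_refused(self):
        table = toy_table({"a1": ("control", [1.0]), "b1": ("challenged", [2.0])})
        with pytest.raises(ValueError, match="fewer than 2"):
            permutation_test_bins(table, single_bin(table), "delta_r1", 100, seed=0)

    def test_missing_response_refused(self, toy_3v2):
        with pytest.raises(ValueError, match="not in pixel table"):
            permutation_test_bins(toy_3v2, single_bin(toy_3v2), "nope", 100, seed=0)

    def test_power_on_default_study_density_bins(self):
        """Low-density bins (where the challenged uptake deficit lives)
        reach small p; some mid-density bin does not."""
        study = make_study(small_study_spec(seed=0, n_pixels=600, grid=48), simulate=False)
        table = build_pixel_table([gt for gt, _ in study])
        bins = assign_bins(table["s0_air"].to_numpy(), 20)
        res = permutation_test_bins(table, bins, "delta_r1", 2000, seed=1)
        assert res.p_value[:3].min() < 0.05 or res.p_value[-3:].min() < 0.05
        assert res.p_value[5:15].max() > 0.1


class TestBootstrap:
    def test_no_between_animal_variance_gives_zero_sd(self):
        table = toy_table(
            {f"a{i}": ("control", [1.0, 2.0, 3.0]) for i in range(5)}
            | {"b1": ("challenged", [1.5]), "b2": ("challenged", [2.5])}
        )
        res = bootstrap_bin_sd(table, single_bin(table), "delta_r1", 200, seed=2)
        assert np.all(res.sd["control"] == 0.0)

    def test_iid_animals_match_analytic_sd_of_mean(self):
        """With one pixel per i.i.d. animal, the bootstrap SD of the group
        mean approximates sd_pop / sqrt(n)."""
        rng = np.random.default_rng(7)
        n = 12
        values = rng.normal(0.0, 1.0, n)
        table = toy_table(
            {f"a{i}": ("control", [values[i]]) for i in range(n)}
            | {f"b{i}": ("challenged", [float(rng.normal())]) for i in range(4)}
        )
        res = bootstrap_bin_sd(table, single_bin(table), "delta_r1", 4000, seed=3)
        analytic = values.std() / np.sqrt(n)
        assert abs(res.sd["control"][0] - analytic) / analytic < 0.25

    def test_seed_reproducibility(self, ):
        table = toy_table(
            {f"a{i}": ("control", [float(i), float(i + 1)]) for i in range(4)}
            | {f"b{i}": ("challenged", [float(2 * i)]) for i in range(3)}
        )
        bins = single_bin(table)
        r1 = bootstrap_bin_sd(table, bins, "delta_r1", 500, seed=11)
        r2 = bootstrap_bin_sd(table, bins, "delta_r1", 500, seed=11)
        for g in r1.sd:
            np.testing.assert_array_equal(r1.sd[g], r2.sd[g])

    def test_default_study_bin_sds_finite_positive(self):
        study = make_study(small_study_spec(seed=4), simulate=False)
        table = build_pixel_table([gt for gt, _ in study])
        bins = assign_bins(table["s0_air"].to_numpy(), 20)
        res = bootstrap_bin_sd(table, bins, "delta_r1", 300, seed=5)
        for g in ("control", "challenged"):
            assert np.all(np.isfinite(res.sd[g]))
            assert np.all(res.sd[g] > 0)
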