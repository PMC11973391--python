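import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ystrkit.distance import (
    DistanceMatrix,
    distance_matrix,
    nei_standard_distance,
    rst_pairwise,
    sample_profiles,
    squared_step_matrix,
    step_distance,
)
from ystrkit.io import AlleleCall, build_table
from ystrkit.simulate import SimulationConfig, simulate_tribe
from tests.conftest import make_record

V = AlleleCall.value


class TestStepDistance:
    def test_identical_haplotypes(self):
        h = [V(14), V(30), V(11)]
        assert step_distance(h, h) == 0.0

    def test_single_locus_absolute_and_squared(self):
        assert step_distance([V(14)], [V(16)]) == 2.0
        assert step_distance([V(14)], [V(16)], mode="squared") == 4.0

    def test_microvariant_rounds_to_nearest_integer(self):
        assert step_distance([V(13.2)], [V(13)]) == 0.0

    def test_pairwise_deletion_of_nulls_and_duplications(self):
        a = [V(14), AlleleCall.null(), V(11)]
        b = [V(15), V(30), AlleleCall.duplicated(11, 12)]
        assert step_distance(a, b) == 1.0

    def test_no_shared_loci_is_an_error(self):
        with pytest.raises(ValueError, match="no shared"):
            step_distance([AlleleCall.null()], [V(14)])

    @given(
        st.lists(st.tuples(st.integers(8, 20), st.integers(8, 20),
                           st.integers(8, 20)), min_size=1, max_size=8)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_triangle_inequality(self, triples):
        a = [t[0] for t in triples]
        b = [t[1] for t in triples]
        c = [t[2] for t in triples]
        dab = step_distance(a, b)
        dbc = step_distance(b, c)
        dac = step_distance(a, c)
        assert dac <= dab + dbc + 1e-12


def _two_clans(seed=3, n=50, t=600.0):
    cfg = SimulationConfig(seed=seed, n_clans=2, samples_per_clan=(n, n),
                           t_years=t)
    table, _ = simulate_tribe(cfg)
    clans = table.groupby_clan()
    names = list(clans)
    return clans[names[0]], clans[names[1]]


class TestRst:
    def test_identical_monomorphic_populations(self):
        recs_a = [make_record(f"A{i}") for i in range(4)]
        recs_b = [make_record(f"B{i}") for i in range(4)]
        assert rst_pairwise(build_table(recs_a), build_table(recs_b)) == 0.0

    def test_fixed_difference_approaches_one(self):
        n = 30
        recs_a = [make_record(f"A{i}") for i in range(n)]
        recs_b = [
            make_record(f"B{i}", overrides={"DYS393": V(13)}) for i in range(n)
        ]
        r = rst_pairwise(build_table(recs_a), build_table(recs_b))
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_variance_component_oracle(self):
        """Two simulated clans against an explicit sum-of-squares R_ST."""
        pop_a, pop_b = _two_clans()
        prof_a, names = sample_profiles(pop_a)
        prof_b, _ = sample_profiles(pop_b, names)
        x = np.vstack([prof_a, prof_b])
        na, nb = len(prof_a), len(prof_b)
        n_tot = na + nb
        d2 = np.zeros((n_tot, n_tot))
        for i in range(n_tot):
            for j in range(n_tot):
                d2[i, j] = np.sum((x[i] - x[j]) ** 2)
        idx_a, idx_b = range(na), range(na, n_tot)
        ss_total = sum(d2[i, j] for i in range(n_tot) for j in range(n_tot)) / (2 * n_tot)
        ss_within = (
            sum(d2[i, j] for i in idx_a for j in idx_a) / (2 * na)
            + sum(d2[i, j] for i in idx_b for j in idx_b) / (2 * nb)
        )
        ss_among = ss_total - ss_within
        ms_within = ss_within / (n_tot - 2)
        n_prime = (n_tot - (na**2 + nb**2) / n_tot) / 1
        sigma_b = (ss_among / 1 - ms_within) / n_prime
        expected = sigma_b / (sigma_b + ms_within)
        assert rst_pairwise(pop_a, pop_b) == pytest.approx(expected, abs=1e-10)

    def test_translation_invariance(self):
        """Adding a constant to every allele at a locus leaves R_ST fixed."""
        pop_a, pop_b = _two_clans(seed=9, n=10)
        base = rst_pairwise(pop_a, pop_b)

        def shift(table, locus, delta):
            t = table
            j = t.locus_index(locus)
            calls = t.calls.copy()
            for i in range(t.n_samples):
                c = calls[i, j]
                if c.is_value:
                    calls[i, j] = V(c.repeats + delta)
            from ystrkit.io import HaplotypeTable

            return HaplotypeTable(t.meta.copy(), calls, t.loci)

        shifted = rst_pairwise(shift(pop_a, "DYS393", 2), shift(pop_b, "DYS393", 2))
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_requires_two_samples_per_population(self):
        recs = [make_record("A0")]
        with pytest.raises(ValueError):
            rst_pairwise(build_table(recs), build_table([make_record("B0")]))


class TestNeiDistance:
    def test_identical_populations_distance_zero(self):
        t = build_table([make_record(f"S{i}") for i in range(5)])
        assert nei_standard_distance(t, t) == 0.0

    def test_disjoint_alleles_infinite(self):
        a = build_table([make_record("A0"), make_record("A1")])
        b = build_table([
            make_record(f"B{i}", overrides={d.name: _shift_call(make_record("x")[d.name]) for d in a.loci})
            for i in range(2)
        ])
        assert nei_standard_distance(a, b) == float("inf")

    def test_two_locus_toy_frequencies_match_hand_computation(self):
        # pop A: DYS393 12 x3, 13 x1; pop B: 12 x1, 13 x3 (others identical)
        recs_a = [make_record(f"A{i}", overrides={"DYS393": V(12 if i < 3 else 13)})
                  for i in range(4)]
        recs_b = [make_record(f"B{i}", overrides={"DYS393": V(12 if i < 1 else 13)})
                  for i in range(4)]
        a, b = build_table(recs_a), build_table(recs_b)
        loci = ["DYS393", "DYS19"]
        ja = ((0.75**2 + 0.25**2) + 1.0) / 2
        jb = ((0.25**2 + 0.75**2) + 1.0) / 2
        jab = ((0.75 * 0.25 + 0.25 * 0.75) + 1.0) / 2
        expected = -np.log(jab / np.sqrt(ja * jb))
        assert nei_standard_distance(a, b, loci) == pytest.approx(expected, abs=1e-12)


def _shift_call(call):
    if call.is_value:
        return V(call.repeats + 1)
    return AlleleCall.duplicated(call.pair[0] + 1, call.pair[1] + 1)


class TestDistanceMatrix:
    def test_three_identical_populations_zero_matrix(self):
        t = build_table([make_record(f"S{i}") for i in range(4)])
        dm = distance_matrix({"x": t, "y": t, "z": t}, metric="rst")
        assert np.allclose(dm.values, 0.0)

    def test_row_means(self):
        dm = DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0, 0.01, 0.03], [0.01, 0, 0.02], [0.03, 0.02, 0]]),
            "rst",
        )
        assert dm.row_means()["a"] == pytest.approx(0.02)

    def test_simulated_clan_system_entries_match_pairwise(self, small_tribe):
        table, _ = small_tribe
        clans = table.groupby_clan()
        dm = distance_matrix(clans, metric="rst")
        names = list(clans)
        assert np.allclose(dm.values, dm.values.T)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    assert dm.values[i, j] == pytest.approx(
                        rst_pairwise(clans[a], clans[b]), abs=1e-12
                    )

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "a"), np.zeros((2, 2)), "rst")
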