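import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from autocatnet.chemistry import (
    RateTable,
    SpeciesId,
    build_network,
    network_key,
)
from autocatnet.kinetics import Composition
from autocatnet.perturbation import (
    PerturbationParams,
    UndefinedPerturbationError,
    background_strength,
    enumerate_perturbation_pairs,
    mean_perturbation,
    perturbation,
    perturbation_params,
    predict_perturbation,
)
from oracle_utils import direct_indegree_perturbation, generalized_prediction, make_eq1_instance

U, V, W = SpeciesId("A", "U"), SpeciesId("C", "G"), SpeciesId("G", "C")


def comp(**fractions) -> Composition:
    ids = {"u": U, "v": V, "w": W}
    return Composition(fractions={ids[k]: f for k, f in fractions.items()})


class TestPerturbationMetric:
    def test_full_switch_reaches_maximum_two(self):
        assert perturbation(comp(u=0, v=1), comp(u=1, v=0), {U, V}) == pytest.approx(2.0)

    def test_identical_compositions_give_zero(self):
        assert perturbation(comp(u=0.3, v=0.7), comp(u=0.3, v=0.7), {U, V}) == 0.0

    def test_hand_evaluated_l1(self):
        p = perturbation(comp(u=0.5, v=0.5), comp(u=0.75, v=0.25), {U, V})
        assert p == pytest.approx(0.5)

    def test_renormalizes_within_common_set(self):
        # G' has mass on a third species; only the common set enters
        a = comp(u=0.5, v=0.5)
        b = comp(u=0.3, v=0.3, w=0.4)
        assert perturbation(a, b, {U, V}) == pytest.approx(0.0)

    def test_symmetry(self):
        a, b = comp(u=0.2, v=0.8), comp(u=0.6, v=0.4)
        assert perturbation(a, b, {U, V}) == perturbation(b, a, {U, V})

    def test_zero_mass_on_common_set_raises(self):
        with pytest.raises(UndefinedPerturbationError):
            perturbation(comp(u=0, v=0, w=1), comp(u=1, v=0), {U, V})

    def test_empty_common_set_raises(self):
        with pytest.raises(UndefinedPerturbationError):
            perturbation(comp(u=1), comp(u=1), set())

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=2),
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=2),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds(self, ys, yps):
        a = Composition(fractions={U: ys[0], V: ys[1]})
        b = Composition(fractions={U: yps[0], V: yps[1]})
        p = perturbation(a, b, {U, V})
        assert 0.0 <= p <= 2.0 + 1e-12


def three_cycle_table(e=1.0):
    igs, tags = ("p", "q", "r", "x", "y"), ("s", "t", "u", "z")
    # cycle u -> v -> w -> u with rate e: species (p,s), (q,t), (r,u)
    alpha = {("p", "t"): e, ("q", "u"): e, ("r", "s"): e}
    # 'x' is a novel IGS targeting tags t and u; 'p'-IGS strong rate is e
    alpha[("x", "t")] = e
    alpha[("x", "u")] = e
    return RateTable(alpha, {}, 1e-9, igs, tags)


class TestPerturbationParams:
    def test_novel_igs_two_targets(self):
        table = three_cycle_table(e=1.0)
        G = build_network([SpeciesId("p", "s"), SpeciesId("q", "t"), SpeciesId("r", "u")], table)
        a = SpeciesId("x", "z")
        params = perturbation_params(G, a, table)
        assert (params.n, params.m) == (2, 0)
        assert params.sigma_G == pytest.approx(3.0)
        assert params.e == pytest.approx(1.0)

    def test_shared_igs_single_target(self):
        table = three_cycle_table(e=1.0)
        G = build_network([SpeciesId("p", "s"), SpeciesId("q", "t"), SpeciesId("r", "u")], table)
        a = SpeciesId("p", "z")  # same IGS as (p,s); p targets tag t only
        params = perturbation_params(G, a, table)
        assert (params.n, params.m) == (1, 1)
        assert params.sigma_G == pytest.approx(3.0)

    def test_no_targets_gives_zero_breadth(self):
        table = three_cycle_table()
        G = build_network([SpeciesId("p", "s")], table)
        a = SpeciesId("y", "z")  # inert IGS
        assert perturbation_params(G, a, table).n == 0

    def test_species_already_present_raises(self, table):
        G = build_network([SpeciesId("G", "C")], table)
        with pytest.raises(ValueError):
            perturbation_params(G, SpeciesId("G", "C"), table)

    def test_sigma_includes_self_loops(self, table):
        G = build_network([SpeciesId("A", "U")], table)  # one self-loop
        assert background_strength(G) == pytest.approx(table.pair_alpha("A", "U"))


class TestPredictPerturbation:
    @pytest.mark.parametrize(
        "n,m,s,expected",
        [
            (1, 0, 1.0, 1.0),  # 2*1/(1+1)
            (1, 1, 2.0, 1 / 3),  # 2(1 - 1/2)/(2 + 1)
            (2, 0, 2.0, 1.0),  # 2*2/(2+2)
        ],
    )
    def test_closed_form_values(self, n, m, s, expected):
        p_hat, valid = predict_perturbation(PerturbationParams(n=n, m=m, sigma_G=s, e=1.0))
        assert p_hat == pytest.approx(expected)
        assert valid

    def test_vanishes_for_large_background(self):
        p_hat, _ = predict_perturbation(PerturbationParams(n=1, m=0, sigma_G=1e9, e=1.0))
        assert p_hat == pytest.approx(0.0, abs=1e-8)

    def test_invalid_outside_assumptions_not_clamped(self):
        # n*m/s > 1 drives the prediction negative; reported as-is, flagged
        p_hat, valid = predict_perturbation(PerturbationParams(n=2, m=2, sigma_G=1.0, e=1.0))
        assert p_hat < 0 and not valid

    def test_zero_sigma_raises(self):
        with pytest.raises(ZeroDivisionError):
            predict_perturbation(PerturbationParams(n=1, m=0, sigma_G=0.0, e=1.0))

    def test_innovation_prediction_decreases_with_background(self):
        s = np.linspace(0.5, 20, 40)
        p = [predict_perturbation(PerturbationParams(1, 0, si, 1.0))[0] for si in s]
        assert all(b < a for a, b in zip(p, p[1:]))

    def test_shared_igs_prediction_peaks_at_intermediate_background(self):
        s = np.linspace(1.2, 30, 200)
        p = np.array([predict_perturbation(PerturbationParams(1, 1, si, 1.0))[0] for si in s])
        k = p.argmax()
        assert 0 < k < len(s) - 1  # interior maximum


class TestEq1Oracle:
    def test_direct_indegree_equals_prediction_under_assumptions(self, rng):
        """On networks built to the derivation's assumptions the closed form is exact."""
        checked = 0
        for _ in range(120):
            G, a, table = make_eq1_instance(rng)
            params = perturbation_params(G, a, table)
            p_hat, valid = predict_perturbation(params)
            if not valid:
                continue
            p_direct = direct_indegree_perturbation(G, a, table)
            assert p_direct == pytest.approx(p_hat, abs=1e-10)
            checked += 1
        assert checked >= 100

    def test_generalized_formula_on_random_concrete_networks(self, table, rng):
        """2en(sigma - D_T)/(sigma(sigma + ne)) matches direct computation."""
        from autocatnet.chemistry import all_species

        pool = all_species()
        checked = 0
        attempts = 0
        while checked < 100 and attempts < 5000:
            attempts += 1
            size = int(rng.integers(2, 7))
            idx = rng.choice(16, size=size + 1, replace=False)
            G_species = [pool[i] for i in idx[:-1]]
            a = pool[idx[-1]]
            G = build_network(G_species, table)
            expected = generalized_prediction(G, a, table)
            if expected is None:
                continue
            p_direct = direct_indegree_perturbation(G, a, table)
            assert p_direct == pytest.approx(expected, abs=1e-12)
            checked += 1
        assert checked >= 100


class TestLandscapeEnumeration:
    def test_single_nested_pair(self, table):
        landscape = {
            network_key([U, V]): comp(u=0.5, v=0.5),
            network_key([U, V, W]): comp(u=0.3, v=0.3, w=0.4),
        }
        records = enumerate_perturbation_pairs(landscape, table)
        assert len(records) == 1
        assert records[0].added == W

    def test_no_nested_pairs_empty(self, table):
        landscape = {
            network_key([U, V]): comp(u=0.5, v=0.5),
            network_key([U, W]): comp(u=0.5, w=0.5),
        }
        assert enumerate_perturbation_pairs(landscape, table) == []

    def test_count_matches_brute_force_subset_scan(self, table, rng):
        from itertools import combinations

        from autocatnet.chemistry import all_species

        pool = all_species()[:6]
        sets = []
        for size in (2, 3, 4):
            for c in combinations(pool, size):
                if rng.random() < 0.5:
                    sets.append(frozenset(c))
        landscape = {
            network_key(s): Composition(fractions={sp: 1 / len(s) for sp in s}) for s in sets
        }
        expected = sum(
            1 for s1 in sets for s2 in sets if len(s2) == len(s1) + 1 and s1 < s2
        )
        assert len(enumerate_perturbation_pairs(landscape, table)) == expected


class TestMeanPerturbation:
    def test_grouped_means_match_brute_force(self, table, rng):
        landscape = {}
        base_sets = []
        from itertools import combinations

        from autocatnet.chemistry import all_species

        pool = all_species()[:5]
        for size in (2, 3):
            for c in combinations(pool, size):
                base_sets.append(frozenset(c))
        for s in base_sets:
            fr = rng.dirichlet(np.ones(len(s)))
            landscape[network_key(s)] = Composition(fractions=dict(zip(sorted(s), fr)))
        records = enumerate_perturbation_pairs(landscape, table)
        assert len(records) >= 10
        means = mean_perturbation(records)
        # independent re-aggregation
        acc: dict[str, list[float]] = {}
        for r in records:
            acc.setdefault(r.G_key, []).append(r.p)
        for key, ps in acc.items():
            assert means[key] == pytest.approx(float(np.mean(ps)))

    def test_single_and_pair_values(self):
        import pandas as pd

        from autocatnet.perturbation import PerturbationRecord

        params = PerturbationParams(1, 0, 1.0, 1.0)
        recs = [
            PerturbationRecord("G1", "Gp1", U, params, 0.2, 0.2, True),
            PerturbationRecord("G1", "Gp2", V, params, 0.4, 0.4, True),
            PerturbationRecord("G2", "Gp3", W, params, 0.7, 0.7, True),
        ]
        means = mean_perturbation(recs)
        assert means["G1"] == pytest.approx(0.3)
        assert means["G2"] == pytest.approx(0.7)
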