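import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from autocatnet.chemistry import SpeciesId, all_species, build_network
from autocatnet.kinetics import Composition
from autocatnet.landscape import (
    aggregate_networks,
    landscape_table,
    model_measurement_correlation,
    rank_conservation,
    sigma_yield_correlation,
    tradeoff_test,
    yield_ranking,
)

U, V, W = SpeciesId("A", "U"), SpeciesId("C", "G"), SpeciesId("G", "C")


def droplet(species, fracs, yield_uM=0.05):
    return (
        frozenset(species),
        Composition(fractions=dict(zip(species, fracs)), yield_uM=yield_uM),
    )


class TestAggregation:
    def test_replicates_grouped_into_one_record(self):
        drops = [droplet([U, V], [0.4, 0.6]) for _ in range(3)]
        records = aggregate_networks(drops)
        assert len(records) == 1
        assert records[0].n_replicates == 3

    def test_distinct_sets_distinct_records(self):
        records = aggregate_networks([droplet([U, V], [0.5, 0.5]), droplet([U, W], [0.5, 0.5])])
        assert len(records) == 2

    def test_total_droplet_count_preserved(self, rng):
        drops = []
        for _ in range(50):
            k = int(rng.integers(2, 5))
            sp = sorted(rng.choice(16, size=k, replace=False))
            species = [all_species()[i] for i in sp]
            drops.append(droplet(species, rng.dirichlet(np.ones(k)), float(rng.uniform(0.01, 0.2))))
        records = aggregate_networks(drops)
        assert sum(r.n_replicates for r in records) == 50

    def test_mean_and_sem_match_independent_recomputation(self, rng):
        # 100 droplets over a handful of networks; re-aggregate by hand
        pool = [[U, V], [U, W], [U, V, W]]
        drops = []
        for _ in range(100):
            species = pool[int(rng.integers(0, 3))]
            drops.append(
                droplet(species, rng.dirichlet(np.ones(len(species))), float(rng.uniform(0.01, 0.3)))
            )
        records = aggregate_networks(drops)
        for rec in records:
            mine = [
                (c, y)
                for s, c in drops
                if s == frozenset(rec.species)
                for y in [c.yield_uM]
            ]
            yields = np.array([y for _, y in mine])
            assert rec.mean_yield_uM == pytest.approx(yields.mean())
            assert rec.sem_yield == pytest.approx(yields.std(ddof=1) / np.sqrt(len(yields)))
            mat = np.array([c.as_vector(rec.species) for c, _ in mine])
            mean = mat.mean(axis=0)
            mean /= mean.sum()
            for k, s in enumerate(rec.species):
                assert rec.mean_fractions.fractions[s] == pytest.approx(mean[k])

    def test_landscape_table_schema(self):
        records = aggregate_networks([droplet([U, V], [0.4, 0.6])])
        df = landscape_table(records)
        assert set(df.columns) == {
            "network_id",
            "size",
            "species",
            "mean_fraction",
            "sd",
            "n_replicates",
            "mean_yield_uM",
            "sem_yield",
        }


class TestRankConservation:
    def test_identical_ranking_everywhere_gives_zero(self):
        drops = [droplet([U, V], [0.7, 0.3]), droplet([U, V, W], [0.5, 0.3, 0.2])]
        records = aggregate_networks(drops)
        assert rank_conservation(records) == 0.0

    def test_flip_in_twenty_percent_counts(self):
        # U > V in 8 networks, V > U in 2 of 10: minority share 0.2 >= 0.1
        drops = []
        for i in range(8):
            other = all_species()[i + 4]
            drops.append(droplet([U, V, other], [0.5, 0.3, 0.2]))
        for i in range(2):
            other = all_species()[i + 12]
            drops.append(droplet([U, V, other], [0.3, 0.5, 0.2]))
        records = aggregate_networks(drops)
        # the (U, V) pair is non-conserved; pairs with 'other' co-occur once only
        assert rank_conservation(records) == pytest.approx(1.0)

    def test_independent_catalysts_fully_conserved(self, rng):
        # non-interacting catalysts with fixed per-species rates: within any
        # network, fractions are the renormalized rates, so ranking never flips
        pool = all_species()
        rates = rng.uniform(0.1, 1.0, size=16)
        drops = []
        for _ in range(30):
            idx = rng.choice(16, size=int(rng.integers(2, 6)), replace=False)
            fr = rates[idx] / rates[idx].sum()
            drops.append(droplet([pool[i] for i in idx], fr))
        assert rank_conservation(aggregate_networks(drops)) == 0.0

    def test_no_co_occurring_pair_raises(self):
        records = aggregate_networks([droplet([U, V], [0.6, 0.4])])
        with pytest.raises(ValueError):
            rank_conservation(records)


class TestYieldRanking:
    def _records(self, yields, n_reps=12):
        drops = []
        pool = all_species()
        for i, y in enumerate(yields):
            species = [pool[i], pool[i + 8]]
            for _ in range(n_reps):
                drops.append(droplet(species, [0.5, 0.5], y))
        return aggregate_networks(drops)

    def test_ascending_order(self):
        df = yield_ranking(self._records([0.1, 0.3, 0.2]), size=2, min_replicates=10)
        assert list(df["mean_yield_uM"]) == pytest.approx([0.1, 0.2, 0.3])
        assert df.attrs["fold_range"] == pytest.approx(3.0)

    def test_underreplicated_networks_excluded(self):
        records = self._records([0.1, 0.3], n_reps=9)
        df = yield_ranking(records, size=2, min_replicates=10)
        assert df.empty


class TestTradeoffTest:
    @staticmethod
    def _df(table):
        rows = []
        (a, b), (c, d) = table
        rows += [{"p": 0.9, "yield_uM": 0.2}] * a  # strong & high
        rows += [{"p": 0.9, "yield_uM": 0.01}] * b  # strong & low
        rows += [{"p": 0.1, "yield_uM": 0.2}] * c  # weak & high
        rows += [{"p": 0.1, "yield_uM": 0.01}] * d  # weak & low
        return pd.DataFrame(rows)

    def test_independence_gives_odds_ratio_one(self):
        res = tradeoff_test(self._df([[5, 5], [5, 5]]))
        assert res.odds_ratio == pytest.approx(1.0)
        assert not res.degenerate

    def test_perfect_exclusion_matches_hypergeometric_point_mass(self):
        res = tradeoff_test(self._df([[0, 10], [10, 0]]))
        # P(X <= 0) with N=20, K=10 successes, n=10 draws, by direct enumeration
        expected = hypergeom.cdf(0, 20, 10, 10)
        assert res.p_value == pytest.approx(expected, rel=1e-10)
        assert res.odds_ratio == 0.0

    def test_fisher_equals_hypergeometric_tail_enumeration(self, rng):
        # exhaustive-tail oracle over random tables with N <= 40
        for _ in range(50):
            t = rng.integers(1, 11, size=4).reshape(2, 2)
            res = tradeoff_test(self._df(t.tolist()))
            a = t[0, 0]
            N, K, n = t.sum(), t[0].sum(), t[:, 0].sum()
            expected = sum(hypergeom.pmf(k, N, K, n) for k in range(0, a + 1))
            assert res.p_value == pytest.approx(expected, rel=1e-8)

    def test_empty_margin_degenerate(self):
        res = tradeoff_test(self._df([[0, 0], [5, 5]]))
        assert res.degenerate and res.p_value == 1.0


class TestSigmaYieldCorrelation:
    def _records_from_sets(self, sets, yields):
        drops = [
            droplet(list(s), np.full(len(s), 1.0 / len(s)), y) for s, y in zip(sets, yields)
        ]
        return aggregate_networks(drops)

    def test_exact_linear_relation_gives_r_one(self, table):
        from autocatnet.perturbation import background_strength

        pool = all_species()
        sets = [[pool[0], pool[7]], [pool[1], pool[14]], [pool[3], pool[12]], pool[:4]]
        sigmas = [background_strength(build_network(s, table)) for s in sets]
        records = self._records_from_sets(sets, [2 * s for s in sigmas])
        r, _ = sigma_yield_correlation(records, table)
        assert r == pytest.approx(1.0)

    def test_shuffled_yields_uncorrelated(self, table, rng):
        pool = all_species()
        sets = []
        for _ in range(40):
            k = int(rng.integers(2, 6))
            sets.append([pool[i] for i in rng.choice(16, size=k, replace=False)])
        rs = []
        for _ in range(100):
            yields = rng.uniform(0.01, 0.3, size=len(sets))
            r, _ = sigma_yield_correlation(self._records_from_sets(sets, yields), table)
            rs.append(r)
        # correlation under the null scatters around zero
        assert abs(np.mean(rs)) < 0.1

    def test_kinetic_landscape_positively_correlated(self, table, rng):
        from autocatnet.kinetics import predict_fractions

        pool = all_species()
        sets, yields = [], []
        from autocatnet.kinetics import UndefinedCompositionError

        while len(sets) < 60:
            k = int(rng.integers(2, 7))
            s = [pool[i] for i in rng.choice(16, size=k, replace=False)]
            try:
                comp = predict_fractions(build_network(s, table), 60)
            except UndefinedCompositionError:
                continue  # species set without any interaction: no production
            sets.append(s)
            yields.append(comp.yield_uM)
        r, _ = sigma_yield_correlation(self._records_from_sets(sets, yields), table)
        assert r > 0

    def test_constant_input_raises(self, table):
        records = self._records_from_sets([[U, V]] * 3, [0.1, 0.1, 0.1])
        with pytest.raises(ValueError):
            sigma_yield_correlation(records, table)


class TestModelMeasurementCorrelation:
    def test_identity_gives_r_one(self, rng):
        comps = {}
        for i in range(20):
            fr = rng.dirichlet(np.ones(3))
            comps[f"net{i}"] = Composition(fractions=dict(zip([U, V, W], fr)))
        r, _ = model_measurement_correlation(comps, comps)
        assert r == pytest.approx(1.0)

    def test_multinomial_resampling_preserves_correlation(self, rng):
        # measurements = depth-100 multinomial resamples of the predictions
        predicted, measured = {}, {}
        for i in range(200):
            fr = rng.dirichlet(np.ones(4))
            sp = all_species()[:4]
            predicted[f"net{i}"] = Composition(fractions=dict(zip(sp, fr)))
            counts = rng.multinomial(100, fr)
            measured[f"net{i}"] = Composition(fractions=dict(zip(sp, counts / 100)))
        r, bins = model_measurement_correlation(predicted, measured)
        assert r > 0.9
        assert (bins["n"] >= 10).all()

    def test_disjoint_keys_raise(self):
        a = {"x": Composition(fractions={U: 1.0})}
        b = {"y": Composition(fractions={U: 1.0})}
        with pytest.raises(ValueError):
            model_measurement_correlation(a, b)
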