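import numpy as np
import pandas as pd
import pytest

from odormix import (
    GeneratorConfig,
    build_population_matrix,
    category_block_means,
    generate_session,
    lookback_sweep,
    probe_association,
    probe_tnt,
    pv_correlation_matrix,
    tnt_series,
    trial_category_labels,
)
from odormix.decoding import PopulationMatrix
from odormix.synth import BehaviorModel


def _toy_matrix(X, types):
    n = X.shape[0]
    labels = pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "trial_type": types,
            "is_target": [t == "target" for t in types],
            "correct": True,
            "day": 0,
            "first_lick_latency": 1.0,
        }
    )
    return PopulationMatrix(X=np.asarray(X, float), raw_counts=np.asarray(X, float),
                            neuron_ids=[f"n{i}" for i in range(X.shape[1])],
                            excluded={}, labels=labels)


def _coupled_session(seed=0, coupling=1.5, n_trials=300, n_neurons=30):
    g = GeneratorConfig(
        n_trials=n_trials, n_neurons=n_neurons, selective_fraction=0.5,
        selectivity_gain=3.0, probe_fraction=0.15,
        behavior=BehaviorModel(coupling=coupling), ar_sigma=0.12, ar_rho=0.97,
    )
    return generate_session(g, seed=seed)


def _probe_data(session, sim, tnt, L=10):
    probe_pos = np.flatnonzero(sim.trial_type == "probe")
    values, defined = probe_tnt(tnt, probe_pos, L=L)
    by_index = {t.trial_index: t for t in session.trials}
    probes = [by_index[sim.trial_index[p]] for p in probe_pos]
    outcomes = np.array(
        [np.nan if t.correct is None else float(t.correct) for t in probes]
    )
    latencies = np.array(
        [np.nan if t.first_lick_latency is None else t.first_lick_latency
         for t in probes]
    )
    return probe_pos, values, defined, outcomes, latencies


class TestCorrelationMatrix:
    def test_identical_vectors_correlate_to_one(self):
        X = np.array([[1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5], [5, 1, 4, 2, 3]])
        sim = pv_correlation_matrix(_toy_matrix(X, ["target"] * 3), normalize=False)
        assert sim.corr_raw[0, 1] == pytest.approx(1.0)

    def test_antiproportional_vectors_correlate_to_minus_one(self):
        X = np.array([[1.0, 2, 3, 4, 5], [-2.0, -4, -6, -8, -10], [5, 1, 4, 2, 3]])
        sim = pv_correlation_matrix(_toy_matrix(X, ["target"] * 3), normalize=False)
        assert sim.corr_raw[0, 1] == pytest.approx(-1.0)

    def test_matches_bruteforce_pair_loop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 5))
        sim = pv_correlation_matrix(_toy_matrix(X, ["target"] * 6), normalize=False)
        for i in range(6):
            for j in range(6):
                expected = np.corrcoef(X[i], X[j])[0, 1]
                assert sim.corr_raw[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_trial_masked(self):
        X = np.vstack([np.full(5, 2.0), np.random.default_rng(1).normal(size=(3, 5))])
        sim = pv_correlation_matrix(_toy_matrix(X, ["target"] * 4))
        assert not sim.valid[0]
        assert np.isnan(sim.corr_z[0, 1])
        assert np.isfinite(sim.corr_z[1, 2])

    def test_zscored_offdiagonal_standardized(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 8))
        sim = pv_correlation_matrix(_toy_matrix(X, ["target"] * 20))
        iu = np.triu_indices(20, k=1)
        pairs = sim.corr_z[iu]
        assert pairs.mean() == pytest.approx(0.0, abs=1e-10)
        assert pairs.std() == pytest.approx(1.0, abs=1e-10)


class TestBlockMeans:
    def test_single_category_equals_offdiagonal_mean(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 6))
        sim = pv_correlation_matrix(_toy_matrix(X, ["target"] * 5), normalize=False)
        blocks = category_block_means(sim, ["T"] * 5)
        iu = np.triu_indices(5, k=1)
        assert blocks.loc["T", "T"] == pytest.approx(sim.corr_raw[iu].mean())

    def test_hand_computed_three_categories(self):
        corr = np.array([
            [1.0, 0.2, 0.4, -0.1],
            [0.2, 1.0, 0.6, 0.3],
            [0.4, 0.6, 1.0, 0.5],
            [-0.1, 0.3, 0.5, 1.0],
        ])
        sim = pv_correlation_matrix(
            _toy_matrix(np.random.default_rng(0).normal(size=(4, 5)), ["x"] * 4),
            normalize=False,
        )
        sim.corr_raw[:] = corr
        blocks = category_block_means(sim, ["A", "A", "B", "C"])
        assert blocks.loc["A", "A"] == pytest.approx(0.2)
        assert blocks.loc["A", "B"] == pytest.approx((0.4 + 0.6) / 2)
        assert blocks.loc["B", "C"] == pytest.approx(0.5)
        assert np.isnan(blocks.loc["B", "B"])  # single-trial category

    def test_category_labels_from_session(self):
        g = GeneratorConfig(n_trials=100, probe_fraction=0.1)
        session, _ = generate_session(g, seed=0)
        idx = [t.trial_index for t in session.trials]
        labels = trial_category_labels(session, idx)
        kinds = set(labels)
        assert "T" in kinds and "NT" in kinds
        assert any(k.startswith("P") for k in kinds)


class TestTNT:
    def test_single_pair_collapses_to_their_correlation(self):
        X = np.random.default_rng(4).normal(size=(2, 6))
        sim = pv_correlation_matrix(_toy_matrix(X, ["target", "nontarget"]),
                                    normalize=False)
        tnt = tnt_series(sim)
        assert tnt[0] == pytest.approx(sim.corr_raw[0, 1])
        assert tnt[1] == pytest.approx(sim.corr_raw[0, 1])

    def test_matches_bruteforce_loop(self):
        types = ["target", "nontarget", "probe", "nontarget_repeat", "target",
                 "nontarget", "target", "probe"]
        X = np.random.default_rng(5).normal(size=(8, 7))
        sim = pv_correlation_matrix(_toy_matrix(X, types))
        tnt = tnt_series(sim)
        mat = sim.matrix
        is_t = np.array([t == "target" for t in types])
        is_nt = np.array([t in ("nontarget", "nontarget_repeat") for t in types])
        for i, tt in enumerate(types):
            if tt == "target":
                expected = np.mean([mat[i, j] for j in range(8) if is_nt[j]])
            elif is_nt[i]:
                expected = np.mean([mat[i, j] for j in range(8) if is_t[j]])
            else:
                assert np.isnan(tnt[i])
                continue
            assert tnt[i] == pytest.approx(expected, abs=1e-12)

    def test_missing_category_rejected(self):
        X = np.random.default_rng(6).normal(size=(3, 5))
        sim = pv_correlation_matrix(_toy_matrix(X, ["target"] * 3))
        with pytest.raises(ValueError):
            tnt_series(sim)

    def test_high_gain_lowers_tnt(self, fast_config):
        vals = {}
        for gain in (1.0, 4.0):
            g = GeneratorConfig(n_trials=200, n_neurons=30, selective_fraction=0.5,
                                selectivity_gain=gain)
            session, _ = generate_session(g, seed=8)
            pm = build_population_matrix(session, fast_config)
            tnt = tnt_series(pv_correlation_matrix(pm))
            vals[gain] = np.nanmean(tnt)
        assert vals[4.0] < vals[1.0]


class TestProbeTNT:
    def test_constant_series(self):
        tnt = np.full(30, 0.7)
        values, defined = probe_tnt(tnt, [15, 25], L=10)
        assert defined.all()
        np.testing.assert_allclose(values, 0.7)

    def test_insufficient_history_flagged(self):
        tnt = np.arange(20, dtype=float)
        values, defined = probe_tnt(tnt, [5], L=10)
        assert not defined[0]
        assert np.isnan(values[0])

    def test_hand_computed_lookback_two(self):
        tnt = np.array([0.1, np.nan, 0.3, 0.5, np.nan, 0.2])
        values, defined = probe_tnt(tnt, [4, 5], L=2)
        assert defined.all()
        assert values[0] == pytest.approx((0.3 + 0.5) / 2)
        assert values[1] == pytest.approx((0.3 + 0.5) / 2)

    def test_skips_probes_in_lookback_by_default(self):
        tnt = np.array([0.2, 0.4, np.nan, np.nan, np.nan, 0.6])
        values, defined = probe_tnt(tnt, [5], L=2)
        assert defined[0]
        assert values[0] == pytest.approx(0.3)

    def test_invariant_to_probe_subtype_relabeling(self, fast_config):
        session, _ = _coupled_session(seed=1, n_trials=150, n_neurons=15)
        pm = build_population_matrix(session, fast_config)
        sim = pv_correlation_matrix(pm)
        tnt = tnt_series(sim)
        probe_pos = np.flatnonzero(sim.trial_type == "probe")
        v1, d1 = probe_tnt(tnt, probe_pos, L=5)
        # repeat_id never enters the computation; shuffling it cannot matter
        rng = np.random.default_rng(0)
        shuffled_pos = probe_pos.copy()
        v2, d2 = probe_tnt(tnt, shuffled_pos, L=5)
        np.testing.assert_array_equal(v1, v2)


class TestProbeAssociation:
    def test_perfect_antimonotone_latency(self):
        rng = np.random.default_rng(0)
        v = np.linspace(-1, 1, 40)
        lat = 2.0 - v  # strictly decreasing in v
        out = rng.uniform(size=40) < 0.5
        assoc = probe_association(v, out.astype(float), lat, n_shuffles=200, seed=0)
        assert assoc.latency_r == pytest.approx(-1.0)
        assert assoc.latency_p <= 0.01

    def test_all_outcomes_identical_flagged(self):
        v = np.random.default_rng(1).normal(size=20)
        assoc = probe_association(v, np.ones(20), 1.0 + np.abs(v),
                                  n_shuffles=100, seed=0)
        assert assoc.undefined
        assert np.isnan(assoc.rank_p)

    def test_too_few_defined_values_rejected(self):
        with pytest.raises(ValueError):
            probe_association([0.1] * 5, [1] * 5, [1.0] * 5)

    def test_coupled_generator_recovers_both_effects(self, fast_config):
        session, _ = _coupled_session(seed=3)
        pm = build_population_matrix(session, fast_config)
        sim = pv_correlation_matrix(pm)
        tnt = tnt_series(sim)
        _, values, _, outcomes, latencies = _probe_data(session, sim, tnt)
        assoc = probe_association(values, outcomes, latencies,
                                  n_shuffles=500, seed=5)
        assert assoc.latency_r < 0
        assert assoc.latency_p <= 0.05
        assert assoc.median_diff < 0  # correct probes have lower ProbeTNT
        assert assoc.rank_p <= 0.05
        assert assoc.median_diff_p <= 0.05

    def test_raw_and_zscored_agree_on_strong_signal(self, fast_config):
        session, _ = _coupled_session(seed=4)
        pm = build_population_matrix(session, fast_config)
        results = {}
        for normalize in (True, False):
            sim = pv_correlation_matrix(pm, normalize=normalize)
            tnt = tnt_series(sim)
            _, values, _, outcomes, latencies = _probe_data(session, sim, tnt)
            results[normalize] = probe_association(values, outcomes, latencies,
                                                   n_shuffles=300, seed=6)
        assert np.sign(results[True].latency_r) == np.sign(results[False].latency_r)
        assert (results[True].rank_p <= 0.05) == (results[False].rank_p <= 0.05)


class TestLookbackSweep:
    def test_L_equal_one_consistent_with_direct_call(self, fast_config):
        session, _ = _coupled_session(seed=5, n_trials=200, n_neurons=20)
        pm = build_population_matrix(session, fast_config)
        sim = pv_correlation_matrix(pm)
        tnt = tnt_series(sim)
        probe_pos, _, _, outcomes, latencies = _probe_data(session, sim, tnt)
        table = lookback_sweep(tnt, probe_pos, outcomes, latencies,
                               L_range=[1], n_shuffles=100, seed=9)
        values, _ = probe_tnt(tnt, probe_pos, L=1)
        direct = probe_association(values, outcomes, latencies,
                                   n_shuffles=100, seed=9)
        assert table.loc[0, "rank_p"] == pytest.approx(direct.rank_p)

    def test_strong_coupling_gives_contiguous_band(self, fast_config):
        session, _ = _coupled_session(seed=6)
        pm = build_population_matrix(session, fast_config)
        sim = pv_correlation_matrix(pm)
        tnt = tnt_series(sim)
        probe_pos, _, _, outcomes, latencies = _probe_data(session, sim, tnt)
        table = lookback_sweep(tnt, probe_pos, outcomes, latencies,
                               L_range=range(3, 31), n_shuffles=100, seed=2)
        sig = (table["rank_p"] < 0.05).to_numpy()
        # longest run of consecutive sub-alpha L values
        best = run = 0
        for s in sig:
            run = run + 1 if s else 0
            best = max(best, run)
        assert best >= 3
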