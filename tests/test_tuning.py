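"""Single-neuron tuning statistics: modulation, cosine fits, variability."""

import numpy as np
import pytest
from scipy import stats

from oromotor.simulate import simulate_rate_samples
from oromotor.tuning import (
    CosineTuning,
    bootstrap_modulation_test,
    circular_k_test,
    cosine_fit,
    directional_index,
    drinking_pd_bootstrap,
    fano,
    mean_matched_fano,
    octant_unit_vectors,
    peth,
    proportion_comparison,
    rayleigh_test_sphere,
    tuning_summary,
    rate_matrix_from_session,
)


class TestBootstrapModulation:
    def test_constant_rates_not_modulated(self):
        rates = np.full((80, 1), 12.0)
        labels = np.repeat(list("ABCDEFGH"), 10)
        res = bootstrap_modulation_test(rates, labels, B=200, seed=0)
        assert not res.loc[0, "modulated"]

    def test_strong_single_octant_modulation_detected(self, rng):
        labels = np.repeat(list("ABCDEFGH"), 50)
        hits = 0
        for rep in range(20):
            lam = np.where(labels == "A", 4.0, 2.0)  # 2x rate in one direction
            rates = rng.poisson(lam)[:, None] / 0.1
            res = bootstrap_modulation_test(rates, labels, B=500, seed=rep)
            hits += int(res.loc[0, "modulated"])
        assert hits >= 19

    def test_needs_two_directions(self):
        with pytest.raises(ValueError, match="two directions"):
            bootstrap_modulation_test(np.ones((10, 1)), np.repeat("A", 10))

    def test_deterministic_given_seed(self, rng):
        rates = rng.poisson(2.0, size=(160, 3)).astype(float)
        labels = np.repeat(list("ABCDEFGH"), 20)
        a = bootstrap_modulation_test(rates, labels, B=300, seed=9)
        b = bootstrap_modulation_test(rates, labels, B=300, seed=9)
        assert a.equals(b)


class TestCosineFit:
    def test_noiseless_identity_recovers_pd(self):
        cent = octant_unit_vectors()
        labels = np.array(list(cent) * 5)
        p = np.array([0.0, 0.0, 1.0])
        rates = np.array([10.0 + 5.0 * (cent[l] @ p) for l in labels])
        fit = cosine_fit(rates, labels)
        assert fit["R2"] == pytest.approx(1.0)
        assert np.allclose(fit["PD"], p, atol=1e-9)
        assert fit["b0"] == pytest.approx(10.0)

    def test_constant_rates_not_significant(self):
        cent = octant_unit_vectors()
        labels = np.array(list(cent) * 5)
        fit = cosine_fit(np.full(len(labels), 7.0), labels)
        assert fit["F_p"] > 0.05
        assert fit["PD"] is None

    def test_pd_invariant_to_baseline_shift(self, rng):
        rates, labels, _, _ = simulate_rate_samples(1, 30, seed=3)
        f1 = cosine_fit(rates[:, 0], labels)
        f2 = cosine_fit(rates[:, 0] + 50.0, labels)
        assert np.allclose(f1["PD"], f2["PD"], atol=1e-9)

    def test_recovery_improves_with_samples(self):
        """Median angular PD error decreases as samples per octant grow."""
        med = []
        for spo in (10, 50, 200):
            rates, labels, _, gt = simulate_rate_samples(
                60, spo, baseline=20, modulation=20, seed=40 + spo)
            errs = []
            for j in range(60):
                fit = cosine_fit(rates[:, j], labels)
                if fit["PD"] is not None:
                    errs.append(np.degrees(np.arccos(
                        np.clip(fit["PD"] @ gt.pd[j], -1, 1))))
            med.append(np.median(errs))
        assert med[0] > med[1] > med[2]

    def test_rank_deficient_design_rejected(self):
        U = np.tile(np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1]]), (4, 1))
        with pytest.raises(ValueError):
            CosineTuning().fit(U, np.ones(12))


class TestDirectionalIndex:
    @pytest.mark.parametrize("means, expected", [
        ([5, 5, 5, 5], 0.0),
        ([0, 3, 8, 10], 1.0),
        ([10, 5], 0.5),
    ])
    def test_formula(self, means, expected):
        assert directional_index(means) == pytest.approx(expected)

    def test_invariant_to_rate_scaling(self, rng):
        means = rng.uniform(2, 20, 8)
        assert directional_index(means) == pytest.approx(directional_index(5.0 * means))

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            directional_index([0.0, 0.0])


class TestDrinkingPDBootstrap:
    def test_dominant_spout_probability_one(self):
        rates = np.array([10.0] * 5 + [2.0] * 5 + [2.5] * 5)
        spouts = np.array(["L"] * 5 + ["M"] * 5 + ["R"] * 5)
        out = drinking_pd_bootstrap(rates, spouts, B=500, seed=0)
        assert out["mode"] == "L"
        assert out["probs"]["L"] == 1.0

    def test_exchangeable_rates_uniform_across_datasets(self):
        """With exchangeable rates no spout is preferred on average.

        Within any one finite dataset the bootstrap argmax concentrates on
        the spout that happened to have the larger sample mean, so
        uniformity is a property of the average over replicate datasets,
        not of a single one.
        """
        local = np.random.default_rng(7)
        spouts = np.repeat(["L", "M", "R"], 20)
        avg = {"L": 0.0, "M": 0.0, "R": 0.0}
        reps = 60
        for rep in range(reps):
            rates = local.normal(10, 1, 60)
            out = drinking_pd_bootstrap(rates, spouts, B=300, seed=rep)
            for k, v in out["probs"].items():
                avg[k] += v / reps
        for p in avg.values():
            assert p == pytest.approx(1.0 / 3.0, abs=0.07)

    def test_deterministic_given_seed(self, rng):
        rates = rng.normal(10, 2, 30)
        spouts = np.repeat(["L", "M", "R"], 10)
        a = drinking_pd_bootstrap(rates, spouts, B=400, seed=5)
        b = drinking_pd_bootstrap(rates, spouts, B=400, seed=5)
        assert a == b


class TestFano:
    def test_reference_values(self):
        assert fano([1, 3]) == pytest.approx(1.0)   # var 2 / mean 2
        assert fano([4, 4, 4, 4]) == 0.0

    def test_poisson_counts_near_one(self, rng):
        assert fano(rng.poisson(3.0, 2000)) == pytest.approx(1.0, abs=0.1)

    def test_zero_mean_undefined(self):
        with pytest.raises(ValueError):
            fano([0, 0, 0])

    def test_mean_matched_controls_rate_confound(self, rng):
        # same Poisson statistics, one group at doubled rates: matched FFs ~ 1
        g1 = [rng.poisson(lam, 200) for lam in rng.uniform(1, 6, 60)]
        g2 = [rng.poisson(lam, 200) for lam in rng.uniform(2, 12, 60)]
        out = mean_matched_fano({"a": g1, "b": g2}, seed=0)
        assert out["a"] == pytest.approx(1.0, abs=0.15)
        assert out["b"] == pytest.approx(1.0, abs=0.15)


class TestRayleighSphere:
    def test_identical_pds_highly_significant(self):
        pds = np.tile([0.0, 0.0, 1.0], (12, 1))
        _, p = rayleigh_test_sphere(pds)
        assert p < 1e-6

    def test_antipodal_pairs_null(self):
        v = np.array([1.0, 0, 0])
        pds = np.vstack([v, -v] * 5)
        stat, p = rayleigh_test_sphere(pds)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_null_pvalues_uniform(self, rng):
        """Under a uniform sphere distribution p-values are U(0, 1)."""
        pvals = []
        for _ in range(1000):
            v = rng.standard_normal((40, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pvals.append(rayleigh_test_sphere(v)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_non_unit_inputs_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            rayleigh_test_sphere(np.ones((6, 3)))


class TestCircularKTest:
    def test_same_concentration_null_rate(self, rng):
        rejections = 0
        reps = 200
        for _ in range(reps):
            a = rng.vonmises(0.0, 4.0, 60)
            b = rng.vonmises(0.0, 4.0, 60)
            rejections += circular_k_test(a, b)[1] < 0.05
        assert 0.02 <= rejections / reps <= 0.10

    def test_concentration_difference_detected(self, rng):
        hits = 0
        reps = 40
        with np.errstate(all="ignore"):
            for _ in range(reps):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    a = rng.vonmises(0.0, 1.0, 100)
                    b = rng.vonmises(0.0, 10.0, 100)
                    hits += circular_k_test(a, b)[1] < 0.01
        assert hits / reps >= 0.90

    def test_identical_samples_not_significant(self, rng):
        a = rng.vonmises(0.5, 5.0, 50)
        f, p = circular_k_test(a, a.copy())
        assert f == pytest.approx(1.0)
        assert p > 0.05

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            circular_k_test(np.zeros(10), np.linspace(0, 1, 10))


class TestProportionComparison:
    def test_equal_proportions_statistic_zero(self):
        stat, p = proportion_comparison([50, 50], [100, 100])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_difference_significant(self):
        _, p = proportion_comparison([80, 52], [100, 100])
        assert p < 0.001

    def test_three_identical_groups(self):
        stat, p = proportion_comparison([30, 30, 30], [50, 50, 50])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            proportion_comparison([0, 5], [0, 10])


class TestPETH:
    def test_spikes_at_event_time_peak_at_zero(self, rng):
        events = np.arange(10.0, 200.0, 10.0)
        out = peth(events.copy(), events, window=(-0.5, 0.5))
        assert abs(out.loc[out["rate"].idxmax(), "time_s"]) < 0.01

    def test_wider_kernel_lowers_peak(self, rng):
        events = np.arange(10.0, 200.0, 10.0)
        spikes = np.concatenate([events + rng.normal(0, 0.02, events.size)
                                 for _ in range(3)])
        narrow = peth(spikes, events, kernel_sd=0.025)
        wide = peth(spikes, events, kernel_sd=0.050)
        assert wide["rate"].max() <= narrow["rate"].max()

    def test_constant_rate_flat_within_se(self, rng):
        spikes = np.sort(rng.uniform(0, 400, 8000))  # 20 spikes/s homogeneous
        events = np.arange(20.0, 380.0, 4.0)
        out = peth(spikes, events, window=(-0.5, 0.5))
        grand = out["rate"].mean()
        cover = np.mean(np.abs(out["rate"] - grand) <= 3.0 * out["se"])
        assert cover > 0.95
        assert grand == pytest.approx(20.0, rel=0.1)

    def test_requires_events(self):
        with pytest.raises(ValueError):
            peth(np.arange(10.0), np.array([1.0]))


class TestTuningSummaryEndToEnd:
    def test_feeding_summary_recovers_ground_truth(self, feeding_session):
        rm = rate_matrix_from_session(feeding_session, balance=True, seed=1)
        table = tuning_summary(rm, B=400, seed=1)
        gt = feeding_session.ground_truth
        tuned = {n: t for n, t in zip(gt["neuron_ids"], gt["tuned"])}
        # tuned neurons are flagged much more often than untuned ones
        flag_tuned = table.loc[[tuned[n] for n in table["neuron_id"]], "modulated"].mean()
        flag_untuned = table.loc[[not tuned[n] for n in table["neuron_id"]], "modulated"].mean()
        assert flag_tuned > 0.7
        assert flag_untuned < 0.3
        # PDs of significantly fit tuned neurons point near the true PD
        errs = []
        for _, row in table.iterrows():
            gi = list(gt["neuron_ids"]).index(row["neuron_id"])
            if gt["tuned"][gi] and np.isfinite(row["pd_x"]):
                pd_hat = np.array([row["pd_x"], row["pd_y"], row["pd_z"]])
                errs.append(np.degrees(np.arccos(
                    np.clip(pd_hat @ np.array(gt["pd"][gi]), -1, 1))))
        assert np.median(errs) < 30.0

    def test_drinking_summary_has_spout_preferences(self, drinking_session):
        rm = rate_matrix_from_session(drinking_session)
        table = tuning_summary(rm, B=300, seed=2)
        assert set(table["preferred_spout"]).issubset({"L", "M", "R"})
        probs = table[["p_L", "p_M", "p_R"]].to_numpy().sum(axis=1)
        assert np.allclose(probs, 1.0)
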