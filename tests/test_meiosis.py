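"""Meiotic segregation model: multivalents, gametes, F2 ratios, estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from translokit.meiosis import (
    AlternateFreqEstimate,
    EventCarrier,
    KaryotypeConfig,
    MeiosisError,
    SegregationParams,
    enumerate_gametes,
    estimate_alternate_frequency,
    expected_f2_segregation,
    predict_diakinesis_configuration,
    predict_sterility_and_seed_reduction,
    simulate_cross,
    uniform_chain_table,
)


def het_config(k: int, pairs: int = 11) -> KaryotypeConfig:
    return KaryotypeConfig(pairs, [EventCarrier(f"E{i + 1}") for i in range(k)])


class TestDiakinesis:
    def test_one_heterozygous_reciprocal(self):
        out = predict_diakinesis_configuration(het_config(1))
        assert out == {"bivalents": 9, "quadrivalents": 1}

    def test_two_independent_reciprocals(self):
        out = predict_diakinesis_configuration(het_config(2))
        assert out == {"bivalents": 7, "quadrivalents": 2}

    def test_homozygotes_all_bivalents(self):
        cfg = KaryotypeConfig(11, [EventCarrier("E1", zygosity="homozygous"),
                                   EventCarrier("E2", zygosity="homozygous")])
        assert predict_diakinesis_configuration(cfg) == {
            "bivalents": 11, "quadrivalents": 0}
        assert predict_diakinesis_configuration(KaryotypeConfig(11, [])) == {
            "bivalents": 11, "quadrivalents": 0}

    def test_chained_event_forms_hexavalent(self):
        cfg = KaryotypeConfig(
            11, [EventCarrier("E1", "complex_chain", n_donors=3)])
        out = predict_diakinesis_configuration(cfg)
        assert out == {"bivalents": 8, "quadrivalents": 0, "multivalent_6": 1}

    def test_overcommitted_karyotype_rejected(self):
        with pytest.raises(MeiosisError):
            KaryotypeConfig(3, [EventCarrier("E1"), EventCarrier("E2")])


class TestGametes:
    def test_forced_alternate(self):
        dist = enumerate_gametes(het_config(1), SegregationParams(1.0))
        assert sorted((c.alleles, round(c.probability, 9), c.balanced)
                      for c in dist.classes) == [
            (("N",), 0.5, True), (("T",), 0.5, True)]

    def test_classical_half_alternate(self):
        dist = enumerate_gametes(het_config(1), SegregationParams(0.5))
        assert dist.balanced_fraction == pytest.approx(0.5)

    def test_two_events_sixteen_zygote_enumeration(self):
        """a=0.5 each: balanced gamete fraction 1/4, with 4 balanced classes
        of 1/16 each — the four fertile gamete types that combine into the
        16 zygote types on selfing."""
        dist = enumerate_gametes(het_config(2), SegregationParams(0.5))
        assert dist.balanced_fraction == pytest.approx(0.25)
        balanced = [c for c in dist.classes if c.balanced]
        assert len(balanced) == 4
        for c in balanced:
            assert c.probability == pytest.approx(1 / 16)

    def test_chain_requires_table(self):
        cfg = KaryotypeConfig(11, [EventCarrier("E1", "complex_chain", 3)])
        with pytest.raises(MeiosisError, match="segregation table"):
            enumerate_gametes(cfg, SegregationParams())
        table = uniform_chain_table(3)
        assert table["N"] == table["T"] == pytest.approx(1 / 20)
        dist = enumerate_gametes(cfg, SegregationParams(complex_table=table))
        assert dist.balanced_fraction == pytest.approx(0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a1=st.floats(0.0, 1.0), a2=st.floats(0.0, 1.0))
    def test_probabilities_always_sum_to_one(self, a1, a2):
        cfg = het_config(2)
        params = SegregationParams({"E1": a1, "E2": a2})
        dist = enumerate_gametes(cfg, params)
        assert sum(c.probability for c in dist.classes) == pytest.approx(1.0)


class TestExpectedF2:
    @pytest.mark.parametrize("k,ratio,fertile", [
        (0, (1, 0), 1.0),
        (1, (1, 1), 0.5),
        (2, (1, 3), 0.25),
    ])
    def test_normal_to_semisterile(self, k, ratio, fertile):
        out = expected_f2_segregation(het_config(k))
        assert out["normal_to_semisterile"] == ratio
        assert out["fully_homozygous_fraction"] == pytest.approx(fertile)
        for probs in out["genotype_probs"].values():
            assert probs == {"NN": 0.25, "NT": 0.5, "TT": 0.25}

    def test_fertile_fraction_halves_per_event(self):
        fracs = [expected_f2_segregation(het_config(k, pairs=11))
                 ["fully_homozygous_fraction"] for k in range(0, 5)]
        for a, b in zip(fracs, fracs[1:]):
            assert b == pytest.approx(a / 2)


class TestSimulation:
    def test_partition_sums(self):
        df = simulate_cross(het_config(1), het_config(1), SegregationParams(),
                            237, seed=11)
        assert len(df) == 237
        assert set(df["E1"]) <= {"NN", "NT", "TT"}
        assert df["E1"].value_counts().sum() == 237

    def test_deterministic_for_seed(self):
        a = simulate_cross(het_config(2), het_config(2), SegregationParams(), 500, seed=3)
        b = simulate_cross(het_config(2), het_config(2), SegregationParams(), 500, seed=3)
        assert a.equals(b)

    def test_large_sample_matches_theory(self):
        """Empirical class frequencies converge to the analytic expectation
        within 3 binomial SE at n = 1e5."""
        n = 100_000
        df = simulate_cross(het_config(1), het_config(1), SegregationParams(),
                            n, seed=29)
        het = (df["E1"] == "NT").mean()
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(het - 0.5) < 3 * se
        semi = (df["phenotype"] == "semi_sterile").mean()
        assert abs(semi - 0.5) < 3 * se

    def test_wt_by_homozygous_tl_all_heterozygous(self):
        wt = KaryotypeConfig(11, [])
        tl = KaryotypeConfig(11, [EventCarrier("E1", zygosity="homozygous")])
        df = simulate_cross(wt, tl, SegregationParams(), 100, seed=1)
        assert (df["E1"] == "NT").all()
        assert (df["phenotype"] == "semi_sterile").all()


class TestSterility:
    def test_classical_half(self):
        s, seed_red = predict_sterility_and_seed_reduction(
            het_config(1), SegregationParams(0.5))
        assert s == pytest.approx(0.5) and seed_red == pytest.approx(0.5)

    def test_inverts_observed_rate(self):
        """a = 0.5193 reproduces the observed 48.07% pollen sterility of a
        single-quadrivalent heterozygote."""
        s, _ = predict_sterility_and_seed_reduction(
            het_config(1), SegregationParams(0.5193))
        assert s == pytest.approx(0.4807)

    def test_no_events_fully_fertile(self):
        s, seed_red = predict_sterility_and_seed_reduction(KaryotypeConfig(11, []))
        assert s == 0.0 and seed_red == 0.0

    def test_asymmetric_ovule_viability_hook(self):
        params = SegregationParams(0.5, ovule_alternate_freq=0.8)
        s, seed_red = predict_sterility_and_seed_reduction(het_config(1), params)
        assert s == pytest.approx(0.5) and seed_red == pytest.approx(0.2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(0.0, 1.0), delta=st.floats(0.0, 0.2))
    def test_monotone_in_alternate_frequency(self, a, delta):
        hi = min(a + delta, 1.0)
        s_lo, _ = predict_sterility_and_seed_reduction(
            het_config(2), SegregationParams(a))
        s_hi, _ = predict_sterility_and_seed_reduction(
            het_config(2), SegregationParams(hi))
        assert s_hi <= s_lo + 1e-12


class TestEstimator:
    @pytest.mark.parametrize("sterility,k,expected", [
        (0.5, 1, 0.5),
        (0.75, 2, 0.5),
        (0.7429, 2, (1 - 0.7429) ** 0.5),  # observed two-quadrivalent rate
    ])
    def test_point_estimates(self, sterility, k, expected):
        est = estimate_alternate_frequency(sterility, k, 10_000)
        assert est.a_hat == pytest.approx(expected, abs=1e-9)
        assert est.ci[0] < est.a_hat < est.ci[1]

    def test_estimate_matches_printed_value(self):
        # (0.2571)^(1/2) ~= 0.507
        est = estimate_alternate_frequency(0.7429, 2, 10_000)
        assert est.a_hat == pytest.approx(0.507, abs=0.001)

    def test_degenerate_full_sterility(self):
        with pytest.warns(UserWarning):
            est = estimate_alternate_frequency(1.0, 1, 100)
        assert est.a_hat == 0.0

    def test_round_trip_with_prediction(self):
        for a in (0.3, 0.5, 0.9):
            for k in (1, 2, 3):
                s, _ = predict_sterility_and_seed_reduction(
                    het_config(k), SegregationParams(a))
                est = estimate_alternate_frequency(s, k, 10_000)
                assert est.a_hat == pytest.approx(a, abs=1e-9)

    def test_ci_coverage(self):
        """Wilson-transformed CI covers the generating value in ~95% of
        binomial replicates (the 200-replicate check runs in acceptance)."""
        rng = np.random.default_rng(17)
        a_true, k, n = 0.5, 1, 10_000
        sterile_p = 1 - a_true ** k
        hits = 0
        reps = 60
        for _ in range(reps):
            s = rng.binomial(n, sterile_p) / n
            est = estimate_alternate_frequency(s, k, n)
            hits += est.ci[0] <= a_true <= est.ci[1]
        assert hits / reps >= 0.9
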