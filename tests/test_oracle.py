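"""AP score, synthetic CGMD-surrogate landscape, and noise-model behaviour."""

import numpy as np
import pytest

from pepal.fixtures import landscape_summary
from pepal.oracle import (
    CachedOracle,
    ExternalOracle,
    OracleMeasurement,
    SyntheticOracle,
    SyntheticOracleConfig,
    ap_score,
    measure,
    read_label_cache,
    replicate_sigma,
    replicate_stats,
    true_ap,
    write_label_cache,
)
from pepal.peptides import enumerate_space, sample_space
import random


class TestApScore:
    def test_identity_ratio(self):
        assert ap_score(123.4, 123.4) == 1.0

    def test_two_to_one_burial(self):
        assert ap_score(150.0, 75.0) == 2.0

    def test_scale_invariance(self):
        assert ap_score(7 * 3.3, 7 * 1.1) == pytest.approx(ap_score(3.3, 1.1))

    @pytest.mark.parametrize("bad", [(0, 1), (1, 0), (-1, 2)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            ap_score(*bad)

    def test_measurement_recomputes_ap(self):
        m = OracleMeasurement("AAA", sasa_initial=200.0, sasa_final=100.0, replicate_seed=0)
        assert m.ap == 2.0
        assert m.ap * m.sasa_final == pytest.approx(m.sasa_initial)


class TestTrueAp:
    def test_zero_weights_hit_logistic_midpoint(self):
        cfg = SyntheticOracleConfig(weights={aa: 0.0 for aa in "ACDEFGHIKLMNPQRSTVWY"},
                                    logistic_mid=0.0)
        lo, hi = cfg.ap_floor, cfg.ap_ceiling(3)
        assert true_ap("AAA", cfg) == pytest.approx((lo + hi) / 2)

    def test_aromatics_outscore_polar(self, oracle_config):
        assert true_ap("FFF", oracle_config) > true_ap("SSS", oracle_config)

    def test_dipeptide_ceiling_brute_force(self, oracle_config):
        aps = [true_ap(p, oracle_config) for p in enumerate_space(2)]
        assert max(aps) <= oracle_config.ap_ceiling(2)
        assert min(aps) >= oracle_config.ap_floor

    def test_pure_function(self, oracle_config):
        assert true_ap("WFW", oracle_config) == true_ap("WFW", oracle_config)

    def test_monotone_in_propensity_sum(self, oracle_config):
        # weight ordering at residue level carries to sequence level
        assert (
            true_ap("WWW", oracle_config)
            > true_ap("LLL", oracle_config)
            > true_ap("AAA", oracle_config)
            > true_ap("EEE", oracle_config)
        )

    def test_ceiling_decreases_with_length(self, oracle_config):
        ceilings = [oracle_config.ap_ceiling(L) for L in range(3, 9)]
        assert all(a > b for a, b in zip(ceilings, ceilings[1:]))


class TestMeasure:
    def test_noiseless_config_equals_truth(self, noiseless_config):
        m = measure("WFW", noiseless_config, replicate_seed=3)
        assert m.ap == pytest.approx(true_ap("WFW", noiseless_config))

    def test_deterministic_per_seed_pair(self, oracle_config):
        a = measure("WFW", oracle_config, replicate_seed=7)
        b = measure("WFW", oracle_config, replicate_seed=7)
        c = measure("WFW", oracle_config, replicate_seed=8)
        assert a.ap == b.ap and a.ap != c.ap

    def test_sasa_invariant_holds_for_every_measurement(self, oracle_config):
        for seed in range(20):
            m = measure("FFYK", oracle_config, replicate_seed=seed)
            assert m.ap * m.sasa_final == pytest.approx(m.sasa_initial, rel=1e-12)

    def test_replicate_std_matches_configured_sigma(self, oracle_config):
        # Monte-Carlo: sample std of replicates within 15% of the model sigma
        pep = "WFW"  # high-AP peptide, sigma at the cap
        truth = true_ap(pep, oracle_config)
        sigma = min(oracle_config.noise_slope * (truth - 1.0), oracle_config.noise_cap)
        aps = [measure(pep, oracle_config, s).ap for s in range(1000)]
        assert np.std(aps, ddof=1) == pytest.approx(sigma, rel=0.15)

    def test_mean_recovers_truth_clt(self, oracle_config):
        pep = "FFA"
        truth = true_ap(pep, oracle_config)
        mean, std, _, _ = replicate_stats(pep, oracle_config, n=1000)
        sigma = min(oracle_config.noise_slope * max(0, truth - 1), oracle_config.noise_cap)
        assert abs(mean - truth) < 3 * sigma / np.sqrt(1000)


class TestReplicateStats:
    def test_noise_free_std_zero(self, noiseless_config):
        _, std, lo, hi = replicate_stats("FFF", noiseless_config, n=5)
        assert std == 0.0 and lo == hi

    def test_reproducible_tuple(self, oracle_config):
        assert replicate_stats("WAY", oracle_config, n=5) == replicate_stats(
            "WAY", oracle_config, n=5
        )

    def test_needs_two_replicates(self, oracle_config):
        with pytest.raises(ValueError):
            replicate_stats("AAA", oracle_config, n=1)


class TestNoiseStructure:
    def test_replicate_std_monotone_in_ap_ladder(self, oracle_config):
        # a ladder of sequences spanning the AP range: model sigma must be
        # non-decreasing in true AP (heteroscedastic replicate error)
        ladder = ["EEE", "KDS", "GGG", "AAG", "PAA", "LAA", "LLA", "ILV", "FLW", "WWW"]
        ladder.sort(key=lambda p: true_ap(p, oracle_config))
        sigmas = [
            min(
                oracle_config.noise_slope * max(0.0, true_ap(p, oracle_config) - 1.0),
                oracle_config.noise_cap,
            )
            for p in ladder
        ]
        assert all(a <= b + 1e-12 for a, b in zip(sigmas, sigmas[1:]))
        # and the empirical stds follow the same ordering within noise
        stds = [replicate_stats(p, oracle_config, n=300)[1] for p in ladder]
        assert stds[0] < stds[-1]

    def test_replicate_sigma_bounded_below_012_everywhere(self, oracle_config):
        # the model replicate std is capped strictly below 0.12 for every
        # peptide; sample stds track it to within sampling error
        peps = sample_space(3, 50, random.Random(5))
        for pep in peps:
            sigma = replicate_sigma(pep, oracle_config)
            assert sigma < 0.12
            aps = [measure(pep, oracle_config, s).ap for s in range(200)]
            sample_std = np.std(aps, ddof=1)
            # chi-distribution tolerance: ~5 sampling sds at n = 200
            assert abs(sample_std - sigma) < 5 * 0.119 / np.sqrt(2 * 199)

    def test_ap_range_narrows_with_chain_length(self, oracle_config):
        r3 = landscape_summary(oracle_config, length=3, n_sample=800, seed=0)["range"]
        r6 = landscape_summary(oracle_config, length=6, n_sample=800, seed=0)["range"]
        assert r3 > r6


class TestOracleAdapters:
    def test_synthetic_oracle_batches(self, oracle_config):
        orc = SyntheticOracle(oracle_config)
        labels = orc.label(["AAA", "WWW"], iteration_seed=1)
        assert set(labels) == {"AAA", "WWW"}
        assert labels["WWW"] > labels["AAA"]

    def test_label_cache_roundtrip(self, tmp_path, oracle_config):
        ms = [measure(p, oracle_config, 0) for p in ["AAA", "WFW"]]
        path = tmp_path / "cache.csv"
        write_label_cache(path, ms, oracle_id="synthetic")
        cache = read_label_cache(path)
        assert cache == {m.sequence: m.ap for m in ms}

    def test_cached_oracle_refuses_unknown(self):
        orc = CachedOracle({"AAA": 1.2})
        assert orc.label(["AAA"]) == {"AAA": 1.2}
        with pytest.raises(KeyError):
            orc.label(["WWW"])

    def test_external_adapter_file_contract(self, tmp_path):
        req, resp = tmp_path / "request.txt", tmp_path / "response.csv"
        orc = ExternalOracle(req, resp)
        with pytest.raises(RuntimeError):
            orc.label(["AAA"])
        assert req.read_text() == "AAA\n"
        resp.write_text("sequence,sasa_initial_nm2,sasa_final_nm2\nAAA,200.0,100.0\n")
        assert orc.label(["AAA"]) == {"AAA": 2.0}
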