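"""Synthetic study generator: seasonal structure, internal consistency,
forward-model exactness and determinism."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from coralcf.constants import (
    DomainError,
    SeawaterConditions,
    constants_for,
    dic_from_ph_co3,
)
from coralcf.boron import omega as omega_of
from coralcf.synthetic import (
    GeneratorParams,
    forward_geochem,
    gen_calcification,
    gen_cf_cycles,
    gen_environment,
    generate_study,
    noise_sigma_for_r2,
)
from coralcf import pipeline


def _winter_mask(dates):
    return np.array(
        [
            (d.month == 4 and d.day >= 16) or d.month in (5, 6, 7, 8, 9)
            or (d.month == 10 and d.day <= 15)
            for d in dates
        ]
    )


class TestEnvironment:
    def test_monthly_mean_temperature_range(self):
        env = gen_environment(GeneratorParams(seed=1)).set_index("date")
        monthly = env["temperature"].resample("MS").agg(["mean", "count"])
        complete = monthly[monthly["count"] >= 28]["mean"]
        assert complete.max() - complete.min() == pytest.approx(4.4, abs=0.05)

    def test_par_bounded_with_extremes_attained(self):
        env = gen_environment(GeneratorParams(seed=1))
        assert env["PAR"].min() >= 15.0 - 1e-9
        assert env["PAR"].max() <= 48.0 + 1e-9
        assert env["PAR"].min() == pytest.approx(15.0, rel=0.02)
        assert env["PAR"].max() == pytest.approx(48.0, rel=0.02)

    def test_phsw_within_published_band(self):
        env = gen_environment(GeneratorParams(seed=1))
        assert env["pH_sw"].between(8.03 - 1e-9, 8.10 + 1e-9).all()

    def test_deterministic_given_seed(self):
        a = gen_environment(GeneratorParams(seed=5))
        b = gen_environment(GeneratorParams(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_inverted_temperature_bounds_rejected(self):
        with pytest.raises(DomainError):
            GeneratorParams(seed=1, T_min=24.0, T_max=20.0)


class TestCfCycles:
    def test_counter_cyclical_construction(self, study_seed1):
        _, _, _, truth = study_seed1
        assert np.corrcoef(truth.pH_cf, truth.temperature)[0, 1] < 0
        assert np.corrcoef(truth.dic_cf, truth.temperature)[0, 1] > 0

    def test_winter_omega_exceeds_summer_at_default_seed(self, study_seed1):
        _, _, _, truth = study_seed1
        winter = _winter_mask(truth.dates)
        assert truth.omega_cf[winter].mean() > truth.omega_cf[~winter].mean()

    def test_flat_ph_makes_omega_procyclical_with_dic(self):
        p = replace(
            GeneratorParams(seed=3).zero_noise(),
            pHcf_summer=8.49, pHcf_winter=8.49, counter_cyclical=False,
        )
        env = gen_environment(p)
        truth = gen_cf_cycles(p, env)
        assert np.corrcoef(truth.omega_cf, truth.dic_cf)[0, 1] > 0.95

    def test_internal_consistency_under_constants_module(self, study_seed1):
        """CO3 and Ω are derived, never free: they must satisfy the same
        equilibria the pipeline uses."""
        _, _, _, truth = study_seed1
        for i in range(len(truth.periods)):
            consts = constants_for(
                SeawaterConditions(float(truth.temperature[i]), truth.salinity)
            )
            dic = dic_from_ph_co3(
                float(truth.pH_cf[i]), float(truth.co3_cf[i]), consts
            )
            assert dic == pytest.approx(truth.dic_cf[i], rel=1e-9)
            om = omega_of(float(truth.co3_cf[i]), consts.Ca, consts.Ksp_arag)
            assert om == pytest.approx(truth.omega_cf[i], rel=1e-12)

    def test_miscoupled_extremes_rejected(self):
        with pytest.raises(DomainError, match="counter-cyclical"):
            GeneratorParams(seed=1, pHcf_summer=8.60, pHcf_winter=8.38)


class TestForwardGeochem:
    def test_zero_noise_pipeline_recovers_truth_exactly(self, study_zero_noise):
        samples, env, rates, truth = study_zero_noise
        env_periods = pipeline.env_period_means(
            env, {r["period"]: pd.Timestamp(r["date"]).date()
                  for _, r in samples.iterrows()},
        )
        recs, _, _ = _as_records(samples)
        per_sample = pipeline.reconstruct_samples(recs, env_periods)
        summ = pipeline.period_summaries(per_sample)
        for var, truth_vals in (
            ("pH_cf", truth.pH_cf), ("dic_cf", truth.dic_cf),
            ("co3_cf", truth.co3_cf), ("omega_cf", truth.omega_cf),
        ):
            got = summ.loc[list(truth.periods), f"{var}_mean"].to_numpy()
            assert got == pytest.approx(truth_vals, rel=1e-6)

    def test_same_seed_identical_tables(self):
        p = GeneratorParams(seed=9)
        a = generate_study(p)[0]
        b = generate_study(p)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_d11b_noise_propagates_with_expected_sign(self):
        """Noise on δ¹¹B alone: a positive pH error raises borate and hence
        the inferred CO3 at fixed B/Ca — errors positively correlated."""
        p = replace(
            GeneratorParams(seed=21).zero_noise(), sigma_d11B=0.3
        )
        env = gen_environment(p)
        truth = gen_cf_cycles(p, env)
        samples = forward_geochem(truth, env, p)
        env_periods = pipeline.env_period_means(
            env, {r["period"]: pd.Timestamp(r["date"]).date()
                  for _, r in samples.iterrows()},
        )
        recs, _, _ = _as_records(samples)
        per_sample = pipeline.reconstruct_samples(recs, env_periods)
        truth_ph = dict(zip(truth.periods, truth.pH_cf))
        truth_co3 = dict(zip(truth.periods, truth.co3_cf))
        ph_err = per_sample["pH_cf"] - per_sample["period"].map(truth_ph)
        co3_err = per_sample["co3_cf"] - per_sample["period"].map(truth_co3)
        assert np.corrcoef(ph_err, co3_err)[0, 1] > 0.5

    def test_negative_noise_sigma_rejected(self):
        with pytest.raises(DomainError):
            GeneratorParams(seed=1, sigma_d11B=-0.1)


class TestCalcification:
    def test_zero_noise_flat_omega_gives_constant_rates(self):
        p = replace(
            GeneratorParams(seed=2).zero_noise(),
            pHcf_summer=8.49, pHcf_winter=8.49,
            DICcf_summer=4000.0, DICcf_winter=4000.0,
            counter_cyclical=False,
        )
        env = gen_environment(p)
        truth = gen_cf_cycles(p, env)
        # flatten residual T-driven variation in omega by overriding truth
        rates = gen_calcification(
            replace_truth_omega(truth, 14.0), env, p
        )
        assert rates["rate"].to_numpy() == pytest.approx(
            [float(rates["rate"].iloc[0])] * len(rates)
        )

    def test_schema_matches_rate_table(self, study_seed1):
        _, _, rates, _ = study_seed1
        assert set(rates.columns) == {"species", "period", "date", "rate", "se", "n"}
        assert (rates["rate"] > 0).all()

    def test_same_seed_identical(self):
        p = GeneratorParams(seed=4)
        env = gen_environment(p)
        truth = gen_cf_cycles(p, env, np.random.default_rng(4))
        a = gen_calcification(truth, env, p, np.random.default_rng(7))
        b = gen_calcification(truth, env, p, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_base_rate_rejected(self):
        with pytest.raises(DomainError):
            GeneratorParams(seed=1, base_rate=0.0)


class TestNoiseSigma:
    def test_closed_form(self):
        # r2 = s/(s+n) -> sigma² = s(1-r2)/r2
        sigma = noise_sigma_for_r2(-0.08, 1.613, 0.8)
        signal = 0.08**2 * 1.613
        assert signal / (signal + sigma**2) == pytest.approx(0.8, rel=1e-12)

    def test_degenerate_r2_rejected(self):
        with pytest.raises(DomainError):
            noise_sigma_for_r2(-0.08, 1.0, 0.0)


def _as_records(samples: pd.DataFrame):
    """Convert a generated geochemistry table to SkeletalSample records."""
    import datetime as dt

    from coralcf.records import SkeletalSample

    recs = [
        SkeletalSample(
            species=r["species"], colony=r["colony"], period=r["period"],
            date=dt.date.fromisoformat(r["date"]), d11B=r["d11B"],
            BCa=r["BCa"], LiMg=r["LiMg"], SrCa=r["SrCa"],
        )
        for _, r in samples.iterrows()
    ]
    return recs, None, None


def replace_truth_omega(truth, value: float):
    """A truth copy with a constant Ω series (isolates rate-noise behaviour)."""
    return replace(truth, omega_cf=np.full_like(truth.omega_cf, value))
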