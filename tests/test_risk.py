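"""Exposure equations, screening rules, distribution fitting, and the
Monte Carlo certainty machinery."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urbansoilrisk import io as uio
from urbansoilrisk import risk
from urbansoilrisk.types import SampleTable, ValidationError


def child_ingestion(**kw):
    defaults = dict(receptor="child", pathway="ingestion",
                    intake_rate=2.0e-4, body_weight=15.0,
                    frequency_days=350.0, duration_years=6.0)
    defaults.update(kw)
    return risk.ExposureScenario(**defaults)


class TestExposureFactor:
    def test_noncarcinogenic_is_f_over_365(self):
        assert risk.exposure_factor(350, 6) == pytest.approx(350 / 365)
        assert risk.exposure_factor(350, 6) == pytest.approx(0.9589, abs=1e-4)

    def test_continuous_exposure_is_one(self):
        assert risk.exposure_factor(365, 30) == pytest.approx(1.0)

    def test_carcinogenic_uses_lifetime(self):
        ef = risk.exposure_factor(350, 6, carcinogenic=True, lifetime_years=70)
        assert ef == pytest.approx(2100 / 25550)
        assert ef == pytest.approx(0.08219, abs=1e-5)

    def test_out_of_range_frequency(self):
        with pytest.raises(ValidationError):
            risk.exposure_factor(400, 6)


class TestDose:
    def test_ingestion_arithmetic(self):
        sc = child_ingestion(intake_rate=1.0e-4)
        d = risk.dose(100.0, sc)
        assert d == pytest.approx(100 * 1e-4 * 1.0 * (350 / 365) / 15)
        assert d == pytest.approx(6.393e-4, rel=1e-3)

    def test_bioavailability_linearity(self):
        full = risk.dose(50.0, child_ingestion())
        half = risk.dose(50.0, child_ingestion(bioavailability=0.5))
        assert half == pytest.approx(full / 2)

    def test_inverted_concentration_gives_unit_hq(self):
        sc = child_ingestion()
        rfd = 3e-4
        ef = risk.exposure_factor(sc.frequency_days, sc.duration_years)
        c = sc.body_weight * rfd / (sc.intake_rate * ef)
        assert risk.hazard_quotient(risk.dose(c, sc), rfd) == pytest.approx(1.0)

    def test_inhalation_is_bw_free(self):
        sc = risk.ExposureScenario("adult", "inhalation", intake_rate=20.0,
                                   body_weight=70.0, pef=1.36e9,
                                   frequency_days=350, duration_years=24)
        d = risk.dose(1000.0, sc)
        assert d == pytest.approx(1000.0 / 1.36e9 * (350 / 365))

    def test_inhalation_requires_pef(self):
        with pytest.raises(ValidationError):
            risk.ExposureScenario("adult", "inhalation", intake_rate=20.0,
                                  body_weight=70.0, frequency_days=350,
                                  duration_years=24)


class TestHQHI:
    def test_hq_ratio_and_screening(self):
        assert risk.hazard_quotient(3e-4, 3e-4) == 1.0
        assert risk.hazard_quotient(3e-5, 3e-4) == pytest.approx(0.1)
        assert risk.hazard_quotient(3e-5, 3e-4) < risk.HQ_THRESHOLD

    def test_hq_linear_in_concentration(self):
        sc = child_ingestion()
        hq1 = risk.hazard_quotient(risk.dose(10.0, sc), 1e-3)
        hq2 = risk.hazard_quotient(risk.dose(20.0, sc), 1e-3)
        assert hq2 == pytest.approx(2 * hq1)

    def test_hi_screens_below_threshold(self):
        his = risk.hazard_index(
            {"Cu": 0.3, "Hg": 0.1, "Pb": 0.5, "V": 0.4},
            {"kidney": ["Cu", "Hg", "Pb", "V"]})
        assert his["kidney"] == pytest.approx(1.2)   # Hg screened out
        assert his["kidney"] >= risk.HI_THRESHOLD

    def test_hi_zero_when_all_screened(self):
        his = risk.hazard_index({"Cu": 0.1, "V": 0.15},
                                {"gastrointestinal": ["Cu", "V"]})
        assert his["gastrointestinal"] == 0.0

    def test_single_contributor_hi_is_its_hq(self):
        his = risk.hazard_index({"V": 0.9}, {"blood": ["V"]})
        assert his["blood"] == pytest.approx(0.9)
        assert his["blood"] < risk.HI_THRESHOLD

    def test_hi_at_least_max_hq(self):
        rng = np.random.default_rng(0)
        hqs = {f"e{i}": rng.uniform(0, 3, 100) for i in range(4)}
        his = risk.hazard_index(hqs, {"organ": list(hqs)})
        included = np.stack([np.where(h >= 0.2, h, 0) for h in hqs.values()])
        assert (his["organ"] >= included.max(axis=0) - 1e-12).all()


class TestILCR:
    def test_product_and_classes(self):
        v = risk.ilcr(1e-4, 1.5)
        assert v == pytest.approx(1.5e-4)
        assert risk.ilcr_class(v) == "unacceptable"
        assert risk.ilcr_class(5e-5) == "tolerable"
        assert risk.ilcr_class(1e-6) == "tolerable"   # inclusive boundary
        assert risk.ilcr_class(9.99e-7) == "no risk"

    def test_missing_slope_rejected(self):
        with pytest.raises(ValidationError):
            risk.ilcr(1e-4, 0.0)


class TestDistributionFit:
    def test_lognormal_recovery(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(1.0, 0.5, 10_000)
        fit = risk.fit_concentration_distribution(v)
        assert fit.family == "lognormal"
        shape, loc, scale = fit.params
        assert loc == 0.0
        assert shape == pytest.approx(0.5, rel=0.02)
        assert np.log(scale) == pytest.approx(1.0, rel=0.02)

    def test_constant_vector_point_mass(self):
        fit = risk.fit_concentration_distribution(np.full(20, 3.3))
        assert fit.family == "point"
        rng = np.random.default_rng(0)
        assert (fit.rvs(100, rng) == 3.3).all()

    def test_deterministic_selection(self):
        rng = np.random.default_rng(2)
        v = rng.gamma(4.0, 2.0, 500)
        a = risk.fit_concentration_distribution(v)
        b = risk.fit_concentration_distribution(v)
        assert a.family == b.family and a.params == b.params

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            risk.fit_concentration_distribution([1.0] * 5)


def _single_element_survey(values, element="As"):
    n = len(values)
    df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                       "x": np.arange(n, dtype=float),
                       "y": np.arange(n, dtype=float),
                       element: values})
    return SampleTable(df, [element])


class TestMonteCarlo:
    def test_certainty_matches_closed_form_exceedance(self):
        """Simulated P(HQ >= 0.2) agrees with the fitted distribution's
        own CDF-based exceedance probability (closed-form oracle)."""
        rng = np.random.default_rng(3)
        t = _single_element_survey(rng.lognormal(np.log(15.0), 0.5, 500))
        sc = child_ingestion()
        rfd = 3.0e-4
        tox = {"As": risk.ToxRecord("As", rfd=rfd)}
        n_iter = 50_000
        rr = risk.monte_carlo_risk(t, [sc], tox, n_iter=n_iter, seed=7)
        cert = rr.hq.iloc[0]["certainty_percent"] / 100

        fit = rr.distributions["As"]
        kf = (sc.intake_rate * sc.bioavailability
              * risk.exposure_factor(sc.frequency_days, sc.duration_years)
              / sc.body_weight)
        c0 = 0.2 * rfd / kf                # concentration at HQ = 0.2
        shape, loc, scale = fit.params
        p_true = stats.lognorm.sf(c0, shape, loc, scale)
        se = np.sqrt(p_true * (1 - p_true) / n_iter)
        assert abs(cert - p_true) <= 3 * se
        assert fit.family == "lognormal"

    def test_degenerate_full_exceedance(self):
        t = _single_element_survey(np.full(20, 1e6))
        tox = {"As": risk.ToxRecord("As", rfd=3e-4)}
        rr = risk.monte_carlo_risk(t, [child_ingestion()], tox,
                                   n_iter=1000, seed=0)
        assert rr.hq.iloc[0]["certainty_percent"] == 100.0

    def test_seed_reproducibility_bit_exact(self, kernel_survey):
        kw = dict(scenarios=uio.default_scenarios(),
                  tox_table=uio.default_toxicity(),
                  organ_map=uio.default_organ_map(), n_iter=2000, seed=5)
        a = risk.monte_carlo_risk(kernel_survey, **kw)
        b = risk.monte_carlo_risk(kernel_survey, **kw)
        pd.testing.assert_frame_equal(a.hq, b.hq)
        pd.testing.assert_frame_equal(a.hi, b.hi)
        pd.testing.assert_frame_equal(a.ilcr, b.ilcr)

    def test_stochastic_dominance_orders_certainty(self):
        """Of two elements with identical toxicity, the one with the
        stochastically larger concentration has >= certainty."""
        rng = np.random.default_rng(4)
        lo = rng.lognormal(np.log(10.0), 0.4, 300)
        n = len(lo)
        df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                           "x": np.arange(n, dtype=float),
                           "y": np.arange(n, dtype=float),
                           "A": lo, "B": lo * 3.0})
        t = SampleTable(df, ["A", "B"])
        tox = {"A": risk.ToxRecord("A", rfd=1e-3),
               "B": risk.ToxRecord("B", rfd=1e-3)}
        rr = risk.monte_carlo_risk(t, [child_ingestion()], tox,
                                   n_iter=20_000, seed=1)
        hq = rr.hq.set_index("element")["certainty_percent"]
        assert hq["B"] >= hq["A"]

    def test_half_vs_full_iterations_converge(self, kernel_survey):
        tox = uio.default_toxicity()
        scen = [child_ingestion()]
        full = risk.monte_carlo_risk(kernel_survey, scen, tox,
                                     n_iter=20_000, seed=9)
        half = risk.monte_carlo_risk(kernel_survey, scen, tox,
                                     n_iter=10_000, seed=10)
        merged = full.hq.merge(half.hq, on="element",
                               suffixes=("_f", "_h"))
        for _, row in merged.iterrows():
            p = row["certainty_percent_f"] / 100
            se = 100 * np.sqrt(max(p * (1 - p), 1e-9) / 10_000)
            assert abs(row["certainty_percent_f"]
                       - row["certainty_percent_h"]) < max(4 * se, 0.5)

    def test_hi_monotone_in_organ_membership(self):
        """Adding a >=0.2-HQ element to an organ never lowers its HI
        certainty."""
        rng = np.random.default_rng(6)
        n = 300
        df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                           "x": np.arange(n, dtype=float),
                           "y": np.arange(n, dtype=float),
                           "A": rng.lognormal(np.log(40.0), 0.4, n),
                           "B": rng.lognormal(np.log(40.0), 0.4, n)})
        t = SampleTable(df, ["A", "B"])
        tox = {"A": risk.ToxRecord("A", rfd=1e-5),
               "B": risk.ToxRecord("B", rfd=1e-5)}
        one = risk.monte_carlo_risk(t, [child_ingestion()], tox,
                                    organ_map={"organ": ["A"]},
                                    n_iter=5000, seed=2)
        both = risk.monte_carlo_risk(t, [child_ingestion()], tox,
                                     organ_map={"organ": ["A", "B"]},
                                     n_iter=5000, seed=2)
        assert (both.hi.iloc[0]["certainty_percent"]
                >= one.hi.iloc[0]["certainty_percent"])

    def test_median_consistency_deterministic_vs_stochastic(self):
        """The deterministic equations at the fitted median agree with
        the median of the simulated HQ distribution."""
        rng = np.random.default_rng(8)
        t = _single_element_survey(rng.lognormal(np.log(20.0), 0.3, 400))
        sc = child_ingestion()
        tox = {"As": risk.ToxRecord("As", rfd=3e-4)}
        rr = risk.monte_carlo_risk(t, [sc], tox, n_iter=50_000, seed=3)
        med_c = rr.distributions["As"].median()
        det = risk.deterministic_risk({"As": med_c}, sc, tox)
        assert rr.hq.iloc[0]["median"] == pytest.approx(det["hq"]["As"],
                                                        rel=0.02)

    def test_empty_toxicity_rejected(self, kernel_survey):
        with pytest.raises(ValidationError):
            risk.monte_carlo_risk(kernel_survey, [child_ingestion()], {},
                                  n_iter=10, seed=0)


class TestDeterministic:
    def test_screening_at_fixed_concentrations(self):
        sc = child_ingestion()
        tox = {"Pb": risk.ToxRecord("Pb", rfd=3.5e-3, sf=8.5e-3,
                                    target_organs=["cns"])}
        out = risk.deterministic_risk({"Pb": 1000.0}, sc, tox,
                                      organ_map={"cns": ["Pb"]})
        d = risk.dose(1000.0, sc)
        assert out["hq"]["Pb"] == pytest.approx(d / 3.5e-3)
        d_ca = risk.dose(1000.0, sc, carcinogenic=True)
        assert out["ilcr"]["Pb"] == pytest.approx(d_ca * 8.5e-3)
        assert out["ilcr_class"]["Pb"] in ("no risk", "tolerable",
                                           "unacceptable")
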