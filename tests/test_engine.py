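"""Deaths-averted arithmetic, cascade combination and scenario projection."""

import pytest

from liststill.coverage import ChildbirthMix
from liststill.engine import (
    Scenario,
    averted_fraction,
    childbirth_impact,
    compartment_cascade,
    enap_met,
    run_scenario,
    sbr,
)
from liststill.epi import paf
from liststill.errors import InputDomainError
from conftest import make_worked_profile, single_target_scenario

ALL_HOME = ChildbirthMix(home_no_sba=1.0, sba_outside=0.0, bemoc=0.0, cemoc=0.0)
ALL_CEMOC = ChildbirthMix(home_no_sba=0.0, sba_outside=0.0, bemoc=0.0, cemoc=1.0)
ALL_BEMOC = ChildbirthMix(home_no_sba=0.0, sba_outside=0.0, bemoc=1.0, cemoc=0.0)


class TestAvertedFraction:
    def test_syphilis_worked_example(self):
        assert averted_fraction(0.82, 0.0, 0.50, 1.0) == pytest.approx(0.41)

    def test_balanced_energy_worked_example(self):
        assert averted_fraction(0.40, 0.0, 0.50, 0.20) == pytest.approx(0.04)

    def test_no_coverage_change(self):
        assert averted_fraction(0.9, 0.3, 0.3, 0.7) == 0.0

    def test_falling_coverage_is_negative(self):
        assert averted_fraction(0.5, 0.6, 0.2, 1.0) == pytest.approx(-0.2)

    def test_domain_error(self):
        with pytest.raises(InputDomainError):
            averted_fraction(1.2, 0.0, 0.5, 1.0)


class TestCascade:
    def test_single_syphilis_term(self):
        averted, residual = compartment_cascade(1000, [(0.82, 1.0, 0.0, 0.5)])
        assert averted[0] == pytest.approx(410)
        assert residual == pytest.approx(590)

    def test_no_terms(self):
        assert compartment_cascade(1000, []) == ([], 1000)

    def test_two_ten_percent_terms_multiply(self):
        averted, residual = compartment_cascade(
            1000, [(0.5, 0.2, 0.0, 1.0), (0.5, 0.2, 0.0, 1.0)]
        )
        assert residual == pytest.approx(810)  # 1000 x 0.9 x 0.9
        assert sum(averted) + residual == pytest.approx(1000, abs=1e-9)

    def test_conservation_is_exact(self):
        terms = [(0.7, 0.3, 0.1, 0.9), (0.2, 1.0, 0.0, 0.4), (0.9, 0.05, 0.2, 0.8)]
        averted, residual = compartment_cascade(12345.6, terms)
        assert sum(averted) + residual == pytest.approx(12345.6, abs=1e-9)

    def test_order_invariance(self):
        terms = [(0.7, 0.3, 0.1, 0.9), (0.2, 1.0, 0.0, 0.4), (0.9, 0.05, 0.2, 0.8)]
        _, r1 = compartment_cascade(1000.0, terms)
        _, r2 = compartment_cascade(1000.0, terms[::-1])
        assert r1 == r2

    def test_negative_deaths_rejected(self):
        with pytest.raises(InputDomainError):
            compartment_cascade(-1, [])


class TestChildbirthImpact:
    def test_identical_mixes(self):
        assert childbirth_impact(1000, ALL_HOME, ALL_HOME) == 0.0

    def test_all_home_to_all_cemoc(self):
        assert childbirth_impact(1000, ALL_HOME, ALL_CEMOC) == pytest.approx(750)

    def test_all_home_to_all_bemoc(self):
        assert childbirth_impact(1000, ALL_HOME, ALL_BEMOC) == pytest.approx(450)

    def test_reverse_shift_is_symmetric(self):
        assert childbirth_impact(1000, ALL_CEMOC, ALL_HOME) == pytest.approx(-750)

    def test_renormalised_form_matches_plain_at_zero_baseline(self):
        plain = childbirth_impact(1000, ALL_HOME, ALL_CEMOC)
        renorm = childbirth_impact(1000, ALL_HOME, ALL_CEMOC, renormalise=True)
        assert plain == renorm

    def test_renormalised_form_scales_up_nonzero_baseline(self):
        base = ChildbirthMix(home_no_sba=0.5, sba_outside=0.3, bemoc=0.1, cemoc=0.1)
        plain = childbirth_impact(1000, base, ALL_CEMOC)
        renorm = childbirth_impact(1000, base, ALL_CEMOC, renormalise=True)
        assert renorm == pytest.approx(plain / (1 - (0.23 * 0.3 + 0.45 * 0.1 + 0.75 * 0.1)))


class TestSbr:
    @pytest.mark.parametrize(
        "deaths,births,rate,met",
        [(12, 1000, 12.0, True), (0, 1000, 0.0, True), (26, 1000, 26.0, False)],
    )
    def test_rate_and_enap(self, deaths, births, rate, met):
        assert sbr(deaths, births) == rate
        assert enap_met(sbr(deaths, births)) is met

    def test_zero_births_rejected(self):
        with pytest.raises(InputDomainError):
            sbr(10, 0)


class TestRunScenario:
    def test_zero_change_scenario_averts_nothing(self, worked_profile):
        result = run_scenario(worked_profile, Scenario(2025, 2030, {}))
        assert (result.detail["averted"] == 0).all()
        assert result.summary["sbr"].nunique() == 1
        assert (result.summary["residual"] == 20_000).all()

    def test_syphilis_scaleup_averts_41pct_of_attributable(self, worked_profile):
        result = run_scenario(worked_profile, single_target_scenario("syphilis", 0.5))
        ap_envelope = 20_000 * 0.6
        attributable = ap_envelope * paf(0.03, 10.89)
        final = result.detail.query(
            "year == 2030 and intervention == 'syphilis' and timing == 'antepartum'"
        )["averted"].item()
        assert final == pytest.approx(0.41 * attributable, rel=1e-9)

    def test_linear_trajectory_interpolates(self, worked_profile):
        result = run_scenario(worked_profile, single_target_scenario("syphilis", 0.5))
        per_year = result.detail.query(
            "intervention == 'syphilis' and timing == 'antepartum'"
        ).set_index("year")["averted"]
        assert per_year[2025] == 0.0
        # one fifth of the way in 2026, linear thereafter
        assert per_year[2026] == pytest.approx(per_year[2030] / 5, rel=1e-9)

    def test_step_trajectory_jumps_immediately(self, worked_profile):
        scen = Scenario(2025, 2030, {"syphilis": 0.5}, trajectory="step")
        per_year = (
            run_scenario(worked_profile, scen)
            .detail.query("intervention == 'syphilis' and timing == 'antepartum'")
            .set_index("year")["averted"]
        )
        assert per_year[2025] == 0.0
        assert per_year[2026] == per_year[2030] != 0.0

    def test_induction_capped_at_cemoc_share(self, worked_profile):
        # facility 0.40 -> CEmOC share = 0.20 x 0.40 = 0.08 of births
        result = run_scenario(worked_profile, single_target_scenario("induction", 0.9))
        averted = result.detail.query(
            "year == 2030 and intervention == 'induction' and timing == 'antepartum'"
        )["averted"].item()
        ap_envelope = 20_000 * 0.6
        expected = ap_envelope * 0.69 * 0.08 * paf(0.075, 1.8)
        assert averted == pytest.approx(expected, rel=1e-9)

    def test_raising_coverage_never_raises_residual(self, worked_profile):
        lo = run_scenario(worked_profile, single_target_scenario("malaria", 0.4))
        hi = run_scenario(worked_profile, single_target_scenario("malaria", 0.8))
        assert (
            hi.summary.set_index("year")["residual"]
            <= lo.summary.set_index("year")["residual"] + 1e-9
        ).all()

    def test_falling_coverage_increases_deaths_symmetrically(self):
        profile = make_worked_profile(
            baseline_indicators={
                "anc4": 0.5,
                "sba": 0.5,
                "facility_delivery": 0.4,
                "iptp_or_itn": 0.2,
                "syphilis": 0.5,
                "malaria": 0.0,
                "micronutrient": 0.0,
                "balanced_energy": 0.0,
                "diabetes": 0.0,
                "hdp": 0.0,
                "induction": 0.0,
            }
        )
        down = run_scenario(profile, single_target_scenario("syphilis", 0.0))
        up = run_scenario(
            make_worked_profile(), single_target_scenario("syphilis", 0.5)
        )
        final_down = down.detail.query(
            "year == 2030 and intervention == 'syphilis' and timing == 'antepartum'"
        )["averted"].item()
        final_up = up.detail.query(
            "year == 2030 and intervention == 'syphilis' and timing == 'antepartum'"
        )["averted"].item()
        assert final_down == pytest.approx(-final_up, rel=1e-9)
        # deaths increase: residual exceeds the envelope, conservation holds
        assert down.summary["residual"].iloc[-1] > down.envelope
        assert down.conservation_errors().max() < 1e-6

    def test_childbirth_targets_produce_package_rows(self, worked_profile):
        scen = Scenario(2025, 2030, {"facility_delivery": 0.8, "sba": 0.9})
        result = run_scenario(worked_profile, scen)
        cb = result.detail.query("year == 2030 and intervention == 'cemoc'")
        assert cb["averted"].item() > 0
        assert result.conservation_errors().max() < 1e-6
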