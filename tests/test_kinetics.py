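"""Structural kinetics: analytic solutions, linearity, the ODE cross-check."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import meromipd as m
from meromipd.errors import DomainError

RNG_CASES = 25  # randomized oracle cases per compartment count (fast unit-level run)


def _random_case(rng, n_cpt):
    kw = dict(cl=rng.uniform(2, 20), vc=rng.uniform(5, 35))
    if n_cpt >= 2:
        kw.update(q2=rng.uniform(2, 40), vp2=rng.uniform(4, 40))
    if n_cpt == 3:
        kw.update(q3=rng.uniform(2, 60), vp3=rng.uniform(4, 30))
    params = m.StructuralParams(**kw)
    doses = [m.DoseEvent(float(t), float(rng.uniform(250, 2000)),
                         float(rng.uniform(0.25, 3.0)))
             for t in rng.uniform(0.0, 24.0, rng.integers(1, 4))]
    times = np.sort(rng.uniform(0.05, 36.0, 8))
    return params, doses, times


class TestClosedForms:
    def test_no_drug_before_first_infusion(self, one_cpt_params, single_infusion):
        assert m.predict_concentration(one_cpt_params, single_infusion, [0.0])[0] == 0.0
        late = [m.DoseEvent(5.0, 1000.0, 0.5)]
        conc = m.predict_concentration(one_cpt_params, late, [0.0, 2.0, 4.9])
        assert np.all(conc == 0.0)

    def test_end_of_infusion_concentration_matches_hand_oracle(
            self, one_cpt_params, single_infusion):
        """(R0/CL)(1 - e^{-CL t/V}) with R0 = 2000 mg/h gives 28.51 mg/L at t = 0.5 h."""
        conc = m.predict_concentration(one_cpt_params, single_infusion, [0.5])[0]
        assert conc == pytest.approx(28.51, abs=0.01)

    def test_linearity_in_dose(self, two_cpt_params):
        doses = [m.DoseEvent(0, 1000, 0.5), m.DoseEvent(8, 500, 1.0)]
        double = [m.DoseEvent(0, 2000, 0.5), m.DoseEvent(8, 1000, 1.0)]
        times = [0.5, 2.0, 8.5, 12.0, 20.0]
        c1 = m.predict_concentration(two_cpt_params, doses, times)
        c2 = m.predict_concentration(two_cpt_params, double, times)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_superposition_of_dose_events(self, two_cpt_params):
        d1, d2 = m.DoseEvent(0, 1000, 0.5), m.DoseEvent(6, 1500, 1.0)
        times = np.linspace(0.25, 24, 30)
        both = m.predict_concentration(two_cpt_params, [d1, d2], times)
        parts = (m.predict_concentration(two_cpt_params, [d1], times)
                 + m.predict_concentration(two_cpt_params, [d2], times))
        np.testing.assert_allclose(both, parts, rtol=1e-10)

    def test_monotone_washout_after_last_infusion(self, two_cpt_params, single_infusion):
        times = np.linspace(0.5, 30, 200)
        conc = m.predict_concentration(two_cpt_params, single_infusion, times)
        assert np.all(np.diff(conc) < 0)

    def test_negative_time_rejected(self, one_cpt_params, single_infusion):
        with pytest.raises(DomainError):
            m.predict_concentration(one_cpt_params, single_infusion, [-1.0])

    def test_batch_matches_scalar_path(self, two_cpt_params, single_infusion):
        times = [0.5, 2.0, 7.5]
        batch = m.predict_concentration_batch(
            single_infusion, times,
            cl=np.array([10.0, 20.0]), vc=np.array([12.0, 12.0]),
            q2=np.array([15.0, 15.0]), vp2=np.array([12.0, 12.0]))
        single = m.predict_concentration(two_cpt_params, single_infusion, times)
        np.testing.assert_allclose(batch[0], single, rtol=1e-12)


class TestOdeOracle:
    @pytest.mark.parametrize("n_cpt", [1, 2, 3])
    def test_analytic_matches_ode_on_randomized_cases(self, n_cpt):
        rng = np.random.default_rng(100 + n_cpt)
        worst = 0.0
        for _ in range(RNG_CASES):
            params, doses, times = _random_case(rng, n_cpt)
            analytic = m.predict_concentration(params, doses, times)
            ode = m.predict_concentration_ode(params, doses, times)
            # compare where the concentration is meaningful on the profile's
            # own scale; far below that the ODE answer is limited by its
            # absolute tolerance, not the analytic solution
            mask = ode > 1e-6 * ode.max()
            if not mask.any():  # all sample times can precede the first dose
                np.testing.assert_allclose(analytic, ode, atol=1e-12)
                continue
            rel = np.abs(analytic[mask] - ode[mask]) / ode[mask]
            worst = max(worst, rel.max())
        assert worst <= 1e-6

    def test_zero_dose_course_is_identically_zero(self, two_cpt_params):
        conc = m.predict_concentration_ode(two_cpt_params, [], [0.0, 1.0, 5.0])
        assert np.all(conc == 0.0)

    def test_mass_balance_during_and_after_infusion(self, two_cpt_params,
                                                    single_infusion):
        res = m.predict_amounts_ode(two_cpt_params, single_infusion,
                                    [0.25, 0.5, 2.0, 12.0])
        total = res["amounts"].sum(axis=1) + res["eliminated"]
        np.testing.assert_allclose(total, res["infused"], rtol=1e-8)


@given(cl=st.floats(2, 20), vc=st.floats(5, 35), q2=st.floats(2, 40),
       vp2=st.floats(4, 40), amount=st.floats(250, 2000), dur=st.floats(0.25, 3))
def test_concentrations_nonnegative_and_peak_at_infusion_end(cl, vc, q2, vp2,
                                                             amount, dur):
    """Single-infusion profiles are nonnegative and peak exactly at end of infusion."""
    params = m.StructuralParams(cl=cl, vc=vc, q2=q2, vp2=vp2)
    doses = [m.DoseEvent(0.0, amount, dur)]
    times = np.linspace(0.0, dur + 24.0, 60)
    conc = m.predict_concentration(params, doses, times)
    assert np.all(conc >= 0)
    peak = m.predict_concentration(params, doses, [dur])[0]
    assert peak >= conc.max() - 1e-9 * max(peak, 1.0)
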