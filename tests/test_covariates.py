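"""Body-size descriptors and the multiplicative covariate model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rifpk.covariates import (CovariateEffect, apply_covariates,
                              bsa_mosteller, covariate_log_offset, ffm,
                              weighted_mean)


class TestFFM:
    @pytest.mark.parametrize(
        "sex, bw, bmi, expected",
        [
            # male/female study medians through the sex-specific FFM model
            ("male", 82.9, 24.7, 768483.0 / 12015.2),
            ("female", 63.8, 23.09, 591426.0 / 14413.96),
        ],
    )
    def test_reference_values(self, sex, bw, bmi, expected):
        assert ffm(sex, bw, bmi) == pytest.approx(expected, rel=1e-12)

    def test_proportional_to_bw_at_fixed_bmi(self):
        assert ffm("female", 0.0, 23.0) == 0.0
        assert ffm("female", 50.0, 23.0) == pytest.approx(
            0.5 * ffm("female", 100.0, 23.0))

    @given(bw=st.floats(30, 200), bmi=st.floats(15, 45),
           dbw=st.floats(0.1, 30), dbmi=st.floats(0.1, 10))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_below_bw(self, bw, bmi, dbw, dbmi):
        for sex in ("male", "female"):
            f0 = ffm(sex, bw, bmi)
            assert f0 < bw              # fat-free mass below total mass
            assert ffm(sex, bw + dbw, bmi) > f0     # increasing in BW
            assert ffm(sex, bw, bmi + dbmi) < f0    # decreasing in BMI

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ffm("male", 70.0, 0.0)
        with pytest.raises(ValueError):
            ffm("other", 70.0, 23.0)


class TestBSA:
    @pytest.mark.parametrize(
        "bw, bh, expected, rel",
        [
            (82.9, 1.81, 2.0415, 1e-3),      # male medians
            (63.8, 1.65, 1.7100, 1e-3),      # female medians
            (3600.0 / 170.0, 1.70, 1.0, 1e-12),  # constructed exact identity
        ],
    )
    def test_values(self, bw, bh, expected, rel):
        assert bsa_mosteller(bw, bh) == pytest.approx(expected, rel=rel)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bsa_mosteller(-1.0, 1.7)


class TestWeightedMean:
    def test_equal_weights_is_mean(self):
        assert weighted_mean([60, 80], [38, 38]) == pytest.approx(70.0)

    def test_unequal_weights(self):
        assert weighted_mean([60, 80], [10, 30]) == pytest.approx(75.0)

    def test_empty_and_bad_weights(self):
        with pytest.raises(ValueError):
            weighted_mean([], [])
        with pytest.raises(ValueError):
            weighted_mean([1.0], [0.0])


class TestApplyCovariates:
    cov = {"FFM": 100.0, "sex": "male", "BW": 80.0}

    def test_empty_specs_identity(self):
        assert apply_covariates(36.2, [], self.cov) == 36.2

    def test_at_reference_identity(self):
        spec = CovariateEffect("V", "FFM", "power", beta=1.0, reference=100.0)
        assert apply_covariates(36.2, [spec], self.cov) == pytest.approx(36.2)

    def test_ffm_doubling(self):
        # published fixed exponents: 1 on V, 0.75 on Vmax
        v_spec = CovariateEffect("V", "FFM", "power", beta=1.0, reference=50.0)
        vm_spec = CovariateEffect("Vmax", "FFM", "power", beta=0.75,
                                  reference=50.0)
        assert apply_covariates(36.2, [v_spec], self.cov) == pytest.approx(72.4)
        assert apply_covariates(190.0, [vm_spec], self.cov) == pytest.approx(
            190.0 * 2**0.75)

    def test_categorical_sex(self):
        spec = CovariateEffect("Vmax", "sex", "categorical", beta=0.42,
                               reference="female")
        assert apply_covariates(157.0, [spec], self.cov) == pytest.approx(
            157.0 * np.exp(0.42))
        assert apply_covariates(
            157.0, [spec], {**self.cov, "sex": "female"}) == pytest.approx(157.0)

    @given(beta1=st.floats(-1, 2), beta2=st.floats(-1, 2),
           x=st.floats(20, 200))
    @settings(max_examples=100, deadline=None)
    def test_multiplicative_composition(self, beta1, beta2, x):
        """Applying terms one at a time in any order equals joint application."""
        cov = {"FFM": x, "BW": 70.0}
        s1 = CovariateEffect("V", "FFM", "power", beta=beta1, reference=50.0)
        s2 = CovariateEffect("V", "BW", "power", beta=beta2, reference=72.0)
        joint = apply_covariates(36.2, [s1, s2], cov)
        seq12 = apply_covariates(apply_covariates(36.2, [s1], cov), [s2], cov)
        seq21 = apply_covariates(apply_covariates(36.2, [s2], cov), [s1], cov)
        assert joint == pytest.approx(seq12, rel=1e-12)
        assert joint == pytest.approx(seq21, rel=1e-12)

    def test_missing_covariate_names_spec(self):
        spec = CovariateEffect("V", "BSA", "power", beta=1.0, reference=1.8)
        with pytest.raises(KeyError, match="BSA"):
            apply_covariates(36.2, [spec], self.cov)

    def test_log_offset_selects_parameter(self):
        s1 = CovariateEffect("V", "FFM", "power", beta=1.0, reference=50.0)
        s2 = CovariateEffect("Vmax", "FFM", "power", beta=0.75, reference=50.0)
        off_v = covariate_log_offset([s1, s2], "V", self.cov)
        assert off_v == pytest.approx(np.log(2.0))
        assert covariate_log_offset([s1, s2], "Tlag", self.cov) == 0.0
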