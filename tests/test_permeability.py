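import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cochperm.errors import ValidationError
from cochperm.permeability import (ChannelDensityResult, DiffusionalInputs,
                                   OsmoticInputs, compute_Jv, compute_Pd,
                                   compute_Pf, compute_ratio,
                                   estimate_channel_density, load_reference_table,
                                   mean_reference_Pd)

pos = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestComputePd:
    @pytest.mark.parametrize("p_prime,area,want_1e5", [
        (0.691, 11.46, 12.06),   # Reissner's membrane
        (0.499, 9.78, 10.2),     # organ of Corti
        (0.869, 21.24, 8.18),    # entire barrier
    ])
    def test_published_values(self, p_prime, area, want_1e5):
        res = compute_Pd(DiffusionalInputs(p_prime, 1.2, area))
        assert res.scaled(1e-5) == pytest.approx(want_1e5, abs=0.011)

    def test_doubling_area_halves_pd(self):
        a = compute_Pd(DiffusionalInputs(0.7, 1.2, 10.0)).value_cm_s
        b = compute_Pd(DiffusionalInputs(0.7, 1.2, 20.0)).value_cm_s
        assert a == pytest.approx(2 * b, rel=1e-12)

    @given(p=pos, v=pos, a=pos, c=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=100, deadline=None)
    def test_homogeneity(self, p, v, a, c):
        base = compute_Pd(DiffusionalInputs(p, v, a)).value_cm_s
        assert compute_Pd(DiffusionalInputs(c * p, v, a)).value_cm_s == \
            pytest.approx(c * base, rel=1e-9)
        assert compute_Pd(DiffusionalInputs(p, c * v, a)).value_cm_s == \
            pytest.approx(c * base, rel=1e-9)
        assert compute_Pd(DiffusionalInputs(p, v, c * a)).value_cm_s == \
            pytest.approx(base / c, rel=1e-9)

    def test_zero_area_rejected(self):
        with pytest.raises(ValidationError):
            DiffusionalInputs(0.7, 1.2, 0.0)


class TestComputeJv:
    def test_area_volume_flow(self):
        assert compute_Jv(1.2, 22.1, 20.0) * 1e3 == pytest.approx(13.26, abs=0.011)

    def test_movement_volume_flow(self):
        assert compute_Jv(1.2, 12.29, 20.0) * 1e3 == pytest.approx(7.37, abs=0.011)

    def test_zero_si(self):
        assert compute_Jv(1.2, 0.0, 20.0) == 0.0

    def test_negative_si_rejected(self):
        with pytest.raises(ValidationError):
            compute_Jv(1.2, -1.0, 20.0)


class TestComputePf:
    def test_entire_barrier(self):
        res = compute_Pf(OsmoticInputs(area_mm2=21.24, delta_c_mol_l=0.094,
                                       jv_ul_min=13.26e-3))
        assert res.scaled(1e-4) == pytest.approx(6.15, abs=0.011)

    def test_shunt(self):
        res = compute_Pf(OsmoticInputs(area_mm2=0.04627, delta_c_mol_l=0.094,
                                       jv_ul_min=7.37e-3))
        assert res.scaled(1e-3) == pytest.approx(156.90, abs=0.011)

    def test_linearity_in_jv(self):
        kwargs = dict(area_mm2=21.24, delta_c_mol_l=0.094)
        a = compute_Pf(OsmoticInputs(jv_ul_min=1e-3, **kwargs)).value_cm_s
        b = compute_Pf(OsmoticInputs(jv_ul_min=3e-3, **kwargs)).value_cm_s
        assert b == pytest.approx(3 * a, rel=1e-12)

    def test_jv_derived_from_si(self):
        direct = compute_Pf(OsmoticInputs(area_mm2=21.24, delta_c_mol_l=0.094,
                                          v_e_ul=1.2, si_pct=22.1))
        assert direct.inputs["jv_ul_min"] == pytest.approx(13.26e-3)

    def test_chained_pipeline_matches_printed(self):
        # volume-flow formula feeding the osmotic formula, unrounded
        jv = compute_Jv(1.2, 22.1, 20.0)
        pf = compute_Pf(OsmoticInputs(area_mm2=21.24, delta_c_mol_l=0.094,
                                      jv_ul_min=jv))
        assert pf.value_cm_s == pytest.approx(6.15e-4, rel=1e-3)
        jv2 = compute_Jv(1.2, 12.29, 20.0)
        pf2 = compute_Pf(OsmoticInputs(area_mm2=0.04627, delta_c_mol_l=0.094,
                                       jv_ul_min=jv2))
        assert pf2.value_cm_s == pytest.approx(156.90e-3, rel=1e-3)

    def test_missing_jv_and_si_rejected(self):
        with pytest.raises(ValidationError):
            OsmoticInputs(area_mm2=1.0, delta_c_mol_l=0.1)


class TestRatios:
    def test_entire_barrier_ratio(self):
        pf = compute_Pf(OsmoticInputs(area_mm2=21.24, delta_c_mol_l=0.094,
                                      jv_ul_min=13.26e-3))
        pd_ = compute_Pd(DiffusionalInputs(0.869, 1.2, 21.24))
        assert round(compute_ratio(pf, pd_), 2) == 7.52

    def test_shunt_ratio_printed_intermediates(self):
        # the source arithmetic divides the two printed, rounded coefficients
        assert round(156.90e-3 / 64.83e-5, 2) == 242.02

    def test_identity_ratio(self):
        pf = compute_Pf(OsmoticInputs(area_mm2=1.0, delta_c_mol_l=0.1,
                                      jv_ul_min=1.0))
        from cochperm.permeability import PermeabilityResult
        pd_ = PermeabilityResult(value_cm_s=pf.value_cm_s, kind="P_D")
        assert compute_ratio(pf, pd_) == 1.0

    def test_kind_mismatch_rejected(self):
        pd_ = compute_Pd(DiffusionalInputs(0.869, 1.2, 21.24))
        with pytest.raises(ValidationError):
            compute_ratio(pd_, pd_)


class TestMeanReferencePd:
    def test_published_mean(self):
        assert mean_reference_Pd([1.30, 1.68, 8.18, 13, 300]) == \
            pytest.approx(64.83, abs=0.011)

    def test_single_value(self):
        assert mean_reference_Pd([42.0]) == 42.0

    def test_permutation_invariance(self):
        vals = [1.30, 1.68, 8.18, 13, 300]
        assert mean_reference_Pd(vals) == mean_reference_Pd(vals[::-1])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mean_reference_Pd([])

    def test_reference_table_flags_five_epithelia(self):
        df = load_reference_table()
        ref = df[df["aqp5_reference"] == 1]
        assert len(ref) == 5
        assert mean_reference_Pd(list(ref["P_D_1e-5_cm_s"].astype(float))) == \
            pytest.approx(64.83, abs=0.011)


class TestChannelDensity:
    def test_computed_quotient_documents_discrepancy(self):
        res = estimate_channel_density(156.90e-3, 5e-14)
        # direct quotient is 3.14e4 per um^2, not the printed 3.45e4
        assert res.channels_per_um2 == pytest.approx(3.138e4, rel=1e-3)
        assert "3.14e4" in res.note and "3.45e4" in res.note

    def test_unit_sanity(self):
        res = estimate_channel_density(5e-6, 5e-14)
        assert res.channels_per_um2 == pytest.approx(1.0, rel=1e-12)

    def test_linearity(self):
        a = estimate_channel_density(1e-3, 5e-14).channels_per_um2
        b = estimate_channel_density(2e-3, 5e-14).channels_per_um2
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_zero_single_channel_rejected(self):
        with pytest.raises(ValidationError):
            estimate_channel_density(1e-3, 0.0)
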