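"""Unit and property tests for DVHs, EUD, NTCP and the sigmoid inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csidose import (
    DVH,
    DomainError,
    DoseValue,
    InconsistencyError,
    OrganNTCPParams,
    ValidationError,
    compute_eud,
    compute_ntcp,
    convert_dvh,
    default_organ_params,
    dvh_metrics,
    eqd2_transform,
    fit_ntcp_params,
    read_dvh_csv,
    write_dvh_csv,
)


# ---------------------------------------------------------------------------
# DVH model and conversion
# ---------------------------------------------------------------------------
class TestDVH:
    def test_differential_must_normalise(self):
        with pytest.raises(ValidationError):
            DVH.from_bins("x", [(10.0, 0.5), (30.0, 0.4)])

    def test_cumulative_must_be_monotone_and_start_at_one(self):
        with pytest.raises(ValidationError):
            DVH.from_bins("x", [(10.0, 0.5), (30.0, 0.9)], form="cumulative")
        with pytest.raises(ValidationError):
            DVH.from_bins("x", [(10.0, 0.8), (30.0, 0.5)], form="cumulative")

    def test_bin_doses_strictly_increasing(self):
        with pytest.raises(ValidationError):
            DVH.from_bins("x", [(10.0, 0.5), (10.0, 0.5)])

    def test_differential_to_cumulative_matches_definition(self, two_bin_dvh):
        cum = convert_dvh(two_bin_dvh, "cumulative")
        assert cum.volume == pytest.approx([1.0, 0.5])

    def test_identity_conversion_returns_input(self, two_bin_dvh):
        assert convert_dvh(two_bin_dvh, "differential") is two_bin_dvh

    @given(
        volumes=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=30),
    )
    @settings(deadline=None, max_examples=100)
    def test_round_trip_is_lossless(self, volumes):
        v = np.array(volumes) / np.sum(volumes)
        d = np.arange(1.0, len(v) + 1)
        dvh = DVH("x", d, v, "differential")
        back = convert_dvh(convert_dvh(dvh, "cumulative"), "differential")
        assert np.allclose(back.volume, v, atol=1e-12)

    def test_csv_round_trip(self, tmp_path, two_bin_dvh):
        path = tmp_path / "dvh.csv"
        write_dvh_csv([two_bin_dvh], path)
        loaded = read_dvh_csv(path)["organ"]
        assert np.allclose(loaded.dose_gy, two_bin_dvh.dose_gy)
        assert np.allclose(loaded.volume, two_bin_dvh.volume)
        assert loaded.form == two_bin_dvh.form


# ---------------------------------------------------------------------------
# EUD
# ---------------------------------------------------------------------------
class TestEUD:
    @pytest.mark.parametrize("a", [-5.0, 0.5, 1.0, 4.0, 50.0])
    def test_uniform_dose_identity(self, a):
        dvh = DVH.from_bins("x", [(10.0, 1.0)])
        assert compute_eud(dvh, a).eud.gy == pytest.approx(10.0)

    def test_a_equal_one_is_mean_dose(self):
        dvh = DVH.from_bins("x", [(0.0, 0.5), (20.0, 0.5)])
        assert compute_eud(dvh, 1.0).eud.gy == pytest.approx(10.0)

    def test_two_bin_generalised_mean(self, two_bin_dvh):
        # oracle: direct power-mean arithmetic on the two bins
        expected = (0.5 * 10.0**4 + 0.5 * 30.0**4) ** 0.25
        assert compute_eud(two_bin_dvh, 4.0).eud.gy == pytest.approx(expected, rel=1e-12)
        assert compute_eud(two_bin_dvh, 4.0).eud.gy == pytest.approx(25.30, abs=0.01)

    def test_accepts_cumulative_input(self, two_bin_dvh):
        cum = convert_dvh(two_bin_dvh, "cumulative")
        assert compute_eud(cum, 4.0).eud.gy == pytest.approx(
            compute_eud(two_bin_dvh, 4.0).eud.gy
        )

    def test_a_zero_rejected(self, two_bin_dvh):
        with pytest.raises(ValidationError):
            compute_eud(two_bin_dvh, 0.0)

    def test_negative_a_with_zero_dose_bin_is_domain_error(self):
        dvh = DVH.from_bins("x", [(0.0, 0.5), (20.0, 0.5)])
        with pytest.raises(DomainError):
            compute_eud(dvh, -1.0)

    @given(a=st.floats(0.2, 50.0))
    @settings(deadline=None)
    def test_bounded_by_dvh_extremes(self, a, two_bin_dvh):
        eud = compute_eud(two_bin_dvh, a).eud.gy
        assert 10.0 - 1e-9 <= eud <= 30.0 + 1e-9

    def test_monotone_in_a_and_dmax_limit(self, two_bin_dvh):
        a_grid = [0.5, 1.0, 2.0, 5.0, 10.0, 50.0]
        euds = [compute_eud(two_bin_dvh, a).eud.gy for a in a_grid]
        assert all(x <= y + 1e-12 for x, y in zip(euds, euds[1:]))
        # closed-form tail: EUD(a) = Dmax * v_max**(1/a); at a=50 with
        # v_max=0.5 that is 1.39% below Dmax, exactly as computed
        assert euds[-1] == pytest.approx(30.0 * 0.5 ** (1 / 50), rel=1e-12)
        # with most volume in the top bin the a=50 EUD sits within 1% of Dmax
        skewed = DVH.from_bins("x", [(10.0, 0.3), (30.0, 0.7)])
        assert compute_eud(skewed, 50.0).eud.gy == pytest.approx(30.0, rel=0.01)

    def test_matches_per_voxel_brute_force(self, rng):
        """Binning voxel doses into a DVH must not change the generalised mean."""
        voxels = rng.uniform(0.5, 40.0, size=500)
        doses, counts = np.unique(np.round(voxels, 3), return_counts=True)
        v = counts / counts.sum()
        dvh = DVH("x", doses, v, "differential")
        for a in (0.5, 1.0, 3.0, 8.0, -2.0):
            brute = (np.mean(np.round(voxels, 3) ** a)) ** (1.0 / a)
            assert compute_eud(dvh, a).eud.gy == pytest.approx(brute, rel=1e-9)


# ---------------------------------------------------------------------------
# NTCP and its inversion
# ---------------------------------------------------------------------------
def _params(d50=50.0, g=2.0, a=1.0):
    return OrganNTCPParams("x", a, DoseValue(d50, "Gy"), g)


class TestNTCP:
    def test_half_probability_at_d50(self):
        assert compute_ntcp(DoseValue(50.0, "Gy"), _params()).ntcp == pytest.approx(0.5)

    def test_zero_eud_limit(self):
        assert compute_ntcp(DoseValue(0.0, "Gy"), _params()).ntcp == 0.0

    @given(
        e1=st.floats(0.5, 200.0),
        delta=st.floats(0.1, 50.0),
        g=st.floats(0.3, 5.0),
    )
    @settings(deadline=None)
    def test_strictly_increasing_in_eud(self, e1, delta, g):
        p = _params(g=g)
        lo = compute_ntcp(DoseValue(e1, "Gy"), p).ntcp
        hi = compute_ntcp(DoseValue(e1 + delta, "Gy"), p).ntcp
        assert hi > lo

    def test_steeper_slope_raises_ntcp_above_d50(self):
        e = DoseValue(70.0, "Gy")
        assert (
            compute_ntcp(e, _params(g=3.0)).ntcp > compute_ntcp(e, _params(g=1.0)).ntcp
        )

    def test_extreme_dose_ratio_does_not_overflow(self):
        lo = compute_ntcp(DoseValue(1e-6, "Gy"), _params(g=5.0)).ntcp
        assert 0.0 <= lo < 1e-100
        assert compute_ntcp(DoseValue(1e6, "Gy"), _params(g=5.0)).ntcp == pytest.approx(1.0)


class TestFitNTCP:
    def test_heart_pair_two_point_solve(self, heart_pair):
        p = fit_ntcp_params(heart_pair, organ="heart")
        assert p.d50.gy == pytest.approx(18.79, abs=0.01)
        assert p.gamma50 == pytest.approx(1.318, abs=0.002)
        # back-substitution reproduces the inputs exactly
        assert compute_ntcp(heart_pair[0][0], p).ntcp == pytest.approx(0.30, rel=1e-10)
        assert compute_ntcp(heart_pair[1][0], p).ntcp == pytest.approx(0.004, rel=1e-10)

    def test_midpoint_pair_pins_d50_exactly(self):
        p = fit_ntcp_params([(DoseValue(23.0, "Gy"), 0.5), (DoseValue(40.0, "Gy"), 0.9)])
        assert p.d50.gy == 23.0

    def test_round_trip_parameter_recovery(self):
        truth = _params(d50=40.0, g=2.0)
        pairs = [
            (DoseValue(e, "Gy"), compute_ntcp(DoseValue(e, "Gy"), truth).ntcp)
            for e in (20.0, 50.0)
        ]
        fitted = fit_ntcp_params(pairs)
        assert fitted.d50.gy == pytest.approx(40.0, rel=1e-6)
        assert fitted.gamma50 == pytest.approx(2.0, rel=1e-6)

    def test_overdetermined_fit_on_noise_free_grid(self):
        truth = _params(d50=30.0, g=1.5)
        pairs = [
            (DoseValue(e, "Gy"), compute_ntcp(DoseValue(e, "Gy"), truth).ntcp)
            for e in (10.0, 20.0, 30.0, 45.0, 60.0)
        ]
        fitted = fit_ntcp_params(pairs)
        assert fitted.d50.gy == pytest.approx(30.0, rel=1e-9)
        assert fitted.gamma50 == pytest.approx(1.5, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            fit_ntcp_params([(DoseValue(10, "Gy"), 0.0), (DoseValue(20, "Gy"), 0.5)])
        with pytest.raises(InconsistencyError):
            fit_ntcp_params([(DoseValue(10, "Gy"), 0.2), (DoseValue(10, "Gy"), 0.4)])


# ---------------------------------------------------------------------------
# plan metrics / EQD2
# ---------------------------------------------------------------------------
class TestPlanMetrics:
    def test_uniform_dvh(self):
        m = dvh_metrics(DVH.from_bins("x", [(12.0, 1.0)]), [10.0, 20.0])
        assert m.dmax.gy == m.dmean.gy == pytest.approx(12.0)
        assert m.vx[10.0] == pytest.approx(100.0)
        assert m.vx[20.0] == pytest.approx(0.0)

    def test_two_bin_metrics_by_hand(self):
        dvh = DVH.from_bins("x", [(10.0, 0.75), (25.0, 0.25)])
        m = dvh_metrics(dvh, [20.0])
        assert m.dmean.gy == pytest.approx(13.75)
        assert m.vx[20.0] == pytest.approx(25.0)

    def test_vx_threshold_inclusive(self, two_bin_dvh):
        m = dvh_metrics(two_bin_dvh, [30.0])
        assert m.vx[30.0] == pytest.approx(50.0)

    def test_metrics_invariant_under_form_round_trip(self, two_bin_dvh):
        cum = convert_dvh(two_bin_dvh, "cumulative")
        m1 = dvh_metrics(two_bin_dvh, [20.0])
        m2 = dvh_metrics(cum, [20.0])
        assert m1.dmax.gy == m2.dmax.gy
        assert m1.dmean.gy == pytest.approx(m2.dmean.gy, rel=1e-12)
        assert m1.vx == m2.vx

    def test_eud_a1_equals_dmean(self, two_bin_dvh):
        assert compute_eud(two_bin_dvh, 1.0).eud.gy == pytest.approx(
            dvh_metrics(two_bin_dvh).dmean.gy, rel=1e-12
        )


class TestEQD2:
    def test_two_gray_per_fraction_is_fixed_point(self):
        dvh = DVH.from_bins("x", [(40.0, 1.0)])  # 20 fractions of 2 Gy
        out = eqd2_transform(dvh, 3.0, 20)
        assert out.dose_gy[0] == pytest.approx(40.0)

    def test_hand_computed_bin(self):
        dvh = DVH.from_bins("x", [(36.0, 1.0)])
        out = eqd2_transform(dvh, 3.0, 20)
        assert out.dose_gy[0] == pytest.approx(36.0 * (1.8 + 3.0) / 5.0)  # 34.56

    def test_volumes_unchanged_and_bad_alpha_beta_rejected(self, two_bin_dvh):
        out = eqd2_transform(two_bin_dvh, 2.0, 10)
        assert np.allclose(out.volume, two_bin_dvh.volume)
        with pytest.raises(ValidationError):
            eqd2_transform(two_bin_dvh, 0.0, 10)


def test_default_parameter_file_loads_and_validates():
    params = default_organ_params()
    assert {"heart", "thyroid", "lungs"} <= set(params)
    for p in params.values():
        assert p.d50.gy > 0 and p.gamma50 > 0 and p.a != 0
        assert p.source  # provenance tag is mandatory in the bundled set
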