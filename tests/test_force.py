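"""Force-spectroscopy unit tests: WLC model, event detection, fits, stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smhairpin.constants import kbt
from smhairpin.errors import AnalysisError, FitError, ParameterError
from smhairpin.force import (
    ForceDistanceCurve,
    RuptureSegment,
    WLCParams,
    aggregate_replicates,
    detect_rupture,
    filter_specific,
    fit_gaussian_hist,
    fit_wlc,
    ks_compare,
    wlc_extension,
    wlc_force,
)
from smhairpin.synthetic import FDGenParams, gen_fd_curves


class TestWLCModel:
    def test_zero_extension_gives_zero_force(self):
        assert wlc_force(0.0, WLCParams(Lp=0.38, Lc=33.0)) == 0.0

    def test_half_contour_identity(self):
        # F(Lc/2) = (1/4*4 - 1/4 + 1/2) kBT/Lp = 1.25 kBT/Lp
        p = WLCParams(Lp=0.38, Lc=33.0, temperature=298.0)
        expected = 1.25 * kbt(298.0) / 0.38
        assert wlc_force(16.5, p) == pytest.approx(expected, rel=1e-12)
        # hand evaluation: ~13.5 pN at room temperature
        assert wlc_force(16.5, p) == pytest.approx(13.5, abs=0.1)

    def test_domain_error_at_contour_length(self):
        p = WLCParams(Lp=0.38, Lc=33.0)
        with pytest.raises(ParameterError):
            wlc_force(33.0, p)
        with pytest.raises(ParameterError):
            wlc_force(-1.0, p)

    @given(st.floats(0.1, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, frac):
        p = WLCParams(Lp=0.38, Lc=33.0)
        x = frac * 33.0
        h = min(1e-4, (33.0 - x) / 2)
        assert wlc_force(x + h, p) > wlc_force(x, p)

    def test_divergence_near_contour_length(self):
        p = WLCParams(Lp=0.38, Lc=33.0)
        assert wlc_force(33.0 * (1 - 1e-9), p) > 1e6

    @given(st.floats(1.0, 500.0))
    @settings(max_examples=30, deadline=None)
    def test_extension_inverts_force(self, f):
        p = WLCParams(Lp=0.38, Lc=33.0)
        x = wlc_extension(f, p)
        assert wlc_force(x, p) == pytest.approx(f, rel=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            WLCParams(Lp=40.0, Lc=33.0)
        with pytest.raises(ParameterError):
            WLCParams(Lp=-1.0, Lc=33.0)


def _make_wlc_curve(fr=164.0, lc=33.0, lp=0.38, noise=0.0, seed=0, dx=0.05):
    """Distance-sampled curve with one WLC ramp rupturing at force fr."""
    rng = np.random.default_rng(seed)
    params = WLCParams(Lp=lp, Lc=lc)
    x = np.arange(0.0, 55.0, dx)
    x_rup = wlc_extension(fr, params)
    f = np.where(x < x_rup, 0.0, 0.0)
    f[x < x_rup] = wlc_force(x[x < x_rup], params)
    if noise > 0:
        f = f + rng.normal(0, noise, x.size)
    return ForceDistanceCurve(distance=x, force=f, id="synthetic"), x_rup


class TestRuptureDetection:
    def test_noise_only_curve_has_no_event(self, rng):
        x = np.arange(0.0, 55.0, 0.05)
        curve = ForceDistanceCurve(distance=x, force=rng.normal(0, 10, x.size))
        assert detect_rupture(curve) is None

    def test_known_rupture_position_recovered(self):
        curve, x_rup = _make_wlc_curve(noise=10.0, seed=3)
        seg = detect_rupture(curve)
        assert seg is not None
        assert abs(seg.x_rupture - x_rup) <= 0.05  # within one sample

    def test_short_range_adhesion_excluded(self, rng):
        x = np.arange(0.0, 55.0, 0.05)
        f = rng.normal(0, 5, x.size)
        peak = 3.0
        f[x <= peak] += 80.0 * x[x <= peak] / peak
        fall = (x > peak) & (x < 6.0)
        f[fall] += 80.0 * (6.0 - x[fall]) / 3.0
        curve = ForceDistanceCurve(distance=x, force=f)
        assert detect_rupture(curve) is None

    def test_yield_matches_specific_fraction(self):
        params = FDGenParams(n_curves=500, specific_fraction=0.09, seed=11)
        curves, truth = gen_fd_curves(params)
        n_events = sum(detect_rupture(c) is not None for c in curves)
        assert 0.06 <= n_events / 500 <= 0.12  # ~8-10% experimental yield

    def test_false_positive_rate_below_one_percent(self):
        params = FDGenParams(n_curves=300, specific_fraction=0.0,
                             nonspecific_fraction=0.0, seed=12)
        curves, _ = gen_fd_curves(params)
        n_events = sum(detect_rupture(c) is not None for c in curves)
        assert n_events / 300 < 0.01


class TestWLCFitting:
    def test_noise_free_round_trip(self):
        curve, x_rup = _make_wlc_curve(noise=0.0)
        seg = detect_rupture(curve)
        ev = fit_wlc(seg)
        assert ev.Lp == pytest.approx(0.38, rel=1e-3)
        assert ev.Lc == pytest.approx(33.0, rel=1e-3)

    def test_noisy_lc_recovery_within_ten_percent(self):
        devs = []
        for seed in range(30):
            curve, _ = _make_wlc_curve(noise=10.0, seed=seed)
            seg = detect_rupture(curve)
            if seg is None:
                continue
            ev = fit_wlc(seg)
            devs.append(abs(ev.Lc - 33.0) / 33.0)
        assert len(devs) >= 25
        assert np.median(devs) < 0.10

    def test_flat_segment_raises(self):
        seg = RuptureSegment(x=np.linspace(5, 20, 50), f=np.zeros(50),
                             x_rupture=20.0, drop_pn=0.0, noise_sd=1.0)
        with pytest.raises(FitError):
            fit_wlc(seg)

    def test_fixed_lp_option(self):
        curve, _ = _make_wlc_curve(noise=0.0)
        seg = detect_rupture(curve)
        ev = fit_wlc(seg, fix_lp=0.38)
        assert ev.Lp == 0.38
        assert ev.Lc == pytest.approx(33.0, rel=1e-3)


class TestSpecificFilter:
    def _event(self, fr, lc):
        return type("E", (), {"Fr": fr, "Lc": lc})()

    def test_window_and_floor(self):
        events = [self._event(164.0, 31.0),   # kept: Lc in window
                  self._event(164.0, 80.0),   # rejected: Lc outside
                  self._event(15.0, 31.0)]    # rejected: below noise floor
        kept = filter_specific(events, lc_window=(23, 43), noise_floor_pn=20.0)
        assert len(kept) == 1 and kept[0].Lc == 31.0

    def test_never_increases_count_and_empty_ok(self):
        assert filter_specific([]) == []


class TestGaussianHistogram:
    def test_recovery_of_normal_sample(self, rng):
        values = rng.normal(164.0, 17.0, 180)
        res = fit_gaussian_hist(values)
        se = 17.0 / np.sqrt(180)
        assert abs(res.mean - 164.0) < 3 * se
        assert res.n == 180

    def test_identical_values_raise(self):
        with pytest.raises(FitError):
            fit_gaussian_hist(np.full(50, 42.0))

    def test_bimodal_sample_flagged_by_large_residual(self, rng):
        # a single Gaussian cannot represent both modes: the fit lands
        # between/on them and the residual exposes the model mismatch
        a = rng.normal(100.0, 3.0, 200)
        b = rng.normal(200.0, 3.0, 200)
        res = fit_gaussian_hist(np.concatenate([a, b]), bin_width=5.0)
        unimodal = fit_gaussian_hist(rng.normal(150.0, 5.0, 400), bin_width=5.0)
        assert 100.0 - 10.0 <= res.mean <= 200.0 + 10.0
        assert res.rss > 5 * unimodal.rss  # flagged poor fit by residual

    def test_too_few_values(self):
        with pytest.raises(FitError):
            fit_gaussian_hist(np.arange(5.0))


class TestReplicatesAndKS:
    def test_identical_replicates(self):
        assert aggregate_replicates([164.0, 164.0, 164.0]) == (164.0, 0.0)

    def test_hand_computed_sd(self):
        mean, sd = aggregate_replicates([150.0, 164.0, 178.0])
        assert mean == pytest.approx(164.0)
        assert sd == pytest.approx(14.0)

    def test_single_replicate_raises(self):
        with pytest.raises(AnalysisError):
            aggregate_replicates([164.0])

    def test_ks_identical_samples(self, rng):
        a = rng.normal(0, 1, 100)
        d, p = ks_compare(a, a)
        assert d == 0.0 and p == 1.0

    def test_ks_disjoint_supports(self, rng):
        d, _ = ks_compare(rng.uniform(0, 1, 50), rng.uniform(10, 11, 50))
        assert d == 1.0

    def test_ks_separated_groups_significant(self, rng):
        a = rng.normal(164, 17, 180)
        b = rng.normal(100, 6, 175)
        _, p = ks_compare(a, b)
        assert p < 0.005

    def test_ks_undersized_groups(self, rng):
        with pytest.raises(AnalysisError):
            ks_compare(rng.normal(0, 1, 5), rng.normal(0, 1, 100))
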