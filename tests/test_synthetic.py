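"""Generator unit tests: determinism, ground truth, degenerate settings."""

import numpy as np
import pytest

from smhairpin.errors import ParameterError
from smhairpin.synthetic import (
    DihedralGenParams,
    DihedralState,
    FDGenParams,
    TopoFeature,
    TopoGenParams,
    TraceGenParams,
    gen_cg_dimer,
    gen_dihedral_traj,
    gen_dwell_dataset,
    gen_fd_curves,
    gen_intensity_traces,
    gen_topograph,
)


class TestFDCurves:
    def test_specific_count_is_exact(self):
        curves, truth = gen_fd_curves(FDGenParams(n_curves=2000,
                                                  specific_fraction=0.09, seed=0))
        n_spec = sum(t["kind"] == "specific" for t in truth)
        assert n_spec == 180
        assert len(curves) == 2000

    def test_fixed_seed_bitwise_identical(self):
        p = FDGenParams(n_curves=20, seed=7)
        c1, t1 = gen_fd_curves(p)
        c2, t2 = gen_fd_curves(p)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.force, b.force)
        assert t1 == t2

    def test_degenerate_spreads_give_exact_rupture_force(self):
        p = FDGenParams(n_curves=30, rupture_sd=0.0, noise_sd=0.0,
                        lc_sd=0.0, specific_fraction=1.0,
                        nonspecific_fraction=0.0, seed=1)
        _, truth = gen_fd_curves(p)
        assert all(t["Fr"] == p.rupture_mean for t in truth)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ParameterError):
            FDGenParams(specific_fraction=0.7, nonspecific_fraction=0.5)

    def test_rupture_force_moments_converge(self):
        """Ground-truth Fr moments match (mean, sd) at n = 10,000 draws."""
        p = FDGenParams(n_curves=10000, specific_fraction=1.0,
                        nonspecific_fraction=0.0, noise_sd=0.0, seed=2)
        _, truth = gen_fd_curves(p)
        fr = np.array([t["Fr"] for t in truth])
        se_mean = p.rupture_sd / np.sqrt(fr.size)
        assert abs(fr.mean() - p.rupture_mean) < 3 * se_mean
        se_sd = p.rupture_sd / np.sqrt(2 * fr.size)
        assert abs(fr.std(ddof=1) - p.rupture_sd) < 3 * se_sd


class TestIntensityTraces:
    def test_single_500ms_dwell_spans_five_frames(self):
        p = TraceGenParams.from_mean(500.0, 0.0, n_traces=1, burst_rate=1 / 120.0,
                                     seed=3)
        traces, truth = gen_intensity_traces(p)
        for events in truth:
            for ev in events:
                assert ev["n_frames"] == 5
                assert ev["dwell_true_ms"] == pytest.approx(500.0)

    def test_zero_burst_rate_flat_traces(self):
        p = TraceGenParams(n_traces=3, burst_rate=0.0, seed=4)
        traces, truth = gen_intensity_traces(p)
        assert all(len(ev) == 0 for ev in truth)
        for trace in traces:
            assert np.abs(trace.intensity).max() < 10 * 30.0

    def test_zero_sigma_dwells_all_equal(self):
        traces, truth = gen_dwell_dataset(40, 800.0, sigma=0.0, seed=5)
        dwells = [ev["dwell_true_ms"] for tr in truth for ev in tr]
        assert dwells == pytest.approx([800.0] * len(dwells))
        assert len(dwells) == 40

    def test_quantized_within_one_frame_of_truth(self):
        traces, truth = gen_dwell_dataset(100, 617.0, seed=6)
        for tr in truth:
            for ev in tr:
                assert abs(ev["dwell_quantized_ms"] - ev["dwell_true_ms"]) \
                    <= 100.0

    def test_sub_resolution_flagged(self):
        traces, truth = gen_dwell_dataset(200, 150.0, sigma=1.0, seed=7)
        flagged = [ev for tr in truth for ev in tr if ev["sub_resolution"]]
        assert all(ev["dwell_true_ms"] < 100.0 for ev in flagged)
        assert all(ev["n_frames"] == 1 for ev in flagged)

    def test_fixed_seed_determinism(self):
        p = TraceGenParams(n_traces=2, seed=8)
        t1, _ = gen_intensity_traces(p)
        t2, _ = gen_intensity_traces(p)
        np.testing.assert_array_equal(t1[0].intensity, t2[0].intensity)


class TestTopographs:
    def test_fibril_apex_equals_stated_height(self):
        feat = TopoFeature(shape="fibril", height_nm=6.0, size_nm=40.0,
                           position=(64.0, 64.0))
        topo = gen_topograph(TopoGenParams(grid=(128, 128), features=(feat,),
                                           roughness_sd=0.0))
        assert topo.heights.max() == pytest.approx(6.0, abs=1e-9)

    def test_empty_features_roughness_only(self):
        topo = gen_topograph(TopoGenParams(grid=(64, 64), features=(),
                                           roughness_sd=0.05, seed=9))
        assert abs(topo.heights.mean()) < 0.01
        assert 0.03 < topo.heights.std() < 0.07

    def test_overlapping_features_compose_by_max(self):
        f1 = TopoFeature(shape="disk", height_nm=1.0, size_nm=30.0,
                         position=(32.0, 32.0))
        f2 = TopoFeature(shape="disk", height_nm=2.0, size_nm=30.0,
                         position=(32.0, 32.0))
        topo = gen_topograph(TopoGenParams(grid=(64, 64), features=(f1, f2),
                                           roughness_sd=0.0))
        assert topo.heights.max() == pytest.approx(2.0)  # max, never 3.0

    def test_feature_outside_grid_rejected(self):
        feat = TopoFeature(shape="cap", height_nm=2.0, size_nm=20.0,
                           position=(500.0, 10.0))
        with pytest.raises(ParameterError):
            TopoGenParams(grid=(64, 64), features=(feat,))


class TestDihedralTrajectories:
    def test_occupancy_ratio_converges(self):
        c = tuple([0.0] * 12)
        params = DihedralGenParams(
            n_frames=40000, n_residues=6, seed=10,
            states=(DihedralState(c, 20.0, 0.8),
                    DihedralState(tuple([120.0] * 12), 20.0, 0.2)))
        _, labels = gen_dihedral_traj(params)
        ratio = (labels == 0).sum() / (labels == 1).sum()
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_zero_scatter_single_state_identical_frames(self):
        c = tuple([30.0] * 8)
        params = DihedralGenParams(n_frames=50, n_residues=4, seed=11,
                                   states=(DihedralState(c, 0.0, 1.0),))
        traj, _ = gen_dihedral_traj(params)
        assert np.all(traj.angles == traj.angles[0])
        np.testing.assert_allclose(traj.angles[0], 30.0)

    def test_occupancies_must_sum_to_one(self):
        c = tuple([0.0] * 8)
        with pytest.raises(ParameterError):
            DihedralGenParams(n_residues=4,
                              states=(DihedralState(c, 10.0, 0.5),
                                      DihedralState(c, 10.0, 0.3)))

    def test_fixed_seed_identical_trajectory(self):
        c = tuple([0.0] * 8)
        params = DihedralGenParams(n_frames=100, n_residues=4, seed=12,
                                   states=(DihedralState(c, 5.0, 1.0),))
        t1, _ = gen_dihedral_traj(params)
        t2, _ = gen_dihedral_traj(params)
        np.testing.assert_array_equal(t1.angles, t2.angles)


class TestCGDimers:
    def test_hm_has_six_inter_chain_contacts(self):
        model = gen_cg_dimer("HM")
        inter = model.inter_contacts
        assert len(inter) == 6  # five H-bonds + the Lys-Asp salt bridge
        salt = [c for c in inter if c.cls == "saltbridge"]
        assert len(salt) == 1
        assert salt[0].depth == pytest.approx(
            2 * [c for c in inter if c.cls == "inter"][0].depth)

    def test_hh_has_four_inter_chain_contacts(self):
        model = gen_cg_dimer("HH")
        assert len(model.inter_contacts) == 4
        assert all(c.cls == "inter" for c in model.inter_contacts)

    def test_chain_lengths_follow_sequences(self):
        hm = gen_cg_dimer("HM")
        # hairpin CHQKLVFFAED-YNGK-HQKLVFFAED = 25 beads, monomer 11
        assert np.bincount(hm.chain_of).tolist() == [25, 11]
        hh = gen_cg_dimer("HH")
        assert np.bincount(hh.chain_of).tolist() == [25, 25]

    def test_pulling_groups_are_chain_n_termini(self):
        for kind in ("HM", "HH"):
            model = gen_cg_dimer(kind)
            a, b = model.pulling_groups
            assert a == 0 and b == 25
            assert model.chain_of[a] != model.chain_of[b]

    def test_invalid_kind_rejected(self):
        with pytest.raises(ParameterError):
            gen_cg_dimer("XX")
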