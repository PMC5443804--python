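"""Monte Carlo pulling unit tests: energy model, engine, statistics."""

import numpy as np
import pytest

from smhairpin.errors import AnalysisError, ParameterError
from smhairpin.mcpull import (
    CGModel,
    Contact,
    PullConfig,
    energy,
    mc_pull,
    rupture_stats,
    sample_equilibrium,
)
from smhairpin.synthetic import gen_cg_dimer


@pytest.fixture(scope="module")
def hm_model():
    return gen_cg_dimer("HM")


@pytest.fixture(scope="module")
def hh_model():
    return gen_cg_dimer("HH")


class TestEnergy:
    def test_native_energy_is_sum_of_well_depths(self, hm_model, hh_model):
        for model in (hm_model, hh_model):
            expected = -sum(c.depth for c in model.contacts)
            assert energy(model) == pytest.approx(expected, abs=0.1)

    def test_bond_stretch_is_harmonic(self, hm_model):
        # stretch via the terminal bead, which carries a single bond
        coords = hm_model.coords.copy()
        i, j, r0, k = hm_model.bonds[0]
        assert i == 0
        e0 = energy(hm_model, coords)
        delta = 0.05
        direction = (coords[i] - coords[j]) / np.linalg.norm(coords[i] - coords[j])
        coords2 = coords.copy()
        coords2[i] += delta * direction
        de = energy(hm_model, coords2) - e0
        assert de == pytest.approx(0.5 * k * delta ** 2, rel=0.05)

    def test_removing_contact_shallows_minimum(self, hm_model):
        reduced = CGModel(coords=hm_model.coords.copy(),
                          chain_of=hm_model.chain_of.copy(),
                          bonds=list(hm_model.bonds),
                          contacts=hm_model.contacts[:-1],
                          pulling_groups=hm_model.pulling_groups)
        removed = hm_model.contacts[-1]
        assert energy(reduced) == pytest.approx(
            energy(hm_model) + removed.depth, abs=0.1)

    def test_overlapping_beads_finite_energy(self):
        model = CGModel(coords=np.zeros((2, 3)), chain_of=np.array([0, 1]),
                        bonds=[], contacts=[], pulling_groups=(0, 1))
        e = energy(model)
        assert np.isfinite(e) and e > 100.0

    def test_random_configurations_never_nan(self, hm_model, rng):
        for _ in range(10):
            coords = rng.normal(0, 2, hm_model.coords.shape)
            assert np.isfinite(energy(hm_model, coords))


class TestPullingEngine:
    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            PullConfig(k_spring=-1.0)
        with pytest.raises(ParameterError):
            PullConfig(velocity_v=0.0)
        with pytest.raises(ParameterError):
            PullConfig(contact_break_fraction=1.5)

    def test_seeded_determinism(self, hm_model):
        cfg = PullConfig(sweeps=200, seed=42)
        t1 = mc_pull(hm_model, cfg)
        t2 = mc_pull(hm_model, cfg)
        assert t1.rupture_force == t2.rupture_force
        np.testing.assert_array_equal(t1.spring_force, t2.spring_force)

    def test_no_inter_contacts_ruptures_at_low_force(self, hm_model):
        stripped = CGModel(
            coords=hm_model.coords.copy(), chain_of=hm_model.chain_of.copy(),
            bonds=list(hm_model.bonds),
            contacts=[c for c in hm_model.contacts if c.cls == "intra"],
            pulling_groups=hm_model.pulling_groups)
        trace = mc_pull(stripped, PullConfig(sweeps=400, seed=3))
        bound = mc_pull(hm_model, PullConfig(sweeps=1200, seed=3))
        assert trace.rupture_sweep == 0
        assert trace.rupture_force < bound.rupture_force / 3

    def test_acceptance_rate_reasonable(self, hm_model):
        trace = mc_pull(hm_model, PullConfig(sweeps=200, seed=0))
        assert 0.2 < trace.accept_rate < 0.8

    def test_rupture_force_is_max_before_rupture(self, hm_model):
        trace = mc_pull(hm_model, PullConfig(seed=5))
        assert trace.rupture_sweep is not None
        assert trace.rupture_force == pytest.approx(
            trace.spring_force[:trace.rupture_sweep + 1].max())


class TestOrderingSmall:
    def test_hm_stronger_than_hh_small_batch(self, hm_model, hh_model):
        """10-seed smoke version of the H-M > H-H force ordering."""
        hm_f = [mc_pull(hm_model, PullConfig(seed=s)).rupture_force
                for s in range(10)]
        hh_f = [mc_pull(hh_model, PullConfig(seed=s)).rupture_force
                for s in range(10)]
        assert np.mean(hm_f) > np.mean(hh_f)


class TestLoadingRate:
    def test_doubling_velocity_does_not_lower_rupture_force(self, hm_model):
        """Faster loading cannot soften the bond (Bell-Evans monotonicity)."""
        f_v = np.array([mc_pull(hm_model, PullConfig(seed=s)).rupture_force
                        for s in range(15)])
        f_2v = np.array([mc_pull(hm_model,
                                 PullConfig(velocity_v=0.04, seed=s)).rupture_force
                         for s in range(15)])
        se_diff = np.sqrt(f_v.var(ddof=1) / 15 + f_2v.var(ddof=1) / 15)
        assert f_2v.mean() >= f_v.mean() - 2 * se_diff


class TestDetailedBalance:
    def test_two_bead_bond_length_boltzmann_distributed(self):
        model = CGModel(coords=np.array([[0.0, 0, 0], [0.5, 0, 0]]),
                        chain_of=np.array([0, 0]),
                        bonds=[(0, 1, 0.5, 20.0)], contacts=[],
                        pulling_groups=None)
        samples, _ = sample_equilibrium(model, sweeps=6000, step_size=0.15,
                                        seed=7, thin=10, burn_in=500)
        r = np.linalg.norm(samples[:, 1] - samples[:, 0], axis=1)
        # expected marginal p(r) ~ r^2 exp(-beta k/2 (r-r0)^2)
        grid = np.linspace(0.01, 1.6, 2000)
        w = grid ** 2 * np.exp(-10.0 * (grid - 0.5) ** 2)
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        qs = np.interp(np.linspace(0, 1, 9)[1:-1], cdf, grid)
        edges = np.concatenate([[0.0], qs, [np.inf]])
        obs, _ = np.histogram(r, bins=edges)
        probs = np.diff(np.concatenate([[0.0], np.interp(qs, grid, cdf), [1.0]]))
        from scipy.stats import chisquare
        _, p = chisquare(obs, probs * r.size)
        assert p > 0.01


class TestRuptureStats:
    def test_identical_traces_zero_sd(self):
        mean, sd = rupture_stats([100.0, 100.0, 100.0])
        assert (mean, sd) == (100.0, 0.0)

    def test_hand_computed_sample_sd(self):
        mean, sd = rupture_stats([100.0, 120.0])
        assert mean == pytest.approx(110.0)
        assert sd == pytest.approx(14.1421, abs=1e-3)

    def test_single_trace_raises(self):
        with pytest.raises(AnalysisError):
            rupture_stats([100.0])
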