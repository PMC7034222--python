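"""Brownian-dynamics tracking, deposition statistics and pathline export."""

import numpy as np
import pytest

import nanoflux as nf
from nanoflux.flow import VelocityField
from nanoflux.lagrangian import DEPOSITED, EXITED, sample_inlet_radii


@pytest.fixture(scope="module")
def coarse_wall_mesh(channel):
    """Coarser wall clustering so moderate-diffusivity runs take large steps."""
    return nf.build_mesh(65, 49, 7, first_wall_spacing=3e-3, channel=channel)


class TestDeterministicLimits:
    def test_zero_diffusivity_all_exit(self, fc_low, poiseuille_field):
        """Streamlines are parallel to the wall: nothing deposits."""
        _, res = nf.simulate_particles(fc_low, 0.0, poiseuille_field, 2000,
                                       rng_seed=11)
        assert res.mass_loss_fraction == 0.0
        assert res.diagnostics["n_exited"] == 2000

    def test_zero_diffusivity_exit_times_match_streamline_transit(
            self, fc_low, poiseuille_field):
        """With flux-weighted seeding, exit time is L/u(r0) per particle."""
        ens, _ = nf.simulate_particles(fc_low, 0.0, poiseuille_field, 10,
                                       rng_seed=3, record_pathlines=10)
        L = fc_low.channel.length
        for pl in ens.pathlines:
            u0 = nf.poiseuille_velocity(pl.r[0], fc_low)
            expected = L / u0
            assert pl.t[-1] == pytest.approx(expected, abs=ens.time_step * 1.01)

    def test_seeded_determinism(self, fc_low, diffusivity_144, poiseuille_field):
        runs = [nf.simulate_particles(fc_low, diffusivity_144, poiseuille_field,
                                      500, rng_seed=99)[0] for _ in range(2)]
        assert np.array_equal(runs[0].status, runs[1].status)
        assert np.array_equal(runs[0].positions, runs[1].positions)


class TestInletSampling:
    def test_flux_weighted_cdf(self, poiseuille_field, fc_low):
        """Sampled radii follow P(r <= x R) = 2 x^2 - x^4 (Poiseuille flux)."""
        rng = np.random.default_rng(5)
        r = sample_inlet_radii(rng, 40000, poiseuille_field)
        x = r / fc_low.channel.radius
        for q in (0.2, 0.5, 0.8):
            expected = 2.0 * q**2 - q**4
            assert np.mean(x <= q) == pytest.approx(expected, abs=0.01)


class TestEnsembleBookkeeping:
    def test_status_partition(self, fc_low, diffusivity_144, poiseuille_field):
        ens, res = nf.simulate_particles(fc_low, diffusivity_144, poiseuille_field,
                                         3000, rng_seed=21)
        assert ens.n_deposited + ens.n_exited + ens.n_in_transit == 3000
        d = res.diagnostics
        assert d["n_deposited"] + d["n_exited"] + d["n_stuck"] == 3000

    def test_deposited_at_wall_exited_past_outlet(self, fc_low, channel,
                                                  coarse_wall_mesh):
        D = 1e-9  # inflated diffusivity for countable deposition
        field = VelocityField.fully_developed(fc_low, coarse_wall_mesh)
        ens, _ = nf.simulate_particles(fc_low, D, field, 2000, rng_seed=8)
        r = ens.positions[:, 0]
        z = ens.positions[:, 2]
        assert np.all(r[ens.status == DEPOSITED] >= channel.radius * 0.99)
        assert np.all(z[ens.status == EXITED] >= channel.length)

    def test_time_step_bound_enforced(self, fc_low, diffusivity_144,
                                      poiseuille_field):
        with pytest.raises(nf.ConfigurationError):
            nf.simulate_particles(fc_low, diffusivity_144, poiseuille_field,
                                  10, time_step=10.0, rng_seed=0)

    def test_invalid_counts(self, fc_low, diffusivity_144, poiseuille_field):
        with pytest.raises(nf.InvalidInputError):
            nf.simulate_particles(fc_low, diffusivity_144, poiseuille_field, 0,
                                  rng_seed=0)


class TestDepositionPhysics:
    def test_monotone_in_diffusivity_length_velocity(self, nanofluid, channel):
        """Deposition rises with D_B and L, falls with mean velocity."""
        def loss(D, L, v):
            fc = nf.FlowConditions(nanofluid, nf.Channel(4e-3, L), v)
            mesh = nf.build_mesh(65, 49, 7, first_wall_spacing=3e-3,
                                 channel=fc.channel)
            field = VelocityField.fully_developed(fc, mesh)
            tot = sum(nf.simulate_particles(fc, D, field, 3000,
                                            rng_seed=400 + s)[1].diagnostics["n_deposited"]
                      for s in range(3))
            return tot / 9000.0

        base = loss(1e-9, 0.047, 0.0051)
        assert loss(3e-9, 0.047, 0.0051) > base
        assert loss(1e-9, 0.141, 0.0051) > base
        assert loss(1e-9, 0.047, 0.0153) < base

    def test_matches_eulerian_at_moderate_diffusivity(self, fc_low,
                                                      coarse_wall_mesh):
        """Monte-Carlo and Graetz losses agree where counts are plentiful."""
        D = 3.4e-10
        field = VelocityField.fully_developed(fc_low, coarse_wall_mesh)
        _, eul = nf.solve_graetz(fc_low, D, field, coarse_wall_mesh)
        _, lag = nf.simulate_particles(fc_low, D, field, 30000, rng_seed=77)
        se = lag.diagnostics["binomial_se"]
        assert abs(lag.mass_loss_fraction - eul.mass_loss_fraction) < 3.0 * se


class TestPathlines:
    def test_export_empty_sample(self, fc_low, diffusivity_144, poiseuille_field,
                                 tmp_path):
        ens, _ = nf.simulate_particles(fc_low, diffusivity_144, poiseuille_field,
                                       20, rng_seed=2, record_pathlines=5)
        out = tmp_path / "empty.vtk"
        assert nf.export_pathlines(ens, out, sample=0) == 0
        text = out.read_text()
        assert "POLYDATA" in text and "LINES 0 0" in text

    def test_point_counts_match_records(self, fc_low, diffusivity_144,
                                        poiseuille_field, tmp_path):
        ens, _ = nf.simulate_particles(fc_low, diffusivity_144, poiseuille_field,
                                       20, rng_seed=2, record_pathlines=4)
        out = tmp_path / "pl.vtk"
        nf.export_pathlines(ens, out)
        text = out.read_text().splitlines()
        n_points = int(next(l for l in text if l.startswith("POINTS")).split()[1])
        assert n_points == sum(len(pl) for pl in ens.pathlines)
        lines_hdr = next(l for l in text if l.startswith("LINES")).split()
        assert int(lines_hdr[1]) == len(ens.pathlines)

    def test_centreline_velocity_magnitude(self, fc_low, poiseuille_field,
                                           tmp_path):
        """A particle seeded on the axis carries |u| ~ 2 v_mean in the export."""
        ens, _ = nf.simulate_particles(fc_low, 0.0, poiseuille_field, 200,
                                       rng_seed=13, record_pathlines=200)
        axis_pl = min(ens.pathlines, key=lambda pl: pl.r[0])
        out = tmp_path / "axis.vtk"
        nf.export_pathlines(ens, out)
        u_axis = nf.poiseuille_velocity(axis_pl.r[0], fc_low)
        assert u_axis == pytest.approx(2.0 * fc_low.mean_inlet_velocity, rel=0.02)

    def test_recording_disabled_raises(self, fc_low, diffusivity_144,
                                       poiseuille_field, tmp_path):
        ens, _ = nf.simulate_particles(fc_low, diffusivity_144, poiseuille_field,
                                       10, rng_seed=1)
        with pytest.raises(nf.InvalidInputError):
            nf.export_pathlines(ens, tmp_path / "x.vtk")

    def test_pathline_time_strictly_increasing(self, fc_low, diffusivity_144,
                                               poiseuille_field):
        ens, _ = nf.simulate_particles(fc_low, diffusivity_144, poiseuille_field,
                                       5, rng_seed=6, record_pathlines=5)
        for i, pl in enumerate(ens.pathlines):
            assert np.all(np.diff(pl.t) > 0.0)
            assert pl.terminal_status == ens.status[i]
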