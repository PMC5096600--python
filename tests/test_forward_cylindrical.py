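import numpy as np
import pytest

import oasim as oa
from oasim.forward_cylindrical import (
    BinnedIntegrand,
    azimuthal_weights,
    bin_shell_contributions,
    default_bin_width,
    temporal_derivative,
)

CONST = oa.SourceConstant()


class TestAzimuthalWeights:
    def test_on_axis_closed_form(self):
        beam = oa.TopHatBeam(a=0.15, d=0.15 / 4)
        grid = oa.CylindricalGrid(0.3, 600, 90, 0.15, 30)
        tab = azimuthal_weights(beam, 0.0, grid)
        i = np.argmin(np.abs(tab.rho_values - 0.1))
        rho = tab.rho_values[i]
        assert tab.F_D[i] == pytest.approx(2 * np.pi * rho, rel=1e-12)

    def test_constant_beam_gives_ring_circumference(self):
        # a beam that is flat over the whole grid: F_D = 2 pi rho at any x_D
        beam = oa.TopHatBeam(a=10.0, d=1.0)
        grid = oa.CylindricalGrid(0.3, 100, 120, 0.15, 30)
        tab = azimuthal_weights(beam, 0.2, grid)
        np.testing.assert_allclose(tab.F_D, 2 * np.pi * tab.rho_values, rtol=1e-12)

    def test_ring_outside_beam_support_vanishes(self):
        beam = oa.TopHatBeam(a=0.01, d=0.005)
        grid = oa.CylindricalGrid(0.05, 100, 90, 0.15, 30)
        tab = azimuthal_weights(beam, 0.5, grid)  # rings never reach the beam
        assert np.all(tab.F_D < 1e-12)

    def test_explicit_sum_converges_to_shortcut(self):
        # off-axis sums at increasing N_phi converge to a fine reference
        beam = oa.TopHatBeam(a=0.15, d=0.15 / 4)
        x_D = 0.08
        ref = azimuthal_weights(
            beam, x_D, oa.CylindricalGrid(0.3, 200, 2880, 0.15, 30)
        ).F_D
        errs = []
        for n_phi in (45, 90, 180, 360):
            tab = azimuthal_weights(beam, x_D, oa.CylindricalGrid(0.3, 200, n_phi, 0.15, 30))
            errs.append(np.max(np.abs(tab.F_D - ref)) / np.max(ref))
        assert errs[0] > errs[-1]
        assert all(a >= b * 0.99 for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-4


class TestShellBinning:
    GRID = oa.CylindricalGrid(0.3, 300, 90, 0.15, 50)
    BEAM = oa.TopHatBeam(a=0.15, d=0.15 / 4)
    DET = oa.DetectionPoint(0.0, -0.5)

    def _bin(self, stack, **kw):
        w = azimuthal_weights(self.BEAM, self.DET.x_D, self.GRID)
        return bin_shell_contributions(
            w, stack, CONST, self.DET, self.GRID, bin_width=0.003, **kw
        )

    def test_clear_stack_gives_zero(self):
        clear = oa.LayerStack([oa.AbsorbingLayer(0.0, 0.1, 0.0)], L_z=0.15)
        assert np.all(self._bin(clear).q == 0.0)

    def test_thin_absorber_fills_single_bin(self):
        # absorber confined to one spherical shell thinner than a bin
        grid = oa.CylindricalGrid(0.001, 2, 90, 0.15, 150)  # near-axial pencil
        thin = oa.LayerStack([oa.AbsorbingLayer(0.07, 0.071, 10.0)], L_z=0.15)
        w = azimuthal_weights(self.BEAM, 0.0, grid)
        binned = bin_shell_contributions(w, thin, CONST, self.DET, grid, bin_width=0.005)
        assert np.count_nonzero(binned.q) == 1

    def test_total_mass_matches_cartesian_quadrature(self):
        """Binned mass must equal the direct 3D midpoint quadrature of
        the Poisson integrand W / |r - r'| over the source volume."""
        stack = oa.LayerStack(
            [oa.AbsorbingLayer(0.0, 0.05, 10.0), oa.AbsorbingLayer(0.05, 0.1, 20.0)],
            L_z=0.15,
        )
        det = oa.DetectionPoint(0.07, -0.4)
        grid = oa.CylindricalGrid(0.4, 800, 720, 0.15, 100)
        w = azimuthal_weights(self.BEAM, det.x_D, grid)
        binned = bin_shell_contributions(w, stack, CONST, det, grid, bin_width=0.002)

        # independent brute-force quadrature on a Cartesian voxel grid
        n = 180
        x = np.linspace(-0.4, 0.4, n, endpoint=False) + 0.4 / n
        y = x.copy()
        z = np.linspace(0, 0.15, 120, endpoint=False) + 0.15 / 240
        dv = (x[1] - x[0]) ** 2 * (z[1] - z[0])
        f = oa.beam_profile(self.BEAM, np.hypot(x[:, None], y[None, :]))
        g = oa.depth_profile_g(stack, z)
        total = 0.0
        for k, gz in enumerate(g):
            if gz == 0:
                continue
            dist = np.sqrt((x[:, None] - det.x_D) ** 2 + y[None, :] ** 2 + (z[k] + 0.4) ** 2)
            total += np.sum(f * gz / dist) * dv
        total *= CONST.prefactor / (4 * np.pi)
        assert binned.q.sum() == pytest.approx(total, rel=0.02)

    def test_insufficient_bin_range_rejected(self):
        stack = oa.LayerStack([oa.AbsorbingLayer(0.0, 0.1, 10.0)], L_z=0.15)
        with pytest.raises(ValueError, match="does not cover"):
            self._bin(stack, ct_min=0.5, n_bins=10)


class TestTemporalDerivative:
    DET = oa.DetectionPoint(0.0, -1.0)

    def _signal_of(self, q, bw=0.01):
        ct = 1.0 + np.arange(q.size) * bw
        return temporal_derivative(
            BinnedIntegrand(ct=ct, q=q, bin_width=bw, detection=self.DET)
        )

    def test_constant_integrand_gives_zero_pressure(self):
        sig = self._signal_of(np.full(50, 2.0))
        np.testing.assert_allclose(sig.p, 0.0, atol=1e-12)

    def test_linear_ramp_gives_constant_pressure(self):
        sig = self._signal_of(np.arange(50) * 0.25)
        np.testing.assert_allclose(sig.p, 0.25 / 0.01, rtol=1e-9)

    @pytest.mark.parametrize("n", [100, 200, 400])
    def test_sinusoid_derivative_second_order(self, n):
        # error of the central difference of sin(k ct) shrinks as O(d^2)
        k = 20.0
        bw = 0.2 / n
        ct = 1.0 + np.arange(n) * bw
        sig = temporal_derivative(
            BinnedIntegrand(ct=ct, q=np.sin(k * ct), bin_width=bw, detection=self.DET)
        )
        err = np.max(np.abs(sig.p[1:-1] - k * np.cos(k * ct[1:-1])))
        assert err < 0.6 * k * (k * bw) ** 2

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="3 bins"):
            self._signal_of(np.ones(2))


class TestSolve:
    def test_causality_of_leading_zeros(self, ff_signal):
        # nothing arrives before the detector-to-surface distance, up to the
        # foil window and derivative stencil
        margin = 0.005 / 2 + 2 * ff_signal.bin_width
        pre = ff_signal.p[ff_signal.ct < 4.0 - margin]
        assert pre.size > 0
        np.testing.assert_allclose(pre, 0.0, atol=1e-12)

    def test_linear_in_source_constant(self, two_layer, small_grid):
        det = oa.DetectionPoint(0.0, -0.5)
        kw = dict(grid=small_grid, foil=two_layer.foil)
        base = oa.solve(two_layer.stack, two_layer.beam, oa.SourceConstant(4 * np.pi), det, **kw)
        doubled = oa.solve(
            two_layer.stack, two_layer.beam, oa.SourceConstant(8 * np.pi), det, **kw
        )
        np.testing.assert_allclose(doubled.p, 2 * base.p, rtol=1e-12, atol=1e-15)

    def test_default_bin_width_matches_spatial_step(self, small_grid):
        assert default_bin_width(small_grid) == pytest.approx(small_grid.d_z)

    def test_far_field_spherical_spreading(self, two_layer):
        # integrated |p| decays as 1/|z_D| once in the far field; the peak
        # amplitude follows only when the foil window dominates the
        # diffraction smear, i.e. at larger standoff
        cfg = two_layer
        sigs = {
            zd: oa.solve(
                cfg.stack, cfg.beam, cfg.const, oa.DetectionPoint(0.0, zd),
                grid=cfg.grid, foil=cfg.foil,
            )
            for zd in (-2.0, -4.0, -8.0, -16.0)
        }
        area = {zd: np.trapezoid(np.abs(s.p), s.ct) for zd, s in sigs.items()}
        assert area[-2.0] / area[-4.0] == pytest.approx(2.0, rel=0.10)
        peak = {zd: np.max(np.abs(s.p)) for zd, s in sigs.items()}
        assert peak[-8.0] / peak[-16.0] == pytest.approx(2.0, rel=0.10)

    def test_deterministic(self, two_layer, small_grid):
        det = oa.DetectionPoint(0.1, -0.5)
        a = oa.solve(two_layer.stack, two_layer.beam, two_layer.const, det, grid=small_grid)
        b = oa.solve(two_layer.stack, two_layer.beam, two_layer.const, det, grid=small_grid)
        np.testing.assert_array_equal(a.p, b.p)
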