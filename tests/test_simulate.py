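import numpy as np
import pytest

import esrdecouple as esr
from esrdecouple.errors import (
    CombinatorialOverflowError,
    GridSpanError,
    InvalidInputError,
    UnsupportedSymmetryError,
)
from esrdecouple.simulate import FieldGrid, NucleusGroup, SpinSystem

from _oracles import multiplet_weights


class TestStickPattern:
    def test_six_equivalent_protons_binomial_septet(self):
        sticks = esr.stick_pattern([NucleusGroup(A=7.91, I=0.5, n=6)])
        assert len(sticks) == 7
        w = np.array([s[1] for s in sticks])
        np.testing.assert_allclose(w * 64, [1, 6, 15, 20, 15, 6, 1], atol=1e-12)

    def test_four_nitrogens_nonet(self):
        """Four I=1 nuclei split a line into nine with fourfold-(1,1,1) weights."""
        sticks = esr.stick_pattern([NucleusGroup(A=15.0, I=1.0, n=4)])
        assert len(sticks) == 9
        expect = multiplet_weights(4, 3)
        np.testing.assert_allclose(
            [s[1] for s in sticks], expect / expect.sum(), atol=1e-12
        )

    def test_single_copper_quartet(self):
        sticks = esr.stick_pattern([NucleusGroup(A=198.0, I=1.5, n=1)])
        assert len(sticks) == 4
        assert all(abs(s[1] - 0.25) < 1e-12 for s in sticks)
        offsets = [s[0] for s in sticks]
        np.testing.assert_allclose(np.diff(offsets), 198.0, atol=1e-9)

    def test_reference_radical_has_175_lines(self):
        cfg = esr.load_system("R1", band="L")
        assert cfg.system.n_lines == 7 * 5 * 5 == 175
        assert len(esr.stick_pattern(cfg.system.nuclei)) == 175

    def test_combinatorial_cap(self):
        groups = [NucleusGroup(A=1.0 + k, I=0.5, n=4) for k in range(10)]
        with pytest.raises(CombinatorialOverflowError):
            esr.stick_pattern(groups, cap=10_000)


class TestResonanceCondition:
    def test_free_electron_x_band(self):
        assert esr.center_field(2.0023, 9.8) == pytest.approx(3496.9, abs=0.5)

    def test_field_scaling_laws(self):
        b = esr.center_field(2.0, 9.8)
        assert esr.center_field(4.0, 9.8) == pytest.approx(b / 2, rel=1e-12)
        assert esr.center_field(2.0, 3.3) == pytest.approx(b * 3.3 / 9.8, rel=1e-12)

    def test_g_from_field_round_trip(self):
        b = esr.center_field(2.20, 9.8)
        assert esr.g_from_field(b, 9.8) == pytest.approx(2.20, rel=1e-12)
        assert esr.g_from_field(b / 2, 9.8) == pytest.approx(4.40, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            esr.center_field(-1.0, 9.8)
        with pytest.raises(InvalidInputError):
            esr.g_from_field(0.0, 9.8)


class TestIsotropic:
    def test_single_coupling_doublet_spacing(self):
        sysm = SpinSystem(
            g=2.0, nuclei=(NucleusGroup(10.0, 0.5, 1),), linewidth=0.5
        )
        spec = esr.simulate_isotropic(sysm, 9.8)
        pk = esr.find_lines(spec)
        assert pk.n_lines == 2
        assert np.diff(pk.crossings)[0] == pytest.approx(10.0, abs=0.05)

    def test_derivative_integrates_to_zero(self, r1_l, m2_x):
        """The integral of a derivative spectrum vanishes; truncated Lorentzian
        tails (x^-3 decay) leave a small, bounded residue."""
        gauss_resid = abs(np.sum(r1_l.intensity)) / np.sum(np.abs(r1_l.intensity))
        assert gauss_resid <= 1e-8
        lorentz_resid = abs(np.sum(m2_x.intensity)) / np.sum(np.abs(m2_x.intensity))
        assert lorentz_resid <= 5e-3

    def test_grid_too_narrow_reports_required_span(self):
        sysm = SpinSystem(g=2.0, nuclei=(NucleusGroup(50.0, 0.5, 1),), linewidth=1.0)
        with pytest.raises(GridSpanError, match="required span"):
            esr.simulate_isotropic(sysm, 9.8, grid=FieldGrid(3490, 3510, 256))

    def test_rejects_axial_system(self):
        sysm = SpinSystem(g=(2.0, 2.2), linewidth=1.0)
        with pytest.raises(UnsupportedSymmetryError):
            esr.simulate_isotropic(sysm, 9.8)


class TestAxialPowder:
    def test_degenerate_limit_equals_isotropic(self):
        iso = SpinSystem(g=2.1, nuclei=(NucleusGroup(12.0, 0.5, 2),), linewidth=2.0)
        axial = SpinSystem(
            g=(2.1, 2.1), nuclei=(NucleusGroup((12.0, 12.0), 0.5, 2),), linewidth=2.0
        )
        grid = FieldGrid(3250, 3420, 2048)
        a = esr.simulate_isotropic(iso, 9.8, grid)
        b = esr.simulate_axial_powder(axial, 9.8, grid, n_orient=512)
        scale = np.max(np.abs(a.intensity))
        np.testing.assert_allclose(a.intensity / scale, b.intensity / scale, atol=1e-6)

    def test_pure_g_anisotropy_edges(self):
        """Without hyperfine structure the derivative extremes mark B_par and B_perp."""
        sysm = SpinSystem(g=(2.05, 2.19), lineshape="lorentzian",
                          linewidth=6.5, linewidth_convention="peak-to-peak")
        spec = esr.simulate_axial_powder(sysm, 9.8, n_orient=1024)
        b_par = esr.center_field(2.19, 9.8)
        b_perp = esr.center_field(2.05, 9.8)
        # the perpendicular singularity carries the global derivative minimum,
        # the parallel edge a local maximum
        i_min = spec.field[np.argmin(spec.intensity)]
        assert abs(i_min - b_perp) <= 6.5
        from scipy.signal import find_peaks
        mx, _ = find_peaks(spec.intensity,
                           prominence=0.01 * np.max(np.abs(spec.intensity)))
        assert np.min(np.abs(spec.field[mx] - b_par)) <= 6.5

    def test_parallel_quartet_spacing_matches_a_par(self, m2_x_decoupled):
        """The low-field quartet of the Cu-N4 powder is spaced by A_par(Cu)."""
        pk = esr.find_lines(m2_x_decoupled.hyperfine)
        low = np.sort(pk.maxima)[:2]
        assert np.diff(low)[0] == pytest.approx(198.68, abs=2.0)

    def test_rejects_isotropic_g(self):
        with pytest.raises(UnsupportedSymmetryError):
            esr.simulate_axial_powder(SpinSystem(g=2.0, linewidth=1.0), 9.8)


class TestNoise:
    def test_zero_sigma_is_identity(self, r1_l):
        out = esr.add_noise(r1_l, 0.0, seed=1)
        np.testing.assert_array_equal(out.intensity, r1_l.intensity)

    def test_seeded_reproducibility(self, r1_l):
        a = esr.add_noise(r1_l, 0.02, seed=42)
        b = esr.add_noise(r1_l, 0.02, seed=42)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_noise_amplitude_calibration(self, r1_l):
        out = esr.add_noise(r1_l, 0.02, seed=7)
        target = 0.02 * np.max(np.abs(r1_l.intensity))
        measured = np.std(out.intensity - r1_l.intensity)
        assert abs(measured - target) <= 0.05 * target


def test_grid_convergence_of_extracted_splittings():
    """Doubling the grid density moves extracted splittings by < 0.02 G."""
    cfg = esr.load_system("R1", band="L")
    vals = {}
    for factor in (1, 2):
        g = cfg.grid
        spec = esr.simulate_isotropic(
            cfg.system, cfg.mw_freq_GHz,
            FieldGrid(g.start_G, g.stop_G, g.points * factor),
        )
        res = esr.pseudo_decouple(spec, j_star=7 + (factor - 1))  # same physical scale
        pk = esr.find_lines(res.hyperfine)
        vals[factor] = esr.splittings(pk).spacings.mean()
    assert abs(vals[1] - vals[2]) < 0.02
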