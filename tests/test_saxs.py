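"""SEC-SAXS reduction, Guinier/Kratky analysis, Debye profiles, fitting."""

import numpy as np
import pytest

import oligomod as om
from oligomod.errors import SpecError
from oligomod.saxs import (
    FrameSeries,
    ScatteringProfile,
    debye_profile,
    fit_theoretical,
    guinier_fit,
    normalized_kratky,
    read_profile,
    rg_from_coords,
    subtract_background,
    write_profile,
)
from oligomod.structio import Atom, Chain, Residue, StructureModel


def guinier_curve(q, i0=7.0, rg=25.0):
    return i0 * np.exp(-(q**2) * rg**2 / 3.0)


def point_model(positions, element="X"):
    chain = Chain("A")
    for i, p in enumerate(positions):
        chain.residues.append(
            Residue(i + 1, "GLY", atoms=[Atom("CA", element, np.asarray(p, float))])
        )
    return StructureModel(chains=[chain])


class TestProfileIO:
    def test_round_trip(self, tmp_path):
        q = np.linspace(0.01, 0.3, 20)
        p = ScatteringProfile(q, guinier_curve(q), sigma=np.full(20, 0.1))
        path = tmp_path / "p.dat"
        write_profile(p, path)
        back = read_profile(path)
        assert np.allclose(back.q, p.q)
        assert np.allclose(back.intensity, p.intensity)
        assert np.allclose(back.sigma, p.sigma)

    def test_headers_and_comments_skipped(self, tmp_path):
        path = tmp_path / "h.dat"
        path.write_text(
            "# experimental profile\nSample: test\n"
            "0.01 100.0 1.0\n0.02 95.0 1.0\n"
        )
        p = read_profile(path)
        assert len(p) == 2 and p.sigma is not None

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ScatteringProfile(np.array([0.2, 0.1]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            ScatteringProfile(np.array([0.1, 0.2]), np.array([1.0, 1.0]),
                              sigma=np.array([1.0, -1.0]))


class TestSubtractBackground:
    def _series(self, n=20, q=None, const=5.0):
        q = np.linspace(0.01, 0.3, 15) if q is None else q
        frames = [ScatteringProfile(q, np.full_like(q, const)) for _ in range(n)]
        return FrameSeries(frames=frames)

    def test_identical_constant_frames_cancel(self):
        series = self._series()
        out = subtract_background(series, range(0, 5), range(10, 15))
        assert np.allclose(out.intensity, 0.0, atol=1e-12)

    def test_linearity_recovers_added_curve(self):
        q = np.linspace(0.01, 0.3, 15)
        g = guinier_curve(q)
        frames = [ScatteringProfile(q, np.full_like(q, 5.0)) for _ in range(5)]
        frames += [ScatteringProfile(q, 5.0 + g) for _ in range(5)]
        out = subtract_background(FrameSeries(frames=frames), range(0, 5), range(5, 10))
        assert np.allclose(out.intensity, g, atol=1e-12)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(SpecError):
            subtract_background(self._series(), range(0, 5), range(4, 8))

    def test_out_of_range_frames_rejected(self):
        with pytest.raises(SpecError):
            subtract_background(self._series(), range(0, 5), range(50, 55))

    def test_sigma_propagated_in_quadrature(self):
        q = np.linspace(0.01, 0.3, 10)
        frames = [
            ScatteringProfile(q, np.full_like(q, 5.0), sigma=np.full_like(q, 2.0))
            for _ in range(8)
        ]
        out = subtract_background(FrameSeries(frames=frames), range(0, 4), range(4, 8))
        # mean of 4 frames: sigma 2/sqrt(4) = 1; difference: sqrt(2)
        assert np.allclose(out.sigma, np.sqrt(2.0), atol=1e-12)

    def test_synthetic_sec_series_recovery_within_3sigma(self):
        """Reduction of a simulated elution series recovers the injected
        particle curve pointwise within 3 propagated sigma."""
        q = np.linspace(0.01, 0.3, 60)
        particle = ScatteringProfile(q, guinier_curve(q, i0=100.0, rg=25.0))
        series, conc = om.simulate_sec_series(
            particle, n_frames=303, peak_center=139.0, peak_width=8.0,
            buffer_level=10.0,
            noise=om.NoiseSpec(seed=42, intensity_relative_sigma=0.01),
        )
        sample = range(134, 145)
        out = subtract_background(series, range(0, 15), sample)
        scale = conc[list(sample)].mean()
        assert out.sigma is not None
        resid = np.abs(out.intensity - scale * particle.intensity)
        assert np.all(resid <= 3.0 * out.sigma)


class TestRgFromCoords:
    def test_single_atom_zero(self):
        assert rg_from_coords(point_model([(1.0, 2.0, 3.0)])) == 0.0

    def test_two_unit_points(self):
        m = point_model([(0, 0, 0), (2.0, 0, 0)])
        assert rg_from_coords(m, weighting="uniform") == pytest.approx(1.0, abs=1e-12)

    def test_bead_sphere_analytic(self):
        sphere = om.make_bead_sphere(10.0, n_beads=5000, seed=3)
        assert rg_from_coords(sphere, "uniform") == pytest.approx(
            np.sqrt(3.0 / 5.0) * 10.0, rel=0.01
        )

    def test_electron_weighting_differs_from_uniform(self):
        chain = Chain("A", [
            Residue(1, "GLY", atoms=[Atom("CA", "C", np.zeros(3))]),
            Residue(2, "GLY", atoms=[Atom("O", "O", np.array([2.0, 0, 0]))]),
        ])
        m = StructureModel(chains=[chain])
        assert rg_from_coords(m, "electron_count") != pytest.approx(
            rg_from_coords(m, "uniform"), abs=1e-6
        )


class TestDebyeProfile:
    def test_single_atom_flat_f_squared(self):
        m = point_model([(0, 0, 0)], element="C")
        p = debye_profile(m, np.linspace(0.01, 0.5, 10))
        assert np.allclose(p.intensity, 36.0, atol=1e-9)  # f_C = 6 electrons

    def test_two_atoms_closed_form(self):
        d = 5.0
        m = point_model([(0, 0, 0), (d, 0, 0)], element="X")
        q = np.linspace(0.01, 1.0, 50)
        p = debye_profile(m, q)
        # I(q)/I(0) = (1 + sinc(qd))/2 for two equal scatterers
        expected = (1.0 + np.sinc(q * d / np.pi)) / 2.0
        assert np.allclose(p.intensity / p.intensity.max() * expected.max(),
                           expected, atol=1e-9)
        assert np.allclose(p.intensity, 2.0 + 2.0 * np.sinc(q * d / np.pi),
                           atol=1e-9)

    def test_q_zero_sinc_limit(self):
        m = point_model([(0, 0, 0), (3.0, 0, 0)], element="X")
        p = debye_profile(m, np.array([0.0, 0.1]))
        assert p.intensity[0] == pytest.approx(4.0, abs=1e-9)  # (sum f)^2

    def test_forward_intensity_is_total_scattering_squared(self):
        sphere = om.make_bead_sphere(8.0, n_beads=400, seed=4)
        p = debye_profile(sphere, np.array([1e-6]))
        assert p.intensity[0] == pytest.approx(400.0**2, rel=1e-6)

    def test_sphere_matches_analytic_form_factor(self):
        """Bead-sphere Debye curve tracks the analytic sphere form factor
        within 3% for qR <= 4.

        A single random bead realization carries Monte-Carlo structure noise
        that is amplified near the form-factor minimum, so the normalized
        intensity is ensemble-averaged over independent realizations (the
        residual 1/N incoherent floor is well below the tolerance).
        """
        R = 10.0
        q = np.linspace(0.02, 4.0 / R, 30)
        mean = np.zeros_like(q)
        n_realizations = 6
        for seed in range(n_realizations):
            sphere = om.make_bead_sphere(R, n_beads=12000, seed=seed)
            p = debye_profile(sphere, q)
            mean += p.intensity / p.intensity[0]
        mean /= n_realizations
        x = q * R
        analytic = (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
        assert np.max(np.abs(mean / (analytic / analytic[0]) - 1.0)) < 0.03

    def test_strictly_positive(self):
        sphere = om.make_bead_sphere(6.0, n_beads=300, seed=6)
        p = debye_profile(sphere, np.linspace(0.01, 1.0, 40))
        assert np.all(p.intensity > 0.0)

    def test_coarse_graining_approximates_full_sum(self):
        helix = om.make_helix(om.HelixSpec(n_residues=30))
        q = np.linspace(0.01, 0.15, 20)
        full = debye_profile(helix, q)
        coarse = debye_profile(helix, q, coarse_grain_threshold=10)
        assert np.allclose(coarse.intensity / coarse.intensity[0],
                           full.intensity / full.intensity[0], atol=0.02)


class TestGuinierFit:
    def test_exact_inversion(self):
        q = np.linspace(0.005, 0.2, 80)
        p = ScatteringProfile(q, guinier_curve(q, i0=7.0, rg=25.0))
        g = guinier_fit(p)
        assert g.rg == pytest.approx(25.0, abs=1e-6)
        assert g.i0 == pytest.approx(7.0, abs=1e-6)
        assert q[g.fit_range[1]] * g.rg <= 1.3 + 1e-9

    def test_noisy_recovery_within_2_percent(self):
        rng = np.random.default_rng(1234)
        q = np.linspace(0.005, 0.12, 50)
        clean = guinier_curve(q, i0=100.0, rg=25.0)
        noisy = clean * (1.0 + 0.01 * rng.normal(size=len(q)))
        g = guinier_fit(ScatteringProfile(q, noisy, sigma=0.01 * clean))
        assert g.rg == pytest.approx(25.0, rel=0.02)

    def test_scale_equivariance(self):
        q = np.linspace(0.005, 0.2, 60)
        p1 = ScatteringProfile(q, guinier_curve(q))
        p2 = ScatteringProfile(q, 13.0 * guinier_curve(q))
        g1, g2 = guinier_fit(p1), guinier_fit(p2)
        assert g2.rg == pytest.approx(g1.rg, abs=1e-9)
        assert g2.i0 == pytest.approx(13.0 * g1.i0, rel=1e-9)

    def test_rising_profile_rejected(self):
        q = np.linspace(0.01, 0.2, 30)
        with pytest.raises(SpecError):
            guinier_fit(ScatteringProfile(q, np.exp(q**2 * 100.0)))

    def test_debye_curve_of_globular_body_recovers_coordinate_rg(self):
        """Guinier analysis of the theoretical curve reproduces the
        coordinate-space radius of gyration within 1%.

        A noise-free hard body is fit in the strict Guinier regime
        (qRg <= 0.8): the log-space slope of a compact particle picks up a
        quartic-term bias growing as (q_max Rg)^2, which at the conventional
        1.3 bound alone amounts to ~2% for a uniform sphere.
        """
        sphere = om.make_bead_sphere(12.0, n_beads=2000, seed=7)
        rg_coords = rg_from_coords(sphere, "uniform")
        q = np.linspace(0.002, 0.2, 120)
        p = debye_profile(sphere, q)
        g = guinier_fit(p, q_rg_max=0.8)
        assert g.rg == pytest.approx(rg_coords, rel=0.01)


class TestNormalizedKratky:
    def test_guinier_peak_at_sqrt3(self):
        """For a pure Guinier curve the dimensionless Kratky peak is 3/e at
        qRg = sqrt(3)."""
        q = np.linspace(0.001, 0.2, 4000)
        p = ScatteringProfile(q, guinier_curve(q, i0=1.0, rg=25.0))
        g = guinier_fit(p)
        x, y = normalized_kratky(p, g)
        k = int(np.argmax(y[x < 3.0]))
        assert x[k] == pytest.approx(np.sqrt(3.0), abs=0.01)
        assert y[k] == pytest.approx(3.0 / np.e, abs=0.005)

    def test_zero_at_low_q(self):
        q = np.linspace(0.001, 0.2, 100)
        p = ScatteringProfile(q, guinier_curve(q))
        g = guinier_fit(p)
        x, y = normalized_kratky(p, g)
        assert y[0] < 1e-3
        assert len(x) == len(p)

    def test_extended_chain_plateaus(self):
        """An expanded-chain-like profile rises and flattens at qRg > 4,
        the signature of a flexible or extended particle."""
        q = np.linspace(0.002, 0.6, 400)
        rg = 25.0
        # Debye polymer form factor: globule-free, plateaus at 2 in
        # dimensionless Kratky representation
        x2 = (q * rg) ** 2
        debye_chain = 2.0 * (np.exp(-x2) - 1.0 + x2) / x2**2
        p = ScatteringProfile(q, debye_chain)
        g = guinier_fit(p)
        xk, yk = normalized_kratky(p, g)
        tail = yk[xk > 4.0]
        assert np.all(np.diff(yk[xk < 2.0]) > -1e-9)  # monotonic rise early
        assert tail.std() < 0.05 * tail.mean()  # plateau


class TestFitTheoretical:
    def test_exact_linear_recovery(self):
        q = np.linspace(0.01, 0.3, 50)
        theory = ScatteringProfile(q, guinier_curve(q, i0=10.0))
        exp = ScatteringProfile(q, 3.0 * theory.intensity + 2.0,
                                sigma=np.ones_like(q))
        fit = fit_theoretical(theory, exp)
        assert fit.scale == pytest.approx(3.0, rel=1e-9)
        assert fit.offset == pytest.approx(2.0, rel=1e-6)
        assert fit.chi2_reduced == pytest.approx(0.0, abs=1e-12)

    def test_reduced_chi2_near_one_for_matched_noise(self):
        rng = np.random.default_rng(77)
        q = np.linspace(0.01, 0.3, 100)
        theory = ScatteringProfile(q, guinier_curve(q, i0=100.0))
        sigma = np.full_like(q, 0.5)
        exp = ScatteringProfile(q, theory.intensity + rng.normal(0, 0.5, len(q)),
                                sigma=sigma)
        fit = fit_theoretical(theory, exp)
        assert fit.chi2_reduced == pytest.approx(1.0, abs=0.3)

    def test_missing_sigma_warns(self):
        q = np.linspace(0.01, 0.3, 20)
        theory = ScatteringProfile(q, guinier_curve(q))
        exp = ScatteringProfile(q, 2.0 * theory.intensity)
        with pytest.warns(UserWarning):
            fit = fit_theoretical(theory, exp)
        assert fit.scale == pytest.approx(2.0, rel=1e-9)

    def test_interpolates_different_grids(self):
        qt = np.linspace(0.005, 0.35, 200)
        qe = np.linspace(0.01, 0.3, 40)
        theory = ScatteringProfile(qt, guinier_curve(qt, i0=50.0))
        exp = ScatteringProfile(qe, 4.0 * guinier_curve(qe, i0=50.0),
                                sigma=np.ones_like(qe))
        fit = fit_theoretical(theory, exp)
        assert fit.scale == pytest.approx(4.0, rel=1e-3)
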