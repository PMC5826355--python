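import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss

from shoremaps.phantom import GM_EIGENVALUES, WM_EIGENVALUES, CompartmentSpec, simulate_voxel_signal
from shoremaps.shore import (
    ShoreFit,
    estimate_zeta,
    fit_shore,
    gfa,
    main_direction,
    msd,
    odf,
    pa,
    rtap,
    rtpp,
    shore_design_matrix,
    shore_index_set,
)
from shoremaps.tensor import fit_tensor

from conftest import shore_fit_of_tensor, tensor_signal

TAU = 0.0538


class TestBasis:
    def test_index_count_nmax6(self):
        assert len(shore_index_set(6)) == 50

    def test_odd_nmax_rejected(self):
        with pytest.raises(ValueError):
            shore_index_set(5)

    def test_origin_kills_anisotropic_columns(self):
        idx = shore_index_set(6)
        row = shore_design_matrix(np.zeros((1, 3)), 6, 700.0)[0]
        for j, (n, l, m) in enumerate(idx):
            if l > 0:
                assert row[j] == 0.0
            else:
                assert row[j] != 0.0

    def test_design_shape(self, scheme):
        M = shore_design_matrix(scheme, 6, 700.0)
        assert M.shape == (515, 50)

    def test_numeric_orthonormality(self):
        """int Phi_a Phi_b d^3q = delta_ab on a dense product quadrature
        (Gauss-Legendre radially and in cos(theta), uniform in phi)."""
        zeta = 700.0
        n_max = 6
        nr, nt, nph = 80, 24, 24
        xr, wr = leggauss(nr)
        rmax = 9 * np.sqrt(zeta)
        r = (xr + 1) / 2 * rmax
        wr = wr * rmax / 2
        xc, wc = leggauss(nt)  # cos(theta)
        phi = np.arange(nph) * 2 * np.pi / nph
        wphi = 2 * np.pi / nph
        ct, ph, rr = np.meshgrid(xc, phi, r, indexing="ij")
        st = np.sqrt(1 - ct**2)
        pts = np.stack(
            [rr * st * np.cos(ph), rr * st * np.sin(ph), rr * ct], axis=-1
        ).reshape(-1, 3)
        w = (
            wc[:, None, None]
            * np.full((1, nph, 1), wphi)
            * (wr * r**2)[None, None, :]
        ).ravel()
        M = shore_design_matrix(pts, n_max, zeta)
        gram = (M * w[:, None]).T @ M
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-3

    def test_estimate_zeta_value(self):
        assert estimate_zeta(1e-3, 0.02) == pytest.approx(633.26, rel=1e-3)

    def test_zeta_halves_when_tau_doubles(self):
        assert estimate_zeta(1e-3, 0.04) == pytest.approx(estimate_zeta(1e-3, 0.02) / 2)

    @pytest.mark.parametrize("md_val,tau", [(0.0, 0.02), (1e-3, 0.0), (-1e-3, 0.02)])
    def test_zeta_invalid(self, md_val, tau):
        with pytest.raises(ValueError):
            estimate_zeta(md_val, tau)


class TestFit:
    def test_roundtrip_random_coefficients(self, scheme):
        rng = np.random.default_rng(4)
        zeta = 650.0
        c = rng.normal(size=len(shore_index_set(6)))
        sig = shore_design_matrix(scheme, 6, zeta) @ c
        fit = fit_shore(sig, scheme, n_max=6, zeta=zeta, lambda_reg=0.0)
        assert np.abs(fit.coeffs - c).max() < 1e-8

    def test_isotropic_gaussian_is_purely_isotropic(self, scheme):
        d = 0.8e-3
        sig = np.exp(-scheme.bvals * d)
        fit = fit_shore(sig, scheme, n_max=6, zeta=estimate_zeta(d, scheme.tau))
        idx = fit.index_set
        aniso = sum(fit.coeffs[j] ** 2 for j, (n, l, m) in enumerate(idx) if l > 0)
        assert aniso / np.sum(fit.coeffs**2) < 1e-6
        assert np.abs(fit.predict_signal(scheme.qvecs) - sig).max() < 1e-10

    def test_underdetermined_without_regularization(self, scheme):
        sub = scheme.qvecs[:10]
        from shoremaps.qspace import AcquisitionScheme

        small = AcquisitionScheme(
            grid=scheme.grid[:10], qvecs=sub, bvals=scheme.bvals[:10],
            is_b0=scheme.is_b0[:10], radial_grid_size=5, b_max=8000.0, tau=TAU,
        )
        sig = np.ones(10)
        with pytest.raises(ValueError):
            fit_shore(sig, small, n_max=6, zeta=700.0, lambda_reg=0.0)


def iso_fit(scheme, d=1e-3, n_max=8):
    sig = np.exp(-scheme.bvals * d)
    return fit_shore(sig, scheme, n_max=n_max, zeta=estimate_zeta(d, scheme.tau))


class TestGaussianClosedForms:
    """The key oracle suite: on noiseless Gaussian signals the propagator
    indices match their closed forms.  The basis order is 8: the radial
    tail of the sharper tensors needs the extra two orders beyond the
    pipeline default to integrate within 1%."""

    def test_isotropic_rtap(self, scheme):
        d = 1e-3
        fit = iso_fit(scheme, d)
        assert rtap(fit, [0, 0, 1.0]) == pytest.approx(1 / (4 * np.pi * d * TAU), rel=0.01)

    def test_isotropic_rtpp(self, scheme):
        d = 1e-3
        fit = iso_fit(scheme, d)
        assert rtpp(fit, [0, 0, 1.0]) == pytest.approx(
            1 / np.sqrt(4 * np.pi * d * TAU), rel=0.01
        )

    def test_isotropic_msd_einstein(self, scheme):
        d = 1e-3
        fit = iso_fit(scheme, d)
        assert msd(fit) == pytest.approx(6 * d * TAU, rel=0.01)

    @pytest.mark.parametrize("evals", [WM_EIGENVALUES, GM_EIGENVALUES])
    def test_axially_symmetric_closed_forms(self, scheme, evals):
        lam_par, lam_perp, _ = evals
        fit = shore_fit_of_tensor(scheme, evals, n_max=8)
        direction = [0, 0, 1.0]
        assert rtap(fit, direction) == pytest.approx(
            1 / (4 * np.pi * lam_perp * TAU), rel=0.01
        )
        assert rtpp(fit, direction) == pytest.approx(
            1 / np.sqrt(4 * np.pi * lam_par * TAU), rel=0.01
        )
        assert msd(fit) == pytest.approx(6 * np.mean(evals) * TAU, rel=0.01)

    @pytest.mark.parametrize("evals", [WM_EIGENVALUES, (1e-3, 1e-3, 1e-3)])
    def test_dual_path_agreement(self, scheme, evals):
        """q-space (projection-slice) and EAP-space integrals agree."""
        fit = shore_fit_of_tensor(scheme, evals, n_max=8)
        d = [0, 0, 1.0]
        assert rtap(fit, d, method="eap") == pytest.approx(rtap(fit, d), rel=5e-3)
        assert rtpp(fit, d, method="eap") == pytest.approx(rtpp(fit, d), rel=5e-3)
        assert msd(fit, method="quadrature") == pytest.approx(msd(fit), rel=5e-3)

    def test_rtap_rtpp_rtop_separability(self, scheme):
        """For a Gaussian propagator RTAP * RTPP = RTOP = P(0)."""
        fit = shore_fit_of_tensor(scheme, WM_EIGENVALUES, n_max=8)
        rtop = float(fit.eap(np.zeros((1, 3)))[0])
        product = rtap(fit, [0, 0, 1.0]) * rtpp(fit, [0, 0, 1.0])
        assert product == pytest.approx(rtop, rel=0.02)

    def test_rtpp_invariant_to_inplane_rotation(self, scheme):
        fit = shore_fit_of_tensor(scheme, WM_EIGENVALUES, n_max=8)
        base = rtap(fit, [0, 0, 1.0])
        # the in-plane quadrature frame is arbitrary; perturbing the
        # direction's sign must not matter either (antipodal symmetry)
        assert rtap(fit, [0, 0, -1.0]) == pytest.approx(base, rel=1e-9)

    def test_zero_direction_errors(self, wm_fit):
        with pytest.raises(ValueError):
            rtap(wm_fit, [0.0, 0.0, 0.0])


class TestPa:
    def test_isotropic_part_only_gives_zero(self):
        idx = shore_index_set(6)
        c = np.zeros(len(idx))
        for j, (n, l, m) in enumerate(idx):
            if l == 0:
                c[j] = 1.0
        fit = ShoreFit(c, 6, 700.0, TAU)
        assert pa(fit) == 0.0

    def test_half_energy_split(self):
        idx = shore_index_set(6)
        c = np.zeros(len(idx))
        c[idx.index((0, 0, 0))] = 1.0
        c[idx.index((2, 2, 0))] = 1.0
        fit = ShoreFit(c, 6, 700.0, TAU)
        assert pa(fit) == pytest.approx(np.sqrt(0.5), rel=1e-12)

    def test_bounded_by_one(self, scheme):
        fit = shore_fit_of_tensor(scheme, (1.7e-3, 0.2e-3, 0.2e-3))
        assert 0.0 <= pa(fit) <= 1.0

    def test_all_zero_errors(self):
        fit = ShoreFit(np.zeros(len(shore_index_set(6))), 6, 700.0, TAU)
        with pytest.raises(ValueError):
            pa(fit)


class TestOdfGfa:
    def test_isotropic_odf_constant(self, scheme, sphere642):
        fit = iso_fit(scheme)
        vals, clipped = odf(fit, sphere642)
        assert not clipped
        assert np.std(vals) / np.mean(vals) < 1e-6
        assert gfa(vals) < 1e-6

    def test_peak_aligns_with_fiber(self, scheme, sphere642):
        e1 = np.array([0.0, 0.6, 0.8])
        fit = shore_fit_of_tensor(scheme, (1.7e-3, 0.3e-3, 0.3e-3), e1)
        vals, _ = odf(fit, sphere642)
        peak = sphere642.directions[np.argmax(vals)]
        angle = np.degrees(np.arccos(abs(np.clip(peak @ e1, -1, 1))))
        assert angle < 5.0

    def test_antipodal_symmetry(self, wm_fit, sphere642):
        vals, _ = odf(wm_fit, sphere642)
        # the tessellation is closed under u -> -u: match each direction
        d = sphere642.directions
        order = {tuple(np.round(v, 10)): i for i, v in enumerate(d)}
        for i, v in enumerate(d):
            j = order[tuple(np.round(-v, 10))]
            assert vals[i] == pytest.approx(vals[j], abs=1e-10)

    def test_gfa_constant_zero(self):
        assert gfa(np.full(100, 3.7)) == 0.0

    @pytest.mark.parametrize("n", [4, 17, 642])
    def test_gfa_single_spike_is_one(self, n):
        v = np.zeros(n)
        v[0] = 1.0
        assert gfa(v) == pytest.approx(1.0, rel=1e-12)

    def test_gfa_scale_invariant(self, wm_fit, sphere642):
        vals, _ = odf(wm_fit, sphere642)
        assert gfa(vals * 37.0) == pytest.approx(gfa(vals), rel=1e-12)

    def test_gfa_all_zero_errors(self):
        with pytest.raises(ValueError):
            gfa(np.zeros(10))


class TestMainDirection:
    def test_single_tensor_within_one_degree(self, dti_scheme):
        e1 = np.array([0.0, 0.6, 0.8])
        tf = fit_tensor(tensor_signal(dti_scheme, (1.7e-3, 0.3e-3, 0.3e-3), e1), dti_scheme)
        d, ambiguous = main_direction(tensor_fit=tf)
        assert not ambiguous
        assert np.degrees(np.arccos(abs(d @ e1))) < 1.0

    def test_crossing_flagged_ambiguous_under_dti(self, dti_scheme):
        evals = (1.7e-3, 0.3e-3, 0.3e-3)
        sig = simulate_voxel_signal(
            [
                CompartmentSpec(evals, (0, 0, 1.0), 0.5),
                CompartmentSpec(evals, (1.0, 0, 0), 0.5),
            ],
            dti_scheme,
        )
        tf = fit_tensor(sig, dti_scheme)
        _, ambiguous = main_direction(tensor_fit=tf)
        assert ambiguous

    def test_dti_and_odf_paths_agree_on_single_fiber(self, scheme, dti_scheme, sphere642):
        e1 = np.array([0.0, 0.6, 0.8])
        evals = (1.7e-3, 0.3e-3, 0.3e-3)
        tf = fit_tensor(tensor_signal(dti_scheme, evals, e1), dti_scheme)
        sf = shore_fit_of_tensor(scheme, evals, e1)
        d1, _ = main_direction(tensor_fit=tf, method="dti")
        d2, _ = main_direction(shore_fit=sf, sampling=sphere642, method="odf")
        assert np.degrees(np.arccos(abs(np.clip(d1 @ d2, -1, 1)))) < 5.0


class TestCrossingBehavior:
    def test_rtap_drops_rtpp_rises_in_crossings(self, scheme):
        """Moving from a single fiber to an orthogonal two-fiber crossing
        of the same per-compartment tensors lowers RTAP and raises RTPP."""
        evals = WM_EIGENVALUES
        single = simulate_voxel_signal(
            [CompartmentSpec(evals, (0, 0, 1.0), 1.0)], scheme
        )
        crossing = simulate_voxel_signal(
            [
                CompartmentSpec(evals, (0, 0, 1.0), 0.5),
                CompartmentSpec(evals, (1.0, 0, 0), 0.5),
            ],
            scheme,
        )
        md_true = float(np.mean(evals))
        zeta = estimate_zeta(md_true, scheme.tau)
        f1 = fit_shore(single, scheme, n_max=8, zeta=zeta)
        f2 = fit_shore(crossing, scheme, n_max=8, zeta=zeta)
        d = [0, 0, 1.0]
        assert rtap(f2, d) < rtap(f1, d)
        assert rtpp(f2, d) > rtpp(f1, d)


def test_msd_tracks_md_across_random_tensors(scheme):
    """MSD and MD are linearly related for Gaussian voxels (Einstein
    relation); across a random-tensor phantom they correlate near
    perfectly."""
    rng = np.random.default_rng(77)
    mds, msds = [], []
    for _ in range(120):
        lam = np.sort(rng.uniform(0.3e-3, 1.8e-3, 3))[::-1]
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        fit = shore_fit_of_tensor(scheme, tuple(lam), tuple(u), n_max=6)
        mds.append(np.mean(lam))
        msds.append(msd(fit))
    r = np.corrcoef(mds, msds)[0, 1]
    assert r > 0.95
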