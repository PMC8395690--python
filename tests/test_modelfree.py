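import numpy as np
import pytest

from bindentropy import modelfree as mf
from bindentropy import synthetic_data as syn
from bindentropy.observables import RateRecord

ISO7 = mf.DiffusionTensor.isotropic(7.0e-9)


# ---------------------------------------------------------------------------
# diffusion tensor geometry

def test_anisotropy_rhombicity_hand_values():
    assert mf.anisotropy_rhombicity(1.0, 2.0, 3.0) == pytest.approx((2.0, 1.0))
    assert mf.anisotropy_rhombicity(1.0, 1.0, 2.0) == pytest.approx((2.0, 0.0))
    assert mf.anisotropy_rhombicity(1.0, 1.0, 1.0) == pytest.approx((1.0, 0.0))


def test_anisotropy_rhombicity_requires_sorted():
    with pytest.raises(mf.InvalidInputError):
        mf.anisotropy_rhombicity(2.0, 1.0, 3.0)


def test_tensor_round_trip_zeta_eta():
    t = mf.DiffusionTensor.from_zeta_eta(2.5e7, 1.11, 0.4)
    assert t.zeta == pytest.approx(1.11, rel=1e-12)
    assert t.eta == pytest.approx(0.4, rel=1e-12)
    assert t.D_iso == pytest.approx(2.5e7, rel=1e-12)


def test_tensor_tau_c():
    assert ISO7.tau_c == pytest.approx(7.0e-9, rel=1e-12)
    assert ISO7.is_isotropic


def test_tensor_ordering_enforced():
    with pytest.raises(mf.InvalidInputError):
        mf.DiffusionTensor(3.0, 2.0, 1.0)


def test_correlation_amplitudes_sum_to_one():
    t = mf.DiffusionTensor.from_zeta_eta(2.4e7, 1.3, 0.6, euler=(0.4, 1.1, 2.0))
    rng = np.random.default_rng(1)
    for _ in range(5):
        v = rng.normal(size=3)
        amps, rates = t.correlation_components(v / np.linalg.norm(v))
        assert amps.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(rates > 0)


def test_correlation_axial_closed_form():
    # axially symmetric tensor: amplitudes reduce to the classic
    # (3cos^2 b - 1)^2/4, 3 sin^2 b cos^2 b, (3/4) sin^4 b at rates
    # 6Dper, 5Dper+Dpar, 2Dper+4Dpar
    dper, dpar = 2.0e7, 3.0e7
    t = mf.DiffusionTensor(dper, dper, dpar)
    beta = 0.7
    v = np.array([np.sin(beta), 0.0, np.cos(beta)])
    amps, rates = t.correlation_components(v)
    c2, s2 = np.cos(beta) ** 2, np.sin(beta) ** 2
    expect = {
        6 * dper: (3 * c2 - 1) ** 2 / 4,
        5 * dper + dpar: 3 * s2 * c2,
        2 * dper + 4 * dpar: 0.75 * s2 * s2,
    }
    got = {}
    for a, r in zip(amps, rates):
        got[round(r, 3)] = got.get(round(r, 3), 0.0) + a
    for r, a in expect.items():
        assert got[round(r, 3)] == pytest.approx(a, abs=1e-12)


def test_correlation_anisotropic_requires_orientation():
    t = mf.DiffusionTensor(1.0e7, 2.0e7, 3.0e7)
    with pytest.raises(mf.InvalidInputError):
        t.correlation_components(None)


# ---------------------------------------------------------------------------
# spectral density

def test_spectral_density_rigid_isotropic_J0():
    p = mf.ModelFreeParams(model_id="m1", O2=1.0)
    assert mf.spectral_density(p, ISO7, None, 0.0) == pytest.approx(
        0.4 * 7.0e-9, rel=1e-12)


def test_spectral_density_lorentzian_shape():
    p = mf.ModelFreeParams(model_id="m1", O2=1.0)
    tau = 7.0e-9
    w = 1.0 / tau
    assert mf.spectral_density(p, ISO7, None, w) == pytest.approx(
        0.4 * tau / 2.0, rel=1e-12)


def test_spectral_density_matches_cosine_transform_oracle():
    # J(w) = (2/5) * 2 * int_0^inf C(t) cos(wt) dt with
    # C(t) = C_O(t) * [O2 + (1-O2) exp(-t/tau_e)]
    t = mf.DiffusionTensor.from_zeta_eta(1.0 / (6 * 7e-9), 1.3, 0.6,
                                         euler=(0.4, 1.1, 2.0))
    v = np.array([0.3, -0.5, 0.81])
    v /= np.linalg.norm(v)
    p = mf.ModelFreeParams(model_id="m2", O2=0.8, tau_e=40e-12)
    amps, rates = t.correlation_components(v)

    # dense trapezoidal cosine transform: 0.1 ps grid resolves the 40 ps
    # internal decay, 200 ns span covers the ~7 ns tumbling tail
    tt = np.arange(0.0, 200e-9, 1e-13)
    Ct = (np.exp(-np.outer(tt, rates)) @ amps) \
        * (0.8 + 0.2 * np.exp(-tt / 40e-12))
    for om in (0.0, 5e8, 3e9):
        num = np.trapezoid(Ct * np.cos(om * tt), tt)
        assert mf.spectral_density(p, t, v, om) == pytest.approx(
            0.4 * num, rel=1e-5)


def test_spectral_density_axial_factor_plateau():
    # with axis_factor f, J(0) of a rigid site becomes f*O2*0.4*tau_c
    p = mf.ModelFreeParams(model_id="m1", O2=0.9)
    j_full = mf.spectral_density(p, ISO7, None, 0.0, axis_factor=1.0)
    j_methyl = mf.spectral_density(p, ISO7, None, 0.0, axis_factor=1.0 / 9.0)
    assert j_full == pytest.approx(0.9 * 0.4 * 7e-9, rel=1e-12)
    assert j_methyl == pytest.approx(0.1 * 0.4 * 7e-9, rel=1e-12)


def test_spectral_density_array_and_scalar_agree():
    p = mf.ModelFreeParams(model_id="m2", O2=0.85, tau_e=30e-12)
    w = np.array([0.0, 1e8, 5e8])
    arr = mf.spectral_density(p, ISO7, None, w)
    assert arr.shape == (3,)
    for wi, ji in zip(w, arr):
        assert mf.spectral_density(p, ISO7, None, float(wi)) == ji


def test_spectral_density_rejects_negative_omega():
    p = mf.ModelFreeParams(model_id="m1", O2=0.9)
    with pytest.raises(mf.InvalidInputError):
        mf.spectral_density(p, ISO7, None, -1.0)


def test_model_free_params_validation():
    with pytest.raises(mf.InvalidInputError):
        mf.ModelFreeParams(model_id="m2", O2=1.2, tau_e=1e-12)
    with pytest.raises(mf.InvalidInputError):
        mf.ModelFreeParams(model_id="m2", O2=0.9, tau_e=-1e-12)
    p = mf.ModelFreeParams(model_id="s4", Of2=0.8, Os2=0.5,
                           tau_f=20e-12, tau_s=2e-9)
    assert p.order_parameter == pytest.approx(0.4)
    assert p.tau_eff(7e-9) == pytest.approx(1.0 / (1 / 7e-9 + 1 / 2e-9))


# ---------------------------------------------------------------------------
# rate expressions

def _oracle_rates_15N(p, tau_c, B0, c=mf.DEFAULT_CONSTANTS):
    """Independent closed-form 15N rates for isotropic tumbling."""
    def J(w):
        out = 0.0
        for a, tau in ((p.O2, tau_c),
                       (1 - p.O2, 1 / (1 / tau_c + 1 / p.tau_e)
                        if p.tau_e else 0.0)):
            if tau > 0:
                out += a * tau / (1 + (w * tau) ** 2)
        return 0.4 * out

    wH = mf.GAMMA_H * B0
    wN = abs(mf.GAMMA_N15) * B0
    d = (mf.MU0 / (4 * np.pi)) * mf.GAMMA_H * mf.GAMMA_N15 * mf.HBAR / c.r_NH**3
    d2, c2 = d * d, (wN * c.csa_N) ** 2 / 3
    r1 = d2 / 4 * (J(wH - wN) + 3 * J(wN) + 6 * J(wH + wN)) + c2 * J(wN)
    r2 = d2 / 8 * (4 * J(0) + J(wH - wN) + 3 * J(wN) + 6 * J(wH)
                   + 6 * J(wH + wN)) + c2 / 6 * (4 * J(0) + 3 * J(wN))
    if p.Rex is not None:
        r2 += p.Rex * (B0 / c.rex_reference_field) ** 2
    sigma = d2 / 4 * (6 * J(wH + wN) - J(wH - wN))
    return r1, r2, 1 + (mf.GAMMA_H / mf.GAMMA_N15) * sigma / r1


@pytest.mark.parametrize("model,kw", [
    ("m1", dict(O2=0.85)),
    ("m2", dict(O2=0.85, tau_e=30e-12)),
    ("m3", dict(O2=0.85, Rex=2.5)),
])
def test_rates_15N_match_independent_oracle(model, kw):
    p = mf.ModelFreeParams(model_id=model, **kw)
    for b0 in (11.7, 14.1, 18.8):
        got = mf.rates_15N(p, ISO7, None, b0)
        want = _oracle_rates_15N(p, 7.0e-9, b0)
        np.testing.assert_allclose(got, want, rtol=1e-10)


def test_rates_15N_physical_regime():
    p = mf.ModelFreeParams(model_id="m2", O2=0.85, tau_e=30e-12)
    r1, r2, noe = mf.rates_15N(p, ISO7, None, 14.1)
    assert 0.5 < r1 < 5.0
    assert r2 > r1  # slow tumbling
    assert noe < 1.0  # negative gamma ratio


def test_rates_15N_rex_field_scaling():
    p0 = mf.ModelFreeParams(model_id="m1", O2=0.85)
    p3 = mf.ModelFreeParams(model_id="m3", O2=0.85, Rex=3.0)
    for b0 in (11.7, 18.8):
        _, r2_0, _ = mf.rates_15N(p0, ISO7, None, b0)
        _, r2_3, _ = mf.rates_15N(p3, ISO7, None, b0)
        assert r2_3 - r2_0 == pytest.approx(3.0 * (b0 / 11.7) ** 2, rel=1e-9)


def test_rates_2H_methyl_combinations():
    # R1Dz, R3Dz2, R2Dplus, RDplusDz are fixed linear combinations of
    # J(0), J(wD), J(2wD); verify against direct evaluation
    p = mf.ModelFreeParams(model_id="s2", O2=0.6, tau_f=30e-12)
    b0 = 14.1
    wD = mf.GAMMA_D * b0
    J = [mf.spectral_density(p, ISO7, None, w, axis_factor=1.0 / 9.0)
         for w in (0.0, wD, 2 * wD)]
    xi2 = (2 * np.pi * 167e3) ** 2
    want = (3 / 16 * xi2 * (J[1] + 4 * J[2]),
            9 / 16 * xi2 * J[1],
            1 / 32 * xi2 * (9 * J[0] + 15 * J[1] + 6 * J[2]),
            1 / 32 * xi2 * (9 * J[0] + 3 * J[1] + 6 * J[2]))
    got = mf.rates_2H_methyl(p, ISO7, b0)
    np.testing.assert_allclose(got, want, rtol=1e-12)
    assert all(r > 0 for r in got)
    assert got[2] >= got[0]  # R2(D+) >= R1(Dz) in slow tumbling


# ---------------------------------------------------------------------------
# per-site fitting

def _records_for(p, tensor=ISO7, v=None, fields=(11.7, 14.1, 18.8),
                 sd_frac=0.01):
    recs = []
    for b0 in fields:
        r1, r2, noe = mf.rates_15N(p, tensor, v, b0)
        recs.append(RateRecord("s", b0, "R1", r1, sd_frac * r1))
        recs.append(RateRecord("s", b0, "R2", r2, sd_frac * r2))
        recs.append(RateRecord("s", b0, "NOE", noe, 0.015))
    return recs


def test_fit_site_noiseless_m1_exact():
    truth = mf.ModelFreeParams(model_id="m1", O2=0.87)
    fit = mf.fit_site(_records_for(truth), ISO7, n_mc=0)
    assert fit.params.model_id == "m1"
    assert fit.params.O2 == pytest.approx(0.87, abs=1e-6)
    assert fit.chi2 == pytest.approx(0.0, abs=1e-10)


def test_fit_site_noiseless_m2_recovers_tau_e():
    truth = mf.ModelFreeParams(model_id="m2", O2=0.8, tau_e=45e-12)
    fit = mf.fit_site(_records_for(truth), ISO7, n_mc=0)
    assert fit.params.model_id == "m2"
    assert fit.params.O2 == pytest.approx(0.8, abs=1e-4)
    assert fit.params.tau_e == pytest.approx(45e-12, rel=1e-3)


def test_fit_site_noiseless_m3_recovers_rex():
    truth = mf.ModelFreeParams(model_id="m3", O2=0.85, Rex=3.0)
    fit = mf.fit_site(_records_for(truth), ISO7, n_mc=0)
    assert fit.params.model_id == "m3"
    assert fit.params.Rex == pytest.approx(3.0, rel=1e-3)


def test_fit_site_methyl_noiseless_s2():
    truth = mf.ModelFreeParams(model_id="s2", O2=0.65, tau_f=35e-12)
    recs = []
    for b0 in (11.7, 14.1):
        for name, val in zip(("R1Dz", "R3Dz2", "R2Dplus", "RDplusDz"),
                             mf.rates_2H_methyl(truth, ISO7, b0)):
            recs.append(RateRecord("m", b0, name, val, 0.01 * val))
    fit = mf.fit_site(recs, ISO7, model_set="methyl", n_mc=0)
    assert fit.params.model_id == "s2"
    assert fit.params.O2 == pytest.approx(0.65, abs=1e-4)
    assert fit.params.tau_f == pytest.approx(35e-12, rel=1e-3)


def test_fit_site_anisotropic_orientation_matters():
    t = mf.DiffusionTensor.from_zeta_eta(1 / (6 * 7e-9), 1.3, 0.0)
    truth = mf.ModelFreeParams(model_id="m1", O2=0.9)
    v_par = np.array([0.0, 0.0, 1.0])
    recs = _records_for(truth, tensor=t, v=v_par)
    fit = mf.fit_site(recs, t, v_par, n_mc=0)
    assert fit.params.O2 == pytest.approx(0.9, abs=1e-5)
    # fitting with the wrong orientation must misfit a rigid site
    fit_wrong = mf.fit_site(recs, t, np.array([1.0, 0.0, 0.0]), n_mc=0)
    assert fit_wrong.candidates["m1"] > 10 * max(fit.candidates["m1"], 1e-10)


def test_fit_site_mc_errors_reasonable():
    truth = mf.ModelFreeParams(model_id="m1", O2=0.85)
    rng = np.random.default_rng(0)
    recs = []
    for r in _records_for(truth):
        recs.append(RateRecord(r.site_id, r.field_strength, r.rate_type,
                               r.value + rng.normal(0, r.sd), r.sd))
    fit = mf.fit_site(recs, ISO7, n_mc=60, rng=np.random.default_rng(1))
    assert 1e-4 < fit.sds["O2"] < 0.05
    assert abs(fit.params.O2 - 0.85) < 4 * fit.sds["O2"]


def test_fit_site_underdetermined():
    recs = [RateRecord("s", 14.1, "R1", 1.6, 0.02)]
    with pytest.raises(mf.UnderDeterminedError):
        mf.fit_site(recs, ISO7, model_set="backbone", n_mc=0)
    with pytest.raises(mf.UnderDeterminedError):
        mf.fit_site([], ISO7, n_mc=0)


def test_fit_site_aic_selection_runs():
    truth = mf.ModelFreeParams(model_id="m1", O2=0.9)
    fit = mf.fit_site(_records_for(truth), ISO7, selection="aic", n_mc=0)
    assert fit.params.model_id == "m1"


# ---------------------------------------------------------------------------
# tensor fitting

def test_select_rigid_sites():
    recs = {
        "flex": [RateRecord("flex", 18.8, "NOE", 0.3, 0.02)],
        "rigid": [RateRecord("rigid", 18.8, "NOE", 0.8, 0.02)],
        "norate": [RateRecord("norate", 18.8, "R1", 1.5, 0.02)],
    }
    assert mf.select_rigid_sites(recs) == ["rigid"]


def test_fit_diffusion_tensor_isotropic_recovery():
    rng = np.random.default_rng(21)
    truths = {f"r{i}": mf.ModelFreeParams(model_id="m1", O2=0.88)
              for i in range(15)}
    orients = {s: syn.random_unit_vector(rng) for s in truths}
    records, _, _, _ = syn.gen_relaxation(
        rng, truths=truths, orientations=orients, noise_frac=0.005,
        noe_sd=0.005)
    t = mf.fit_diffusion_tensor(records, orients, "isotropic")
    assert t.tau_c == pytest.approx(7.0e-9, rel=0.02)


def test_fit_diffusion_tensor_needs_sites():
    rng = np.random.default_rng(2)
    truths = {f"r{i}": mf.ModelFreeParams(model_id="m1", O2=0.9)
              for i in range(4)}
    orients = {s: syn.random_unit_vector(rng) for s in truths}
    records, _, _, _ = syn.gen_relaxation(rng, truths=truths,
                                          orientations=orients)
    with pytest.raises(mf.InvalidInputError):
        mf.fit_diffusion_tensor(records, orients, "isotropic")


def test_fit_diffusion_tensor_degenerate_geometry_warns():
    rng = np.random.default_rng(3)
    truths = {f"r{i}": mf.ModelFreeParams(model_id="m1", O2=0.9)
              for i in range(12)}
    z = np.array([0.0, 0.0, 1.0])
    orients = {s: z for s in truths}
    records, _, _, _ = syn.gen_relaxation(rng, truths=truths,
                                          orientations=orients)
    with pytest.warns(UserWarning, match="nearly parallel"):
        t = mf.fit_diffusion_tensor(records, orients, "axial")
    assert t.is_isotropic


def test_vectorized_rigid_rates_match_scalar_path():
    t = mf.DiffusionTensor.from_zeta_eta(1 / (6 * 7e-9), 1.2, 0.7,
                                         euler=(0.4, 1.0, 2.2))
    rng = np.random.default_rng(0)
    vs = rng.normal(size=(6, 3))
    vs /= np.linalg.norm(vs, axis=1, keepdims=True)
    table = mf._rigid_rates_allsites(t, vs, [11.7, 18.8], mf.DEFAULT_CONSTANTS)
    rigid = mf.ModelFreeParams(model_id="m1", O2=1.0)
    for i, v in enumerate(vs):
        for b0 in (11.7, 18.8):
            r1, r2, _ = mf.rates_15N(rigid, t, v, b0)
            assert table[(b0, "R1")][i] == pytest.approx(r1, rel=1e-12)
            assert table[(b0, "R2")][i] == pytest.approx(r2, rel=1e-12)


# ---------------------------------------------------------------------------
# NH vectors from structure

def test_nh_vectors_from_structure(tmp_path):
    pdb = tmp_path / "mini.pdb"
    pdb.write_text(
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
        "  1.00  0.00           N\n"
        "ATOM      2  H   ALA A   1       0.000   0.000   1.020"
        "  1.00  0.00           H\n"
        "ATOM      3  CA  ALA A   1       1.400   0.000   0.000"
        "  1.00  0.00           C\n"
        "ATOM      4  N   GLY A   2       3.000   0.000   0.000"
        "  1.00  0.00           N\n"
        "ATOM      5  H   GLY A   2       3.720   0.720   0.000"
        "  1.00  0.00           H\n"
        "END\n")
    vecs = mf.nh_vectors_from_structure(pdb)
    np.testing.assert_allclose(vecs["1"], [0.0, 0.0, 1.0], atol=1e-12)
    np.testing.assert_allclose(vecs["2"],
                               [1 / np.sqrt(2), 1 / np.sqrt(2), 0.0],
                               atol=1e-12)
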