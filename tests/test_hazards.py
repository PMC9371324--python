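"""Hazard models and the hazard <-> ISI-density conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mprc.hazards import (
    ISIDensity,
    _survivor,
    dS_dh_from_isi,
    hazard_to_isi,
    isi_to_hazard,
    make_preset,
)

ALL_FORMS = [
    ("exp_relax", {"t_ref": 10.0, "tau": 5.0}),
    ("exp_relax", {"t_ref": 8.0, "tau": 0.0}),
    ("ramp", {"t_ref": 6.0, "eps": 3.0}),
    ("tanh", {"t_ref": 5.0}),
    ("tanh_cos", {"t_ref": 10.0, "eps": 3.0, "omega": 1.0}),
    ("gamma_isi", {"alpha": 2.0}),
]


@pytest.mark.parametrize(
    "form,params,h,r,expected",
    [
        # inside the refractory period the rate is zero
        ("exp_relax", {"t_ref": 10.0, "tau": 5.0}, 2.0, 8.0, 0.0),
        # degenerate T_ref=0, tau=0: pure exp(h)
        ("exp_relax", {"t_ref": 0.0, "tau": 0.0}, 0.0, 3.0, 1.0),
        # direct evaluation of the relaxation factor
        ("exp_relax", {"t_ref": 10.0, "tau": 5.0}, 0.0, 15.0, 1.0 - np.exp(-1.0)),
        # hazard switches on exactly at r = T_ref (H(0) = 1)
        ("exp_relax", {"t_ref": 8.0, "tau": 0.0}, 0.0, 8.0, 1.0),
        ("ramp", {"t_ref": 6.0, "eps": 3.0}, 0.0, 7.0, 3.0),
        # gamma alpha=2 hazard has the closed form r/(1+r) at h=0
        ("gamma_isi", {"alpha": 2.0}, 0.0, 1.0, 0.5),
        ("gamma_isi", {"alpha": 2.0}, 0.0, 3.0, 0.75),
    ],
)
def test_preset_rate_values(form, params, h, r, expected):
    model = make_preset(form, **params)
    assert model.rate(h, np.array([r]))[0] == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("form,params", ALL_FORMS)
def test_rate_dh_matches_finite_difference(form, params):
    """Analytic input-derivatives agree with a central difference in h."""
    model = make_preset(form, **params)
    # stay below the survivor floor for the gamma quotient (hold region)
    r_hi = 6.0 if form == "gamma_isi" else 2.0 * max(model.t_ref, 4.0)
    r = np.linspace(0.0, r_hi, 301)
    h, eps = 1.2, 1e-6
    num = (model.rate(h + eps, r) - model.rate(h - eps, r)) / (2 * eps)
    assert np.allclose(model.rate_dh(h, r), num, rtol=1e-4, atol=1e-6)


@given(
    h=st.floats(-2.0, 3.0),
    form_idx=st.integers(0, len(ALL_FORMS) - 1),
)
@settings(max_examples=40, deadline=None)
def test_rate_invariants(h, form_idx):
    """S >= 0 everywhere, S = 0 below T_ref, and S non-decreasing in h."""
    form, params = ALL_FORMS[form_idx]
    model = make_preset(form, **params)
    r = np.linspace(0.0, 2.5 * max(model.t_ref, 4.0), 400)
    S = model.rate(h, r)
    assert np.all(S >= 0.0)
    assert np.all(S[r < model.t_ref] == 0.0)
    assert np.all(model.rate(h + 0.5, r) >= S - 1e-12)


def test_make_preset_errors():
    with pytest.raises(ValueError, match="unknown hazard form"):
        make_preset("lif")
    with pytest.raises(ValueError, match="tau"):
        make_preset("exp_relax", t_ref=5.0, tau=-1.0)
    with pytest.raises(ValueError, match="T_ref"):
        make_preset("exp_relax", t_ref=-5.0, tau=1.0)


def test_hazard_to_isi_exponential_renewal():
    """Constant hazard s gives the exponential density s exp(-s r)."""
    model = make_preset("exp_relax", t_ref=0.0, tau=0.0)
    r = np.arange(0.0, 12.0, 0.005)
    s = np.exp(0.4)
    isi = hazard_to_isi(model, 0.4, r)
    assert np.allclose(isi.density, s * np.exp(-s * r), rtol=1e-4)
    assert isi.integral == pytest.approx(1.0, abs=1e-4)


def test_isi_integral_matches_cumulative_hazard(fig3_hazard):
    """int ISI = 1 - exp(-int S) on any truncated grid."""
    r = np.arange(0.0, 14.0, 0.002)
    isi = hazard_to_isi(fig3_hazard, 2.5, r)
    S = fig3_hazard.rate(2.5, r)
    expected = 1.0 - np.exp(-np.trapezoid(S, r))
    assert isi.integral == pytest.approx(expected, abs=1e-6)


def test_isi_shape_refractory_unimodal():
    """Ramp-hazard ISI density: zero below T_ref, one interior mode."""
    model = make_preset("ramp", t_ref=6.0, eps=3.0)
    r = np.arange(0.0, 7.5, 0.01)
    isi = hazard_to_isi(model, 2.5, r)
    assert np.all(isi.density[r < 6.0] == 0.0)
    peak = np.argmax(isi.density)
    assert 6.0 < r[peak] < 7.5
    after = isi.density[peak:]
    assert np.all(np.diff(after) <= 1e-12)  # single mode: decays past the peak


def test_isi_to_hazard_constant():
    s = 0.7
    r = np.arange(0.0, 30.0, 0.01)
    back = isi_to_hazard(ISIDensity(r, s * np.exp(-s * r)))
    mask = _survivor(r, s * np.exp(-s * r)) > 1e-4
    assert np.allclose(back.values[mask], s, atol=1e-5)


def test_isi_to_hazard_gamma_closed_form():
    """gamma(alpha=2) quotient: S(r) = r/(1+r) at h = 0."""
    r = np.arange(0.0, 16.0, 0.002)
    density = r * np.exp(-r)
    back = isi_to_hazard(ISIDensity(r, density))
    mask = _survivor(r, density) > 1e-3
    assert np.allclose(back.values[mask], (r / (1.0 + r))[mask], atol=2e-4)


@pytest.mark.parametrize("h", [-0.5, 0.5])
def test_roundtrip_recovers_hazard(fig3_hazard, h):
    """isi_to_hazard(hazard_to_isi(S)) = S where the survivor is resolved."""
    r = np.arange(0.0, 45.0, 0.002)
    isi = hazard_to_isi(fig3_hazard, h, r)
    back = isi_to_hazard(isi)
    S0 = fig3_hazard.rate(h, r)
    mask = _survivor(r, isi.density) > 1e-4
    assert np.max(np.abs(back.rate(h, r) - S0)[mask]) < 1e-5


def test_isi_to_hazard_reports_truncation():
    """Past the survivor floor the hazard is held flat and the truncation
    age is reported."""
    r = np.arange(0.0, 60.0, 0.01)
    model = isi_to_hazard(ISIDensity(r, np.exp(-r)))  # gamma alpha=1
    assert model.truncation_age is not None
    assert 15.0 < model.truncation_age < 25.0  # survivor 1e-8 near r ~ 18.4
    k = np.searchsorted(r, model.truncation_age) + 2
    assert np.allclose(model.values[k:], model.values[k])


def test_dS_dh_quotient_two_routes_agree():
    """Quotient with analytic d(ISI)/dh vs central difference: same result."""

    def fam(h, rg):
        lam = np.exp(h)
        return lam**2 * rg * np.exp(-lam * rg)

    def dfam(h, rg):
        return fam(h, rg) * (2.0 - np.exp(h) * rg)

    r = np.arange(0.0, 20.0, 0.005)
    a = dS_dh_from_isi(fam, 0.0, r)
    b = dS_dh_from_isi(fam, 0.0, r, disi_dh=dfam)
    mask = _survivor(r, fam(0.0, r)) > 1e-4
    assert np.max(np.abs(a - b)[mask]) < 1e-4


def test_dS_dh_quotient_matches_analytic_gamma():
    """The quotient reproduces dS/dh = S(alpha - r e^h) + r S^2 where the
    survivor is well resolved (deeper in the tail the quotient is known to
    destabilize)."""

    def fam(h, rg):
        lam = np.exp(h)
        return lam**2 * rg * np.exp(-lam * rg)

    model = make_preset("gamma_isi", alpha=2.0)
    r = np.arange(0.0, 20.0, 0.005)
    est = dS_dh_from_isi(fam, 0.0, r)
    ana = model.rate_dh(0.0, r)
    mask = _survivor(r, fam(0.0, r)) > 1e-2
    assert np.max(np.abs(est - ana)[mask]) < 1e-3


def test_dS_dh_exp_prefactor_equals_hazard(fig3_hazard):
    """For pure exp(h)-prefactor models, dS/dh = S (and 0 below T_ref)."""

    def fam(h, rg):
        return hazard_to_isi(fig3_hazard, h, rg).density

    r = np.arange(0.0, 40.0, 0.005)
    est = dS_dh_from_isi(fam, 0.0, r)
    S = fig3_hazard.rate(0.0, r)
    mask = _survivor(r, fam(0.0, r)) > 1e-2
    assert np.all(est[r < 10.0] == 0.0)
    assert np.allclose(est[mask], S[mask], rtol=2e-3, atol=1e-5)


def test_isi_csv_roundtrip(tmp_path):
    r = np.arange(0.0, 10.0, 0.01)
    isi = ISIDensity(r, np.exp(-r))
    path = tmp_path / "isi.csv"
    isi.to_csv(path)
    again = ISIDensity.from_csv(path)
    assert np.allclose(again.r_grid, r)
    assert np.allclose(again.density, isi.density)
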