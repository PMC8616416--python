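"""Forward fluxes and closed-form ratios for the canonical depth profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluordepth import (
    DepthProfile,
    forward_flux,
    profile_ratio,
    ratio_bottom,
    ratio_bottom_exp,
    ratio_exp,
    ratio_limits,
    ratio_top,
    ratio_top_inf,
)
from fluordepth.analytic import ratio_scan, tabulated_flux_integral

# Frozen asymptotes of the dermis preset, computed independently from the
# hand-evaluated coefficients: R0 = 0.2 * 4.9008/4.0963, Rinf = R0 * A/B with
# A = 4.9652 + 0.99333, B = 1.1522 + 0.99333.
R0_DERMIS = 0.23928
RINF_DERMIS = 0.66453


def _profiles(amps, m0):
    return [
        DepthProfile.top_uniform(0.7, amps),
        DepthProfile.bottom_uniform(0.3, amps),
        DepthProfile.exponential(0.4, m0, conserve_total=True),
        DepthProfile.shifted_exponential(0.4, 0.2, amps),
    ]


def test_asymptotes_match_hand_arithmetic(dermis):
    triple, amps = dermis
    r0, rinf = ratio_limits(triple, amps)
    assert r0 == pytest.approx(R0_DERMIS, rel=1e-4)
    assert rinf == pytest.approx(RINF_DERMIS, rel=1e-4)
    assert ratio_top_inf(triple, amps) == pytest.approx(rinf)


@pytest.mark.parametrize("kind", ["top_uniform", "bottom_uniform", "exponential", "shifted_exponential"])
def test_quadrature_oracle_reproduces_closed_forms(dermis, dermis_m0, kind):
    """Adaptive quadrature of the depth integral agrees with the closed forms."""
    triple, amps = dermis
    prof = {p.kind: p for p in _profiles(amps, dermis_m0)}[kind]
    closed = profile_ratio(triple, prof, method="closed")
    quad = profile_ratio(triple, prof, method="quad")
    assert quad.R_lambda == pytest.approx(closed.R_lambda, rel=1e-8)
    assert quad.F_blue == pytest.approx(closed.F_blue, rel=1e-8)


def test_flux_linearity_and_degenerate_cases(dermis):
    triple, amps = dermis
    prof = DepthProfile.top_uniform(0.5, amps)
    double = DepthProfile.top_uniform(0.5, {k: 2 * v for k, v in amps.items()})
    f1 = forward_flux(triple, prof, 405.0)
    assert forward_flux(triple, double, 405.0) == pytest.approx(2 * f1, rel=1e-12)
    # infinite surface layer == uniform semispace (zero cover)
    inf_top = DepthProfile.top_uniform(np.inf, amps)
    semispace = DepthProfile.bottom_uniform(0.0, amps)
    assert forward_flux(triple, inf_top, 405.0) == pytest.approx(
        forward_flux(triple, semispace, 405.0), rel=1e-12
    )


def test_weak_perturbation_warning(dermis):
    triple, _ = dermis
    strong = DepthProfile.top_uniform(0.5, {405.0: 0.5, 660.0: 0.02})
    with pytest.warns(UserWarning, match="weak-perturbation"):
        forward_flux(triple, strong, 405.0)


def test_ratio_top_limits_and_monotonicity(dermis):
    triple, amps = dermis
    r0, rinf = ratio_limits(triple, amps)
    assert ratio_top(triple, 0.0, amps) == pytest.approx(r0)
    assert ratio_top(triple, np.inf, amps) == pytest.approx(rinf)
    d = np.linspace(1e-4, 5.0, 400)
    r = ratio_top(triple, d, amps)
    assert np.all(np.diff(r) > 0)
    assert np.all((r > r0) & (r < rinf))
    # saturation: indistinguishable from the asymptote beyond 10 z*
    d_sat = 10.0 * 3.0 / triple.kappa_red
    assert ratio_top(triple, d_sat, amps) == pytest.approx(rinf, rel=1e-6)


def test_ratio_bottom_is_exponential(dermis):
    triple, amps = dermis
    _, rinf = ratio_limits(triple, amps)
    assert ratio_bottom(triple, 0.0, amps) == pytest.approx(rinf)
    db = np.linspace(0.0, 1.5, 200)
    slope = np.diff(np.log(ratio_bottom(triple, db, amps))) / np.diff(db)
    assert slope == pytest.approx(np.full(slope.shape, 3.813), rel=1e-3)
    # ratio doubles every ln2/delta_mu = 0.1818 mm of cover
    assert ratio_bottom(triple, 0.18179, amps) / rinf == pytest.approx(2.0, rel=1e-3)


def test_ratio_exp_limits_and_slope_factor_two(dermis, dermis_m0):
    triple, amps = dermis
    r0, rinf = ratio_limits(triple, amps)
    assert ratio_exp(triple, 0.0, amps) == pytest.approx(r0)
    assert ratio_exp(triple, np.inf, amps) == pytest.approx(rinf)
    assert ratio_exp(triple, 1e6, amps) == pytest.approx(rinf, rel=1e-5)
    # the exponential profile responds twice as steeply at small depths
    h = 1e-7
    slope_exp = (ratio_exp(triple, h, amps) - r0) / h
    slope_top = (ratio_top(triple, h, amps) - r0) / h
    assert slope_exp / slope_top == pytest.approx(2.0, rel=1e-4)
    # ratio is independent of the conserve_total convention
    assert ratio_exp(triple, 0.4, dermis_m0) == pytest.approx(ratio_exp(triple, 0.4, amps))


def test_ratio_bottom_exp_factorization(dermis, dermis_m0):
    triple, _ = dermis
    for d1e in (0.1, 0.4, 2.0):
        for db in (0.0, 0.15, 0.6):
            lhs = ratio_bottom_exp(triple, d1e, db, dermis_m0)
            rhs = ratio_exp(triple, d1e, dermis_m0) * np.exp(triple.delta_mu * db)
            assert lhs == pytest.approx(rhs, rel=1e-12)
    _, rinf = ratio_limits(triple, dermis_m0)
    assert ratio_bottom_exp(triple, np.inf, 0.0, dermis_m0) == pytest.approx(rinf)


@given(scale=st.floats(1e-3, 1e3), depth=st.floats(0.0, 5.0))
@settings(max_examples=100, deadline=None)
def test_concentration_invariance(dermis, scale, depth):
    """Scaling both amplitudes by any c > 0 leaves every ratio unchanged."""
    triple, amps = dermis
    scaled = {k: scale * v for k, v in amps.items()}
    for fn in (ratio_top, ratio_bottom, ratio_exp):
        assert fn(triple, depth, scaled) == pytest.approx(
            fn(triple, depth, amps), rel=1e-12
        )


def test_ordering_between_asymptotes(dermis):
    triple, amps = dermis
    r0, rinf = ratio_limits(triple, amps)
    for d in (0.01, 0.1, 1.0, 3.0):
        assert r0 < ratio_top(triple, d, amps) < rinf
        assert r0 < ratio_exp(triple, d, amps) < rinf


def test_tabulated_profile_integral_matches_closed_form(dermis):
    """Piecewise-linear closed-form integration against a dense tabulation."""
    triple, amps = dermis
    kappa = triple.kappa_blue
    prof = DepthProfile.exponential(0.5, amps)
    z = np.linspace(0.0, 15.0, 40001)
    approx = tabulated_flux_integral(z, prof.mu_a_ps(z, 405.0), kappa)
    exact = amps[405.0] * 0.5 / (kappa * 0.5 + 1.0)
    assert approx == pytest.approx(exact, rel=1e-6)
    with pytest.raises(ValueError):
        tabulated_flux_integral([0.0, 0.0], [1.0, 1.0], kappa)


def test_ratio_scan_frame(dermis):
    triple, amps = dermis
    df = ratio_scan(triple, "bottom_uniform", [0.0, 0.2, 0.4], amps)
    assert list(df.columns) == ["kind", "depth", "F_blue", "F_red", "R_lambda"]
    assert df.R_lambda.is_monotonic_increasing
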