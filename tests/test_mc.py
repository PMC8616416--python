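"""Dual-step fluorescence Monte Carlo: physics limits, conservation, statistics."""

import math

import numpy as np
import pytest
from scipy.special import expn
from scipy import integrate
from scipy.stats import linregress

from fluordepth import (
    DepthProfile,
    MCConfig,
    build_stack,
    excitation_absorption_map,
    fluorescence_response,
    mc_ratio,
    ratio_top,
)
from fluordepth.mc import fresnel_reflectance
from fluordepth.optics import OpticalProperties, SpectralTriple

AMPS = {405.0: 0.1, 660.0: 0.02}


def _absorbing_triple(mu_blue=2.0, mu_red=0.5, mu_em=1.0):
    """Purely absorbing, index-matched medium -- exact transport answers exist."""
    props = {
        405.0: OpticalProperties(mu_blue, 0.0, 0.0, n=1.0),
        660.0: OpticalProperties(mu_red, 0.0, 0.0, n=1.0),
        760.0: OpticalProperties(mu_em, 0.0, 0.0, n=1.0),
    }
    return SpectralTriple(props=props)


def test_fresnel_reflectance_limits():
    # matched boundary reflects nothing at any angle
    for cos_i in (1.0, 0.7, 0.2, 0.05):
        assert fresnel_reflectance(cos_i, 1.37, 1.37) == 0.0
    # normal incidence from tissue into air
    assert fresnel_reflectance(1.0, 1.37, 1.0) == pytest.approx(((0.37) / (2.37)) ** 2)
    # beyond the critical angle: total internal reflection
    cos_crit = math.sqrt(1.0 - (1.0 / 1.37) ** 2)
    assert fresnel_reflectance(0.9 * cos_crit, 1.37, 1.0) == 1.0


def test_same_seed_is_bit_identical(dermis):
    triple, amps = dermis
    cfg = MCConfig(n_photons=5000, seed=42, n_emission=2000)
    stack = build_stack(DepthProfile.top_uniform(1.0, amps), triple, cfg)
    r1 = mc_ratio(stack, cfg)
    r2 = mc_ratio(stack, cfg)
    assert r1.R_lambda == r2.R_lambda
    assert np.array_equal(r1.F_batches[405.0], r2.F_batches[405.0])


def test_absorbing_medium_beer_lambert():
    """With no scattering the absorbed-dose profile is (1-R_spec) mu_a e^{-mu_a z}."""
    triple = _absorbing_triple()
    n_med = 1.37
    props = {lam: OpticalProperties(p.mu_a, 0.0, 0.0, n=n_med) for lam, p in triple.props.items()}
    triple = SpectralTriple(props=props)
    cfg = MCConfig(n_photons=200_000, seed=7, max_depth=10.0)
    stack = build_stack(DepthProfile.bottom_uniform(0.0, AMPS), triple, cfg)
    amap = excitation_absorption_map(stack, 660.0, cfg)
    r_spec = ((n_med - 1.0) / (n_med + 1.0)) ** 2
    mu = 0.5 + AMPS[660.0]  # base + PS absorption
    # compare in 0.25 mm bins down to 3 mm so each bin holds >= 10^3 photons
    edges = np.arange(0.0, 3.01, 0.25)
    got = np.histogram(amap.z, bins=edges, weights=amap.absorbed)[0]
    expected = (1 - r_spec) * (np.exp(-mu * edges[:-1]) - np.exp(-mu * edges[1:]))
    assert np.allclose(got, expected, rtol=0.05)


def test_weight_conservation_roulette_disabled(dermis):
    """specular + escaped + transmitted + absorbed == launched, closed to float error."""
    triple, amps = dermis
    cfg = MCConfig(n_photons=20_000, seed=5, roulette_threshold=0.0, max_depth=8.0)
    stack = build_stack(DepthProfile.top_uniform(1.0, amps), triple, cfg)
    for lam in (405.0, 660.0):
        amap = excitation_absorption_map(stack, lam, cfg)
        assert amap.total_accounted == pytest.approx(1.0, abs=1e-3)
        assert 0.0 <= amap.lost_lateral < 0.2


def test_periodic_lateral_boundary_loses_nothing(dermis):
    """With periodic faces no weight leaves laterally and the budget still closes."""
    triple, amps = dermis
    cfg = MCConfig(
        n_photons=5000, seed=5, roulette_threshold=0.0, max_depth=8.0, lateral_boundary="periodic"
    )
    stack = build_stack(DepthProfile.top_uniform(1.0, amps), triple, cfg)
    amap = excitation_absorption_map(stack, 660.0, cfg)
    assert amap.lost_lateral == 0.0
    assert amap.total_accounted == pytest.approx(1.0, abs=1e-3)


def test_dual_step_matches_exact_absorbing_solution():
    """End-to-end check of the two-step chain against a closed-form answer.

    In a purely absorbing index-matched medium the excitation dose is
    Beer--Lambert and the isotropic escape probability from depth z is
    E2(mu_em z)/2, so F has an exact integral form.
    """
    triple = _absorbing_triple()
    amps = {405.0: 0.2, 660.0: 0.05}
    d_b = 0.3
    cfg = MCConfig(
        n_photons=60_000, seed=3, roulette_threshold=1e-3, n_emission=60_000, max_depth=30.0
    )
    stack = build_stack(DepthProfile.bottom_uniform(d_b, amps), triple, cfg)
    res = mc_ratio(stack, cfg)

    def exact_F(mu_ex, a, mu_em):
        def integrand(z):
            tau = mu_ex * d_b + (mu_ex + a) * (z - d_b)
            return a * np.exp(-tau) * 0.5 * expn(2, mu_em * z)

        return integrate.quad(integrand, d_b, 40.0, limit=400)[0]

    for lam, mu_ex, a in ((405.0, 2.0, 0.2), (660.0, 0.5, 0.05)):
        assert res.F[lam] == pytest.approx(exact_F(mu_ex, a, 1.0), rel=0.03)


def test_zero_photosensitizer_gives_zero_flux(dermis):
    triple, amps = dermis
    cfg = MCConfig(n_photons=2000, seed=1, n_emission=500)
    stack = build_stack(DepthProfile.top_uniform(0.5, amps), triple, cfg)
    with pytest.warns(UserWarning, match="no photosensitizer"):
        F, _, _ = fluorescence_response(stack, 760.0, cfg)  # no PS amplitude at 760
    assert F == 0.0


def test_ratio_invariant_under_amplitude_scaling(dermis):
    """Halving both PS amplitudes leaves R unchanged within Monte Carlo error."""
    triple, amps = dermis
    half = {k: 0.5 * v for k, v in amps.items()}
    cfg = MCConfig(n_photons=60_000, seed=17, roulette_threshold=1e-3, n_emission=40_000)
    r1 = mc_ratio(build_stack(DepthProfile.top_uniform(1.0, amps), triple, cfg), cfg)
    r2 = mc_ratio(build_stack(DepthProfile.top_uniform(1.0, half), triple, cfg), cfg)
    tol = 4 * math.hypot(r1.stderr_R, r2.stderr_R) + 0.01 * r1.R_lambda
    assert abs(r1.R_lambda - r2.R_lambda) < tol


def test_top_uniform_ratio_saturates(dermis):
    """R grows from thin to saturation-scale layers as the model predicts."""
    triple, amps = dermis
    cfg = MCConfig(n_photons=60_000, seed=29, roulette_threshold=1e-3, n_emission=40_000)
    r_thin = mc_ratio(build_stack(DepthProfile.top_uniform(0.25, amps), triple, cfg), cfg)
    r_thick = mc_ratio(build_stack(DepthProfile.top_uniform(3.0, amps), triple, cfg), cfg)
    assert r_thick.R_lambda > r_thin.R_lambda
    # smoke-level agreement with the closed form at saturation
    assert r_thick.R_lambda == pytest.approx(ratio_top(triple, 3.0, amps), rel=0.10)


def test_stderr_scales_as_inverse_sqrt_photons():
    """Batch stderr of R shrinks ~ n^{-1/2} (log-log slope -0.5 +- 0.1)."""
    # strongly absorbing medium so photons die in a few collisions; a thin PS
    # layer on a coarse grid gives 10 source voxels, so the emission budget
    # n/10 divides exactly into k per voxel per batch and the sampling effort
    # of both transport steps scales linearly with n
    props = {
        405.0: OpticalProperties(2.0, 4.0, 0.5, n=1.37),
        660.0: OpticalProperties(0.6, 2.0, 0.5, n=1.37),
        760.0: OpticalProperties(0.5, 1.8, 0.5, n=1.37),
    }
    triple = SpectralTriple(props=props)
    ns = [100_000, 1_000_000, 10_000_000]
    errs = []
    for n in ns:
        cfg = MCConfig(
            n_photons=n,
            seed=101,
            n_batches=32,
            n_emission=n // 10,
            roulette_threshold=1e-3,
            voxel_dz=0.02,
        )
        stack = build_stack(DepthProfile.top_uniform(0.2, AMPS), triple, cfg)
        errs.append(mc_ratio(stack, cfg).stderr_R)
    slope = linregress(np.log(ns), np.log(errs)).slope
    assert slope == pytest.approx(-0.5, abs=0.1)


class TestBuildStack:
    def test_top_uniform_two_layers(self, dermis):
        triple, amps = dermis
        cfg = MCConfig(n_photons=1)
        stack = build_stack(DepthProfile.top_uniform(1.0, amps), triple, cfg)
        assert len(stack.layers) == 2
        assert stack.layers[0].thickness == 1.0
        assert stack.layers[0].mu_a_ps[405.0] == amps[405.0]
        assert stack.layers[1].mu_a_ps[405.0] == 0.0

    def test_conserve_total_amount_independent_of_decay_depth(self, dermis, dermis_m0):
        triple, _ = dermis
        cfg = MCConfig(n_photons=1)
        totals = []
        for d1e in (0.1, 0.3, 0.9):
            prof = DepthProfile.exponential(d1e, dermis_m0, conserve_total=True)
            stack = build_stack(prof, triple, cfg)
            totals.append(
                sum(
                    lay.mu_a_ps[405.0] * lay.thickness
                    for lay in stack.layers
                    if lay.thickness != math.inf
                )
            )
        assert np.allclose(totals, dermis_m0[405.0], rtol=5e-3)

    def test_shifted_exponential_cover_is_ps_free(self, dermis, dermis_m0):
        triple, _ = dermis
        cfg = MCConfig(n_photons=1)
        prof = DepthProfile.shifted_exponential(0.2, 0.3, dermis_m0, conserve_total=True)
        stack = build_stack(prof, triple, cfg)
        assert stack.layers[0].thickness == pytest.approx(0.3)
        assert stack.layers[0].mu_a_ps[405.0] == 0.0
        assert stack.layers[1].mu_a_ps[405.0] > 0

    def test_resolution_error(self, dermis, dermis_m0):
        triple, _ = dermis
        cfg = MCConfig(n_photons=1, voxel_dz=0.05)
        with pytest.raises(ValueError, match="voxel resolution"):
            build_stack(
                DepthProfile.exponential(0.01, dermis_m0, conserve_total=True), triple, cfg
            )

    def test_zero_thickness_top_layer_degenerates(self, dermis):
        triple, amps = dermis
        cfg = MCConfig(n_photons=1)
        stack = build_stack(DepthProfile.bottom_uniform(0.0, amps), triple, cfg)
        assert len(stack.layers) == 1
        assert stack.layers[0].mu_a_ps[405.0] == amps[405.0]


def test_config_validation():
    with pytest.raises(ValueError):
        MCConfig(n_photons=0)
    with pytest.raises(ValueError):
        MCConfig(voxel_dz=0.0)
    with pytest.raises(ValueError):
        MCConfig(roulette_survival=1.5)
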