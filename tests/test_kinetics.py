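"""Local physics: diffusivity law, reaction sources, moment averages."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyscission import (FieldState, ModelParams, MomentTriple, averages,
                          effective_diffusivity, reaction_sources)
from polyscission.kinetics import (InvalidParameterError,
                                   UndefinedAveragesError, N_OLIGOMERS)

from conftest import random_valid_moments


def make_state(CW, CM, mu0, mu1, mu2, Colig=None):
    n = np.atleast_1d(np.asarray(mu0, dtype=float)).size
    if Colig is None:
        Colig = np.zeros((N_OLIGOMERS, n))
    return FieldState(CW=CW, CM=CM, Colig=Colig, mu0=mu0, mu1=mu1, mu2=mu2)


class TestEffectiveDiffusivity:
    @pytest.mark.parametrize("mn_frac, expected", [
        (1.0, 1e-10),                    # no degradation: D = D0
        (0.0, 1.2182493960703473e-9),    # full degradation: D0 * e^2.5
        (0.75, 3.4903429574597904e-10),  # D0 * exp(2.5 * sqrt(0.25))
    ])
    def test_known_values(self, mn_frac, expected):
        D = effective_diffusivity(1e-10, mn_frac * 406_000.0, 406_000.0)
        assert D == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_bounded(self):
        mn = np.linspace(0, 406_000.0, 50)
        D = effective_diffusivity(1e-10, mn, 406_000.0)
        assert np.all(np.diff(D) <= 0)  # non-increasing in Mn
        assert np.all(D >= 1e-10) and np.all(D <= 1e-10 * np.exp(2.5) + 1e-25)

    def test_overshoot_clamped(self):
        # transient Mn above the reference carries no enhancement
        assert effective_diffusivity(1e-10, 5e5, 4e5) == pytest.approx(1e-10)

    @pytest.mark.parametrize("bad", [dict(D0=0.0), dict(Mn_ref=-1.0)])
    def test_invalid_parameters(self, bad):
        kwargs = dict(D0=1e-10, Mn_local=1e5, Mn_ref=4e5) | bad
        with pytest.raises(InvalidParameterError):
            effective_diffusivity(kwargs["D0"], kwargs["Mn_local"],
                                  kwargs["Mn_ref"])


class TestReactionSources:
    def test_all_monomer_node_is_inert(self):
        # no bonds left: every source vanishes
        c = 1e-5
        state = make_state(CW=0.05, CM=c, mu0=c, mu1=c, mu2=c)
        src = reaction_sources(state, ModelParams(kd=1e-4))
        for arr in (src.CW, src.CM, src.Colig, src.mu0, src.mu1, src.mu2):
            assert np.allclose(arr, 0.0, atol=1e-30)

    def test_monomer_production_rate(self):
        # 2 * kd * CW * (mu0 - CM) * mu0 with CM = 0
        state = make_state(CW=0.05, CM=0.0, mu0=1e-5, mu1=1e-3, mu2=0.1)
        src = reaction_sources(state, ModelParams(kd=1e-4))
        assert src.CM[0] == pytest.approx(
            2 * 1e-4 * 0.05 * 1e-5 * 1e-5, rel=1e-12)

    def test_mu2_closure_matches_monodisperse_rate(self):
        # closure is exact for a monodisperse state: source equals
        # -(kd CW mu0 / 3)(mu3 - mu1) with mu3 = n^3 mu0
        state = make_state(CW=0.05, CM=0.0, mu0=1e-6, mu1=1e-4, mu2=1e-2)
        src = reaction_sources(state, ModelParams(kd=1e-4))
        assert src.mu2[0] == pytest.approx(-1.6665e-12, rel=1e-4)
        n = 100.0
        exact = -(1e-4 * 0.05 * 1e-6 / 3.0) * (n ** 3 * 1e-6 - 1e-4)
        assert src.mu2[0] == pytest.approx(exact, rel=1e-12)

    def test_degenerate_node_gives_zero_mu2_source(self):
        state = make_state(CW=0.05, CM=0.0, mu0=0.0, mu1=0.0, mu2=0.0)
        src = reaction_sources(state, ModelParams(kd=1e-4))
        assert src.mu2[0] == 0.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(kd_scale=st.floats(0.1, 10), cw_scale=st.floats(0.1, 10),
           seed=st.integers(0, 2 ** 16))
    def test_linearity_in_kd_and_cw(self, kd_scale, cw_scale, seed):
        rng = np.random.default_rng(seed)
        mu0, mu1, mu2 = random_valid_moments(rng, 4)
        cm = rng.uniform(0, 1, 4) * mu0
        colig = rng.uniform(0, 0.1, (N_OLIGOMERS, 4)) * mu0
        cw = np.full(4, 0.03)
        base = make_state(cw, cm, mu0, mu1, mu2, colig)
        scaled = make_state(cw * cw_scale, cm, mu0, mu1, mu2, colig)
        p1 = ModelParams(kd=2e-5)
        p2 = ModelParams(kd=2e-5 * kd_scale)
        s1 = reaction_sources(base, p1)
        s2 = reaction_sources(scaled, p2)
        for a, b in zip((s1.CW, s1.CM, s1.Colig, s1.mu0, s1.mu2),
                        (s2.CW, s2.CM, s2.Colig, s2.mu0, s2.mu2)):
            np.testing.assert_allclose(b, a * kd_scale * cw_scale,
                                       rtol=1e-12)

    def test_sign_structure_and_mu1_source(self, rng):
        mu0, mu1, mu2 = random_valid_moments(rng, 20)
        state = make_state(np.full(20, 0.05), np.zeros(20), mu0, mu1, mu2)
        src = reaction_sources(state, ModelParams(kd=1e-4))
        assert np.all(src.CW <= 0)       # water consumed
        assert np.all(src.mu0 >= 0)      # scission creates chains
        assert np.all(src.CM >= 0)       # monomer produced
        assert np.all(src.mu1 == 0.0)    # repeating units conserved


class TestAverages:
    def test_monodisperse(self):
        c, n = 3e-6, 47.0
        Mn, Mw, PD = averages(MomentTriple(c, n * c, n ** 2 * c), 90.08)
        assert Mn == pytest.approx(n * 90.08)
        assert Mw == pytest.approx(n * 90.08)
        assert PD == pytest.approx(1.0)

    def test_reference_film_triple(self):
        m = MomentTriple(2.9557e-6, 1.33215e-2, 96.061)
        Mn, Mw, PD = averages(m, 90.08)
        assert Mn == pytest.approx(406_000, rel=2e-4)
        assert PD == pytest.approx(1.60, rel=2e-4)
        assert Mw == pytest.approx(PD * Mn, rel=1e-12)  # exact identity

    def test_identity_and_ordering(self, rng):
        mu0, mu1, mu2 = random_valid_moments(rng, 50)
        Mn, Mw, PD = averages(MomentTriple(mu0, mu1, mu2), 90.08)
        np.testing.assert_allclose(Mw, PD * Mn, rtol=1e-12)
        assert np.all(PD >= 1 - 1e-12)
        assert np.all(Mw >= Mn - 1e-9)

    def test_empty_state_raises(self):
        with pytest.raises(UndefinedAveragesError):
            averages(MomentTriple(0.0, 1e-3, 1.0), 90.08)


class TestModelParams:
    @pytest.mark.parametrize("kwargs", [
        dict(kd=-1e-6), dict(Mmon=0.0), dict(rho_pol=-1.0),
        dict(Mn_ref=10.0),  # below the repeating-unit mass
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ModelParams(**kwargs)

    def test_kd_zero_allowed(self):
        assert ModelParams(kd=0.0).kd == 0.0
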