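import math

import numpy as np
import pytest

from musevol import (
    BetaParams,
    MomentPair,
    SelectionParams,
    beta_density,
    beta_from_moments,
    beta_mode,
    iterate,
    moments_from_beta,
    ratio_diagnostics,
    reweighted_density,
    sce_update,
    selection_peaks,
    typicality_closed_form,
)
from musevol.errors import IllDefinedSelectionError, InvalidParameterError


def riemann_moments(params, sel, n=400_000):
    """Independent brute-force oracle: midpoint-rule moments of the
    normalised reweighted density."""
    th = (np.arange(n) + 0.5) / n
    w = beta_density(params, th) ** (1.0 + sel.beta_T) * np.exp(
        -sel.beta_N * beta_density(params, th)
    )
    m1 = (w * th).sum() / w.sum()
    var = (w * (th - m1) ** 2).sum() / w.sum()
    return m1, math.sqrt(var)


class TestReweightedDensity:
    def test_reduces_to_beta_density_without_selection(self):
        val = reweighted_density(BetaParams(2, 2), SelectionParams(0, 0), 0.5)
        assert val == pytest.approx(1.5)

    def test_novelty_weight(self):
        val = reweighted_density(BetaParams(2, 2), SelectionParams(0, 1.0), 0.5)
        assert val == pytest.approx(1.5 * math.exp(-1.5), rel=1e-12)

    def test_typicality_weight(self):
        val = reweighted_density(BetaParams(2, 2), SelectionParams(1.0, 0), 0.5)
        assert val == pytest.approx(2.25, rel=1e-12)

    def test_ill_defined_below_minus_one(self):
        with pytest.raises(IllDefinedSelectionError):
            SelectionParams(-1.5, 0.0)

    def test_non_integrable_combination_rejected(self):
        # a = 0.2: boundary exponent (1 + 4)(0.2 - 1) = -4 <= -1
        with pytest.raises(IllDefinedSelectionError):
            reweighted_density(BetaParams(0.2, 2.0), SelectionParams(4.0, 0.0), 0.5)


class TestTypicalityClosedForm:
    @pytest.mark.parametrize(
        "a, b, bt, a2, b2",
        [(2, 3, 1.0, 3, 5), (2, 3, 0.0, 2, 3), (3, 12, 0.5, 4, 17.5)],
    )
    def test_parameter_update(self, a, b, bt, a2, b2):
        out = typicality_closed_form(BetaParams(a, b), bt)
        assert out.a == pytest.approx(a2)
        assert out.b == pytest.approx(b2)

    def test_mode_invariance(self):
        p = BetaParams(3, 12)
        for bt in (0.1, 0.5, 1.0, 2.0):
            out = typicality_closed_form(p, bt)
            assert beta_mode(out) == pytest.approx(beta_mode(p), abs=1e-10)


class TestSceUpdate:
    def test_identity_without_selection(self):
        m = sce_update(MomentPair(0.2, 0.1), SelectionParams(0, 0))
        assert m.mu == pytest.approx(0.2, abs=1e-8)
        assert m.sigma == pytest.approx(0.1, abs=1e-8)

    def test_typicality_step_matches_closed_form(self):
        # (mu=0.2, sigma=0.1) is Beta(3, 12); beta_T = 1 maps it to Beta(5, 23)
        got = sce_update(MomentPair(0.2, 0.1), SelectionParams(1.0, 0.0), method="quadrature")
        want = moments_from_beta(BetaParams(5, 23))
        assert got.mu == pytest.approx(want.mu, rel=1e-6)
        assert got.sigma == pytest.approx(want.sigma, rel=1e-6)

    def test_novelty_grows_mean_and_sd(self):
        start = MomentPair(0.02, 0.012)
        out = sce_update(start, SelectionParams(0.0, 1.0))
        assert out.mu > start.mu
        assert out.sigma > start.sigma
        m1, sd = riemann_moments(beta_from_moments(start), SelectionParams(0.0, 1.0))
        assert out.mu == pytest.approx(m1, rel=1e-6)
        assert out.sigma == pytest.approx(sd, rel=1e-6)

    @pytest.mark.parametrize("sel", [SelectionParams(0.3, 0.7), SelectionParams(0.0, 2.0), SelectionParams(1.2, 0.4)])
    def test_quadrature_matches_riemann_oracle(self, sel):
        start = MomentPair(0.1, 0.05)
        out = sce_update(start, sel, method="quadrature")
        m1, sd = riemann_moments(beta_from_moments(start), sel)
        assert out.mu == pytest.approx(m1, rel=1e-6)
        assert out.sigma == pytest.approx(sd, rel=1e-6)

    def test_closed_form_method_requires_no_novelty(self):
        with pytest.raises(InvalidParameterError):
            sce_update(MomentPair(0.2, 0.1), SelectionParams(0, 1.0), method="closed_form")


class TestSelectionPeaks:
    def test_symmetric_quadratic_roots(self):
        # phi = 6 theta (1 - theta); phi = 1 solves to (1 +- sqrt(1/3))/2
        left, right = selection_peaks(BetaParams(2, 2), 1.0)
        assert left == pytest.approx((1 - math.sqrt(1 / 3)) / 2, abs=1e-10)
        assert right == pytest.approx((1 + math.sqrt(1 / 3)) / 2, abs=1e-10)

    @pytest.mark.parametrize("params, beta_n", [(BetaParams(2, 2), 1.0), (BetaParams(3, 12), 2.0), (BetaParams(2, 8), 0.9)])
    def test_peak_heights_equal_one_over_e_beta_n(self, params, beta_n):
        peaks = selection_peaks(params, beta_n)
        assert len(peaks) == 2
        mode = beta_mode(params)
        assert peaks[0] < mode < peaks[1]
        for theta in peaks:
            h = reweighted_density(params, SelectionParams(0.0, beta_n), theta)
            assert h == pytest.approx(1.0 / (math.e * beta_n), abs=1e-8)

    def test_no_peaks_when_density_below_threshold(self):
        assert selection_peaks(BetaParams(2, 2), 0.1) == ()


class TestIterate:
    def test_identity_map_is_fixed(self):
        traj = iterate(MomentPair(0.2, 0.1), SelectionParams(0, 0), 10)
        assert len(traj) == 11
        assert np.allclose(traj.means, 0.2, atol=1e-6)
        assert np.allclose(traj.sds, 0.1, atol=1e-6)

    def test_typicality_only_sd_decays_to_zero(self):
        traj = iterate(MomentPair(0.2, 0.1), SelectionParams(0.5, 0.0), 200)
        assert not traj.terminated
        assert np.all(np.diff(traj.sds) < 0)
        # mean decreases strictly until it reaches the (invariant) mode
        # at float resolution, then stays put
        dmu = np.diff(traj.means)
        assert np.all(dmu <= 1e-15)
        assert np.all(dmu[:20] < 0)
        assert traj.sds[-1] < 1e-6

    def test_typicality_only_mean_converges_to_mode(self):
        p0 = beta_from_moments(MomentPair(0.2, 0.1))
        traj = iterate(MomentPair(0.2, 0.1), SelectionParams(0.5, 0.0), 200)
        assert traj.means[-1] == pytest.approx(beta_mode(p0), abs=1e-4)

    def test_novelty_only_mean_increases_and_converges(self):
        traj = iterate(MomentPair(0.05, 0.03), SelectionParams(0.0, 0.5), 600)
        mus = traj.means
        assert np.all(np.diff(mus) > -1e-12)
        assert abs(mus[-1] - mus[-2]) < 1e-6

    def test_quadrature_iteration_tracks_closed_form(self):
        """Numerical map vs exact parameter recursion over 20 generations."""
        for bt in (0.1, 0.5, 1.0):
            p = BetaParams(2, 3)
            traj = iterate(moments_from_beta(p), SelectionParams(bt, 0.0), 20, method="quadrature")
            for state in traj.states[1:]:
                p = typicality_closed_form(p, bt)
            got = state.params
            assert got.a == pytest.approx(p.a, rel=1e-6)
            assert got.b == pytest.approx(p.b, rel=1e-6)

    def test_generations_must_be_positive(self):
        with pytest.raises(InvalidParameterError):
            iterate(MomentPair(0.2, 0.1), SelectionParams(0, 0), 0)


class TestRatioDiagnostics:
    def test_identity_trajectory_flat(self):
        traj = iterate(MomentPair(0.2, 0.1), SelectionParams(0, 0), 10)
        diag = ratio_diagnostics(traj)
        assert np.allclose(diag.ratios, 0.5, atol=1e-6)
        assert np.allclose(diag.growth_factors, 1.0, atol=1e-6)

    def test_typicality_only_ratio_decreasing_no_growth(self):
        traj = iterate(MomentPair(0.2, 0.1), SelectionParams(0.5, 0.0), 50)
        diag = ratio_diagnostics(traj)
        assert np.all(np.diff(diag.ratios) < 0)
        assert np.all(diag.growth_factors <= 1.0 + 1e-12)

    def test_novelty_only_plateau_detected(self):
        # the orbit approaches the manifold through a damped 2-cycle, so
        # the per-generation tolerance must exceed its residual amplitude
        traj = iterate(MomentPair(0.02, 0.01), SelectionParams(0.0, 1.0), 60)
        diag = ratio_diagnostics(traj, plateau_tol=3e-2)
        assert diag.plateau_ratio is not None
        assert 0.0 < diag.plateau_ratio < 1.0

    def test_too_short_trajectory_rejected(self):
        traj = iterate(MomentPair(0.2, 0.1), SelectionParams(0, 0), 1)
        traj.states = traj.states[:1]
        with pytest.raises(InvalidParameterError):
            ratio_diagnostics(traj)


class TestSlowManifold:
    def test_plateau_ratio_below_one_and_decreasing_in_beta_n(self):
        """The novelty-only slow manifold sits slightly below ratio 1 and
        moves down as the novelty pressure grows."""
        ratios = []
        for bn in (0.5, 1.0, 2.0):
            traj = iterate(MomentPair(0.001, 0.0005), SelectionParams(0.0, bn), 120)
            mus = traj.means
            grow = (mus > 0.01) & (mus < 0.1)
            assert grow.sum() >= 3
            mean_ratio = traj.ratios[grow].mean()
            assert 0.0 < mean_ratio < 1.0
            ratios.append(mean_ratio)
        assert ratios[0] >= ratios[1] >= ratios[2]

    def test_near_exponential_growth_on_plateau(self):
        """Across a decade of mean growth the growth rate stays within
        20% of its plateau value, once the residual 2-cycle of the
        approach to the manifold is smoothed over pairs of generations."""
        traj = iterate(MomentPair(0.005, 0.003), SelectionParams(0.0, 1.0), 200)
        mus = traj.means
        lo = np.searchsorted(mus, 0.01)
        hi = np.searchsorted(mus, 0.1)
        factors = mus[lo + 1 : hi + 1] / mus[lo:hi]
        assert factors.size > 3
        # raw per-generation factors: same order of magnitude
        assert factors.max() / factors.min() < 2.0
        smoothed = np.sqrt(factors[:-1] * factors[1:])
        assert smoothed.max() / smoothed.min() < 1.2

    def test_mixed_regime_sd_converges_and_is_attracting(self):
        """In a typicality-dominated mixed regime sigma approaches a
        fixed value where the two pressures balance, while the mean is
        still moving; perturbing sigma above (below) the fixed value
        makes it fall (rise)."""
        sel = SelectionParams(2.0, 0.5)
        traj = iterate(MomentPair(0.02, 0.01), sel, 200)
        sds, mus = traj.sds, traj.means
        assert abs(sds[-1] - sds[-2]) < 1e-5
        assert abs(mus[-1] - mus[-2]) > 10 * abs(sds[-1] - sds[-2])
        sd_star = sds[-1]
        above = iterate(MomentPair(mus[-1], sd_star * 1.5), sel, 5)
        below = iterate(MomentPair(mus[-1], sd_star * 0.5), sel, 5)
        assert above.sds[1] < above.sds[0]
        assert below.sds[1] > below.sds[0]
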