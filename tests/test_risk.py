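"""Dose formulas, log-normal fitting, truncated sampling, Monte Carlo risk."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegrisk.data_model import METALS, ExposureScenario, VegriskError
from vegrisk.risk import (
    ContentDistribution,
    cdi,
    deterministic_risk,
    fit_lognormal,
    hi,
    hq,
    is_safe,
    mc_risk,
    sample_contents,
    summarize_risk,
)

RFD = {"Cd": 1e-3, "Cr": 3e-3, "Cu": 4e-2, "Pb": 3.5e-3, "V": 7e-3, "Zn": 0.3}


def scenario(ir=100.0, ef=365.0, ed=1.0, bw=60.0, at=None, rfd=None,
             name="test"):
    return ExposureScenario(receptor=name, ir_veg=ir, ef=ef, ed=ed, bw=bw,
                            rfd=rfd or dict(RFD), at=at)


def point_dists(contents, spread=0.0):
    """Degenerate (sigma=0) content distributions at the given means."""
    return [
        ContentDistribution(metal=m, species="x", mean=c, sd=spread * c,
                            minimum=c * 1e-6, maximum=c * 1e6)
        for m, c in contents.items()
    ]


class TestDoseFormulas:
    def test_cdi_closed_form(self):
        # 100 g/day at 1 mg/kg for a 60 kg receptor: 0.1/60 mg/kg/day
        assert cdi(1.0, scenario()) == pytest.approx(0.1 * 365 / (60 * 365))

    def test_cdi_zero_content(self):
        assert cdi(0.0, scenario()) == 0.0

    def test_at_default_cancels_ed(self):
        assert cdi(1.0, scenario(ed=1.0)) == pytest.approx(
            cdi(1.0, scenario(ed=30.0))
        )

    def test_hq_threshold_identity(self):
        assert hq(1e-3, 1e-3) == pytest.approx(1.0)
        assert hq(2e-3, 1e-3) == pytest.approx(2.0)
        with pytest.raises(VegriskError):
            hq(1.0, 0.0)

    def test_hi_sum_and_safety_flag(self):
        assert hi([1, 2, 3]) == 6.0
        assert hi([3, 1, 2]) == 6.0  # permutation invariant
        assert hi([]) == 0.0 and is_safe(0.0)
        assert not is_safe(1.0)


class TestFitLognormal:
    def test_moment_inversion_round_trip(self):
        mu, sigma = fit_lognormal(22.1, 19.6)
        assert sigma == pytest.approx(0.762, abs=5e-3)
        assert mu == pytest.approx(2.806, abs=5e-3)
        # analytic moments of the fitted distribution reproduce the inputs
        mean_back = math.exp(mu + sigma**2 / 2)
        sd_back = mean_back * math.sqrt(math.expm1(sigma**2))
        assert mean_back == pytest.approx(22.1, abs=1e-9)
        assert sd_back == pytest.approx(19.6, abs=1e-9)

    def test_closed_forms(self):
        assert fit_lognormal(1.0, 1.0)[1] == pytest.approx(math.sqrt(math.log(2)))
        mu, sigma = fit_lognormal(5.0, 0.0)
        assert sigma == 0.0 and mu == pytest.approx(math.log(5.0))

    @given(mean=st.floats(1e-3, 1e3), cv=st.floats(0, 5))
    @settings(max_examples=200, deadline=None)
    def test_moments_always_invert(self, mean, cv):
        mu, sigma = fit_lognormal(mean, cv * mean)
        mean_back = math.exp(mu + sigma**2 / 2)
        assert mean_back == pytest.approx(mean, rel=1e-9)


class TestSampleContents:
    def test_degenerate_sigma_zero(self):
        d = ContentDistribution("Cd", "x", mean=2.0, sd=0.0, minimum=1.0,
                                maximum=3.0)
        assert np.all(sample_contents(d, 10, 0) == 2.0)

    def test_untruncated_p90_matches_analytic_quantile(self):
        d = ContentDistribution("Cd", "x", mean=math.exp(0.5),
                                sd=math.exp(0.5) * math.sqrt(math.expm1(1.0)),
                                minimum=1e-12, maximum=1e12)
        assert d.mu == pytest.approx(0.0, abs=1e-12)
        assert d.sigma == pytest.approx(1.0, abs=1e-12)
        x = sample_contents(d, 100_000, 123)
        assert np.percentile(x, 90) == pytest.approx(math.exp(1.2816), rel=0.02)

    def test_truncation_respected(self):
        d = ContentDistribution("Cd", "x", mean=1.0, sd=1.0, minimum=0.5,
                                maximum=2.0)
        x = sample_contents(d, 5000, 7)
        assert np.all((x >= 0.5) & (x <= 2.0))

    def test_same_seed_identical(self):
        d = ContentDistribution("Cd", "x", mean=1.0, sd=1.0, minimum=0.1,
                                maximum=10.0)
        assert np.array_equal(sample_contents(d, 1000, 5),
                              sample_contents(d, 1000, 5))

    def test_infeasible_bounds_error(self):
        d = ContentDistribution("Cd", "x", mean=1.0, sd=0.1,
                                minimum=50.0, maximum=51.0)
        with pytest.raises(VegriskError, match="acceptance"):
            sample_contents(d, 100, 0)


class TestMcRisk:
    def test_sigma_zero_collapses_to_deterministic(self):
        contents = {"Cd": 0.3, "Cr": 0.03, "Cu": 0.5, "Pb": 0.25, "V": 0.4,
                    "Zn": 6.0}
        sc = scenario()
        dist = mc_risk(point_dists(contents), sc, n_iter=500, seed=0)
        det = deterministic_risk(contents, sc)
        out = summarize_risk(dist, 0.9)
        assert out.hi_percentile == pytest.approx(det.hi_percentile, rel=1e-12)
        for m in METALS:
            assert out.hq_percentile[m] == pytest.approx(
                det.hq_percentile[m], rel=1e-12
            )

    def test_hi_equals_sum_of_hqs_on_all_draws(self):
        dist = mc_risk(point_dists({m: 1.0 for m in METALS}, spread=0.5),
                       scenario(), n_iter=2000, seed=3)
        np.testing.assert_allclose(
            dist.hi_draws, dist.hq_draws.to_numpy().sum(axis=1), atol=1e-12
        )
        assert np.all(dist.hi_draws >= 0)

    def test_doubling_rfd_halves_draws(self):
        dists = point_dists({m: 1.0 for m in METALS}, spread=0.5)
        a = mc_risk(dists, scenario(), n_iter=1000, seed=9)
        doubled = scenario(rfd={m: 2 * v for m, v in RFD.items()})
        b = mc_risk(dists, doubled, n_iter=1000, seed=9)
        np.testing.assert_allclose(
            b.hq_draws.to_numpy(), a.hq_draws.to_numpy() / 2, rtol=1e-12
        )
        np.testing.assert_allclose(b.hi_draws, a.hi_draws / 2, rtol=1e-12)

    def test_single_metal_p90_matches_closed_form(self):
        """With one stochastic metal, HQ is a constant times the content
        draw, so the HI P90 equals the analytic log-normal quantile scaled
        by CDI/RfD."""
        tiny = 1e-12
        dists = point_dists({m: tiny for m in METALS})
        # CV 0.3 keeps the P90 Monte Carlo standard error well inside the band
        mean, sd = 0.5, 0.15
        dists[0] = ContentDistribution("Cd", "x", mean=mean, sd=sd,
                                       minimum=1e-12, maximum=1e12)
        sc = scenario()
        dist = mc_risk(dists, sc, n_iter=10_000, seed=17)
        mu, sigma = fit_lognormal(mean, sd)
        q90 = math.exp(mu + 1.2815515655 * sigma)
        const = cdi(1.0, sc) / RFD["Cd"]
        assert summarize_risk(dist, 0.9).hi_percentile == pytest.approx(
            const * q90, rel=0.02
        )

    def test_receptor_scaling_constant_across_table(self):
        """When two receptors differ only in IR and BW, every HQ scales by
        one constant (IR/BW ratio)."""
        a = scenario(ir=345.0, bw=61.8, name="adult")
        c = scenario(ir=231.5, bw=23.6, name="child")
        dists = point_dists({m: 1.0 for m in METALS}, spread=0.5)
        da = mc_risk(dists, a, n_iter=500, seed=4)
        dc = mc_risk(dists, c, n_iter=500, seed=4)
        k = (231.5 / 23.6) / (345.0 / 61.8)
        np.testing.assert_allclose(
            dc.hq_draws.to_numpy(), k * da.hq_draws.to_numpy(), rtol=1e-12
        )

    def test_missing_metal_distribution_errors_before_sampling(self):
        dists = point_dists({m: 1.0 for m in METALS})[:-1]
        with pytest.raises(VegriskError, match="Zn"):
            mc_risk(dists, scenario(), n_iter=10, seed=0)


class TestSummarizeRisk:
    def test_single_iteration_percentile_is_that_value(self):
        dist = mc_risk(point_dists({m: 1.0 for m in METALS}), scenario(),
                       n_iter=1, seed=0)
        out = summarize_risk(dist, 0.9)
        assert out.hi_percentile == pytest.approx(float(dist.hi_draws[0]))

    def test_contributions_sum_to_one(self):
        dist = mc_risk(point_dists({m: 1.0 for m in METALS}, spread=0.8),
                       scenario(), n_iter=3000, seed=2)
        out = summarize_risk(dist, 0.9)
        assert sum(out.contribution.values()) == pytest.approx(1.0, abs=1e-9)

    def test_identical_metals_share_contribution(self):
        """Two metals with the same content distribution and RfD each carry
        about half the hazard."""
        tiny = 1e-15
        contents = {m: tiny for m in METALS}
        dists = point_dists(contents)
        for i, m in enumerate(("Cd", "Cr")):
            dists[i] = ContentDistribution(m, "x", mean=1.0, sd=0.5,
                                           minimum=1e-12, maximum=1e12)
        rfd = dict(RFD)
        rfd["Cr"] = rfd["Cd"]
        dist = mc_risk(dists, scenario(rfd=rfd), n_iter=10_000, seed=21)
        out = summarize_risk(dist, 0.9)
        assert out.contribution["Cd"] == pytest.approx(0.5, abs=0.02)
        assert out.contribution["Cr"] == pytest.approx(0.5, abs=0.02)

    def test_reproducibility_bit_identical(self):
        dists = point_dists({m: 1.0 for m in METALS}, spread=0.5)
        a = summarize_risk(mc_risk(dists, scenario(), 2000, seed=8), 0.9)
        b = summarize_risk(mc_risk(dists, scenario(), 2000, seed=8), 0.9)
        assert a == b

    def test_p90_hi_bounded_by_sum_of_p90_hqs(self):
        """Empirically, the 90th percentile of an independent sum sits at or
        below the sum of the marginals' 90th percentiles. Checked across
        seeded configurations; violations would be a red flag, not a proof."""
        rng = np.random.default_rng(0)
        violations = 0
        for k in range(100):
            spread = float(rng.uniform(0.2, 1.5))
            dists = point_dists(
                {m: float(rng.uniform(0.1, 5.0)) for m in METALS}, spread=spread
            )
            dist = mc_risk(dists, scenario(), n_iter=2000, seed=k)
            out = summarize_risk(dist, 0.9)
            if out.hi_percentile > sum(out.hq_percentile.values()):
                violations += 1
        assert violations <= 5
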