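"""One-off and multi-event risk: impacts, BAM, burn probability, summaries."""

import numpy as np
import pytest

from firebiorisk.fire import FireResult, SpreadModel
from firebiorisk.ignition import FIPSurface, normalize_fip
from firebiorisk.landscape import LandscapeGrid
from firebiorisk.risk import (
    build_bam,
    burn_probability,
    multi_event_risk,
    one_off_impact,
    one_off_risk,
    risk_cdf_by_unit,
    threshold_area,
)


def toy_fire(j, cells, shape, ros=4.0, intensity=100.0):
    n = len(cells)
    return FireResult(j, cells, np.full(n, intensity), np.full(n, ros), shape)


def grid1(n=2, m=2):
    return LandscapeGrid(unit_ids=("a",), composition=np.ones((1, n, m)))


class TestOneOffImpact:
    def test_sum_bl_hand_example(self):
        bl = np.array([0.1, 0.2, 0.0, 0.5])
        oe = one_off_impact([toy_fire(0, [0, 1, 2], (2, 2))], bl, mode="sum_bl")
        assert oe[0] == pytest.approx(0.3)
        assert np.isnan(oe[3])  # no fire simulated there

    def test_zero_loss_burnt_area_gives_zero_impact(self):
        oe = one_off_impact([toy_fire(1, [0, 1, 2], (2, 2))], np.zeros(4), mode="sum_bl")
        assert oe[1] == 0.0

    def test_degenerate_fire_has_zero_impact(self):
        f = FireResult(0, [0], np.zeros(1), np.zeros(1), (2, 2))
        oe = one_off_impact([f], np.full(4, 0.7), mode="severity_weighted")
        assert oe[0] == 0.0

    def test_severity_weighting_uses_per_fire_max(self):
        # ros (4, 2) at equal intensity -> severities (25, 50) -> weights (.5, 1)
        f = FireResult(0, [0, 1], [100.0, 100.0], [4.0, 2.0], (1, 2))
        oe = one_off_impact([f], np.array([0.2, 0.4]), mode="severity_weighted")
        assert oe[0] == pytest.approx(0.5 * 0.2 + 1.0 * 0.4)

    def test_duplicate_ignitions_rejected(self):
        fires = [toy_fire(0, [0], (1, 2)), toy_fire(0, [0, 1], (1, 2))]
        with pytest.raises(ValueError, match="duplicate"):
            one_off_impact(fires, np.zeros(2), mode="sum_bl")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            one_off_impact([], np.zeros(2), mode="bogus")


class TestOneOffRisk:
    def test_hand_normalization(self):
        fip = FIPSurface(values=np.array([[0.5, 1.0]]))
        oer = one_off_risk(np.array([4.0, 1.0]), fip)
        np.testing.assert_allclose(oer, [1.0, 0.5])

    def test_zero_ignition_probability_kills_risk(self):
        fip = FIPSurface(values=np.array([[0.0, 1.0]]))
        oer = one_off_risk(np.array([10.0, 1.0]), fip)
        assert oer[0] == 0.0 and oer[1] == 1.0

    def test_uniform_fip_preserves_impact_ranking(self):
        fip = FIPSurface(values=np.full((1, 4), 0.3))
        oe = np.array([3.0, 1.0, 4.0, 2.0])
        oer = one_off_risk(oe, fip)
        assert (np.argsort(oer) == np.argsort(oe)).all()

    def test_fip_scale_invariance(self):
        oe = np.array([3.0, 1.0, 4.0, 2.0])
        a = one_off_risk(oe, FIPSurface(values=np.array([[1, 2, 3, 4.0]])))
        b = one_off_risk(oe, FIPSurface(values=np.array([[10, 20, 30, 40.0]])))
        np.testing.assert_allclose(a, b, atol=1e-15)


class TestBAM:
    def test_two_disjoint_fires_four_nonzeros(self):
        g = grid1(2, 2)
        fires = [toy_fire(0, [0, 1], (2, 2)), toy_fire(2, [2, 3], (2, 2))]
        bam = build_bam(fires, g)
        assert bam.matrix.nnz == 4
        assert bam.burn_counts().tolist() == [1, 1, 1, 1]

    def test_self_only_fires_give_identity_pattern(self):
        g = grid1(2, 2)
        fires = [toy_fire(j, [j], (2, 2)) for j in range(4)]
        bam = build_bam(fires, g)
        np.testing.assert_array_equal(bam.matrix.toarray(), np.eye(4))

    def test_all_burning_fire_fills_its_column(self):
        g = grid1(2, 2)
        bam = build_bam([toy_fire(1, [0, 1, 2, 3], (2, 2))], g)
        assert bam.matrix[:, 0].toarray().ravel().tolist() == [1, 1, 1, 1]

    def test_duplicate_ignitions_rejected(self):
        g = grid1(2, 2)
        with pytest.raises(ValueError, match="duplicate"):
            build_bam([toy_fire(0, [0], (2, 2)), toy_fire(0, [0], (2, 2))], g)


class TestBurnProbability:
    def test_three_cell_toy_weighted_ratio(self):
        """Fires A->{A,B}, B->{B}, C->{C,B} with FIP (.5,.25,.25)."""
        g = grid1(1, 3)
        fires = [
            toy_fire(0, [0, 1], (1, 3)),
            toy_fire(1, [1], (1, 3)),
            toy_fire(2, [1, 2], (1, 3)),
        ]
        bam = build_bam(fires, g)
        fip = FIPSurface(values=np.array([[0.5, 0.25, 0.25]]))
        np.testing.assert_allclose(burn_probability(bam, fip), [0.5, 1.0, 0.25])

    def test_uniform_fip_reduces_to_finney_bitwise(self, nc_bundle):
        m = SpreadModel(nc_bundle.landscape, nc_bundle.fuel, nc_bundle.weather)
        ign = np.flatnonzero(m.burnable)[::4]
        bam = build_bam(m.simulate_many(ign), nc_bundle.landscape)
        fip = FIPSurface(values=np.full(nc_bundle.landscape.shape, 0.37))
        weighted = burn_probability(bam, fip, "fip_weighted")
        finney = burn_probability(bam, method="uniform")
        np.testing.assert_array_equal(weighted, finney)

    def test_cell_burned_by_every_fire_has_probability_one(self):
        g = grid1(1, 3)
        fires = [toy_fire(j, [j, 1] if j != 1 else [1], (1, 3)) for j in range(3)]
        bam = build_bam(fires, g)
        fip = FIPSurface(values=np.array([[0.2, 0.3, 0.5]]))
        assert burn_probability(bam, fip)[1] == 1.0

    def test_weighted_needs_fip(self):
        bam = build_bam([toy_fire(0, [0], (1, 2))], grid1(1, 2))
        with pytest.raises(ValueError, match="FIP"):
            burn_probability(bam, None, "fip_weighted")

    def test_monte_carlo_oracle_small(self, nc_bundle):
        """Empirical FIP-sampled burn frequency converges to the weighted ratio."""
        rng = np.random.default_rng(4)
        m = SpreadModel(nc_bundle.landscape, nc_bundle.fuel, nc_bundle.weather)
        ign = rng.choice(np.flatnonzero(m.burnable), size=30, replace=False)
        bam = build_bam(m.simulate_many(ign), nc_bundle.landscape)
        bp = burn_probability(bam, nc_bundle.fip)
        w = nc_bundle.fip.flat()[bam.ignitions]
        M = 40_000
        draws = rng.choice(bam.n_fires, size=M, p=w / w.sum())
        freq = (bam.matrix @ np.bincount(draws, minlength=bam.n_fires).astype(float)) / M
        se = np.sqrt(bp * (1 - bp) / M)
        ok = np.abs(bp - freq) <= 3 * se + 1e-12
        assert ok[m.burnable].mean() >= 0.99


class TestMultiEventRisk:
    def test_hand_normalization(self):
        mer = multi_event_risk(np.array([1.0, 0.5]), np.array([0.1, 0.4]))
        np.testing.assert_allclose(mer, [0.5, 1.0])

    def test_zero_loss_cell_has_zero_risk(self):
        mer = multi_event_risk(np.array([1.0, 1.0]), np.array([0.0, 0.3]))
        assert mer[0] == 0.0

    def test_constant_loss_makes_risk_proportional_to_bp(self):
        bp = np.array([0.1, 0.4, 0.2])
        mer = multi_event_risk(bp, np.full(3, 0.7))
        np.testing.assert_allclose(mer, bp / bp.max())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multi_event_risk(np.ones(3), np.ones(4))


class TestSummaries:
    def test_constant_risk_is_a_step_function(self, nc_bundle):
        g = nc_bundle.landscape
        risk = np.full(g.n_cells, 0.3)
        df = risk_cdf_by_unit(risk, g, thresholds=(0.0, 0.29, 0.3, 0.31))
        for u in g.unit_ids:
            sub = df[df.unit_id == u].set_index("threshold")["exceedance"]
            assert sub[0.0] == 1.0 and sub[0.29] == 1.0
            assert sub[0.3] == 0.0 and sub[0.31] == 0.0

    def test_exceedance_matches_exhaustive_enumeration(self, nc_bundle):
        g = nc_bundle.landscape
        rng = np.random.default_rng(8)
        risk = rng.random(g.n_cells)
        df = risk_cdf_by_unit(risk, g, thresholds=(0.2, 0.7))
        comp = g.composition_flat()
        for k, u in enumerate(g.unit_ids):
            for t in (0.2, 0.7):
                brute = sum(comp[k, i] for i in range(g.n_cells) if risk[i] > t) / comp[k].sum()
                got = df[(df.unit_id == u) & (df.threshold == t)].exceedance.iloc[0]
                assert got == pytest.approx(brute, rel=1e-9)

    def test_exceedance_monotone_in_threshold(self, nc_bundle):
        g = nc_bundle.landscape
        risk = np.random.default_rng(9).random(g.n_cells)
        df = risk_cdf_by_unit(risk, g, thresholds=np.linspace(0, 1, 11))
        for u in g.unit_ids:
            vals = df[df.unit_id == u].sort_values("threshold")["exceedance"].to_numpy()
            assert (np.diff(vals) <= 1e-12).all()

    def test_threshold_area_count_times_cell_area(self):
        g = LandscapeGrid(unit_ids=("a",), composition=np.ones((1, 10, 10)))
        risk = np.zeros(100)
        risk[[3, 30, 77]] = 0.9
        area, frac = threshold_area(risk, g, 0.5)
        assert area == pytest.approx(3 * 0.09)
        assert frac == pytest.approx(3 / 100)

    def test_threshold_extremes(self, nc_bundle):
        g = nc_bundle.landscape
        assert threshold_area(np.ones(g.n_cells), g, 1.0)[0] == 0.0
        area, frac = threshold_area(np.full(g.n_cells, 0.5), g, 0.0)
        assert area == pytest.approx(g.n_cells * g.cell_area)
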