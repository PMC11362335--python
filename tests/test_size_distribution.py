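"""Channel merging, histograms, volume transform, integration."""

import math

import numpy as np
import pytest

from caspm import (
    Channel,
    ChannelRegion,
    ParticleType,
    RegionAssignment,
    SizeGrid,
    assign_channel_region,
    build_size_distribution,
    integrate,
    volume_distribution,
)


class TestRegionAssignment:
    @pytest.mark.parametrize(
        "channel,re,im,expected",
        [
            ("s", 0.5, 0.1, RegionAssignment.USE_S),    # inside s rectangle
            ("l", 2.0, 1.0, RegionAssignment.USE_L),    # l window, outside s rect
            ("l", 12.0, 1.0, RegionAssignment.DISCARD), # beyond the outer window
            ("l", 0.5, 0.1, RegionAssignment.DISCARD),  # l event inside s rectangle
            ("s", 2.0, 0.1, RegionAssignment.DISCARD),  # s event outside its window
            ("l", 0.3, 1.2, RegionAssignment.USE_L),    # gap zone goes to l, not lost
        ],
    )
    def test_rule(self, channel, re, im, expected):
        assert assign_channel_region(channel, re, im) is expected

    def test_partition_counts(self, rng):
        region = ChannelRegion()
        n = 5000
        ch = np.where(rng.random(n) < 0.5, "s", "l")
        re = rng.uniform(-1, 12, n)
        im = rng.uniform(-1, 6, n)
        out = region.assign(ch, re, im)
        n_s = (out == RegionAssignment.USE_S.value).sum()
        n_l = (out == RegionAssignment.USE_L.value).sum()
        n_d = (out == RegionAssignment.DISCARD.value).sum()
        assert n_s + n_l + n_d == n
        # an event can only be used by its own channel
        assert ((out == RegionAssignment.USE_S.value) & (ch == "l")).sum() == 0


class TestSizeGrid:
    def test_default_grid(self, grid16):
        assert grid16.n_bins == 32
        assert grid16.dlog == pytest.approx(1 / 16)
        assert grid16.edges[0] == pytest.approx(0.1)
        assert grid16.edges[-1] == pytest.approx(10.0)

    def test_psl_integration_ranges_fit(self, grid16):
        for lo, hi in [(0.6, 0.86), (0.86, 1.2), (2.6, 3.5)]:
            assert grid16.edges[0] <= lo < hi <= grid16.edges[-1]

    def test_non_uniform_edges_rejected(self):
        with pytest.raises(ValueError):
            SizeGrid(edges=np.array([0.1, 0.2, 0.5]))


class TestBuildDistribution:
    def test_no_events_gives_zero(self, grid16):
        dist = build_size_distribution(
            np.array([]), np.array([]), np.array([], dtype=object),
            grid16, {"s": 1.0, "l": 1.0},
        )
        assert all(np.all(arr == 0) for arr in dist.dn_dlogd.values())

    def test_single_bin_arithmetic(self, grid16):
        """100 events of D = 1.0 µm in 1 mL at dlogD = 1/16 -> 1600 mL^-1."""
        n = 100
        dist = build_size_distribution(
            np.full(n, 1.0),
            np.full(n, int(ParticleType.TYPE1)),
            np.full(n, RegionAssignment.USE_S.value, dtype=object),
            grid16,
            {"s": 1.0},
        )
        dn = dist.dn_dlogd[ParticleType.TYPE1]
        bin_idx = np.searchsorted(grid16.edges, 1.0, side="right") - 1
        assert dn[bin_idx] == pytest.approx(1600.0)
        assert np.count_nonzero(dn) == 1

    def test_channels_divide_by_their_own_volume(self, grid16):
        diam = np.array([0.5, 2.0])
        types = np.array([1, 1])
        regions = np.array(
            [RegionAssignment.USE_S.value, RegionAssignment.USE_L.value], dtype=object
        )
        dist = build_size_distribution(diam, types, regions, grid16, {"s": 0.5, "l": 2.0})
        dn = dist.dn_dlogd[ParticleType.TYPE1]
        i_s = np.searchsorted(grid16.edges, 0.5, side="right") - 1
        i_l = np.searchsorted(grid16.edges, 2.0, side="right") - 1
        assert dn[i_s] == pytest.approx(1 / (0.5 * grid16.dlog))
        assert dn[i_l] == pytest.approx(1 / (2.0 * grid16.dlog))

    def test_zero_volume_rejected(self, grid16):
        with pytest.raises(ValueError):
            build_size_distribution(
                np.array([1.0]), np.array([1]),
                np.array([RegionAssignment.USE_S.value], dtype=object),
                grid16, {"s": 0.0},
            )

    def test_lognormal_mode_recovered_within_one_bin(self, grid16, rng):
        """A median-0.8, GSD-1.5 component's histogram peaks at the 0.8 µm bin."""
        d = 0.8 * np.exp(math.log(1.5) * rng.standard_normal(10000))
        dist = build_size_distribution(
            d, np.full(d.size, 1),
            np.full(d.size, RegionAssignment.USE_S.value, dtype=object),
            grid16, {"s": 1.0},
        )
        mode = grid16.mids[np.argmax(dist.dn_dlogd[ParticleType.TYPE1])]
        true_bin = grid16.mids[np.searchsorted(grid16.edges, 0.8, side="right") - 1]
        assert abs(math.log10(mode / true_bin)) <= grid16.dlog + 1e-12


class TestVolumeTransform:
    def test_multiplier_at_one_micron(self, grid16):
        """The dV/dN ratio in the bin holding 1 µm is pi D_mid^3/6."""
        n = 10
        dist = build_size_distribution(
            np.full(n, 1.0), np.full(n, 0),
            np.full(n, RegionAssignment.USE_S.value, dtype=object),
            grid16, {"s": 1.0},
        )
        dv = volume_distribution(dist)
        i = np.searchsorted(grid16.edges, 1.0, side="right") - 1
        ratio = dv.dv_dlogd[ParticleType.TYPE0][i] / dv.dn_dlogd[ParticleType.TYPE0][i]
        assert ratio == pytest.approx(math.pi * grid16.mids[i] ** 3 / 6)

    def test_zero_dn_gives_zero_dv(self, grid16):
        dist = build_size_distribution(
            np.array([]), np.array([]), np.array([], dtype=object), grid16, {"s": 1.0}
        )
        dv = volume_distribution(dist)
        assert all(np.all(arr == 0) for arr in dv.dv_dlogd.values())

    def test_cubic_scaling_between_bins(self, grid16):
        """Doubling D_mid multiplies the per-bin dV/dN ratio by 8."""
        mults = math.pi * grid16.mids**3 / 6
        i = 5
        j = i + 16  # 16 bins per decade... one decade is x10; use explicit pair
        d_ratio = grid16.mids[j] / grid16.mids[i]
        assert mults[j] / mults[i] == pytest.approx(d_ratio**3, rel=1e-12)


class TestIntegrate:
    def _uniform_dist(self, grid):
        dn = {t: np.zeros(grid.n_bins) for t in [ParticleType(i) for i in range(5)]}
        dn[ParticleType.TYPE1][:] = 100.0
        from caspm.size_distribution import SizeResolvedConcentration

        return SizeResolvedConcentration(grid=grid, dn_dlogd=dn)

    def test_full_range_equals_count_over_volume(self, grid16, rng):
        d = np.exp(rng.uniform(np.log(0.2), np.log(5.0), 500))
        dist = build_size_distribution(
            d, np.full(d.size, 2),
            np.full(d.size, RegionAssignment.USE_S.value, dtype=object),
            grid16, {"s": 2.0},
        )
        total = integrate(dist, 0.1, 10.0, "number", ParticleType.TYPE2)
        assert total == pytest.approx(500 / 2.0, rel=1e-12)

    def test_half_ranges_sum_to_full(self, grid16, rng):
        d = np.exp(rng.uniform(np.log(0.2), np.log(5.0), 300))
        dist = build_size_distribution(
            d, np.full(d.size, 1),
            np.full(d.size, RegionAssignment.USE_S.value, dtype=object),
            grid16, {"s": 1.0},
        )
        full = integrate(dist, 0.1, 10.0, "number", ParticleType.TYPE1)
        left = integrate(dist, 0.1, 1.0, "number", ParticleType.TYPE1)
        right = integrate(dist, 1.0, 10.0, "number", ParticleType.TYPE1)
        assert left + right == pytest.approx(full, rel=1e-12)

    def test_partial_bins_pro_rated_in_log(self, grid16):
        """On a uniform dN/dlogD, the integral is linear in the log width."""
        dist = self._uniform_dist(grid16)
        lo, hi = 0.6, 0.86
        val = integrate(dist, lo, hi, "number", ParticleType.TYPE1)
        assert val == pytest.approx(100.0 * math.log10(hi / lo), rel=1e-12)

    def test_empty_range_rejected(self, grid16):
        dist = self._uniform_dist(grid16)
        with pytest.raises(ValueError):
            integrate(dist, 2.0, 2.0, "number")
        with pytest.raises(ValueError):
            integrate(dist, 0.01, 0.05, "number")

    def test_conservation_across_types_and_channels(self, grid16, rng):
        """Sum of per-Type integrals equals used-count/volume per channel."""
        n = 2000
        d = np.exp(rng.uniform(np.log(0.15), np.log(8.0), n))
        types = rng.integers(0, 5, n)
        regions = np.where(
            rng.random(n) < 0.6, RegionAssignment.USE_S.value, RegionAssignment.USE_L.value
        ).astype(object)
        vols = {"s": 0.7, "l": 3.1}
        dist = build_size_distribution(d, types, regions, grid16, vols)
        per_type = integrate(dist, 0.1, 10.0, "number")
        total = sum(per_type.values())
        expected = (regions == RegionAssignment.USE_S.value).sum() / vols["s"] + (
            regions == RegionAssignment.USE_L.value
        ).sum() / vols["l"]
        assert total == pytest.approx(expected, rel=1e-12)
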