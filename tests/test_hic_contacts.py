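"""Contact-pair parsing and P(s) curve analytics."""

import numpy as np
import pytest

from chromonema import (DistanceBins, contact_probability, log_derivative,
                        normalize, ratio_curve, read_pairs, write_pairs)


HEADER = ["## pairs format v1.0",
          "#columns: readID chr1 pos1 chr2 pos2 strand1 strand2",
          "#chromsize: chrA 20000000",
          "#chromsize: chrB 10000000"]


class TestReadPairs:
    def test_header_only_file_gives_zero_records(self, pairs_file_factory):
        pairs = read_pairs(pairs_file_factory(HEADER))
        assert len(pairs) == 0

    def test_toy_file_parses_and_flags_intra(self, pairs_file_factory):
        lines = HEADER + [
            "r1\tchrA\t100\tchrA\t5000\t+\t-",
            "r2\tchrA\t200000\tchrA\t900000\t+\t+",
            "r3\tchrA\t50\tchrB\t60\t+\t-",
        ]
        pairs = read_pairs(pairs_file_factory(lines))
        assert len(pairs) == 3
        assert pairs.n_intra == 2

    def test_position_at_chrom_length_rejected(self, pairs_file_factory):
        lines = HEADER + ["r1\tchrB\t10000000\tchrB\t500\t+\t-"]
        with pytest.raises(ValueError, match="record 0"):
            read_pairs(pairs_file_factory(lines))

    def test_malformed_line_reports_line_number(self, pairs_file_factory):
        lines = HEADER + ["r1\tchrA\tnot_a_number\tchrA\t500\t+\t-"]
        with pytest.raises(ValueError, match="line 5"):
            read_pairs(pairs_file_factory(lines))

    def test_roundtrip(self, toy_pairs_factory, tmp_path):
        pairs = toy_pairs_factory(
            [("chrA", 10, "chrA", 1000), ("chrA", 5, "chrB", 7)],
            {"chrA": 20_000_000, "chrB": 10_000_000})
        path = tmp_path / "rt.pairs"
        write_pairs(pairs, path)
        back = read_pairs(path)
        assert np.array_equal(back.df["pos1"], pairs.df["pos1"])
        assert np.array_equal(back.df["pos2"], pairs.df["pos2"])
        assert back.chrom_sizes == pairs.chrom_sizes


class TestDistanceBins:
    def test_default_grid_spans_100kb_to_1gb(self):
        bins = DistanceBins.log_spaced()
        assert bins.edges[0] == 100_000
        assert bins.edges[-1] == 1_000_000_000
        assert bins.n_bins == 40
        ratios = bins.edges[1:] / bins.edges[:-1]
        assert np.max(np.abs(ratios / ratios[0] - 1)) < 1e-9

    def test_half_open_membership(self):
        bins = DistanceBins.log_spaced(100_000, 1_000_000, 10)
        assert bins.index_of(100_000) == 0
        with pytest.raises(ValueError):
            bins.index_of(1_000_000)


class TestContactProbability:
    def test_single_separation_concentrates_in_one_bin(self, toy_pairs_factory):
        recs = [("c", a, "c", a + 150_000) for a in range(0, 400_000, 40_000)]
        pairs = toy_pairs_factory(recs, {"c": 600_000})
        bins = DistanceBins.log_spaced(100_000, 600_000, 10)
        curve = contact_probability(pairs, bins, bin_size=100_000)
        target = bins.index_of(150_000)
        assert curve.n_obs[target] == len(recs)
        others = np.delete(curve.n_obs, target)
        assert (others == 0).all()

    def test_matches_brute_force_enumeration(self, toy_pairs_factory):
        """Observed/possible ratios equal exhaustive locus-pair enumeration."""
        rng = np.random.default_rng(7)
        L, bin_size = 20_000_000, 1_000_000
        recs = [("c", int(a), "c", int(b))
                for a, b in rng.integers(0, L, size=(300, 2))]
        pairs = toy_pairs_factory(recs, {"c": L})
        bins = DistanceBins.log_spaced(1_000_000, L, 8)
        curve = contact_probability(pairs, bins, bin_size=bin_size)

        n_loci = L // bin_size
        possible = np.zeros(bins.n_bins, dtype=int)
        for i in range(n_loci):
            for j in range(i + 1, n_loci):
                s = (j - i) * bin_size
                if bins.edges[0] <= s < bins.edges[-1]:
                    possible[np.searchsorted(bins.edges, s, "right") - 1] += 1
        observed = np.zeros(bins.n_bins, dtype=int)
        for _, a, _, b in recs:
            s = abs(b - a)
            if bins.edges[0] <= s < bins.edges[-1]:
                observed[np.searchsorted(bins.edges, s, "right") - 1] += 1
        assert np.array_equal(curve.n_obs, observed)
        assert np.array_equal(curve.n_possible, possible)
        defined = possible > 0
        assert np.allclose(curve.p[defined], observed[defined] / possible[defined])
        assert np.isnan(curve.p[~defined]).all()

    def test_counts_conserved_within_range(self, toy_pairs_factory):
        rng = np.random.default_rng(3)
        L = 50_000_000
        recs = [("c", int(a), "c", int(b)) for a, b in rng.integers(0, L, size=(500, 2))]
        pairs = toy_pairs_factory(recs, {"c": L})
        bins = DistanceBins.log_spaced(100_000, L, 10)
        curve = contact_probability(pairs, bins)
        seps = pairs.intra_separations()
        in_range = ((seps >= bins.edges[0]) & (seps < bins.edges[-1])).sum()
        assert curve.n_obs.sum() == in_range

    def test_no_intra_pairs_is_an_error(self, toy_pairs_factory):
        pairs = toy_pairs_factory([("a", 1, "b", 2)], {"a": 1_000_000, "b": 1_000_000})
        with pytest.raises(ValueError, match="no usable contacts"):
            contact_probability(pairs, DistanceBins.log_spaced(100_000, 1_000_000, 5))


class TestNormalize:
    def _curve(self):
        bins = DistanceBins.log_spaced(100_000, 100_000_000, 10)
        from chromonema import ContactCurve
        p = bins.mids ** -0.5
        n = np.full(bins.n_bins, 100)
        return ContactCurve(bins=bins, p=p, n_obs=n, n_possible=n)

    def test_equals_one_at_100kb_and_idempotent(self):
        curve = normalize(self._curve(), 100_000)
        idx = curve.bins.index_of(100_000)
        assert curve.p[idx] == 1.0
        again = normalize(curve, 100_000)
        assert np.array_equal(again.p, curve.p)
        assert curve.normalized_at == 100_000


class TestLogDerivative:
    def _power_law_curve(self, alpha):
        from chromonema import ContactCurve
        bins = DistanceBins.log_spaced(100_000, 1_000_000_000, 10)
        p = bins.mids.astype(float) ** alpha
        n = np.full(bins.n_bins, 10)
        return ContactCurve(bins=bins, p=p, n_obs=n, n_possible=n)

    @pytest.mark.parametrize("alpha", [-0.5, -1.0, -2.3])
    def test_recovers_exact_power_law_exponent(self, alpha):
        track = log_derivative(self._power_law_curve(alpha))
        assert np.max(np.abs(track.slope - alpha)) < 1e-6

    def test_flat_curve_has_zero_slope(self):
        track = log_derivative(self._power_law_curve(0.0))
        assert np.max(np.abs(track.slope)) < 1e-12

    def test_exp_gauss_bump_zero_crossing_near_peak(self):
        """Derivative changes sign within one bin of the analytic maximum."""
        from chromonema import ContactCurve
        bins = DistanceBins.log_spaced(100_000, 200_000_000, 20)
        mu, sig, lam = 30e6, 5e6, 5e6

        def f(s):
            return np.exp(-s / lam) + 0.3 * np.exp(-0.5 * ((s - mu) / sig) ** 2)

        # independent oracle: analytic maximum located on a fine grid
        grid = np.linspace(10e6, 60e6, 200_001)
        s_star = grid[np.argmax(f(grid))]
        p = f(bins.mids)
        n = np.full(bins.n_bins, 10)
        track = log_derivative(ContactCurve(bins=bins, p=p, n_obs=n, n_possible=n))
        sign = np.sign(track.slope)
        crossings = bins.mids[1:][(sign[:-1] > 0) & (sign[1:] <= 0)]
        near = crossings[(crossings > 10e6)]
        assert near.size >= 1
        ratio = near[0] / s_star
        one_bin = bins.edges[1] / bins.edges[0]
        assert 1 / one_bin <= ratio <= one_bin

    def test_undefined_bins_propagate(self):
        curve = self._power_law_curve(-1.0)
        curve.p[5] = np.nan
        track = log_derivative(curve)
        assert np.isnan(track.slope[5])

    def test_too_few_bins_rejected(self):
        curve = self._power_law_curve(-1.0)
        curve.p[2:] = np.nan
        with pytest.raises(ValueError):
            log_derivative(curve)


class TestRatioCurve:
    def _curves(self):
        from chromonema import ContactCurve
        bins = DistanceBins.log_spaced(100_000, 200_000_000, 10)
        mu, sig, lam = 30e6, 5e6, 5e6
        meta = np.exp(-bins.mids / lam) + 0.3 * np.exp(-0.5 * ((bins.mids - mu) / sig) ** 2)
        inter = bins.mids ** -1.0
        n = np.full(bins.n_bins, 10)
        return (ContactCurve(bins=bins, p=meta, n_obs=n, n_possible=n),
                ContactCurve(bins=bins, p=inter, n_obs=n, n_possible=n))

    def test_identity_gives_unit_ratio(self):
        meta, _ = self._curves()
        r = ratio_curve(meta, meta)
        assert np.allclose(r.p[np.isfinite(r.p)], 1.0)

    def test_bump_over_power_law_peaks_near_turn_length(self):
        meta, inter = self._curves()
        r = ratio_curve(meta, inter)
        peak_mid = r.bins.mids[np.nanargmax(r.p)]
        one_bin = r.bins.edges[1] / r.bins.edges[0]
        assert 30e6 / one_bin <= peak_mid <= 30e6 * one_bin

    def test_zero_denominator_bins_become_undefined(self):
        meta, inter = self._curves()
        inter.p[4] = 0.0
        r = ratio_curve(meta, inter)
        assert np.isnan(r.p[4])

    def test_bin_mismatch_rejected(self):
        from chromonema import ContactCurve
        meta, _ = self._curves()
        other_bins = DistanceBins.log_spaced(100_000, 100_000_000, 10)
        n = np.full(other_bins.n_bins, 1)
        other = ContactCurve(bins=other_bins, p=np.ones(other_bins.n_bins),
                             n_obs=n, n_possible=n)
        with pytest.raises(ValueError, match="bin grids"):
            ratio_curve(meta, other)
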