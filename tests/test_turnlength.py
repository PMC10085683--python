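"""Regional turn-length estimation: attribution rule, mixture fit, profile."""

import numpy as np
import pandas as pd
import pytest

from chromonema import (ContactPairs, DistanceBins, HelicalSignalSpec,
                        fit_exp_gauss, generate_helical_pairs,
                        regional_histogram, turn_length_profile)
from chromonema.turnlength import RegionalHistogram, FLAG_NO_SIGNAL

MB = 1_000_000


def _qualifies(a, b, start, end):
    """Independent statement of the regional attribution rule."""
    a, b = min(a, b), max(a, b)
    return (start <= a < end) or (start <= b < end) or (a < start and b >= end)


class TestRegionalHistogram:
    HAND_PAIRS = [  # on a 20 Mb chromosome, region [5, 10) Mb
        (4 * MB, 12 * MB),    # spans the region -> counted
        (1 * MB, 3 * MB),     # entirely left -> excluded
        (6 * MB, 7 * MB),     # both inside -> counted once
        (9 * MB, 15 * MB),    # left endpoint inside -> counted
        (2 * MB, 6 * MB),     # right endpoint inside -> counted
        (11 * MB, 19 * MB),   # entirely right -> excluded
        (4 * MB, 9 * MB),     # right endpoint inside -> counted
        (12 * MB, 4 * MB),    # unordered spanning pair -> counted
    ]

    def _pairs(self, toy_pairs_factory):
        recs = [("c", a, "c", b) for a, b in self.HAND_PAIRS]
        return toy_pairs_factory(recs, {"c": 20 * MB})

    def test_matches_exhaustive_rule_application(self, toy_pairs_factory):
        pairs = self._pairs(toy_pairs_factory)
        bins = DistanceBins.log_spaced(100_000, 20 * MB, 10)
        hist = regional_histogram(pairs, ("c", 5 * MB, 10 * MB), bins)
        expected = sum(_qualifies(a, b, 5 * MB, 10 * MB) for a, b in self.HAND_PAIRS)
        assert hist.total == expected == 6
        # per-bin agreement with the brute-force rule
        brute = np.zeros(bins.n_bins, dtype=int)
        for a, b in self.HAND_PAIRS:
            if _qualifies(a, b, 5 * MB, 10 * MB):
                s = abs(b - a)
                brute[np.searchsorted(bins.edges, s, "right") - 1] += 1
        assert np.array_equal(hist.counts, brute)

    def test_every_pair_attributed_to_some_region(self, toy_pairs_factory):
        """Endpoint rule completeness over a full tiling."""
        rng = np.random.default_rng(11)
        L = 40 * MB
        recs = [("c", int(a), "c", int(b)) for a, b in rng.integers(0, L, (200, 2))
                if a != b]
        pairs = toy_pairs_factory(recs, {"c": L})
        bins = DistanceBins.log_spaced(1000, L, 10)
        regions = [(s, s + 5 * MB) for s in range(0, L, 5 * MB)]
        covered = np.zeros(len(recs), dtype=bool)
        for start, end in regions:
            for k, (_, a, _, b) in enumerate(recs):
                covered[k] |= _qualifies(a, b, start, end)
        assert covered.all()
        total = sum(regional_histogram(pairs, ("c", s, e), bins).total
                    for s, e in regions)
        assert total >= len(recs)  # each pair in >= 1 region

    def test_empty_input_gives_zero_histogram(self, toy_pairs_factory):
        pairs = toy_pairs_factory([], {"c": 20 * MB})
        bins = DistanceBins.log_spaced(100_000, 20 * MB, 10)
        hist = regional_histogram(pairs, ("c", 5 * MB, 10 * MB), bins)
        assert hist.total == 0

    def test_pair_inside_region_counted_once(self, toy_pairs_factory):
        pairs = toy_pairs_factory([("c", 6 * MB, "c", 7 * MB)], {"c": 20 * MB})
        bins = DistanceBins.log_spaced(100_000, 20 * MB, 10)
        hist = regional_histogram(pairs, ("c", 5 * MB, 10 * MB), bins)
        assert hist.total == 1

    def test_region_outside_chromosome_rejected(self, toy_pairs_factory):
        pairs = toy_pairs_factory([("c", 1, "c", 2)], {"c": 20 * MB})
        with pytest.raises(ValueError, match="outside"):
            regional_histogram(pairs, ("c", 19 * MB, 25 * MB),
                               DistanceBins.log_spaced(1000, 20 * MB, 10))


class TestFitExpGauss:
    def _histogram(self, samples, lo=100_000, hi=200 * MB):
        edges = DistanceBins.log_spaced(lo, hi, 40).edges
        counts, _ = np.histogram(samples, bins=edges)
        return RegionalHistogram(region=("c", 0, hi), bin_edges=edges,
                                 counts=counts)

    def test_recovers_mixture_centre_within_1mb(self):
        rng = np.random.default_rng(42)
        n = 200_000
        is_g = rng.random(n) < 0.3
        s = rng.exponential(5 * MB, n)
        s[is_g] = rng.normal(30 * MB, 5 * MB, is_g.sum())
        fit = fit_exp_gauss(self._histogram(s[s > 100_000]))
        assert fit.converged and fit.gauss_detected
        assert abs(fit.mu - 30 * MB) < 1 * MB
        assert abs(fit.scale_exp - 5 * MB) < 1.5 * MB

    def test_pure_exponential_detects_no_gaussian(self):
        rng = np.random.default_rng(43)
        s = rng.exponential(5 * MB, 200_000)
        fit = fit_exp_gauss(self._histogram(s[s > 100_000]))
        assert not fit.gauss_detected

    def test_underpowered_region_is_an_error(self):
        rng = np.random.default_rng(44)
        s = rng.exponential(5 * MB, 10)
        with pytest.raises(ValueError, match="underpowered"):
            fit_exp_gauss(self._histogram(s))


class TestTurnLengthProfile:
    def test_constant_signal_recovered_in_all_interior_regions(self):
        spec = HelicalSignalSpec(chrom_length=100 * MB, turn_length=30 * MB,
                                 n_pairs=2_000_000, seed=5)
        prof = turn_length_profile(generate_helical_pairs(spec))
        df = prof.to_frame()
        interior = df[(df.start >= 30 * MB) & (df.end <= 70 * MB)]
        assert len(interior) >= 5
        assert (np.abs(interior.turn_length - 30 * MB) < 2 * MB).all()

    def test_gradient_profile_monotone_after_smoothing(self):
        grad = lambda x: 20 * MB + 18 * MB * x / (200 * MB)
        spec = HelicalSignalSpec(chrom_length=200 * MB, turn_length=grad,
                                 n_pairs=2_000_000, seed=6)
        prof = turn_length_profile(generate_helical_pairs(spec))
        t = prof.to_frame()
        # interior regions only: within a turn length of either chromosome
        # end the bump is truncated by the rejection rule
        t = t[(t.start >= 20 * MB) & (t.end <= 200 * MB - 38 * MB)]
        mus = t.turn_length[np.isfinite(t.turn_length)]
        smoothed = mus.rolling(3, center=True).mean().dropna().to_numpy()
        assert (np.diff(smoothed) > -1e-9).all()
        assert smoothed[-1] - smoothed[0] > 8 * MB  # gradient actually seen

    def test_noise_region_flagged_without_disturbing_distant_regions(self):
        """Replacing one region's qualifying pairs with pure-exponential noise
        flags that region; regions outside the removal halo (one turn length)
        keep their estimates."""
        L = 200 * MB
        spec = HelicalSignalSpec(chrom_length=L, turn_length=30 * MB,
                                 n_pairs=4_000_000, seed=7)
        pairs = generate_helical_pairs(spec)
        start, end = 95 * MB, 100 * MB
        df = pairs.df
        a = np.minimum(df.pos1, df.pos2).to_numpy()
        b = np.maximum(df.pos1, df.pos2).to_numpy()
        qual = (((a >= start) & (a < end)) | ((b >= start) & (b < end))
                | ((a < start) & (b >= end)))
        kept = df[~qual]
        rng = np.random.default_rng(8)
        n_noise = int(qual.sum())
        na = rng.integers(start, end, n_noise)
        ns = np.maximum(np.rint(rng.exponential(5 * MB, n_noise)), 1).astype(np.int64)
        nb = np.minimum(na + ns, L - 1)
        noise = pd.DataFrame({"chrom1": "chrS", "pos1": na,
                              "chrom2": "chrS", "pos2": nb})
        mixed = ContactPairs(df=pd.concat([kept.drop(columns="intra"), noise],
                                          ignore_index=True),
                             chrom_sizes=pairs.chrom_sizes)
        prof = turn_length_profile(mixed)
        target = prof.lookup("chrS", start + MB)
        assert target["flag"] == FLAG_NO_SIGNAL
        # removing pairs that touch [start, end) also thins the bump of every
        # region within one turn length; beyond that halo (and away from the
        # chromosome ends) estimates must be intact
        for pos in (45 * MB, 55 * MB, 145 * MB, 155 * MB):
            entry = prof.lookup("chrS", pos)
            assert np.isfinite(entry["turn_length"])
            assert abs(entry["turn_length"] - 30 * MB) < 2 * MB

    def test_masked_regions_flagged_and_tiling_complete(self):
        spec = HelicalSignalSpec(chrom_length=52 * MB, turn_length=15 * MB,
                                 bump_sigma=3 * MB, n_pairs=800_000, seed=9)
        prof = turn_length_profile(generate_helical_pairs(spec),
                                   masks=[("chrS", 20 * MB, 23 * MB)],
                                   mu_bounds=(8 * MB, 40 * MB))
        df = prof.to_frame().sort_values("start")
        # masked region annotated
        masked = df[(df.start <= 20 * MB) & (df.end > 20 * MB)]
        assert (masked.flag == FLAG_NO_SIGNAL).all()
        # tiling: contiguous, starts at 0, ends at chromosome end (merged tail)
        assert df.start.iloc[0] == 0
        assert df.end.iloc[-1] == 52 * MB
        assert (df.start.iloc[1:].to_numpy() == df.end.iloc[:-1].to_numpy()).all()

    def test_flags_do_not_alter_mu(self):
        spec = HelicalSignalSpec(chrom_length=60 * MB, turn_length=20 * MB,
                                 n_pairs=600_000, seed=10)
        pairs = generate_helical_pairs(spec)
        free = turn_length_profile(pairs, mu_bounds=(10 * MB, 40 * MB))
        masked = turn_length_profile(pairs, masks=[("chrS", 0, 5 * MB)],
                                     mu_bounds=(10 * MB, 40 * MB))
        for e_free, e_mask in zip(free.entries[1:], masked.entries[1:]):
            if e_free["fit"] is not None and e_mask["fit"] is not None:
                assert e_free["fit"].mu == e_mask["fit"].mu

    def test_short_chromosome_rejected(self, toy_pairs_factory):
        pairs = toy_pairs_factory([("c", 1, "c", 2)], {"c": 3 * MB})
        with pytest.raises(ValueError, match="shorter than region size"):
            turn_length_profile(pairs)
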