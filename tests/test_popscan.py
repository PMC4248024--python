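import itertools

import numpy as np
import pytest

from nadsel import synthdata
from nadsel.popscan import (
    SiteFrequencySpectrum,
    fay_wu_H,
    polarized_sfs,
    sliding_scan,
    subsample_envelope,
    theta_estimators,
    wc_fst,
    zeng_E,
)
from nadsel.seqio import VariantRecord


def _site(pos, ac, an=10, ref="A", alt="G", outgroup="A", pop="P1"):
    return VariantRecord("c", pos, ref, alt, {pop: (ac, an)}, outgroup_allele=outgroup)


class TestPolarizedSFS:
    def test_outgroup_matches_ref(self):
        sfs = polarized_sfs([_site(1, 3)], "P1")
        assert sfs.counts[3] == 1 and sfs.segregating_sites == 1

    def test_outgroup_matches_alt_flips_derived(self):
        sfs = polarized_sfs([_site(1, 3, outgroup="G"), _site(2, 4)], "P1")
        assert sfs.counts[7] == 1  # derived allele is ref, count 10 - 3

    def test_mismatching_outgroup_dropped(self):
        sfs = polarized_sfs([_site(1, 3, outgroup="T"), _site(2, 4)], "P1")
        assert sfs.sites_dropped == 1 and sfs.counts[4] == 1

    def test_no_usable_sites_errors(self):
        with pytest.raises(ValueError):
            polarized_sfs([_site(1, 3, outgroup=None)], "P1")


class TestThetaEstimators:
    def test_singleton_spectrum_n4(self):
        sfs = SiteFrequencySpectrum(n=4, counts=np.array([0, 1, 0, 0.0]))
        tp, th, tl, tw = theta_estimators(sfs)
        assert tp == pytest.approx(0.5)
        assert th == pytest.approx(1 / 6)
        assert tl == pytest.approx(1 / 3)
        assert tw == pytest.approx(1 / (1 + 1 / 2 + 1 / 3))

    def test_n2_pi_equals_H(self, rng):
        counts = np.array([0, rng.integers(0, 20)], dtype=float)
        sfs = SiteFrequencySpectrum(n=2, counts=counts)
        tp, th, _, _ = theta_estimators(sfs)
        assert tp == pytest.approx(th)
        assert fay_wu_H(sfs)[0] == pytest.approx(0.0)

    def test_empty_spectrum_zero(self):
        sfs = SiteFrequencySpectrum(n=10, counts=np.zeros(10))
        assert theta_estimators(sfs) == (0.0, 0.0, 0.0, 0.0)

    def test_pi_matches_pairwise_difference_oracle(self, rng):
        """theta_pi from the SFS equals mean pairwise differences."""
        n, S = 10, 40
        hap = (rng.random((n, S)) < rng.random(S) * 0.8).astype(int)
        seg = (hap.sum(0) > 0) & (hap.sum(0) < n)
        hap = hap[:, seg]
        sfs = synthdata.sfs_from_haplotypes(hap)
        tp = theta_estimators(sfs)[0]
        diffs = [
            np.sum(hap[i] != hap[j]) for i, j in itertools.combinations(range(n), 2)
        ]
        assert tp == pytest.approx(np.mean(diffs))


class TestFayWuH:
    def test_singleton_example(self):
        sfs = SiteFrequencySpectrum(n=4, counts=np.array([0, 1, 0, 0.0]))
        H_raw, H_norm = fay_wu_H(sfs)
        assert H_raw == pytest.approx(0.5 - 1 / 6)

    def test_neutral_mean_near_zero(self):
        hs = []
        for rep in range(500):
            hap, _, _ = synthdata.simulate_neutral_coalescent(20, 5.0, seed=3000 + rep)
            sfs = synthdata.sfs_from_haplotypes(hap)
            if sfs.segregating_sites > 0:
                hs.append(fay_wu_H(sfs)[0])
        hs = np.asarray(hs)
        se = hs.std(ddof=1) / np.sqrt(len(hs))
        assert abs(hs.mean()) < 2 * se

    def test_sweep_spectrum_negative(self):
        hs = [
            fay_wu_H(synthdata.simulate_sweep_sfs(20, 5.0, 0.5, seed=4000 + r))[0]
            for r in range(200)
        ]
        assert np.mean(hs) < 0

    def test_zeng_E_finite_on_typical_spectrum(self):
        hap, _, _ = synthdata.simulate_neutral_coalescent(20, 5.0, seed=77)
        sfs = synthdata.sfs_from_haplotypes(hap)
        E_raw, E_norm = zeng_E(sfs)
        assert np.isfinite(E_raw) and np.isfinite(E_norm)


class TestWCFst:
    def _two_pop_site(self, ac1, ac2, an=200):
        return VariantRecord(
            "c", 1, "A", "G", {"P1": (ac1, an), "P2": (ac2, an)}, outgroup_allele="A"
        )

    def test_identical_frequencies_near_zero(self, rng):
        variants = []
        for pos in range(200):
            p = rng.uniform(0.2, 0.8)
            v = VariantRecord(
                "c", pos + 1, "A", "G",
                {"P1": (int(rng.binomial(200, p)), 200),
                 "P2": (int(rng.binomial(200, p)), 200)},
            )
            variants.append(v)
        assert abs(wc_fst(variants, ["P1", "P2"])) < 0.02

    def test_fixed_difference_is_one(self):
        assert wc_fst([self._two_pop_site(200, 0)], ["P1", "P2"]) == pytest.approx(1.0)

    def test_monomorphic_region_undefined(self):
        assert np.isnan(wc_fst([self._two_pop_site(0, 0)], ["P1", "P2"]))

    def test_allele_label_swap_invariant(self):
        v1 = [self._two_pop_site(30, 80), self._two_pop_site(150, 60)]
        v2 = [self._two_pop_site(170, 120), self._two_pop_site(50, 140)]
        assert wc_fst(v1, ["P1", "P2"]) == pytest.approx(wc_fst(v2, ["P1", "P2"]))

    def test_balding_nichols_recovery(self):
        recs = synthdata.simulate_structured_freqs(10, 2000, 0.15, 100, seed=8)
        pops = sorted(recs[0].per_pop_alt_counts)
        assert abs(wc_fst(recs, pops) - 0.15) < 0.02


class TestSlidingScan:
    def _variants(self, n=50, spacing=100):
        return [_site(1 + i * spacing, 2 + (i % 5)) for i in range(n)]

    def test_window_count_85kb(self):
        variants = self._variants(n=170, spacing=500)
        windows = sliding_scan(variants, ["P1"], (0, 85_000), 3_000, 500, "fay_wu_H")
        full = [w for w in windows if not w.partial]
        assert len(full) == 165

    def test_disjoint_tiling_at_step_equals_window(self):
        windows = sliding_scan(self._variants(), ["P1"], (0, 5000), 1000, 1000, "fay_wu_H")
        for a, b in zip(windows, windows[1:]):
            assert a.end == b.start

    def test_windows_cover_region_without_gaps(self):
        windows = sliding_scan(self._variants(), ["P1"], (0, 5300), 1000, 400, "fay_wu_H")
        covered_to = 0
        for w in sorted(windows, key=lambda w: w.start):
            assert w.start <= covered_to
            covered_to = max(covered_to, w.end)
        assert covered_to == 5300
        assert windows[-1].partial

    def test_region_shorter_than_window(self):
        windows = sliding_scan(self._variants(n=5), ["P1"], (0, 400), 3000, 500, "fay_wu_H")
        assert len(windows) == 1 and (windows[0].start, windows[0].end) == (0, 400)

    def test_empty_window_flagged_undefined(self):
        windows = sliding_scan([_site(4500, 3)], ["P1"], (0, 5000), 1000, 1000, "fay_wu_H")
        assert windows[0].n_variants == 0 and np.isnan(windows[0].value)


class TestSubsampleEnvelope:
    def _panel(self, seed=0):
        recs = synthdata.simulate_structured_freqs(
            3, 60, 0.1, 40, seed=seed
        )  # 20 diploid individuals per pop
        pops = sorted(recs[0].per_pop_alt_counts)
        return recs, pops, {p: 20 for p in pops}

    def test_full_panel_degenerates_to_point(self):
        recs, pops, sizes = self._panel()
        windows = sliding_scan(recs, pops, (0, 60), 60, 60, "fst")
        env = subsample_envelope(
            recs, pops, (0, 60), windows, sizes,
            n_subsamples=5, subsample_size=60, seed=1,
        )
        assert env[0].env_low == pytest.approx(env[0].value)
        assert env[0].env_high == pytest.approx(env[0].value)

    def test_deterministic_given_seed(self):
        recs, pops, sizes = self._panel()
        windows = sliding_scan(recs, pops, (0, 60), 30, 15, "fst")
        e1 = subsample_envelope(recs, pops, (0, 60), windows, sizes, 20, 30, seed=9)
        e2 = subsample_envelope(recs, pops, (0, 60), windows, sizes, 20, 30, seed=9)
        assert [(w.env_low, w.env_high) for w in e1] == [
            (w.env_low, w.env_high) for w in e2
        ]

    def test_envelope_narrows_with_subsample_size(self):
        recs, pops, sizes = self._panel(seed=4)
        windows = sliding_scan(recs, pops, (0, 60), 60, 60, "fst")
        widths = []
        for size in (20, 40, 55):
            env = subsample_envelope(
                recs, pops, (0, 60), windows, sizes, 30, size, seed=2
            )
            widths.append(env[0].env_high - env[0].env_low)
        assert widths[0] > widths[-1]

    def test_envelope_brackets_value(self):
        recs, pops, sizes = self._panel(seed=5)
        windows = sliding_scan(recs, pops, (0, 60), 60, 60, "fst")
        env = subsample_envelope(recs, pops, (0, 60), windows, sizes, 40, 50, seed=3)
        assert env[0].env_low <= env[0].value + 0.05
        assert env[0].env_high >= env[0].value - 0.05
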