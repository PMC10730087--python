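import numpy as np
import pytest

from markdyn.genomic_io import CoverageTrack
from markdyn.profile_analysis import (
    central_accumulation_score,
    length_quartile_metagenes,
    metagene_profile,
    tail_loss_statistic,
    windowed_log2_ratio,
)
from markdyn.synthetic_data import (
    ProfileShape,
    generate_coverage,
    generate_gene_set,
    generate_truncation_scenario,
)
from markdyn.genomic_io import merge_tracks
from conftest import make_gene


def bump_track(genes, amplitude, noise_sd=0.0, seed=0):
    shape = ProfileShape(
        five_prime_level=10, three_prime_level=2,
        central_bump_amplitude=amplitude, central_bump_width=0.2,
        noise_sd=noise_sd,
    )
    ss = np.random.SeedSequence(seed).spawn(len(genes))
    return merge_tracks(
        [
            generate_coverage(g, shape, int(s.generate_state(1)[0] % 2**31), bin_size=20)
            for g, s in zip(genes, ss)
        ]
    )


def fixed_genes(n, length=2000, gap=10_000):
    genes = []
    pos = 10_000
    for i in range(n):
        genes.append(
            make_gene(
                gene_id=f"g{i:04d}", start=pos, end=pos + length,
                strand="+" if i % 2 == 0 else "-",
            )
        )
        pos += length + gap
    return genes


class TestMetagene:
    def test_uniform_coverage_gives_flat_profile(self):
        genes = fixed_genes(3)
        track = CoverageTrack.from_records([("chr1", 0, 60_000, 2.0)])
        prof = metagene_profile([track], genes, normalize="none")
        np.testing.assert_allclose(prof.mean, 2.0)

    def test_rpm_is_depth_invariant(self):
        genes = fixed_genes(4)
        track = bump_track(genes, amplitude=1.0, noise_sd=0.2, seed=3)
        deep = track.scaled(2.0)  # doubled library depth
        a = metagene_profile([track], genes).mean
        b = metagene_profile([deep], genes).mean
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_minus_strand_profile_mirrors_plus(self):
        asym = CoverageTrack.from_records(
            [("chr1", i * 100, (i + 1) * 100, float(i)) for i in range(200)]
        )
        plus = make_gene(gene_id="gp", start=4_000, end=9_000, strand="+")
        minus = make_gene(gene_id="gm", start=4_000, end=9_000, strand="-")
        pp = metagene_profile([asym], [plus], normalize="none").mean
        pm = metagene_profile([asym], [minus], normalize="none").mean
        np.testing.assert_allclose(pm, pp[::-1])

    def test_short_genes_excluded_with_warning(self, caplog):
        genes = fixed_genes(2) + [make_gene(gene_id="tiny", start=0, end=50)]
        track = CoverageTrack.from_records([("chr1", 0, 60_000, 1.0)])
        with caplog.at_level("WARNING"):
            prof = metagene_profile([track], genes, normalize="none")
        assert prof.n_genes == 2
        assert any("tiny" in r.message for r in caplog.records)

    def test_union_is_count_weighted_mean_of_parts(self):
        genes = fixed_genes(6)
        track = bump_track(genes, amplitude=2.0, noise_sd=0.3, seed=5)
        a = metagene_profile([track], genes[:2], normalize="none").mean
        b = metagene_profile([track], genes[2:], normalize="none").mean
        union = metagene_profile([track], genes, normalize="none").mean
        np.testing.assert_allclose(union, (2 * a + 4 * b) / 6, rtol=1e-10)


class TestAccumulationScore:
    def test_flat_and_linear_profiles_score_zero(self):
        assert central_accumulation_score(np.full(100, 3.0)).score == pytest.approx(0.0)
        linear = np.linspace(10, 2, 100)
        assert central_accumulation_score(linear).score == pytest.approx(0.0, abs=1e-9)

    def test_planted_amplitude_recovered_exactly_without_noise(self):
        genes = fixed_genes(10)
        track = bump_track(genes, amplitude=2.0, noise_sd=0.0)
        prof = metagene_profile([track], genes, normalize="none")
        score = central_accumulation_score(prof).score
        assert score == pytest.approx(2.0, abs=1e-9)

    def test_shift_invariance_and_linear_scaling(self):
        genes = fixed_genes(10)
        prof = metagene_profile(
            [bump_track(genes, amplitude=1.5)], genes, normalize="none"
        ).mean
        s0 = central_accumulation_score(prof).score
        assert central_accumulation_score(prof + 7.0).score == pytest.approx(s0)
        prof3 = metagene_profile(
            [bump_track(genes, amplitude=4.5)], genes, normalize="none"
        ).mean
        assert central_accumulation_score(prof3).score == pytest.approx(3 * s0, rel=1e-9)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            central_accumulation_score(np.zeros(100), central=(25, 60))


class TestLengthQuartiles:
    def test_eight_distinct_lengths_split_two_per_quartile(self):
        genes = []
        pos = 0
        for i, length in enumerate([1000, 2000, 3000, 4000, 5000, 6000, 7000, 8000]):
            genes.append(make_gene(gene_id=f"g{i}", start=pos, end=pos + length))
            pos += length + 10_000
        track = CoverageTrack.from_records([("chr1", 0, pos, 1.0)])
        profs = length_quartile_metagenes(genes, [track])
        assert [p.n_genes for p in profs] == [2, 2, 2, 2]

    def test_fewer_than_four_genes_rejected(self):
        with pytest.raises(ValueError):
            length_quartile_metagenes(fixed_genes(3), [])

    def test_tied_lengths_split_deterministically(self):
        genes = fixed_genes(8)  # all the same length
        track = CoverageTrack.from_records([("chr1", 0, 200_000, 1.0)])
        a = length_quartile_metagenes(genes, [track])
        b = length_quartile_metagenes(genes, [track])
        assert [p.n_genes for p in a] == [p.n_genes for p in b] == [2, 2, 2, 2]


class TestWindowedRatio:
    def test_identical_tracks_give_zero_everywhere(self):
        genes = fixed_genes(5)
        track = bump_track(genes, amplitude=1.0, noise_sd=0.4, seed=2)
        ratio = windowed_log2_ratio([track], [track], genes)
        np.testing.assert_allclose(ratio.trace, 0.0, atol=1e-12)

    def test_halved_signal_with_rpm_off_and_large_signal(self):
        genes = fixed_genes(5)
        wt = CoverageTrack.from_records([("chr1", 0, 70_000, 1000.0)])
        mut = wt.scaled(0.5)
        ratio = windowed_log2_ratio([mut], [wt], genes, normalize="none")
        np.testing.assert_allclose(ratio.trace, -1.0, atol=2e-3)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            windowed_log2_ratio([], [], fixed_genes(2))


class TestTruncationRecovery:
    def _scenario(self, f, seed=0, n_genes=40, n_truncated=12):
        genes, _ = generate_gene_set(n_genes, 1000, seed=seed, gap=2_000, min_length=500)
        truncated = {g.gene_id for g in genes[:n_truncated]}
        wt, mut, _ = generate_truncation_scenario(
            genes, truncated, f, seed=seed + 1, depth=50.0, noise_sd=1.0,
            bin_size=10,  # finer than the 100-window width of ~1 kb genes
        )
        target = [g for g in genes if g.gene_id in truncated]
        return wt, mut, target

    def test_planted_truncation_recovered_in_tail_windows(self):
        wt, mut, target = self._scenario(f=0.5)
        ratio = windowed_log2_ratio(mut, wt, target)
        assert ratio.trace[-15:].mean() == pytest.approx(-1.0, abs=0.1)
        assert abs(ratio.trace[:75].mean()) < 0.1
        stat, p = tail_loss_statistic(ratio, n_perm=999, seed=0)
        assert stat < -0.5
        assert p == pytest.approx(1 / 1000, abs=1e-9)  # minimum attainable

    def test_tail_statistic_zero_for_zero_matrix(self):
        wt, mut, target = self._scenario(f=0.0)
        ratio = windowed_log2_ratio(wt, wt, target)  # identical tracks
        stat, _ = tail_loss_statistic(ratio, n_perm=99, seed=0)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_invalid_tail_fraction_rejected(self):
        wt, mut, target = self._scenario(f=0.0)
        ratio = windowed_log2_ratio(mut, wt, target)
        with pytest.raises(ValueError):
            tail_loss_statistic(ratio, tail_fraction=0.8)

    def test_null_truncation_pvalues_calibrated(self):
        # rejection rate at alpha = 0.05 within 3 binomial SEs over 200 seeds
        rejections = 0
        n_runs = 200
        for seed in range(n_runs):
            wt, mut, target = self._scenario(f=0.0, seed=seed, n_genes=15,
                                             n_truncated=15)
            ratio = windowed_log2_ratio(mut[:1], wt[:1], target)
            _, p = tail_loss_statistic(ratio, n_perm=199, seed=seed)
            rejections += p <= 0.05
        rate = rejections / n_runs
        se = np.sqrt(0.05 * 0.95 / n_runs)
        assert abs(rate - 0.05) < 3 * se
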