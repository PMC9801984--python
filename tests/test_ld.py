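import numpy as np
import pytest

from declinesim.ld import (
    NeEstimate,
    PairStore,
    _sample_correction,
    bin_pairs,
    burrows_r2,
    haldane_c,
    ld_ne_point,
    ld_trajectory,
)


class TestBurrowsR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert burrows_r2(g, g) == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        a = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        b = np.array([1, 1, 2, 0, 0, 1], dtype=float)
        # longhand composite-covariance arithmetic
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov**2 / (a.var() * b.var())
        assert burrows_r2(a, b) == pytest.approx(expected, rel=1e-12)
        # longhand: cov = 1/3, var_a = 2/3, var_b = 17/36 -> r2 = 6/17
        assert expected == pytest.approx(6.0 / 17.0, rel=1e-9)

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.integers(0, 3, 30), rng.integers(0, 3, 30)
        assert burrows_r2(a, b) == burrows_r2(b, a)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            burrows_r2(np.ones(10), np.array([0, 1, 2] * 3 + [1]))

    def test_permuted_copies_near_sampling_noise(self):
        rng = np.random.default_rng(2)
        a = np.tile([0, 1, 2], 50)
        vals = [burrows_r2(a, rng.permutation(a)) for _ in range(300)]
        # E[r2] for independent vectors is ~1/(S-1)
        assert np.mean(vals) == pytest.approx(1 / (len(a) - 1), rel=0.3)

    def test_allele_label_swap_invariant(self):
        rng = np.random.default_rng(3)
        a, b = rng.integers(0, 3, 40), rng.integers(0, 3, 40)
        assert burrows_r2(2 - a, b) == pytest.approx(burrows_r2(a, b))


class TestHaldane:
    def test_one_megabase(self):
        # 1 Mb at 1 cM/Mb: d = 0.01 Morgans
        assert haldane_c(1_000_000) == pytest.approx(
            0.5 * (1 - np.exp(-0.02))
        )
        assert haldane_c(1_000_000) == pytest.approx(0.00990, abs=1e-5)

    def test_unlinked_limit(self):
        assert haldane_c(1e12) == pytest.approx(0.5)


def _drift_genotypes(ne, S, m, seed, generations=100):
    """Unlinked loci drifting in a Wright-Fisher population (direct oracle)."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.2, 0.8, size=m)
    for _ in range(generations):
        freqs = rng.binomial(2 * ne, freqs) / (2 * ne)
    # sample S diploids jointly: genotypes independent across loci given freqs
    return rng.binomial(2, np.clip(freqs, 0, 1), size=(S, m))


class TestLdNePoint:
    def test_few_loci_flagged(self):
        g = np.array([[0], [1], [2]])
        est = ld_ne_point(g, maf=0.0)
        assert est.flag != ""
        assert np.isnan(est.point)

    def test_independent_loci_infinite(self):
        # three mutually orthogonal dosage columns: mean r2 is exactly 0, so
        # the corrected r2 goes negative and the estimate is "infinity"
        g = np.array(
            [
                [0, 0, 2],
                [0, 2, 0],
                [2, 0, 0],
                [2, 2, 2],
            ]
        )
        assert np.corrcoef(g.T)[0, 1] == pytest.approx(0.0, abs=1e-12)
        est = ld_ne_point(g, maf=0.0)
        assert est.r2_prime < 0
        assert np.isinf(est.point)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(60, 40))
        est1 = ld_ne_point(g, maf=0.05)
        perm = rng.permutation(40)
        est2 = ld_ne_point(g[:, perm], maf=0.05)
        assert est1.point == pytest.approx(est2.point)
        assert est1.n_pairs == est2.n_pairs

    def test_allele_swap_invariance(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(60, 30))
        flipped = g.copy()
        flipped[:, ::2] = 2 - flipped[:, ::2]
        assert ld_ne_point(g, maf=0.05).point == pytest.approx(
            ld_ne_point(flipped, maf=0.05).point
        )

    def test_same_chromosome_pairs_excluded(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, size=(50, 20))
        chrom = np.repeat([1, 2], 10)
        est = ld_ne_point(g, chrom=chrom, maf=0.0)
        # eligible pairs are only the 10*10 cross-chromosome combinations (at most)
        assert est.n_pairs <= 100

    def test_sample_correction_regimes(self):
        assert _sample_correction(100) == pytest.approx(1 / 100 + 3.19 / 100**2)
        assert _sample_correction(20) == pytest.approx(0.0018 + 0.907 / 20 + 4.44 / 400)

    def test_ci_brackets_point(self):
        rng = np.random.default_rng(7)
        g = _drift_genotypes(200, 100, 60, seed=8)
        poly = (g.sum(axis=0) > 0) & (g.sum(axis=0) < 2 * g.shape[0])
        est = ld_ne_point(g[:, poly], maf=0.05)
        if np.isfinite(est.point):
            assert est.ci_low <= est.point <= est.ci_high


class TestBinPairs:
    def _toy(self, seed=0, m=80, S=40):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(S, m))
        positions = np.sort(rng.choice(5_000_000, size=m, replace=False))
        chrom = np.ones(m, dtype=int)
        return g, positions, chrom

    def test_pairs_within_hc(self):
        g, pos, chrom = self._toy()
        store = bin_pairs(g, pos, chrom, hc=0.05, maf=0.0)
        d = np.abs(pos[store.snp_j] - pos[store.snp_i])
        assert np.all(haldane_c(d) <= 0.05 + 1e-12)

    def test_bin_assignment(self):
        g, pos, chrom = self._toy()
        store = bin_pairs(g, pos, chrom, n_bins=400, hc=0.05, maf=0.0)
        width = 0.05 / 400
        d = np.abs(pos[store.snp_j] - pos[store.snp_i])
        expected_bins = np.minimum((haldane_c(d) / width).astype(int), 399)
        assert np.array_equal(store.bin, expected_bins)

    def test_subsampling_deterministic(self):
        g, pos, chrom = self._toy(m=120)
        a = bin_pairs(g, pos, chrom, max_snps_per_chrom=50, rng=np.random.default_rng(9), maf=0.0)
        b = bin_pairs(g, pos, chrom, max_snps_per_chrom=50, rng=np.random.default_rng(9), maf=0.0)
        assert np.array_equal(a.snp_i, b.snp_i)
        assert np.array_equal(a.r2, b.r2)

    def test_r2_values_match_burrows(self):
        g, pos, chrom = self._toy(m=20)
        store = bin_pairs(g, pos, chrom, maf=0.0)
        for i, j, r2 in zip(store.snp_i[:20], store.snp_j[:20], store.r2[:20]):
            assert r2 == pytest.approx(burrows_r2(g[:, i], g[:, j]), rel=1e-5)


def _synthetic_store(n_per_bin, ne_of_t, S=100, n_bins=400, hc=0.05, seed=0):
    """PairStore whose bin means follow E[r2] = 1/(3+4Nc) + sampling term."""
    rng = np.random.default_rng(seed)
    width = hc / n_bins
    c_mid = (np.arange(n_bins) + 0.5) * width
    bins, r2s = [], []
    corr0 = _sample_correction(S)
    for b, c in enumerate(c_mid):
        ne = ne_of_t(1.0 / (2 * c))
        mean = 1.0 / (3.0 + 4.0 * ne * c) + corr0
        vals = rng.gamma(4.0, mean / 4.0, size=n_per_bin)
        r2s.append(vals)
        bins.append(np.full(n_per_bin, b))
    r2 = np.concatenate(r2s).astype(np.float32)
    bins = np.concatenate(bins).astype(np.int32)
    n = r2.shape[0]
    snp = np.arange(2 * n)
    return PairStore(
        snp_i=snp[:n], snp_j=snp[n:], r2=r2, bin=bins,
        n_bins=n_bins, hc=hc, S=S, n_snps=2 * n,
    )


class TestLdTrajectory:
    def test_flat_for_constant_ne(self):
        store = _synthetic_store(200, lambda t: 1000.0)
        traj = ld_trajectory(store, resamples=1)
        assert traj.ok
        assert traj.ne_c == pytest.approx(1000, rel=0.15)
        assert traj.ne_h == pytest.approx(1000, rel=0.15)

    def test_decline_detected_in_shape(self):
        def ne_of_t(t):
            return 300.0 if t < 40 else 1000.0

        store = _synthetic_store(200, ne_of_t)
        traj = ld_trajectory(store, resamples=1)
        assert traj.ne_c < 0.6 * traj.ne_h

    def test_single_resample_collapses_ci(self):
        store = _synthetic_store(50, lambda t: 500.0)
        traj = ld_trajectory(store, resamples=1)
        assert traj.ne_c_ci == (traj.ne_c, traj.ne_c)
        assert traj.ne_h_ci == (traj.ne_h, traj.ne_h)

    def test_too_few_bins_flagged(self):
        store = _synthetic_store(1, lambda t: 500.0, n_bins=4, seed=3)
        traj = ld_trajectory(store, min_bins=10)
        assert not traj.ok

    def test_generation_mapping(self):
        # hc = 0.05 maps the youngest resolvable bin to ~10 generations
        store = _synthetic_store(50, lambda t: 500.0)
        traj = ld_trajectory(store, resamples=1)
        assert traj.generations.min() == pytest.approx(10.0, rel=0.02)

    def test_resampling_cis_bracket_point(self):
        store = _synthetic_store(100, lambda t: 800.0, seed=5)
        traj = ld_trajectory(store, resamples=20, resample_size=150)
        assert traj.ne_c_ci[0] <= traj.ne_c_ci[1]
        assert traj.ne_h_ci[0] <= traj.ne_h_ci[1]
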