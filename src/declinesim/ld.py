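"""Linkage-disequilibrium estimators of effective population size.

Two estimator families are provided:

* an unlinked-pair single-sample estimator (Burrows composite r-squared with
  the Waples small-sample correction and a delete-one-locus jackknife CI),
  applied per timepoint; and
* a recombination-binned trajectory estimator for whole-genome-like data
  that inverts E[r2] ~ 1/(3 + 4 N c) per distance bin, assigns each bin to
  generation t = 1/(2c), and derives CIs by SNP resampling.

Physical distance is converted to Morgans with a uniform 1 cM/Mb map and to
recombination fractions via Haldane's function c = (1 - exp(-2d))/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeEstimate",
    "NeTrajectory",
    "PairStore",
    "burrows_r2",
    "ld_ne_point",
    "bin_pairs",
    "ld_trajectory",
    "haldane_c",
    "MORGANS_PER_BP",
]

MORGANS_PER_BP = 1e-8  # 1 cM/Mb
INFINITE = np.inf
_EPS_R2 = 1e-6
_MIN_NE = 2.0


def haldane_c(distance_bp: np.ndarray | float, morgans_per_bp: float = MORGANS_PER_BP):
    """Recombination fraction from physical distance via Haldane's map function."""
    d = np.asarray(distance_bp, dtype=float) * morgans_per_bp
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def burrows_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared composite (Burrows) correlation between two unphased loci."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        raise ValueError("monomorphic locus passed to burrows_r2")
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return float(cov * cov / (va * vb))


def _sample_correction(S: int) -> float:
    """Expected composite r2 for unlinked loci in an infinite population."""
    if S >= 30:
        return 1.0 / S + 3.19 / S**2
    return 0.0018 + 0.907 / S + 4.44 / S**2


def _ne_from_unlinked_r2(r2_prime: float, S: int) -> float:
    """Invert the drift expectation of corrected r2 for unlinked pairs."""
    if r2_prime <= 0:
        return INFINITE
    if S >= 30:
        disc = max(1.0 / 9.0 - 2.76 * r2_prime, 0.0)
        ne = (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2_prime)
    else:
        disc = max(0.308**2 - 2.08 * r2_prime, 0.0)
        ne = (0.308 + np.sqrt(disc)) / (2.0 * r2_prime)
    return max(ne, _MIN_NE)


@dataclass
class NeEstimate:
    point: float
    ci_low: float
    ci_high: float
    S: int
    n_pairs: int
    r2_mean: float = np.nan
    r2_prime: float = np.nan
    flag: str = ""

    @property
    def is_infinite(self) -> bool:
        return np.isinf(self.point)


def _standardize(genotypes: np.ndarray) -> np.ndarray:
    g = np.asarray(genotypes, dtype=float)
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = np.nan
    return g / sd


def ld_ne_point(
    genotypes: np.ndarray,
    chrom: np.ndarray | None = None,
    maf: float = 0.05,
    exclude_same_chromosome: bool = True,
    block: int = 2048,
) -> NeEstimate:
    """Single-sample Ne from mean composite r2 across unlinked locus pairs.

    ``genotypes`` is (individuals x loci) diploid dosages; ``chrom`` gives a
    chromosome label per locus (pairs on the same chromosome are excluded by
    default to honour the unlinked assumption).  The jackknife CI deletes one
    locus at a time.
    """
    g = np.asarray(genotypes)
    S = g.shape[0]
    freq = g.sum(axis=0) / (2.0 * S)
    keep = np.minimum(freq, 1 - freq) >= maf
    g = g[:, keep]
    labels = np.asarray(chrom)[keep] if chrom is not None else None
    m = g.shape[1]
    if m < 2:
        return NeEstimate(np.nan, np.nan, np.nan, S, 0, flag="fewer than 2 loci")

    z = _standardize(g)
    r2_total = 0.0
    row_sum = np.zeros(m)
    row_deg = np.zeros(m, dtype=np.int64)
    for a in range(0, m, block):
        b = min(a + block, m)
        corr = (z[:, a:b].T @ z) / S  # (b-a, m)
        r2 = corr * corr
        # mask: only j > i, and optionally different chromosome
        cols = np.arange(m)[None, :]
        rows = np.arange(a, b)[:, None]
        mask = cols > rows
        if exclude_same_chromosome and labels is not None:
            mask &= labels[None, :] != labels[rows]
        vals = np.where(mask, r2, 0.0)
        r2_total += vals.sum()
        # accumulate symmetric row sums/degrees for the jackknife
        row_sum[a:b] += vals.sum(axis=1)
        row_sum += vals.sum(axis=0)
        row_deg[a:b] += mask.sum(axis=1)
        row_deg += mask.sum(axis=0)

    n_pairs = int(row_deg.sum() // 2)
    if n_pairs == 0:
        return NeEstimate(np.nan, np.nan, np.nan, S, 0, flag="no eligible pairs")
    corr0 = _sample_correction(S)
    r2_mean = r2_total / n_pairs
    r2_prime = r2_mean - corr0
    point = _ne_from_unlinked_r2(r2_prime, S)

    # delete-one-locus jackknife on corrected mean r2
    loo_pairs = n_pairs - row_deg
    ok = loo_pairs > 0
    theta_i = np.full(m, r2_prime)
    theta_i[ok] = (r2_total - row_sum[ok]) / loo_pairs[ok] - corr0
    theta_bar = theta_i.mean()
    var_jk = (m - 1) / m * np.sum((theta_i - theta_bar) ** 2)
    half = 1.96 * np.sqrt(var_jk)
    r2p_lo, r2p_hi = r2_prime - half, r2_prime + half
    ci_low = _ne_from_unlinked_r2(r2p_hi, S)  # larger r2 -> smaller Ne
    ci_high = _ne_from_unlinked_r2(r2p_lo, S)
    return NeEstimate(
        point=point,
        ci_low=min(ci_low, point),
        ci_high=max(ci_high, point),
        S=S,
        n_pairs=n_pairs,
        r2_mean=r2_mean,
        r2_prime=r2_prime,
    )


# ---------------------------------------------------------------------------
# Binned-LD trajectory (whole-genome-like data)
# ---------------------------------------------------------------------------

@dataclass
class PairStore:
    """Same-chromosome locus pairs with composite r2 and recombination bins."""

    snp_i: np.ndarray  # global SNP index of first locus
    snp_j: np.ndarray
    r2: np.ndarray
    bin: np.ndarray  # equal-width bin in c over (0, hc]
    n_bins: int
    hc: float
    S: int
    n_snps: int

    @property
    def n_pairs(self) -> int:
        return self.r2.shape[0]

    def bin_c_mid(self) -> np.ndarray:
        width = self.hc / self.n_bins
        return (np.arange(self.n_bins) + 0.5) * width


def bin_pairs(
    genotypes: np.ndarray,
    positions: np.ndarray,
    chrom: np.ndarray,
    n_bins: int = 400,
    hc: float = 0.05,
    max_snps_per_chrom: int = 50_000,
    rng: np.random.Generator | None = None,
    morgans_per_bp: float = MORGANS_PER_BP,
    maf: float = 0.05,
    block: int = 1024,
) -> PairStore:
    """Composite r2 for all same-chromosome pairs with c <= hc, binned in c.

    Loci below ``maf`` are excluded: the Sved-type inversion used downstream
    assumes common variants, and rare alleles systematically depress r2.
    """
    rng = rng or np.random.default_rng(0)
    g = np.asarray(genotypes)
    positions = np.asarray(positions)
    chrom = np.asarray(chrom)
    S = g.shape[0]
    d_max = -np.log(1.0 - 2.0 * hc) / 2.0 / morgans_per_bp

    keep = np.zeros(g.shape[1], dtype=bool)
    for ch in np.unique(chrom):
        idx = np.flatnonzero(chrom == ch)
        if idx.size > max_snps_per_chrom:
            idx = np.sort(rng.choice(idx, size=max_snps_per_chrom, replace=False))
        keep[idx] = True
    freq = g.sum(axis=0) / (2.0 * S)
    minor = np.minimum(freq, 1.0 - freq)
    keep &= (minor > 0) & (minor >= maf)
    sel = np.flatnonzero(keep)

    pi, pj, r2s, bins = [], [], [], []
    width = hc / n_bins
    for ch in np.unique(chrom):
        idx = sel[chrom[sel] == ch]
        if idx.size < 2:
            continue
        order = np.argsort(positions[idx], kind="stable")
        idx = idx[order]
        pos = positions[idx].astype(float)
        z = _standardize(g[:, idx])
        mloc = idx.size
        for a in range(0, mloc, block):
            b = min(a + block, mloc)
            hi = int(np.searchsorted(pos, pos[b - 1] + d_max, side="right"))
            corr = (z[:, a:b].T @ z[:, a:hi]) / S
            r2 = corr * corr
            rows = np.arange(a, b)[:, None]
            cols = np.arange(a, hi)[None, :]
            dist = pos[None, a:hi] - pos[a:b, None]
            mask = (cols > rows) & (dist <= d_max)
            rr, cc = np.nonzero(mask)
            if rr.size == 0:
                continue
            c = haldane_c(dist[rr, cc], morgans_per_bp)
            bin_idx = np.minimum((c / width).astype(np.int64), n_bins - 1)
            pi.append(idx[a + rr])
            pj.append(idx[a + cc])
            r2s.append(r2[rr, cc].astype(np.float32))
            bins.append(bin_idx.astype(np.int32))

    if pi:
        snp_i = np.concatenate(pi)
        snp_j = np.concatenate(pj)
        r2arr = np.concatenate(r2s)
        binarr = np.concatenate(bins)
    else:
        snp_i = snp_j = np.empty(0, dtype=np.int64)
        r2arr = np.empty(0, dtype=np.float32)
        binarr = np.empty(0, dtype=np.int32)
    return PairStore(
        snp_i=snp_i,
        snp_j=snp_j,
        r2=r2arr,
        bin=binarr,
        n_bins=n_bins,
        hc=hc,
        S=S,
        n_snps=int(sel.size),
    )


@dataclass
class NeTrajectory:
    """Recent-Ne trajectory indexed by generations before the sampling time."""

    generations: np.ndarray
    nhat: np.ndarray
    ne_c: float
    ne_h: float
    ne_c_ci: tuple[float, float]
    ne_h_ci: tuple[float, float]
    flag: str = ""

    @property
    def ok(self) -> bool:
        return self.flag == ""


def _moving_median(x: np.ndarray, window: int = 5) -> np.ndarray:
    if x.size == 0:
        return x
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = np.median(x[lo : hi])
    return out


def _trajectory_from_bins(
    mean_r2: np.ndarray,
    counts: np.ndarray,
    c_mid: np.ndarray,
    S: int,
    gen_time: float,
    historic_generations: float,
    min_bins: int,
    window: int = 5,
):
    corr0 = _sample_correction(S)
    r2c = mean_r2 - corr0
    ok = (counts > 0) & (r2c > _EPS_R2)
    if ok.sum() < min_bins:
        return None
    c = c_mid[ok]
    nhat = np.maximum((1.0 / r2c[ok] - 3.0) / (4.0 * c), _MIN_NE)
    nhat = _moving_median(nhat, window)
    gens = 1.0 / (2.0 * c)
    # endpoint reads are medians over narrow generation bands: single bins
    # at the extremes are noisy
    youngest = gens.min()
    young_band = gens <= 1.5 * youngest
    ne_c = float(np.median(nhat[young_band]))
    hist_band = np.abs(np.log(gens / historic_generations)) <= np.log(1.2)
    if not hist_band.any():
        hist_band = np.abs(gens - historic_generations) == np.min(
            np.abs(gens - historic_generations)
        )
    ne_h = float(np.median(nhat[hist_band]))
    return gens, nhat, ne_c, ne_h


def ld_trajectory(
    pairs: PairStore,
    resamples: int = 40,
    resample_size: int = 50_000,
    rng: np.random.Generator | None = None,
    gen_time: float = 1.0,
    historic_ybp: float = 120.0,
    min_bins: int = 10,
    window: int = 5,
) -> NeTrajectory:
    """Per-bin inversion of binned LD into a recent-Ne trajectory with CIs.

    CIs come from re-estimating the trajectory on ``resamples`` random SNP
    subsets of ``resample_size`` (drawn with replacement if fewer SNPs are
    available) and taking 2.5/97.5 percentiles of the endpoint estimates.
    """
    rng = rng or np.random.default_rng(0)
    historic_generations = historic_ybp / gen_time
    c_mid = pairs.bin_c_mid()

    def binned(mask: np.ndarray | None):
        if mask is None:
            w = pairs.r2.astype(float)
            sel = slice(None)
            bins = pairs.bin
        else:
            selpair = mask[pairs.snp_i] & mask[pairs.snp_j]
            bins = pairs.bin[selpair]
            w = pairs.r2[selpair].astype(float)
        counts = np.bincount(bins, minlength=pairs.n_bins)
        sums = np.bincount(bins, weights=w, minlength=pairs.n_bins)
        mean = np.divide(sums, counts, out=np.zeros(pairs.n_bins), where=counts > 0)
        return mean, counts

    mean_r2, counts = binned(None)
    point = _trajectory_from_bins(
        mean_r2, counts, c_mid, pairs.S, gen_time, historic_generations, min_bins, window
    )
    if point is None:
        return NeTrajectory(
            np.empty(0), np.empty(0), np.nan, np.nan,
            (np.nan, np.nan), (np.nan, np.nan), flag="too few usable bins",
        )
    gens, nhat, ne_c, ne_h = point

    snp_ids = np.unique(np.concatenate([pairs.snp_i, pairs.snp_j]))
    ne_c_reps, ne_h_reps = [ne_c], [ne_h]
    if resamples > 1 and snp_ids.size:
        max_id = int(snp_ids.max()) + 1
        for _ in range(resamples):
            if resample_size < snp_ids.size:
                chosen = rng.choice(snp_ids, size=resample_size, replace=False)
            else:
                # fewer SNPs than the nominal resample: subsample a fixed
                # fraction without replacement so the CIs retain the
                # variance of a genuine subsample
                chosen = rng.choice(snp_ids, size=max(2, snp_ids.size // 3), replace=False)
            mask = np.zeros(max_id, dtype=bool)
            mask[chosen] = True
            rep = _trajectory_from_bins(
                *binned(mask), c_mid, pairs.S, gen_time, historic_generations,
                min_bins, window,
            )
            if rep is not None:
                ne_c_reps.append(rep[2])
                ne_h_reps.append(rep[3])
    if len(ne_c_reps) > 1:
        lo_c, hi_c = np.percentile(ne_c_reps[1:], [2.5, 97.5])
        lo_h, hi_h = np.percentile(ne_h_reps[1:], [2.5, 97.5])
    else:
        lo_c = hi_c = ne_c
        lo_h = hi_h = ne_h
    return NeTrajectory(
        generations=gens,
        nhat=nhat,
        ne_c=ne_c,
        ne_h=ne_h,
        ne_c_ci=(float(lo_c), float(hi_c)),
        ne_h_ci=(float(lo_h), float(hi_h)),
    )
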